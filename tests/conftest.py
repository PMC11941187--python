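import numpy as np
import pytest

from conepore.dynamics import AnalysisOptions, EnsembleResult, SimulationConfig
from conepore.geometry import Channel, Spherocylinder

CONE = Channel(L=15.0, R0=0.5, RL=0.25)
CYLINDER = Channel(L=15.0, R0=0.5, RL=0.5)


@pytest.fixture
def cone():
    return CONE


@pytest.fixture
def cylinder():
    return CYLINDER


def make_synthetic_result(
    positions: np.ndarray,
    orientations: np.ndarray | None = None,
    fpt: np.ndarray | None = None,
    sample_times: np.ndarray | None = None,
    channel: Channel = CONE,
) -> EnsembleResult:
    """Wrap externally constructed trajectories (e.g. closed-form walks) in
    an EnsembleResult so the analysis toolchain can be exercised against
    known ground truth.  Occupancy counters are left empty so histograms
    fall back to the pooled recorded samples."""
    positions = np.asarray(positions, dtype=float)
    n, T = positions.shape[:2]
    if orientations is None:
        orientations = np.zeros_like(positions)
        orientations[..., 2] = 1.0
    if sample_times is None:
        sample_times = np.arange(1, T + 1, dtype=np.int64)
    if fpt is None:
        fpt = np.full(n, -1, dtype=np.int64)  # all censored = all surviving
    fpt = np.asarray(fpt, dtype=np.int64)
    max_steps = int(sample_times[-1])
    config = SimulationConfig(
        channel=channel,
        particle=Spherocylinder(l=0.0, r=0.01),
        n_rep=n,
        max_steps=max_steps,
        sample_times=sample_times,
        analysis=AnalysisOptions(),
    )
    return EnsembleResult(
        config=config,
        sample_times=np.asarray(sample_times, dtype=np.int64),
        positions=positions,
        orientations=np.asarray(orientations, dtype=float),
        fpt=fpt,
        censored=fpt < 0,
        accepted_translations=np.zeros(n, dtype=np.int64),
        accepted_rotations=np.zeros(n, dtype=np.int64),
        occ_z=None,
        occ_theta=None,
        occ_stride=0,
        trajectory_seeds=np.arange(n, dtype=np.int64),
        backend="synthetic",
    )
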