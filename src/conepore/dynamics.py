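"""Stochastic kernel of the model: rejection-based Brownian dynamics.

Time is discrete; one step is one translation attempt followed by one
rotation attempt.  The translation proposal adds an isotropic Gaussian
displacement (per-component s.d. ``sigma_x``) to the centre of mass and is
accepted iff the moved body stays clear of the wall and the new centre of
mass is not ejected through the entrance (``z >= 0``).  The rotation draws
a uniform random axis, computes the moment of inertia about it, scales the
Gaussian rotation angle by ``sigma_phi = sigma_x / sqrt(moment)``
(equipartition coupling of translational and rotational noise), and is
accepted iff the rotated body stays clear of the wall.  Time advances by
one per step whether or not the sub-moves were accepted.  A trajectory
terminates when the centre of mass reaches the absorbing plane ``z >= L``;
the step index at which this first happens is the first passage time.

Two interchangeable backends run the same model: a numba-compiled kernel
(default; ~10^7 steps/s) and a pure-Python loop composed of the op-level
functions in this module, kept as an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from . import _kernel
from .geometry import Channel, ParticleState, Spherocylinder, spherocylinder_inside
from .inertia import InertiaModel, moment_about_axis, sigma_phi

__all__ = [
    "SimulationConfig",
    "AnalysisOptions",
    "TrajectoryRecord",
    "EnsembleResult",
    "InfeasibleParticleError",
    "log_sample_times",
    "sample_translation",
    "sample_rotation_axis",
    "rotate_axis_angle",
    "step",
    "initial_state",
    "run_single",
    "run_ensemble",
]


class InfeasibleParticleError(ValueError):
    pass


def log_sample_times(max_steps: int, points_per_decade: int = 200) -> np.ndarray:
    """Approximately log-spaced integer step indices in ``[1, max_steps]``.

    Long runs (10^6+ steps) cannot store every state; a log grid resolves
    the MSD curve equally well per decade with bounded memory.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    n_decades = np.log10(max_steps) if max_steps > 1 else 1.0
    n_pts = max(2, int(np.ceil(points_per_decade * max(n_decades, 0.1))))
    grid = np.unique(np.round(np.logspace(0.0, np.log10(max_steps), n_pts)).astype(np.int64))
    return grid[(grid >= 1) & (grid <= max_steps)]


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the analysis stage (fit bands and histogram binning)."""

    survival_band: tuple[float, float] = (0.01, 0.9)
    n_theta_bins: int = 90
    n_z_bins: int = 60
    points_per_decade: int = 200


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one ensemble run.

    ``sample_times`` (log-spaced by default) controls where trajectory
    states are recorded for the MSD; occupancy statistics (position and
    orientation histograms) instead use a linear-stride channel
    (``occ_stride``) accumulated into fine fixed grids, so that they
    estimate fractions of *time* without log-grid weighting bias.
    """

    channel: Channel
    particle: Spherocylinder
    sigma_x: float = 0.05
    n_rep: int = 1000
    seed: int = 0
    max_steps: int = 50_000_000
    sample_times: np.ndarray | None = None
    occ_stride: int = 8
    n_occ_z_bins: int = 600
    n_occ_theta_bins: int = 720
    axial_start: bool = False
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def __post_init__(self) -> None:
        if self.sigma_x <= 0:
            raise ValueError(f"sigma_x must be positive, got {self.sigma_x}")
        if self.n_rep < 1 or self.max_steps < 1:
            raise ValueError("n_rep and max_steps must be >= 1")
        if self.particle.r >= self.channel.RL:
            raise InfeasibleParticleError(
                f"particle radius r={self.particle.r} must be smaller than the "
                f"exit radius RL={self.channel.RL}"
            )
        if self.sample_times is None:
            object.__setattr__(
                self,
                "sample_times",
                log_sample_times(self.max_steps, self.analysis.points_per_decade),
            )
        else:
            st = np.asarray(self.sample_times, dtype=np.int64)
            if st.size and (np.any(np.diff(st) <= 0) or st[0] < 1 or st[-1] > self.max_steps):
                raise ValueError("sample_times must be strictly increasing within [1, max_steps]")
            object.__setattr__(self, "sample_times", st)

    @property
    def inertia(self) -> InertiaModel:
        return _inertia_model(self.particle.l, self.particle.r)


@lru_cache(maxsize=128)
def _inertia_model(l: float, r: float) -> InertiaModel:
    return InertiaModel.from_shape(l, r)


@dataclass
class TrajectoryRecord:
    """States sampled along one trajectory plus its first passage time."""

    sample_times: np.ndarray
    positions: np.ndarray      # (n_samples, 3); NaN after absorption
    orientations: np.ndarray   # (n_samples, 3); NaN after absorption
    fpt: int | None            # None when censored at max_steps
    censored: bool
    accepted_translations: int
    accepted_rotations: int

    def state_at(self, index: int) -> ParticleState:
        return ParticleState(c=self.positions[index], u=self.orientations[index])


@dataclass
class EnsembleResult:
    """Stacked per-trajectory samples, first passage times and pooled
    occupancy counts for an ensemble of independent trajectories."""

    config: SimulationConfig
    sample_times: np.ndarray          # (T,)
    positions: np.ndarray             # (n_rep, T, 3)
    orientations: np.ndarray          # (n_rep, T, 3)
    fpt: np.ndarray                   # (n_rep,) int64; -1 = censored
    censored: np.ndarray              # (n_rep,) bool
    accepted_translations: np.ndarray
    accepted_rotations: np.ndarray
    occ_z: np.ndarray | None          # pooled pre-absorption counts
    occ_theta: np.ndarray | None
    occ_stride: int
    trajectory_seeds: np.ndarray
    backend: str

    @property
    def n_rep(self) -> int:
        return self.fpt.shape[0]

    @property
    def absorbed_fpts(self) -> np.ndarray:
        return self.fpt[self.fpt >= 0]

    @property
    def censored_fraction(self) -> float:
        return float(np.mean(self.censored))

    def trajectory(self, i: int) -> TrajectoryRecord:
        f = int(self.fpt[i])
        return TrajectoryRecord(
            sample_times=self.sample_times,
            positions=self.positions[i],
            orientations=self.orientations[i],
            fpt=None if f < 0 else f,
            censored=bool(self.censored[i]),
            accepted_translations=int(self.accepted_translations[i]),
            accepted_rotations=int(self.accepted_rotations[i]),
        )


# ---------------------------------------------------------------------------
# op-level reference implementations (pure Python / numpy)
# ---------------------------------------------------------------------------

def sample_translation(rng: np.random.Generator, sigma_x: float) -> np.ndarray:
    """Translation proposal: three independent N(0, sigma_x) components."""
    if sigma_x == 0.0:
        return np.zeros(3)
    return rng.normal(0.0, sigma_x, size=3)


def sample_rotation_axis(rng: np.random.Generator) -> np.ndarray:
    """Uniform random direction: normalized Gaussian triple (resampled on
    numerical underflow of the norm)."""
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n >= 1e-12:
            return v / n


def rotate_axis_angle(u: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``u`` about the unit ``axis`` (right-handed),
    renormalized to unit length."""
    u = np.asarray(u, dtype=float)
    axis = np.asarray(axis, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    out = u * c + np.cross(axis, u) * s + axis * np.dot(axis, u) * (1.0 - c)
    return out / np.linalg.norm(out)


def step(
    state: ParticleState, config: SimulationConfig, rng: np.random.Generator
) -> tuple[ParticleState, bool]:
    """One time step: translation attempt, then rotation attempt.

    Rejected sub-moves leave position/orientation unchanged; the rotation
    is attempted regardless of the translation outcome.  Returns the new
    state and whether the centre of mass has reached the absorbing plane.
    """
    ch, p = config.channel, config.particle
    model = config.inertia

    c_new = state.c + sample_translation(rng, config.sigma_x)
    cand = ParticleState(c=c_new, u=state.u)
    if c_new[2] >= 0.0 and spherocylinder_inside(ch, p, cand):
        state = cand

    axis = sample_rotation_axis(rng)
    moment = moment_about_axis(model, float(np.dot(axis, state.u)))
    angle = sigma_phi(config.sigma_x, moment) * rng.standard_normal()
    u_new = rotate_axis_angle(state.u, axis, angle)
    cand = ParticleState(c=state.c, u=u_new)
    if spherocylinder_inside(ch, p, cand):
        state = cand

    return state, bool(state.c[2] >= ch.L)


def initial_state(config: SimulationConfig, rng: np.random.Generator) -> ParticleState:
    """Insertion at the wide end: centre of mass at the origin, orientation
    uniform over feasible directions (rejection sampling against the
    extrapolated wall), or axis-aligned if ``axial_start``."""
    origin = np.zeros(3)
    if config.axial_start:
        st = ParticleState(c=origin, u=np.array([0.0, 0.0, 1.0]))
        if not spherocylinder_inside(config.channel, config.particle, st):
            raise InfeasibleParticleError("axial start does not fit the channel")
        return st
    for _ in range(1_000_000):
        st = ParticleState(c=origin, u=sample_rotation_axis(rng))
        if spherocylinder_inside(config.channel, config.particle, st):
            return st
    raise InfeasibleParticleError("no feasible initial orientation found in 10^6 draws")


def run_single(
    config: SimulationConfig,
    rng: np.random.Generator,
    occ_z: np.ndarray | None = None,
    occ_theta: np.ndarray | None = None,
) -> TrajectoryRecord:
    """Pure-Python trajectory driver (reference backend)."""
    st = initial_state(config, rng)
    times = config.sample_times
    T = times.shape[0]
    pos = np.full((T, 3), np.nan)
    ori = np.full((T, 3), np.nan)
    si = 0
    acc_t = 0
    acc_r = 0
    L = config.channel.L
    for t in range(1, config.max_steps + 1):
        prev_c, prev_u = st.c, st.u
        st, absorbed = step(st, config, rng)
        if st.c is not prev_c:
            acc_t += 1
        if st.u is not prev_u:
            acc_r += 1
        if si < T and t == times[si]:
            pos[si] = st.c
            ori[si] = st.u
            si += 1
        if (not absorbed) and occ_z is not None and config.occ_stride > 0 and t % config.occ_stride == 0:
            iz = int(st.c[2] / L * occ_z.shape[0])
            if 0 <= iz < occ_z.shape[0]:
                occ_z[iz] += 1
            th = np.arccos(min(abs(st.u[2]), 1.0))
            ith = min(int(th / (0.5 * np.pi) * occ_theta.shape[0]), occ_theta.shape[0] - 1)
            occ_theta[ith] += 1
        if absorbed:
            return TrajectoryRecord(times, pos, ori, t, False, acc_t, acc_r)
    return TrajectoryRecord(times, pos, ori, None, True, acc_t, acc_r)


# ---------------------------------------------------------------------------
# ensemble driver
# ---------------------------------------------------------------------------

def run_ensemble(config: SimulationConfig, backend: str = "numba") -> EnsembleResult:
    """Run ``config.n_rep`` independent trajectories.

    Each trajectory uses its own deterministic RNG substream derived from
    ``config.seed``, so results are bit-for-bit reproducible and do not
    depend on execution order.
    """
    n = config.n_rep
    times = config.sample_times
    T = times.shape[0]
    positions = np.full((n, T, 3), np.nan)
    orientations = np.full((n, T, 3), np.nan)
    fpt = np.empty(n, dtype=np.int64)
    acc_t = np.empty(n, dtype=np.int64)
    acc_r = np.empty(n, dtype=np.int64)
    occ_z = np.zeros(config.n_occ_z_bins, dtype=np.int64)
    occ_theta = np.zeros(config.n_occ_theta_bins, dtype=np.int64)
    seeds = _kernel.trajectory_seeds(config.seed, n)

    if backend == "numba":
        ch, p = config.channel, config.particle
        model = config.inertia
        for i in range(n):
            f, at, ar = _kernel.run_trajectory(
                _kernel.xoshiro_state(int(seeds[i])),
                ch.L,
                ch.R0,
                ch.slope,
                p.half_length,
                p.r,
                config.sigma_x,
                model.Mxx,
                model.Mzz,
                config.axial_start,
                config.max_steps,
                times,
                config.occ_stride,
                occ_z,
                occ_theta,
                positions[i],
                orientations[i],
            )
            if f == -2:
                raise InfeasibleParticleError(
                    "no feasible initial orientation found in 10^6 draws"
                )
            fpt[i] = f
            acc_t[i] = at
            acc_r[i] = ar
    elif backend == "python":
        for i in range(n):
            rng = np.random.default_rng(int(seeds[i]))
            rec = run_single(config, rng, occ_z=occ_z, occ_theta=occ_theta)
            fpt[i] = -1 if rec.fpt is None else rec.fpt
            positions[i] = rec.positions
            orientations[i] = rec.orientations
            acc_t[i] = rec.accepted_translations
            acc_r[i] = rec.accepted_rotations
    else:
        raise ValueError(f"unknown backend {backend!r}")

    return EnsembleResult(
        config=config,
        sample_times=times,
        positions=positions,
        orientations=orientations,
        fpt=fpt,
        censored=fpt < 0,
        accepted_translations=acc_t,
        accepted_rotations=acc_r,
        occ_z=occ_z,
        occ_theta=occ_theta,
        occ_stride=config.occ_stride,
        trajectory_seeds=seeds,
        backend=backend,
    )


def with_particle(config: SimulationConfig, l: float, r: float, seed: int | None = None) -> SimulationConfig:
    """Copy of ``config`` with a different particle (and optionally seed)."""
    kwargs = {"particle": Spherocylinder(l=l, r=r)}
    if seed is not None:
        kwargs["seed"] = seed
    return replace(config, **kwargs)
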