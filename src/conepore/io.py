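"""Configuration parsing, scan orchestration and result serialization.

Run configurations are YAML documents with sections ``channel``,
``particle``, ``noise``, ``run`` and ``analysis``; unknown keys are
rejected.  Outputs are plain CSV tables plus a JSON manifest carrying the
configuration echo, code version, seed and SHA-256 checksums of every file
written, which together suffice to reproduce a run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._kernel import mix_seed
from .analysis import (
    CensoringError,
    InsufficientDataError,
    NoAbsorptionError,
    ensemble_msd,
    entropic_force,
    find_tmin,
    fit_exponential,
    fit_power_law,
    fpt_median,
    orientation_histogram,
    position_histogram,
    survival_curve,
)
from .dynamics import (
    AnalysisOptions,
    EnsembleResult,
    InfeasibleParticleError,
    SimulationConfig,
    run_ensemble,
    with_particle,
)
from .geometry import Channel, Spherocylinder

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "analyze_ensemble",
    "write_results",
    "run_scan",
    "save_ensemble",
    "load_ensemble",
]

_SCHEMA = {
    "channel": {"L", "R0", "RL"},
    "particle": {"l", "r"},
    "noise": {"sigma_x"},
    "run": {"n_rep", "seed", "max_steps", "sample_times", "occ_stride", "axial_start"},
    "analysis": {"survival_band", "n_theta_bins", "n_z_bins", "points_per_decade"},
}


class ConfigError(ValueError):
    pass


def load_config(path) -> SimulationConfig:
    """Parse and validate a YAML run configuration.

    Channel and noise defaults follow the reference setup (L=15, R0=0.5,
    RL=0.25, sigma_x=0.05, n_rep=1000); the particle block is mandatory
    since there is no natural default particle.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping of sections")
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> SimulationConfig:
    for section, keys in doc.items():
        if section not in _SCHEMA:
            raise ConfigError(f"unknown configuration section {section!r}")
        if keys is None:
            continue
        unknown = set(keys) - _SCHEMA[section]
        if unknown:
            raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")

    ch = doc.get("channel") or {}
    channel = Channel(L=ch.get("L", 15.0), R0=ch.get("R0", 0.5), RL=ch.get("RL", 0.25))

    pt = doc.get("particle")
    if not pt or "r" not in pt:
        raise ConfigError("a 'particle' section with at least 'r' is required")
    particle = Spherocylinder(l=pt.get("l", 0.0), r=pt["r"])

    an = doc.get("analysis") or {}
    band = an.get("survival_band")
    analysis = AnalysisOptions(
        survival_band=tuple(band) if band is not None else (0.01, 0.9),
        n_theta_bins=an.get("n_theta_bins", 90),
        n_z_bins=an.get("n_z_bins", 60),
        points_per_decade=an.get("points_per_decade", 200),
    )

    run = doc.get("run") or {}
    noise = doc.get("noise") or {}
    st = run.get("sample_times")
    return SimulationConfig(
        channel=channel,
        particle=particle,
        sigma_x=noise.get("sigma_x", 0.05),
        n_rep=run.get("n_rep", 1000),
        seed=run.get("seed", 0),
        max_steps=run.get("max_steps", 50_000_000),
        sample_times=None if st is None else np.asarray(st, dtype=np.int64),
        occ_stride=run.get("occ_stride", 8),
        axial_start=run.get("axial_start", False),
        analysis=analysis,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return {
        "channel": {
            "L": config.channel.L,
            "R0": config.channel.R0,
            "RL": config.channel.RL,
        },
        "particle": {"l": config.particle.l, "r": config.particle.r},
        "noise": {"sigma_x": config.sigma_x},
        "run": {
            "n_rep": config.n_rep,
            "seed": config.seed,
            "max_steps": config.max_steps,
            "sample_times": [int(t) for t in config.sample_times],
            "occ_stride": config.occ_stride,
            "axial_start": config.axial_start,
        },
        "analysis": {
            "survival_band": list(config.analysis.survival_band),
            "n_theta_bins": config.analysis.n_theta_bins,
            "n_z_bins": config.analysis.n_z_bins,
            "points_per_decade": config.analysis.points_per_decade,
        },
    }


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# analysis pipeline
# ---------------------------------------------------------------------------

def analyze_ensemble(result: EnsembleResult) -> dict:
    """Run the full analysis toolchain on one ensemble.

    Returns a dict of tidy DataFrames (``msd``, ``fits``, ``fpt``,
    ``hist_theta``, ``hist_z``, ``force_z``).  Quantifiers that are
    undefined for the ensemble at hand (no absorption, heavy censoring)
    are reported as NaN rather than aborting the pipeline.
    """
    opts = result.config.analysis
    curve = ensemble_msd(result)
    msd_df = pd.DataFrame({"t": curve.times, "msd": curve.msd, "n_alive": curve.n_alive})

    fits: dict[str, float] = {
        "D": np.nan, "alpha": np.nan, "alpha_loglog": np.nan,
        "t_min": np.nan, "msd_window_lo": np.nan, "msd_window_hi": np.nan,
        "median_fpt": np.nan, "A": np.nan, "lambda": np.nan,
        "survival_r2": np.nan, "survival_window_lo": np.nan,
        "survival_window_hi": np.nan,
        "censored_fraction": result.censored_fraction,
        "n_rep": result.n_rep,
    }
    try:
        tmin = find_tmin(result)
        fits["t_min"] = tmin
        pl = fit_power_law(curve, tmin)
        fits.update(D=pl.D, alpha=pl.alpha, alpha_loglog=pl.alpha_loglog,
                    msd_window_lo=pl.window[0], msd_window_hi=pl.window[1])
    except (NoAbsorptionError, InsufficientDataError):
        pass
    try:
        fits["median_fpt"] = fpt_median(result)
    except (NoAbsorptionError, CensoringError):
        pass

    absorbed = result.absorbed_fpts
    if absorbed.size >= 5:
        t_hi = int(absorbed.max())
        t_grid = np.unique(np.round(np.logspace(0, np.log10(t_hi), 400)).astype(np.int64))
        S = survival_curve(result, t_grid)
        try:
            sf = fit_exponential(S, t_grid, band=opts.survival_band, t_max=t_hi)
            fits.update(A=sf.A, **{"lambda": sf.lam}, survival_r2=sf.r_squared,
                        survival_window_lo=sf.window[0], survival_window_hi=sf.window[1])
        except InsufficientDataError:
            pass

    fits_df = pd.DataFrame([fits])

    fpt_df = pd.DataFrame(
        {
            "trajectory": np.arange(result.n_rep),
            "fpt": result.fpt,
            "censored": result.censored,
            "accepted_translations": result.accepted_translations,
            "accepted_rotations": result.accepted_rotations,
        }
    )

    th = orientation_histogram(result, opts.n_theta_bins)
    theta_df = pd.DataFrame(
        {
            "theta_lo": th.edges[:-1],
            "theta_hi": th.edges[1:],
            "density": th.density,
            "density_sine_corrected": th.density_sine_corrected,
        }
    )

    hz = position_histogram(result, opts.n_z_bins)
    z_df = pd.DataFrame({"z_lo": hz.edges[:-1], "z_hi": hz.edges[1:], "density": hz.density})

    centers = 0.5 * (hz.edges[:-1] + hz.edges[1:])
    try:
        force = entropic_force(hz)
    except Exception:
        force = np.full_like(centers, np.nan)
    force_df = pd.DataFrame({"z": centers, "entropic_force": force})

    return {
        "msd": msd_df,
        "fits": fits_df,
        "fpt": fpt_df,
        "hist_theta": theta_df,
        "hist_z": z_df,
        "force_z": force_df,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(result: EnsembleResult, analyses: dict, outdir) -> dict:
    """Write the analysis tables and a JSON manifest; returns the manifest."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, df in analyses.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        files[path.name] = _sha256(path)
    manifest = {
        "version": __version__,
        "seed": result.config.seed,
        "backend": result.backend,
        "n_trajectories": result.n_rep,
        "censored_fraction": result.censored_fraction,
        "written_at_unix": time.time(),
        "config": config_to_dict(result.config),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def run_scan(
    base_config: SimulationConfig,
    l_values,
    r_values,
    backend: str = "numba",
) -> pd.DataFrame:
    """Run an (l, r) parameter grid and summarize each cell in one row.

    Each cell gets an independent deterministic seed derived from the base
    seed and the cell index, so results do not depend on execution order.
    Infeasible cells (r >= RL) are flagged and skipped.
    """
    l_values = list(l_values)
    r_values = list(r_values)
    rows = []
    for i, l in enumerate(l_values):
        for j, r in enumerate(r_values):
            cell_seed = mix_seed(base_config.seed, 1_000_003 * (i * len(r_values) + j) + 7)
            row: dict = {"l": l, "r": r, "seed": cell_seed, "feasible": True}
            try:
                cfg = with_particle(base_config, l=l, r=r, seed=cell_seed)
            except (InfeasibleParticleError, ValueError):
                row["feasible"] = False
                rows.append(row)
                continue
            result = run_ensemble(cfg, backend=backend)
            fits = analyze_ensemble(result)["fits"].iloc[0].to_dict()
            row.update(fits)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raw-ensemble round trip
# ---------------------------------------------------------------------------

def save_ensemble(result: EnsembleResult, outdir) -> None:
    """Serialize a raw ensemble (samples + FPTs + occupancy) as CSV/YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(result.config, outdir / "config.yaml")

    n, T = result.positions.shape[:2]
    traj = np.repeat(np.arange(n), T)
    t = np.tile(result.sample_times, n)
    flat_p = result.positions.reshape(-1, 3)
    flat_o = result.orientations.reshape(-1, 3)
    keep = np.isfinite(flat_p[:, 0])
    pd.DataFrame(
        {
            "trajectory": traj[keep],
            "t": t[keep],
            "x": flat_p[keep, 0],
            "y": flat_p[keep, 1],
            "z": flat_p[keep, 2],
            "ux": flat_o[keep, 0],
            "uy": flat_o[keep, 1],
            "uz": flat_o[keep, 2],
        }
    ).to_csv(outdir / "samples.csv", index=False, float_format="%.17g")

    pd.DataFrame(
        {
            "trajectory": np.arange(n),
            "fpt": result.fpt,
            "censored": result.censored,
            "accepted_translations": result.accepted_translations,
            "accepted_rotations": result.accepted_rotations,
            "seed": result.trajectory_seeds,
        }
    ).to_csv(outdir / "fpt.csv", index=False)

    occ = pd.DataFrame(
        {
            "occ_z": result.occ_z if result.occ_z is not None else [],
        }
    )
    occ.to_csv(outdir / "occupancy_z.csv", index=False)
    pd.DataFrame(
        {"occ_theta": result.occ_theta if result.occ_theta is not None else []}
    ).to_csv(outdir / "occupancy_theta.csv", index=False)
    with open(outdir / "meta.json", "w") as fh:
        json.dump({"backend": result.backend, "occ_stride": result.occ_stride}, fh)


def load_ensemble(indir) -> EnsembleResult:
    """Inverse of :func:`save_ensemble`."""
    indir = Path(indir)
    config = load_config(indir / "config.yaml")
    fpt_df = pd.read_csv(indir / "fpt.csv")
    n = len(fpt_df)
    times = config.sample_times
    T = times.shape[0]
    positions = np.full((n, T, 3), np.nan)
    orientations = np.full((n, T, 3), np.nan)
    samples = pd.read_csv(indir / "samples.csv", float_precision="round_trip")
    ti = np.searchsorted(times, samples["t"].to_numpy())
    tr = samples["trajectory"].to_numpy()
    positions[tr, ti] = samples[["x", "y", "z"]].to_numpy()
    orientations[tr, ti] = samples[["ux", "uy", "uz"]].to_numpy()
    occ_z = pd.read_csv(indir / "occupancy_z.csv")["occ_z"].to_numpy(dtype=np.int64)
    occ_theta = pd.read_csv(indir / "occupancy_theta.csv")["occ_theta"].to_numpy(dtype=np.int64)
    with open(indir / "meta.json") as fh:
        meta = json.load(fh)
    fpt = fpt_df["fpt"].to_numpy(dtype=np.int64)
    return EnsembleResult(
        config=config,
        sample_times=times,
        positions=positions,
        orientations=orientations,
        fpt=fpt,
        censored=fpt < 0,
        accepted_translations=fpt_df["accepted_translations"].to_numpy(dtype=np.int64),
        accepted_rotations=fpt_df["accepted_rotations"].to_numpy(dtype=np.int64),
        occ_z=occ_z if occ_z.size else None,
        occ_theta=occ_theta if occ_theta.size else None,
        occ_stride=meta["occ_stride"],
        trajectory_seeds=fpt_df["seed"].to_numpy(dtype=np.int64),
        backend=meta["backend"],
    )
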