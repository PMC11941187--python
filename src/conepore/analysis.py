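"""Diffusion quantifiers for ensembles of channel trajectories.

* survivor-averaged mean squared displacement and the power-law fit
  ``<x^2(t)> = D t^alpha`` over the window ``[0.01 t_min, t_min]``, where
  ``t_min`` is the first passage time of the fastest tracer (so no point in
  the window is affected by absorption);
* median first passage time (robust against the heavy right tail);
* survival probability ``S(t)`` and its exponential fit ``A exp(-lambda t)``
  over a configurable band of ``S`` values;
* occupation histograms of axial position ``f(z)`` and orientation angle
  ``p(theta)`` (the director is unsigned, so ``theta = arccos|u_z|`` is
  folded into ``[0, pi/2]``);
* the entropic-force profile ``F_S(z) ~ d ln f / dz``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .dynamics import EnsembleResult

__all__ = [
    "MsdCurve",
    "PowerLawFit",
    "SurvivalFit",
    "PositionHistogram",
    "OrientationHistogram",
    "NoAbsorptionError",
    "InsufficientDataError",
    "CensoringError",
    "UndefinedForceError",
    "ensemble_msd",
    "find_tmin",
    "fit_power_law",
    "fpt_median",
    "survival_curve",
    "fit_exponential",
    "orientation_histogram",
    "position_histogram",
    "entropic_force",
]


class NoAbsorptionError(RuntimeError):
    pass


class InsufficientDataError(RuntimeError):
    pass


class CensoringError(RuntimeError):
    pass


class UndefinedForceError(RuntimeError):
    pass


@dataclass
class MsdCurve:
    times: np.ndarray
    msd: np.ndarray
    n_alive: np.ndarray


@dataclass
class PowerLawFit:
    D: float
    alpha: float
    window: tuple[float, float]
    residual_norm: float
    alpha_loglog: float  # log-log regression estimate, kept for transparency


@dataclass
class SurvivalFit:
    A: float
    lam: float
    window: tuple[float, float]
    r_squared: float


@dataclass
class PositionHistogram:
    edges: np.ndarray
    density: np.ndarray
    count: int


@dataclass
class OrientationHistogram:
    edges: np.ndarray
    density: np.ndarray
    count: int
    density_sine_corrected: np.ndarray | None = None
    """``density / sin(theta)`` renormalized: the density relative to the
    isotropic (uniform-director) measure."""


def ensemble_msd(result: EnsembleResult) -> MsdCurve:
    """Survivor-averaged MSD ``<|x(t) - x(0)|^2>``.

    Trajectories start at the origin.  A tracer that has been absorbed by
    time ``t`` no longer contributes at ``t`` (survivor averaging);
    censored trajectories contribute up to the step cap.  Times with no
    survivors are omitted.
    """
    times = result.sample_times
    # alive at t: not yet absorbed (fpt > t); censored trajectories have
    # fpt == -1 and survive through max_steps
    fpt_eff = np.where(result.censored, np.iinfo(np.int64).max, result.fpt)
    alive = fpt_eff[:, None] > times[None, :]
    sq = np.einsum("ijk,ijk->ij", result.positions, result.positions)
    with np.errstate(invalid="ignore"):
        sq = np.where(alive, sq, np.nan)
    n_alive = alive.sum(axis=0)
    keep = n_alive > 0
    msd = np.full(times.shape, np.nan)
    msd[keep] = np.nanmean(sq[:, keep], axis=0)
    return MsdCurve(times=times[keep], msd=msd[keep], n_alive=n_alive[keep])


def find_tmin(result: EnsembleResult) -> int:
    """First passage time of the fastest tracer (censored runs excluded)."""
    absorbed = result.absorbed_fpts
    if absorbed.size == 0:
        raise NoAbsorptionError("no trajectory was absorbed; cannot define t_min")
    return int(absorbed.min())


def fit_power_law(curve: MsdCurve, t_min: float) -> PowerLawFit:
    """Least-squares fit of ``msd = D t^alpha`` over ``[0.01 t_min, t_min]``.

    The fit is nonlinear least squares in linear space, initialized from a
    log-log linear regression (whose exponent is also reported).
    """
    lo, hi = 0.01 * t_min, t_min
    mask = (curve.times >= lo) & (curve.times <= hi) & np.isfinite(curve.msd) & (curve.msd > 0)
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} MSD points in the fit window [{lo}, {hi}]"
        )
    t = curve.times[mask].astype(float)
    y = curve.msd[mask]
    slope, intercept = np.polyfit(np.log(t), np.log(y), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, _ = curve_fit(lambda tt, D, a: D * tt**a, t, y, p0=p0, maxfev=20000)
    resid = float(np.linalg.norm(popt[0] * t ** popt[1] - y))
    return PowerLawFit(
        D=float(popt[0]),
        alpha=float(popt[1]),
        window=(lo, hi),
        residual_norm=resid,
        alpha_loglog=float(slope),
    )


def fpt_median(result: EnsembleResult, max_censored_fraction: float = 0.10) -> float:
    """Sample median of the non-censored first passage times.

    Raises :class:`CensoringError` when more than ``max_censored_fraction``
    of the ensemble hit the step cap, since the median of the observed
    passages would then be biased low.
    """
    absorbed = result.absorbed_fpts
    if absorbed.size == 0:
        raise NoAbsorptionError("no trajectory was absorbed; median undefined")
    frac = result.censored_fraction
    if frac > max_censored_fraction:
        raise CensoringError(
            f"censored fraction {frac:.2%} exceeds {max_censored_fraction:.0%}; "
            "median would be biased — raise max_steps"
        )
    return float(np.median(absorbed))


def survival_curve(result: EnsembleResult, t_grid: np.ndarray) -> np.ndarray:
    """``S(t)``: fraction of trajectories still in the channel at time t.

    Censored trajectories count as surviving (valid for ``t`` up to the
    step cap).
    """
    t_grid = np.asarray(t_grid)
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    fpt_eff = np.where(result.censored, np.iinfo(np.int64).max, result.fpt)
    return np.mean(fpt_eff[:, None] > t_grid[None, :], axis=0)


def fit_exponential(
    S: np.ndarray,
    t_grid: np.ndarray,
    band: tuple[float, float] = (0.01, 0.9),
    t_max: float | None = None,
) -> SurvivalFit:
    """Log-linear least squares of ``S(t) = A exp(-lambda t)``.

    Only grid points with ``S`` inside ``band`` enter the fit: the band
    excludes the early non-exponential transient (high ``S``) and the noisy
    tail (low ``S``).  ``t_max`` (e.g. the largest observed passage time)
    optionally truncates the grid so a censoring plateau cannot bias the
    rate.
    """
    S = np.asarray(S, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    lo, hi = band
    mask = (S >= lo) & (S <= hi) & (S > 0)
    if t_max is not None:
        mask &= t_grid <= t_max
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"only {int(mask.sum())} survival points inside the band {band}"
        )
    reg = linregress(t_grid[mask], np.log(S[mask]))
    return SurvivalFit(
        A=float(np.exp(reg.intercept)),
        lam=float(-reg.slope),
        window=(float(t_grid[mask].min()), float(t_grid[mask].max())),
        r_squared=float(reg.rvalue**2),
    )


def _pooled_preabsorption_mask(result: EnsembleResult) -> np.ndarray:
    fpt_eff = np.where(result.censored, np.iinfo(np.int64).max, result.fpt)
    return fpt_eff[:, None] > result.sample_times[None, :]


def _rebin(counts: np.ndarray, n_bins: int) -> np.ndarray:
    if counts.shape[0] % n_bins != 0:
        raise ValueError(
            f"n_bins={n_bins} must divide the stored occupancy resolution "
            f"({counts.shape[0]} bins)"
        )
    return counts.reshape(n_bins, -1).sum(axis=1)


def orientation_histogram(result: EnsembleResult, n_bins: int = 90) -> OrientationHistogram:
    """Density of the folded orientation angle ``theta = arccos|u_z|`` over
    ``[0, pi/2]``, pooled over pre-absorption states.

    Uses the linear-stride occupancy counts accumulated during the run when
    available (unbiased in time); otherwise pools the recorded samples.
    Both the raw density and the sine-corrected density (relative to the
    isotropic director measure) are returned.
    """
    edges = np.linspace(0.0, np.pi / 2, n_bins + 1)
    if result.occ_theta is not None and result.occ_theta.sum() > 0:
        counts = _rebin(result.occ_theta, n_bins).astype(float)
    else:
        alive = _pooled_preabsorption_mask(result)
        uz = result.orientations[..., 2][alive]
        uz = uz[np.isfinite(uz)]
        theta = np.arccos(np.minimum(np.abs(uz), 1.0))
        counts, _ = np.histogram(theta, bins=edges)
        counts = counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError("no orientation observations to histogram")
    width = edges[1] - edges[0]
    density = counts / (total * width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    corrected = density / np.sin(centers)
    norm = np.sum(corrected) * width
    corrected = corrected / norm if norm > 0 else corrected
    return OrientationHistogram(
        edges=edges,
        density=density,
        count=int(total),
        density_sine_corrected=corrected,
    )


def position_histogram(result: EnsembleResult, n_bins: int = 60) -> PositionHistogram:
    """Occupation density ``f(z)`` of the centre-of-mass axial position over
    ``[0, L]``, pooled over pre-absorption states.

    The fraction of time spent at ``z`` estimates the probability density
    ``p(z)`` of finding the tracer there.
    """
    L = result.config.channel.L
    edges = np.linspace(0.0, L, n_bins + 1)
    if result.occ_z is not None and result.occ_z.sum() > 0:
        counts = _rebin(result.occ_z, n_bins).astype(float)
    else:
        alive = _pooled_preabsorption_mask(result)
        z = result.positions[..., 2][alive]
        z = z[np.isfinite(z)]
        counts, _ = np.histogram(z, bins=edges)
        counts = counts.astype(float)
    total = counts.sum()
    if total == 0:
        raise InsufficientDataError("no position observations to histogram")
    width = edges[1] - edges[0]
    return PositionHistogram(edges=edges, density=counts / (total * width), count=int(total))


def entropic_force(hist: PositionHistogram) -> np.ndarray:
    """Entropic-force profile ``F_S(z) = d ln f / dz`` at the bin centres.

    Central finite differences in the interior, one-sided at the edges;
    the proportionality constant is set to 1.  Zero density in an interior
    bin leaves the derivative undefined and raises
    :class:`UndefinedForceError`.
    """
    f = np.asarray(hist.density, dtype=float)
    if f.shape[0] < 3:
        raise InsufficientDataError("need at least 3 bins for a force profile")
    if np.any(f[1:-1] <= 0):
        bad = np.nonzero(f[1:-1] <= 0)[0] + 1
        raise UndefinedForceError(f"zero density in interior bin(s) {bad.tolist()}")
    if f[0] <= 0 or f[-1] <= 0:
        raise UndefinedForceError("zero density in an edge bin")
    lnf = np.log(f)
    dz = hist.edges[1] - hist.edges[0]
    force = np.empty_like(lnf)
    force[1:-1] = (lnf[2:] - lnf[:-2]) / (2.0 * dz)
    force[0] = (lnf[1] - lnf[0]) / dz
    force[-1] = (lnf[-1] - lnf[-2]) / dz
    return force
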