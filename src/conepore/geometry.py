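"""Conical-channel geometry and spherocylinder containment tests.

The channel is an axisymmetric pore whose radius varies linearly from ``R0``
at the wide end (``z = 0``, reflecting) to ``RL`` at the narrow end
(``z = L``, absorbing).  The diffusing particle is a spherocylinder
(capsule): the Minkowski sum of an axis segment of length ``l`` and a ball
of radius ``r``.  Containment against the wall therefore reduces to
requiring that the perpendicular distance from each axis-segment endpoint to
the (extrapolated) cone surface is at least ``r``; the clearance along the
segment is concave in the segment parameter (linear wall radius minus a
convex radial distance), so its minimum is attained at an endpoint.

The linear wall is extrapolated beyond ``z in [0, L]``: only the centre of
mass is constrained to the channel interval (entrance/exit rules live in
:mod:`conepore.dynamics`), so a long particle may overhang either end while
its body is still tested against the extended cone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Channel",
    "Spherocylinder",
    "ParticleState",
    "InvalidGeometryError",
    "radius_at",
    "wall_clearance",
    "spherocylinder_inside",
    "collision_oracle",
]


class InvalidGeometryError(ValueError):
    """Raised when a queried geometry is degenerate (e.g. radius <= 0)."""


@dataclass(frozen=True)
class Channel:
    """Axisymmetric conical channel with linearly varying radius.

    Parameters
    ----------
    L : float
        Channel length along the ``z`` axis; ``z = 0`` is the wide
        (reflecting) end and ``z = L`` the narrow (absorbing) end.
    R0 : float
        Wall radius at ``z = 0``.
    RL : float
        Wall radius at ``z = L``; ``RL == R0`` is the cylindrical control
        case.
    """

    L: float
    R0: float
    RL: float
    slope: float = field(init=False)

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise InvalidGeometryError(f"channel length must be positive, got L={self.L}")
        if self.R0 <= 0 or self.RL <= 0:
            raise InvalidGeometryError(
                f"channel radii must be positive, got R0={self.R0}, RL={self.RL}"
            )
        if self.RL > self.R0:
            raise InvalidGeometryError(
                f"channel must not widen: RL={self.RL} > R0={self.R0}"
            )
        object.__setattr__(self, "slope", (self.RL - self.R0) / self.L)


@dataclass(frozen=True)
class Spherocylinder:
    """Rigid capsule of hemisphere/cylinder radius ``r`` and cylindrical
    length ``l`` (``l = 0`` is a sphere).  Total mass is fixed at 1 by
    convention."""

    l: float
    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise InvalidGeometryError(f"particle radius must be positive, got r={self.r}")
        if self.l < 0:
            raise InvalidGeometryError(f"particle length must be non-negative, got l={self.l}")

    @property
    def half_length(self) -> float:
        return 0.5 * self.l


@dataclass
class ParticleState:
    """Centre-of-mass position and unit director of the long axis."""

    c: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        norm = float(np.linalg.norm(self.u))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"orientation must be a unit vector, |u|={norm}")


def radius_at(channel: Channel, z):
    """Wall radius ``R(z) = R0 + slope * z`` of the (extrapolated) cone.

    ``z`` may be a scalar or array and may lie outside ``[0, L]``; the linear
    wall is extrapolated.  A non-positive extrapolated radius raises
    :class:`InvalidGeometryError`.
    """
    R = channel.R0 + channel.slope * np.asarray(z, dtype=float)
    if np.any(R <= 0):
        raise InvalidGeometryError("extrapolated wall radius is non-positive at queried z")
    return R if R.ndim else float(R)


def wall_clearance(channel: Channel, p) -> float:
    """Perpendicular distance from point(s) ``p`` to the cone wall surface.

    Positive when the point is radially inside the wall.  For a point at
    cylindrical radius ``rho`` and height ``z`` this is
    ``(R(z) - rho) / sqrt(1 + slope**2)``: the in-plane distance to the
    generating line of the cone, which equals the 3-D distance to the
    surface of revolution.
    """
    p = np.asarray(p, dtype=float)
    rho = np.hypot(p[..., 0], p[..., 1])
    R = channel.R0 + channel.slope * p[..., 2]
    out = (R - rho) / np.sqrt(1.0 + channel.slope**2)
    return float(out) if out.ndim == 0 else out


def spherocylinder_inside(
    channel: Channel, particle: Spherocylinder, state: ParticleState
) -> bool:
    """True iff the full capsule body does not intersect the wall surface.

    Endpoint reduction: it suffices to check ``wall_clearance >= r`` at the
    two axis-segment endpoints ``c +- (l/2) u``.
    """
    h = particle.half_length
    ends = np.stack([state.c + h * state.u, state.c - h * state.u])
    return bool(np.all(wall_clearance(channel, ends) >= particle.r))


def _surface_points(particle: Spherocylinder, n_samples: int, rng) -> np.ndarray:
    """Area-weighted random points on the capsule surface, in the body frame
    (long axis along z, centred at the origin)."""
    l, r = particle.l, particle.r
    area_cyl = 2.0 * np.pi * r * l
    area_caps = 4.0 * np.pi * r**2  # two hemispheres = one full sphere
    n_cyl = rng.binomial(n_samples, area_cyl / (area_cyl + area_caps)) if l > 0 else 0
    n_cap = n_samples - n_cyl

    pts = np.empty((n_samples, 3))
    if n_cyl:
        phi = rng.uniform(0.0, 2.0 * np.pi, n_cyl)
        z = rng.uniform(-0.5 * l, 0.5 * l, n_cyl)
        pts[:n_cyl] = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if n_cap:
        v = rng.standard_normal((n_cap, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        # shift each hemisphere point to the cap on its own side
        v *= r
        v[:, 2] += np.where(v[:, 2] >= 0, 0.5 * l, -0.5 * l)
        pts[n_cyl:] = v
    return pts


def collision_oracle(
    channel: Channel,
    particle: Spherocylinder,
    state: ParticleState,
    n_samples: int = 10_000,
    rng=None,
) -> bool:
    """Brute-force containment reference: sample points on the capsule
    surface (area-weighted over cylindrical shell and hemispherical caps)
    and require every point to lie radially inside the wall.

    Test-only validator for :func:`spherocylinder_inside`; near-boundary
    disagreements within the sampling resolution are expected and resolved
    in favour of the analytic predicate.
    """
    if n_samples < 1000:
        raise ValueError("collision_oracle needs n_samples >= 1000")
    if rng is None:
        rng = np.random.default_rng(0)
    body = _surface_points(particle, n_samples, rng)

    u = state.u / np.linalg.norm(state.u)
    # orthonormal frame (e1, e2, u); pick a helper axis not parallel to u
    helper = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    lab = state.c + body[:, :1] * e1 + body[:, 1:2] * e2 + body[:, 2:3] * u
    return bool(np.all(wall_clearance(channel, lab) >= 0.0))
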