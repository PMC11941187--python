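"""Mass partition and moment-of-inertia tensor of a uniform spherocylinder.

The particle has unit total mass split between the cylindrical part (mass
``m1``) and the two hemispherical caps (mass ``m2`` each).  Uniform density
fixes the ratio ``m1 / m2 = 3 l / (2 r)`` (cylinder volume over half-sphere
volume), which together with ``m1 + 2 m2 = 1`` determines both masses.

With the body ``z`` axis along the long axis, the inertia tensor is
diagonal with ``Mxx = Myy`` (transverse) and ``Mzz`` (axial):

    Mxx = m1 (l^2/12 + r^2/4) + 2 m2 (2 r^2/5 + l^2/4 + 3 l r/8)
    Mzz = (m1/2 + 4 m2/5) r^2

The rotational noise scale follows from equipartition between the
translational and rotational degrees of freedom: a rotation about a unit
axis ``A`` with moment ``I(A) = A^T M A`` has angle standard deviation
``sigma_phi = sigma_x / sqrt(I(A))``.  Because the tensor is axisymmetric
only the cosine of the angle between the rotation axis and the long axis
enters: ``I = Mxx (1 - cos^2 psi) + Mzz cos^2 psi``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "InertiaModel",
    "InvalidParticleError",
    "component_masses",
    "inertia_tensor",
    "moment_about_axis",
    "sigma_phi",
]


class InvalidParticleError(ValueError):
    pass


@dataclass(frozen=True)
class InertiaModel:
    """Mass partition and principal moments for unit total mass."""

    m1: float
    m2: float
    Mxx: float
    Mzz: float

    @classmethod
    def from_shape(cls, l: float, r: float) -> "InertiaModel":
        m1, m2 = component_masses(l, r)
        Mxx, Mzz = inertia_tensor(l, r)
        return cls(m1=m1, m2=m2, Mxx=Mxx, Mzz=Mzz)


def component_masses(l: float, r: float) -> tuple[float, float]:
    """Masses of the cylindrical part and of one hemisphere.

    Solves ``m1 + 2 m2 = 1`` with ``m1 / m2 = 3 l / (2 r)``, giving
    ``m1 = 3 l / (3 l + 4 r)`` and ``m2 = 2 r / (3 l + 4 r)``.
    """
    if r <= 0:
        raise InvalidParticleError(f"particle radius must be positive, got r={r}")
    if l < 0:
        raise InvalidParticleError(f"particle length must be non-negative, got l={l}")
    denom = 3.0 * l + 4.0 * r
    return 3.0 * l / denom, 2.0 * r / denom


def inertia_tensor(l: float, r: float) -> tuple[float, float]:
    """Principal moments ``(Mxx, Mzz)`` of the unit-mass spherocylinder."""
    m1, m2 = component_masses(l, r)
    Mxx = m1 * (l * l / 12.0 + r * r / 4.0) + 2.0 * m2 * (
        2.0 * r * r / 5.0 + l * l / 4.0 + 3.0 * l * r / 8.0
    )
    Mzz = (0.5 * m1 + 0.8 * m2) * r * r
    return Mxx, Mzz


def moment_about_axis(model: InertiaModel, cos_psi: float) -> float:
    """Moment of inertia about a unit axis at angle ``psi`` to the long axis.

    ``cos_psi`` is the dot product of the rotation axis and the director.
    """
    if abs(cos_psi) > 1.0 + 1e-9:
        raise InvalidParticleError(f"|cos_psi| must be <= 1, got {cos_psi}")
    c2 = min(cos_psi * cos_psi, 1.0)
    return model.Mxx * (1.0 - c2) + model.Mzz * c2


def sigma_phi(sigma_x: float, moment: float) -> float:
    """Rotation-angle noise scale ``sigma_x / sqrt(moment)`` (radians)."""
    if moment <= 0:
        raise InvalidParticleError(f"moment of inertia must be positive, got {moment}")
    if sigma_x <= 0:
        raise InvalidParticleError(f"sigma_x must be positive, got {sigma_x}")
    return sigma_x * moment**-0.5
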