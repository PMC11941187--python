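"""Numba-compiled inner loop of the Brownian-dynamics simulation.

One discrete time step is one translation attempt plus one rotation
attempt; either sub-move is rejected (state unchanged) if the moved capsule
would intersect the channel wall, and a translation is additionally
rejected if it would push the centre of mass out through the entrance
(z < 0).  Time advances by one per step regardless of acceptance.  The
trajectory ends when the centre of mass reaches the absorbing plane
(z >= L) or at the step cap.

Randomness comes from an embedded xoshiro256++ stream per trajectory,
seeded via splitmix64 from (master seed, trajectory index): trajectories
are bit-reproducible, independent of execution order, and independent of
the host RNG.  Gaussian deviates use the Marsaglia polar method and the
uniform rotation axis the Marsaglia sphere method; both are exact
samplers, chosen because the compiled loop spends most of its time in
random-number generation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_trajectory", "mix_seed", "trajectory_seeds", "xoshiro_state"]

_M64 = (1 << 64) - 1


def _splitmix64(x: int) -> tuple[int, int]:
    """One splitmix64 update; returns (new_state, output)."""
    x = (x + 0x9E3779B97F4A7C15) & _M64
    z = x
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return x, z ^ (z >> 31)


def mix_seed(master_seed: int, index: int) -> int:
    """Well-separated 31-bit seed for substream ``index`` of a master seed."""
    x = (int(master_seed) * 0x9E3779B97F4A7C15 + int(index) + 1) & _M64
    _, z = _splitmix64(x)
    return z & 0x7FFFFFFF

def trajectory_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.array([mix_seed(master_seed, i) for i in range(n)], dtype=np.int64)


def xoshiro_state(seed: int) -> np.ndarray:
    """256-bit xoshiro state filled from a splitmix64 stream (never all-zero)."""
    s = np.empty(4, dtype=np.uint64)
    x = int(seed)
    for i in range(4):
        x, z = _splitmix64(x)
        s[i] = z
    if not s.any():
        s[0] = 1
    return s


@njit(cache=True, inline="always")
def _rotl(x, k):
    return (x << k) | (x >> (np.uint64(64) - k))


@njit(cache=True, inline="always")
def _next_u64(s):
    # xoshiro256++
    result = _rotl(s[0] + s[3], np.uint64(23)) + s[0]
    t = s[1] << np.uint64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = _rotl(s[3], np.uint64(45))
    return result


@njit(cache=True, inline="always")
def _uniform(s):
    # 53-bit mantissa uniform in [0, 1)
    return (_next_u64(s) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always")
def _gauss_pair(s):
    # Marsaglia polar method: two independent N(0,1) deviates
    while True:
        v1 = 2.0 * _uniform(s) - 1.0
        v2 = 2.0 * _uniform(s) - 1.0
        rsq = v1 * v1 + v2 * v2
        if 0.0 < rsq < 1.0:
            fac = np.sqrt(-2.0 * np.log(rsq) / rsq)
            return v1 * fac, v2 * fac


@njit(cache=True, inline="always")
def _sphere_point(s):
    # Marsaglia method: uniform direction on the unit sphere
    while True:
        v1 = 2.0 * _uniform(s) - 1.0
        v2 = 2.0 * _uniform(s) - 1.0
        ssq = v1 * v1 + v2 * v2
        if ssq < 1.0:
            root = 2.0 * np.sqrt(1.0 - ssq)
            return v1 * root, v2 * root, 1.0 - 2.0 * ssq


@njit(cache=True, inline="always")
def _clearance(x, y, z, R0, slope, inv_hyp):
    rho = np.sqrt(x * x + y * y)
    return (R0 + slope * z - rho) * inv_hyp


@njit(cache=True, inline="always")
def _body_inside(cx, cy, cz, ux, uy, uz, h, r, R0, slope, inv_hyp):
    # endpoint reduction: clearance along the axis segment is concave
    if _clearance(cx + h * ux, cy + h * uy, cz + h * uz, R0, slope, inv_hyp) < r:
        return False
    return _clearance(cx - h * ux, cy - h * uy, cz - h * uz, R0, slope, inv_hyp) >= r


@njit(cache=True)
def run_trajectory(
    rng_state,     # uint64[4] xoshiro state, advanced in place
    L,
    R0,
    slope,
    h,             # half of the cylindrical length l/2
    r,
    sigma_x,
    Mxx,
    Mzz,
    axial_start,   # True: start aligned with the channel axis
    max_steps,
    sample_times,  # int64, strictly increasing, within [1, max_steps]
    occ_stride,    # record occupancy every occ_stride steps (0 disables)
    occ_z,         # int64[n_z_bins], accumulated in place
    occ_theta,     # int64[n_theta_bins], accumulated in place
    pos_out,       # float64[len(sample_times), 3], NaN-prefilled
    ori_out,       # float64[len(sample_times), 3], NaN-prefilled
):
    """Run one trajectory to absorption or the step cap.

    Returns ``(fpt, accepted_translations, accepted_rotations)`` where
    ``fpt`` is the absorbing step index, ``-1`` if censored at the cap, or
    ``-2`` if no feasible initial orientation was found.
    """
    inv_hyp = 1.0 / np.sqrt(1.0 + slope * slope)

    # insertion at the wide end: centre of mass at the origin, orientation
    # uniform on the sphere, redrawn until the body fits the extrapolated wall
    ux = 0.0
    uy = 0.0
    uz = 1.0
    if axial_start:
        if not _body_inside(0.0, 0.0, 0.0, ux, uy, uz, h, r, R0, slope, inv_hyp):
            return -2, 0, 0
    else:
        ok = False
        for _ in range(1_000_000):
            ux, uy, uz = _sphere_point(rng_state)
            if _body_inside(0.0, 0.0, 0.0, ux, uy, uz, h, r, R0, slope, inv_hyp):
                ok = True
                break
        if not ok:
            return -2, 0, 0

    cx = 0.0
    cy = 0.0
    cz = 0.0
    acc_t = 0
    acc_r = 0
    si = 0
    n_samp = sample_times.shape[0]
    n_z = occ_z.shape[0]
    n_th = occ_theta.shape[0]
    inv_dz = n_z / L
    inv_dth = n_th / (0.5 * np.pi)

    for t in range(1, max_steps + 1):
        # --- translation attempt -------------------------------------
        g1, g2 = _gauss_pair(rng_state)
        g3, g4 = _gauss_pair(rng_state)
        nx = cx + sigma_x * g1
        ny = cy + sigma_x * g2
        nz = cz + sigma_x * g3
        if nz >= 0.0 and _body_inside(nx, ny, nz, ux, uy, uz, h, r, R0, slope, inv_hyp):
            cx, cy, cz = nx, ny, nz
            acc_t += 1

        # --- rotation attempt ----------------------------------------
        # uniform random axis; sigma_phi depends on the axis through the
        # moment of inertia about it (equipartition coupling)
        ax, ay, az = _sphere_point(rng_state)
        cpsi = ax * ux + ay * uy + az * uz
        moment = Mxx * (1.0 - cpsi * cpsi) + Mzz * cpsi * cpsi
        angle = (sigma_x / np.sqrt(moment)) * g4

        ca = np.cos(angle)
        sa = np.sin(angle)
        # Rodrigues: u' = u cos + (a x u) sin + a (a.u)(1 - cos)
        wx = ux * ca + (ay * uz - az * uy) * sa + ax * cpsi * (1.0 - ca)
        wy = uy * ca + (az * ux - ax * uz) * sa + ay * cpsi * (1.0 - ca)
        wz = uz * ca + (ax * uy - ay * ux) * sa + az * cpsi * (1.0 - ca)
        wn = np.sqrt(wx * wx + wy * wy + wz * wz)
        wx /= wn
        wy /= wn
        wz /= wn
        if _body_inside(cx, cy, cz, wx, wy, wz, h, r, R0, slope, inv_hyp):
            ux, uy, uz = wx, wy, wz
            acc_r += 1

        absorbed = cz >= L

        if si < n_samp and t == sample_times[si]:
            pos_out[si, 0] = cx
            pos_out[si, 1] = cy
            pos_out[si, 2] = cz
            ori_out[si, 0] = ux
            ori_out[si, 1] = uy
            ori_out[si, 2] = uz
            si += 1

        if (not absorbed) and occ_stride > 0 and t % occ_stride == 0:
            iz = int(cz * inv_dz)
            if 0 <= iz < n_z:
                occ_z[iz] += 1
            auz = abs(uz)
            if auz > 1.0:
                auz = 1.0
            ith = int(np.arccos(auz) * inv_dth)
            if ith >= n_th:
                ith = n_th - 1
            occ_theta[ith] += 1

        if absorbed:
            return t, acc_t, acc_r

    return -1, acc_t, acc_r
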