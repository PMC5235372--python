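"""Compiled inner loops for chain building and distance-matrix error.

The assembly search evaluates tens of thousands of candidate insertions per
run; each evaluation rebuilds part of a backbone from internal coordinates
and scores it with the pairwise-distance DME.  These two loops are the hot
path and are JIT-compiled with numba.  Plain numpy/scipy reference routes
live in :mod:`fraglib.geometry` and the test suite asserts agreement.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .core import BOND_C_N, BOND_CA_C, BOND_N_CA

_B_NCA = BOND_N_CA
_B_CAC = BOND_CA_C
_B_CN = BOND_C_N


@njit(cache=False)
def nerf_place(coords: np.ndarray, geom_rad: np.ndarray,
               start_atom: int, stop_atom: int) -> None:
    """Place backbone atoms ``[start_atom, stop_atom)`` in-place.

    ``coords`` is the flat ``(3n, 3)`` atom array (N, Cα, C per residue);
    ``geom_rad`` the ``(n, 6)`` internal coordinates in *radians*.  Atoms
    before ``start_atom`` must already hold valid coordinates (the first
    three atoms are placed canonically when ``start_atom`` < 3).
    """
    for k in range(start_atom, stop_atom):
        i = k // 3
        t = k - 3 * i
        if k == 0:
            coords[0, 0] = 0.0
            coords[0, 1] = 0.0
            coords[0, 2] = 0.0
            continue
        if k == 1:
            coords[1, 0] = _B_NCA
            coords[1, 1] = 0.0
            coords[1, 2] = 0.0
            continue
        if k == 2:
            theta = geom_rad[0, 3]
            coords[2, 0] = coords[1, 0] - _B_CAC * math.cos(theta)
            coords[2, 1] = _B_CAC * math.sin(theta)
            coords[2, 2] = 0.0
            continue
        if t == 0:      # N(i): bond C(i-1)-N, angle Cα-C-N(i-1), torsion psi(i-1)
            b = _B_CN
            theta = geom_rad[i - 1, 4]
            tau = geom_rad[i - 1, 1]
        elif t == 1:    # Cα(i): bond N-Cα, angle C-N-Cα(i), torsion omega(i-1)
            b = _B_NCA
            theta = geom_rad[i, 5]
            tau = geom_rad[i - 1, 2]
        else:           # C(i): bond Cα-C, angle N-Cα-C(i), torsion phi(i)
            b = _B_CAC
            theta = geom_rad[i, 3]
            tau = geom_rad[i, 0]

        ax, ay, az = coords[k - 3, 0], coords[k - 3, 1], coords[k - 3, 2]
        bx, by, bz = coords[k - 2, 0], coords[k - 2, 1], coords[k - 2, 2]
        cx, cy, cz = coords[k - 1, 0], coords[k - 1, 1], coords[k - 1, 2]

        # unit vector along B->C
        ux, uy, uz = cx - bx, cy - by, cz - bz
        inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
        ux *= inv
        uy *= inv
        uz *= inv
        # normal to plane A-B-C: cross(B-A, u)
        vx, vy, vz = bx - ax, by - ay, bz - az
        nx = vy * uz - vz * uy
        ny = vz * ux - vx * uz
        nz = vx * uy - vy * ux
        inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
        nx *= inv
        ny *= inv
        nz *= inv
        # in-plane vector m = cross(n, u)
        mx = ny * uz - nz * uy
        my = nz * ux - nx * uz
        mz = nx * uy - ny * ux

        d1 = -b * math.cos(theta)
        st = b * math.sin(theta)
        d2 = st * math.cos(tau)
        d3 = st * math.sin(tau)
        coords[k, 0] = cx + d1 * ux + d2 * mx + d3 * nx
        coords[k, 1] = cy + d1 * uy + d2 * my + d3 * ny
        coords[k, 2] = cz + d1 * uz + d2 * mz + d3 * nz


@njit(cache=False)
def dme_pairs(a: np.ndarray, b: np.ndarray) -> float:
    """DME between two ``(m, 3)`` coordinate sets (same atom ordering)."""
    m = a.shape[0]
    acc = 0.0
    for i in range(m - 1):
        axi, ayi, azi = a[i, 0], a[i, 1], a[i, 2]
        bxi, byi, bzi = b[i, 0], b[i, 1], b[i, 2]
        for j in range(i + 1, m):
            dx = a[j, 0] - axi
            dy = a[j, 1] - ayi
            dz = a[j, 2] - azi
            p = math.sqrt(dx * dx + dy * dy + dz * dz)
            dx = b[j, 0] - bxi
            dy = b[j, 1] - byi
            dz = b[j, 2] - bzi
            q = math.sqrt(dx * dx + dy * dy + dz * dz)
            acc += (p - q) * (p - q)
    npairs = m * (m - 1) // 2
    return math.sqrt(acc / npairs)


@njit(cache=False)
def dme_vs_condensed(a: np.ndarray, ref_condensed: np.ndarray) -> float:
    """DME of ``a`` against a reference given as condensed pair distances."""
    m = a.shape[0]
    acc = 0.0
    idx = 0
    for i in range(m - 1):
        axi, ayi, azi = a[i, 0], a[i, 1], a[i, 2]
        for j in range(i + 1, m):
            dx = a[j, 0] - axi
            dy = a[j, 1] - ayi
            dz = a[j, 2] - azi
            p = math.sqrt(dx * dx + dy * dy + dz * dz)
            d = p - ref_condensed[idx]
            acc += d * d
            idx += 1
    return math.sqrt(acc / idx)


@njit(cache=False)
def _apply_frag(g: np.ndarray, frag: np.ndarray, pos: int) -> None:
    """Masked angle overwrite: NaN entries keep the model's value."""
    for i in range(frag.shape[0]):
        for j in range(6):
            v = frag[i, j]
            if not math.isnan(v):
                g[pos + i, j] = v


@njit(cache=False)
def _rebuild_span(c: np.ndarray, g: np.ndarray,
                  first_res: int, changed_end: int) -> None:
    """Re-place atoms after residues [first_res, changed_end) changed.

    ``c`` holds the pre-change coordinates and is updated in place; the
    untouched tail (internal geometry unchanged) is moved rigidly.
    """
    n = g.shape[0]
    start_atom = 0 if first_res <= 0 else 3 * first_res + 1
    if changed_end >= n:
        nerf_place(c, g, start_atom, 3 * n)
        return
    stop = 3 * changed_end + 2  # rebuild through Cα(changed_end)
    # old triad (frame carrying the rigid tail)
    o0x, o0y, o0z = c[stop - 3, 0], c[stop - 3, 1], c[stop - 3, 2]
    o1x, o1y, o1z = c[stop - 2, 0], c[stop - 2, 1], c[stop - 2, 2]
    o2x, o2y, o2z = c[stop - 1, 0], c[stop - 1, 1], c[stop - 1, 2]
    nerf_place(c, g, start_atom, stop)
    n0x, n0y, n0z = c[stop - 3, 0], c[stop - 3, 1], c[stop - 3, 2]
    n1x, n1y, n1z = c[stop - 2, 0], c[stop - 2, 1], c[stop - 2, 2]
    n2x, n2y, n2z = c[stop - 1, 0], c[stop - 1, 1], c[stop - 1, 2]

    # orthonormal frames at old and new triads
    def _unit(x, y, z):
        inv = 1.0 / math.sqrt(x * x + y * y + z * z)
        return x * inv, y * inv, z * inv

    oe1x, oe1y, oe1z = _unit(o1x - o0x, o1y - o0y, o1z - o0z)
    vx, vy, vz = o2x - o0x, o2y - o0y, o2z - o0z
    d = vx * oe1x + vy * oe1y + vz * oe1z
    oe2x, oe2y, oe2z = _unit(vx - d * oe1x, vy - d * oe1y, vz - d * oe1z)
    oe3x = oe1y * oe2z - oe1z * oe2y
    oe3y = oe1z * oe2x - oe1x * oe2z
    oe3z = oe1x * oe2y - oe1y * oe2x

    ne1x, ne1y, ne1z = _unit(n1x - n0x, n1y - n0y, n1z - n0z)
    vx, vy, vz = n2x - n0x, n2y - n0y, n2z - n0z
    d = vx * ne1x + vy * ne1y + vz * ne1z
    ne2x, ne2y, ne2z = _unit(vx - d * ne1x, vy - d * ne1y, vz - d * ne1z)
    ne3x = ne1y * ne2z - ne1z * ne2y
    ne3y = ne1z * ne2x - ne1x * ne2z
    ne3z = ne1x * ne2y - ne1y * ne2x

    # R = Fnew @ Fold^T
    r00 = ne1x * oe1x + ne2x * oe2x + ne3x * oe3x
    r01 = ne1x * oe1y + ne2x * oe2y + ne3x * oe3y
    r02 = ne1x * oe1z + ne2x * oe2z + ne3x * oe3z
    r10 = ne1y * oe1x + ne2y * oe2x + ne3y * oe3x
    r11 = ne1y * oe1y + ne2y * oe2y + ne3y * oe3y
    r12 = ne1y * oe1z + ne2y * oe2z + ne3y * oe3z
    r20 = ne1z * oe1x + ne2z * oe2x + ne3z * oe3x
    r21 = ne1z * oe1y + ne2z * oe2y + ne3z * oe3y
    r22 = ne1z * oe1z + ne2z * oe2z + ne3z * oe3z
    tx = n0x - (r00 * o0x + r01 * o0y + r02 * o0z)
    ty = n0y - (r10 * o0x + r11 * o0y + r12 * o0z)
    tz = n0z - (r20 * o0x + r21 * o0y + r22 * o0z)

    for k in range(stop, 3 * n):
        x, y, z = c[k, 0], c[k, 1], c[k, 2]
        c[k, 0] = r00 * x + r01 * y + r02 * z + tx
        c[k, 1] = r10 * x + r11 * y + r12 * z + ty
        c[k, 2] = r20 * x + r21 * y + r22 * z + tz


@njit(cache=False)
def best_pair_trials(coords: np.ndarray, geom_rad: np.ndarray,
                     stack_a: np.ndarray, pos_a: int,
                     stack_b: np.ndarray, pos_b: int,
                     kas: np.ndarray, kbs: np.ndarray,
                     ref_condensed: np.ndarray):
    """Evaluate random fragment-pair insertions; return (best_dme, best_trial).

    ``kas``/``kbs`` index fragments of the two slots for each trial; the
    first trial attaining the minimal global DME wins.
    """
    fa = stack_a.shape[1]
    fb = stack_b.shape[1]
    first = min(pos_a, pos_b)
    end = max(pos_a + fa, pos_b + fb)
    g = np.empty_like(geom_rad)
    c = np.empty_like(coords)
    best = np.inf
    best_t = -1
    for t in range(kas.shape[0]):
        g[:, :] = geom_rad
        _apply_frag(g, stack_a[kas[t]], pos_a)
        _apply_frag(g, stack_b[kbs[t]], pos_b)
        c[:, :] = coords
        _rebuild_span(c, g, first, end)
        d = dme_vs_condensed(c, ref_condensed)
        if d < best:
            best = d
            best_t = t
    return best, best_t


@njit(cache=False)
def best_slot_insert(coords: np.ndarray, geom_rad: np.ndarray,
                     stack: np.ndarray, pos: int,
                     ref_condensed: np.ndarray):
    """Try every slot fragment at ``pos``; return (best_dme, best_rank)."""
    f = stack.shape[1]
    g = np.empty_like(geom_rad)
    c = np.empty_like(coords)
    best = np.inf
    best_k = -1
    for k in range(stack.shape[0]):
        g[:, :] = geom_rad
        _apply_frag(g, stack[k], pos)
        c[:, :] = coords
        _rebuild_span(c, g, pos, pos + f)
        d = dme_vs_condensed(c, ref_condensed)
        if d < best:
            best = d
            best_k = k
    return best, best_k


@njit(cache=False)
def condensed_dists(a: np.ndarray) -> np.ndarray:
    """Condensed upper-triangle pairwise distances of ``(m, 3)`` coords."""
    m = a.shape[0]
    out = np.empty(m * (m - 1) // 2, dtype=np.float64)
    idx = 0
    for i in range(m - 1):
        axi, ayi, azi = a[i, 0], a[i, 1], a[i, 2]
        for j in range(i + 1, m):
            dx = a[j, 0] - axi
            dy = a[j, 1] - ayi
            dz = a[j, 2] - azi
            out[idx] = math.sqrt(dx * dx + dy * dy + dz * dz)
            idx += 1
    return out
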