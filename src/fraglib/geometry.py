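"""Backbone geometry: internal ↔ Cartesian conversion and comparison metrics.

Cartesian chains are rebuilt from dihedrals and bond angles by sequential
natural-extension-reference-frame (NeRF) placement with canonical bond
lengths.  The comparison metrics are the superposition-free distance matrix
error (DME) used as the assembly cost function, the optimal-superposition
backbone RMSD, and a windowed-seed GDT-TS.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist

from . import _kernels
from .core import (
    BackboneChain,
    InputError,
    ResidueGeometry,
    STRETCHED_ANG_C_N_CA,
    STRETCHED_ANG_CA_C_N,
    STRETCHED_ANG_N_CA_C,
    array_to_geoms,
    as_geom_array,
)

__all__ = [
    "build_cartesian",
    "build_coords",
    "extract_internal_coordinates",
    "internal_coords_array",
    "stretched_geometry",
    "insert_fragment",
    "apply_fragment_angles",
    "rebuild_coords",
    "dme",
    "local_dme",
    "backbone_rmsd",
    "superpose",
    "gdt_ts",
]

GAP_C_N_CUTOFF = 2.5  # Å; a longer C(i)-N(i+1) bond marks a chain break


# ---------------------------------------------------------------------------
# torsions and bond angles (vectorized reference formulas)

def dihedral_angles(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees, IUPAC convention) for stacked atom quads."""
    p0, p1, p2, p3 = (np.atleast_2d(np.asarray(p, dtype=float))
                      for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 /= np.linalg.norm(b1, axis=1, keepdims=True)
    v = b0 - np.sum(b0 * b1, axis=1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=1, keepdims=True) * b1
    x = np.sum(v * w, axis=1)
    y = np.sum(np.cross(b1, v) * w, axis=1)
    ang = np.degrees(np.arctan2(y, x))
    # map the branch point -180 onto +180 so angles lie in (-180, 180]
    ang[ang == -180.0] = 180.0
    return ang


def bond_angle_deg(p0, p1, p2) -> np.ndarray:
    """Bond angle at ``p1`` (degrees) for stacked atom triples."""
    p0, p1, p2 = (np.atleast_2d(np.asarray(p, dtype=float))
                  for p in (p0, p1, p2))
    u = p0 - p1
    v = p2 - p1
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    cosang = np.clip(np.sum(u * v, axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def internal_coords_array(chain: BackboneChain) -> np.ndarray:
    """Extract the ``(n, 6)`` internal-coordinate array from a chain.

    Angles undefined at the chain termini or across a recorded break are NaN.
    """
    n = chain.n_residues
    if n < 2:
        raise InputError("internal coordinates need at least 2 residues")
    c = chain.coords  # (n, 3, 3): N=0, CA=1, C=2
    g = np.full((n, 6), np.nan)

    # dihedrals
    g[1:, 0] = dihedral_angles(c[:-1, 2], c[1:, 0], c[1:, 1], c[1:, 2])   # phi
    g[:-1, 1] = dihedral_angles(c[:-1, 0], c[:-1, 1], c[:-1, 2], c[1:, 0])  # psi
    g[:-1, 2] = dihedral_angles(c[:-1, 1], c[:-1, 2], c[1:, 0], c[1:, 1])   # omega
    # bond angles
    g[:, 3] = bond_angle_deg(c[:, 0], c[:, 1], c[:, 2])                   # N-CA-C
    g[:-1, 4] = bond_angle_deg(c[:-1, 1], c[:-1, 2], c[1:, 0])            # CA-C-N
    g[1:, 5] = bond_angle_deg(c[:-1, 2], c[1:, 0], c[1:, 1])              # C-N-CA

    for i in chain.breaks:
        if 0 <= i < n - 1:
            g[i, 1] = g[i, 2] = g[i, 4] = np.nan
            g[i + 1, 0] = g[i + 1, 5] = np.nan
    return g


def extract_internal_coordinates(chain: BackboneChain) -> list[ResidueGeometry]:
    """Per-residue dihedrals and bond angles of a Cartesian backbone."""
    return array_to_geoms(internal_coords_array(chain))


# ---------------------------------------------------------------------------
# Cartesian building

def _validate_buildable(g: np.ndarray) -> None:
    """Check that every angle consumed by NeRF placement is defined."""
    n = g.shape[0]
    if n < 2:
        raise InputError("building a chain needs at least 2 residues")
    bad = []
    if np.isnan(g[:, 3]).any():
        bad.append("ang_n_ca_c")
    if np.isnan(g[1:, 0]).any():
        bad.append("phi (interior)")
    if np.isnan(g[1:, 5]).any():
        bad.append("ang_c_n_ca (interior)")
    if np.isnan(g[:-1, 1]).any():
        bad.append("psi (interior)")
    if np.isnan(g[:-1, 2]).any():
        bad.append("omega (interior)")
    if np.isnan(g[:-1, 4]).any():
        bad.append("ang_ca_c_n (interior)")
    if bad:
        raise InputError("undefined interior angle(s): " + ", ".join(bad))


def build_coords(geoms) -> np.ndarray:
    """Build flat ``(3n, 3)`` backbone coordinates from internal coordinates.

    The first residue is placed canonically: N at the origin, Cα on +x,
    C in the xy-plane.  Deterministic.
    """
    g = as_geom_array(geoms)
    _validate_buildable(g)
    coords = np.empty((3 * g.shape[0], 3), dtype=float)
    _kernels.nerf_place(coords, np.deg2rad(g), 0, coords.shape[0])
    return coords


def build_cartesian(geoms, sequence: str | None = None) -> BackboneChain:
    """Build a :class:`BackboneChain` from internal coordinates."""
    coords = build_coords(geoms)
    n = coords.shape[0] // 3
    if sequence is None:
        sequence = "X" * n
    return BackboneChain(coords.reshape(n, 3, 3), sequence)


def stretched_geometry(n: int) -> np.ndarray:
    """Stretched starting conformation: all defined dihedrals at 180°."""
    if n < 2:
        raise InputError("stretched chain needs at least 2 residues")
    g = np.empty((n, 6))
    g[:, 0] = g[:, 1] = g[:, 2] = 180.0
    g[:, 3] = STRETCHED_ANG_N_CA_C
    g[:, 4] = STRETCHED_ANG_CA_C_N
    g[:, 5] = STRETCHED_ANG_C_N_CA
    g[0, 0] = g[0, 5] = np.nan        # first residue: phi, C-N-Cα undefined
    g[-1, 1] = g[-1, 2] = g[-1, 4] = np.nan  # last: psi, omega, Cα-C-N
    return g


# ---------------------------------------------------------------------------
# fragment insertion and incremental rebuilding

def apply_fragment_angles(geom: np.ndarray, frag_geom: np.ndarray,
                          position: int) -> np.ndarray:
    """Return a copy of ``geom`` with the fragment's angles written in.

    Angles the fragment leaves undefined (NaN, e.g. the terminal phi of a
    fragment cut at a chain start) keep the model's value.
    """
    geom = as_geom_array(geom)
    fg = as_geom_array(frag_geom)
    f = fg.shape[0]
    if position < 0 or position + f > geom.shape[0]:
        raise InputError(
            f"fragment span [{position}, {position + f}) outside chain of "
            f"length {geom.shape[0]}"
        )
    out = geom.copy()
    window = out[position:position + f]
    mask = ~np.isnan(fg)
    window[mask] = fg[mask]
    return out


def insert_fragment(geoms, frag, position: int):
    """Replace the six angles of residues ``[position, position+f)``.

    ``frag`` may be a library fragment (anything with a ``geometry``
    attribute), a geometry array or a list of :class:`ResidueGeometry`.
    Returns the same representation as ``geoms`` (list in, list out).
    """
    frag_geom = getattr(frag, "geometry", frag)
    as_list = not isinstance(geoms, np.ndarray)
    out = apply_fragment_angles(as_geom_array(geoms), frag_geom, position)
    return array_to_geoms(out) if as_list else out


def _triad_transform(old: np.ndarray, new: np.ndarray):
    """Rigid transform mapping a congruent 3-point triad ``old`` to ``new``."""
    def frame(p):
        e1 = p[1] - p[0]
        e1 = e1 / np.linalg.norm(e1)
        v = p[2] - p[0]
        e2 = v - (v @ e1) * e1
        e2 = e2 / np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        return np.column_stack((e1, e2, e3))

    r = frame(new) @ frame(old).T
    t = new[0] - r @ old[0]
    return r, t


def rebuild_coords(coords: np.ndarray, geom: np.ndarray,
                   first_res: int, changed_end: int) -> np.ndarray:
    """Rebuild coordinates after residues ``[first_res, changed_end)`` changed.

    Atoms upstream of the change are reused; atoms through Cα of residue
    ``changed_end`` are re-placed sequentially, and the unchanged tail is
    mapped rigidly (its internal geometry is untouched).  Equivalent to a
    full rebuild up to floating-point noise.
    """
    n = geom.shape[0]
    out = coords.copy()
    g = np.deg2rad(geom)
    start_atom = 0 if first_res <= 0 else 3 * first_res + 1
    if changed_end >= n:
        _kernels.nerf_place(out, g, start_atom, 3 * n)
        return out
    stop_atom = 3 * changed_end + 2  # through Cα(changed_end)
    old_triad = coords[stop_atom - 3:stop_atom].copy()
    _kernels.nerf_place(out, g, start_atom, stop_atom)
    r, t = _triad_transform(old_triad, out[stop_atom - 3:stop_atom])
    out[stop_atom:] = coords[stop_atom:] @ r.T + t
    return out


# ---------------------------------------------------------------------------
# metrics

def _atoms(x) -> np.ndarray:
    if isinstance(x, BackboneChain):
        return x.atoms()
    a = np.asarray(x, dtype=float)
    if a.ndim == 3:
        return a.reshape(-1, 3)
    if a.ndim == 2 and a.shape[1] == 3:
        return a
    raise InputError(f"cannot interpret shape {a.shape} as atom coordinates")


def dme(a, b) -> float:
    """Distance matrix error between two conformations (Å).

    ``sqrt( Σ_{i<j} (p_ij − q_ij)² / (N(N−1)/2) )`` over all atom pairs;
    superposition-free and symmetric.
    """
    pa, qa = _atoms(a), _atoms(b)
    if pa.shape != qa.shape:
        raise InputError(f"atom count mismatch: {pa.shape[0]} vs {qa.shape[0]}")
    m = pa.shape[0]
    if m < 2:
        raise InputError("DME needs at least 2 atoms")
    diff = pdist(pa) - pdist(qa)
    return float(np.sqrt(np.mean(diff * diff)))


def _residue_coords(x) -> np.ndarray:
    if isinstance(x, BackboneChain):
        return x.coords
    a = np.asarray(x, dtype=float)
    if a.ndim == 3 and a.shape[1:] == (3, 3):
        return a
    if a.ndim == 2 and a.shape[1] == 3 and a.shape[0] % 3 == 0:
        return a.reshape(-1, 3, 3)
    raise InputError(f"cannot interpret shape {a.shape} as residue coordinates")


def local_dme(a, b, span: tuple[int, int]) -> float:
    """DME restricted to the backbone atoms of residues ``[start, stop)``."""
    start, stop = span
    ra, rb = _residue_coords(a), _residue_coords(b)
    if stop <= start:
        raise InputError(f"empty span [{start}, {stop})")
    if start < 0 or stop > ra.shape[0] or stop > rb.shape[0]:
        raise InputError(f"span [{start}, {stop}) outside chains")
    return dme(ra[start:stop].reshape(-1, 3), rb[start:stop].reshape(-1, 3))


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition (Kabsch): returns ``(R, t)``.

    ``mobile @ R.T + t`` best fits ``target``.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s = np.diag([1.0, 1.0, d])
    r = vt.T @ s @ u.T
    t = tc - r @ mc
    return r, t


def backbone_rmsd(a, b) -> float:
    """Minimal RMSD over rigid superposition of the backbone atoms (Å)."""
    pa, qa = _atoms(a), _atoms(b)
    if pa.shape != qa.shape:
        raise InputError(f"atom count mismatch: {pa.shape[0]} vs {qa.shape[0]}")
    if pa.shape[0] < 3:
        raise InputError("RMSD needs at least 3 atoms")
    r, t = superpose(pa, qa)
    diff = pa @ r.T + t - qa
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)
GDT_SEED_WINDOWS = (4, 8)


def gdt_ts(model, reference) -> float:
    """GDT-TS (percent) from Cα coordinates.

    Mean over the 1/2/4/8 Å cutoffs of the maximal fraction of Cα atoms
    within the cutoff after superposition.  Superpositions are seeded from
    every contiguous Cα window of lengths 4 and 8 plus the full chain, with
    one round of inlier re-superposition per cutoff.
    """
    ma = model.ca() if isinstance(model, BackboneChain) else np.asarray(model, float)
    ra = reference.ca() if isinstance(reference, BackboneChain) else np.asarray(reference, float)
    if ma.shape != ra.shape:
        raise InputError(f"residue count mismatch: {ma.shape[0]} vs {ra.shape[0]}")
    n = ma.shape[0]
    if n < 3:
        raise InputError("GDT-TS needs at least 3 residues")

    windows: list[tuple[int, int]] = [(0, n)]
    for w in GDT_SEED_WINDOWS:
        if w < n:
            windows.extend((s, s + w) for s in range(n - w + 1))

    best = np.zeros(len(GDT_CUTOFFS))
    for s, e in windows:
        r, t = superpose(ma[s:e], ra[s:e])
        d = np.linalg.norm(ma @ r.T + t - ra, axis=1)
        for ci, cut in enumerate(GDT_CUTOFFS):
            inliers = d <= cut
            frac = inliers.mean()
            if inliers.sum() >= 3:
                r2, t2 = superpose(ma[inliers], ra[inliers])
                d2 = np.linalg.norm(ma @ r2.T + t2 - ra, axis=1)
                frac = max(frac, (d2 <= cut).mean())
            if frac > best[ci]:
                best[ci] = frac
    return float(best.mean() * 100.0)
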