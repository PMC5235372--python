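"""Geometry engine: torsion extraction, chain building, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_geometry
from fraglib import geometry
from fraglib.core import (
    BOND_C_N,
    BOND_CA_C,
    BOND_N_CA,
    BackboneChain,
    InputError,
    STRETCHED_ANG_C_N_CA,
    STRETCHED_ANG_CA_C_N,
)


# ---------------------------------------------------------------------------
# independent oracles

def torsion_oracle(p0, p1, p2, p3):
    """Brute-force dihedral: atan2(|b2|·b1·n2, n1·n2) from explicit
    cross/dot products (IUPAC sign convention)."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = n1 @ n2
    y = np.linalg.norm(b2) * (b1 @ n2)
    return np.degrees(np.arctan2(y, x))


def dme_oracle(a, b):
    """Literal double loop over atom pairs."""
    a, b = np.asarray(a), np.asarray(b)
    m = a.shape[0]
    acc = 0.0
    cnt = 0
    for i in range(m):
        for j in range(i + 1, m):
            p = np.linalg.norm(a[i] - a[j])
            q = np.linalg.norm(b[i] - b[j])
            acc += (p - q) ** 2
            cnt += 1
    return np.sqrt(acc / cnt)


def rmsd_quaternion_oracle(a, b):
    """Closed-form minimal RMSD via the quaternion eigenvalue method."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (a * a).sum() + (b * b).sum()
    msd = max(0.0, (e0 - 2.0 * lam) / a.shape[0])
    return np.sqrt(msd)


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    r = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return r, rng.normal(scale=10.0, size=3)


# ---------------------------------------------------------------------------
# torsion extraction

def test_planar_cis_and_trans_dihedrals():
    p1, p2 = np.zeros(3), np.array([1.5, 0.0, 0.0])
    p0 = np.array([0.0, 1.0, 0.0])
    cis = geometry.dihedral_angles(p0, p1, p2, np.array([1.5, 1.0, 0.0]))[0]
    trans = geometry.dihedral_angles(p0, p1, p2, np.array([1.5, -1.0, 0.0]))[0]
    assert cis == pytest.approx(0.0, abs=1e-10)
    assert abs(trans) == pytest.approx(180.0, abs=1e-10)


def test_extracted_torsions_match_bruteforce_oracle():
    rng = np.random.default_rng(7)
    chain = geometry.build_cartesian(random_geometry(5, rng))
    got = geometry.internal_coords_array(chain)
    c = chain.coords
    for i in range(1, 5):
        phi = torsion_oracle(c[i - 1, 2], c[i, 0], c[i, 1], c[i, 2])
        assert got[i, 0] == pytest.approx(phi, abs=1e-8)
    for i in range(4):
        psi = torsion_oracle(c[i, 0], c[i, 1], c[i, 2], c[i + 1, 0])
        omega = torsion_oracle(c[i, 1], c[i, 2], c[i + 1, 0], c[i + 1, 1])
        assert got[i, 1] == pytest.approx(psi, abs=1e-8)
        assert got[i, 2] == pytest.approx(omega, abs=1e-8)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.integers(2, 12), st.integers(0, 10_000))
def test_build_extract_round_trip(n, seed):
    g = random_geometry(n, np.random.default_rng(seed))
    chain = geometry.build_cartesian(g)
    back = geometry.internal_coords_array(chain)
    mask = ~np.isnan(g)
    assert np.array_equal(mask, ~np.isnan(back))
    np.testing.assert_allclose(back[mask], g[mask], atol=1e-6)


def test_terminus_flags():
    g = random_geometry(4, np.random.default_rng(0))
    back = geometry.internal_coords_array(geometry.build_cartesian(g))
    assert np.isnan(back[0, 0]) and np.isnan(back[0, 5])
    assert np.isnan(back[-1, 1]) and np.isnan(back[-1, 2]) and np.isnan(back[-1, 4])


def test_extract_requires_two_residues():
    chain = BackboneChain(np.zeros((1, 3, 3)) + np.arange(9).reshape(3, 3), "A")
    with pytest.raises(InputError):
        geometry.internal_coords_array(chain)


# ---------------------------------------------------------------------------
# Cartesian building

def test_build_bond_lengths_are_canonical():
    rng = np.random.default_rng(3)
    coords = geometry.build_coords(random_geometry(7, rng))
    for i in range(7):
        assert np.linalg.norm(coords[3 * i + 1] - coords[3 * i]) == \
            pytest.approx(BOND_N_CA, abs=1e-9)
        assert np.linalg.norm(coords[3 * i + 2] - coords[3 * i + 1]) == \
            pytest.approx(BOND_CA_C, abs=1e-9)
        if i:
            assert np.linalg.norm(coords[3 * i] - coords[3 * i - 1]) == \
                pytest.approx(BOND_C_N, abs=1e-9)


def test_trans_chain_ca_ca_distance_matches_trig_oracle():
    """All-trans peptide: Cα–Cα distance from an explicit 2-D construction."""
    g = geometry.stretched_geometry(10)
    coords = geometry.build_coords(g).reshape(10, 3, 3)
    d = np.linalg.norm(coords[1:, 1] - coords[:-1, 1], axis=1)
    # planar trans unit: CA - C - N - CA drawn in 2-D
    a1 = np.radians(STRETCHED_ANG_CA_C_N)
    a2 = np.radians(STRETCHED_ANG_C_N_CA)
    ca = np.zeros(2)
    c = ca + [BOND_CA_C, 0.0]
    n = c + BOND_C_N * np.array([-np.cos(a1), np.sin(a1)])
    u = (c - n) / np.linalg.norm(c - n)
    # rotate u by the N angle, on the far side (trans)
    rot = np.array([[np.cos(a2), -np.sin(a2)], [np.sin(a2), np.cos(a2)]])
    ca2 = n + BOND_N_CA * (rot @ u)
    expected = np.linalg.norm(ca2 - ca)
    assert expected == pytest.approx(3.80, abs=0.02)
    np.testing.assert_allclose(d, expected, atol=1e-6)


def test_helix_screw_symmetry():
    g = geometry.stretched_geometry(12)
    g[1:, 0] = -57.0
    g[:-1, 1] = -47.0
    coords = geometry.build_coords(g).reshape(12, 3, 3)
    d = np.linalg.norm(coords[4:, 1] - coords[:-4, 1], axis=1)
    np.testing.assert_allclose(d, d[0], atol=1e-6)


def test_build_rejects_undefined_interior_angle():
    g = random_geometry(5, np.random.default_rng(1))
    g[2, 1] = np.nan
    with pytest.raises(InputError):
        geometry.build_coords(g)


# ---------------------------------------------------------------------------
# DME / RMSD / GDT

def test_dme_matches_double_loop_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        a = geometry.build_coords(random_geometry(4, rng))
        b = geometry.build_coords(random_geometry(4, rng))
        assert geometry.dme(a, b) == pytest.approx(dme_oracle(a, b), abs=1e-10)
        assert geometry.dme(a, b) == geometry.dme(b, a)
    assert geometry.dme(a, a) == 0.0


def test_dme_two_atom_closed_form():
    a = np.array([[0.0, 0, 0], [3.8, 0, 0]])
    b = np.array([[0.0, 0, 0], [0, 3.6, 0]])
    assert geometry.dme(a, b) == pytest.approx(0.2, abs=1e-12)


def test_dme_rigid_invariance():
    rng = np.random.default_rng(5)
    a = geometry.build_coords(random_geometry(5, rng))
    b = geometry.build_coords(random_geometry(5, rng))
    r, t = random_rigid(rng)
    assert geometry.dme(a @ r.T + t, b) == pytest.approx(geometry.dme(a, b), abs=1e-9)


def test_local_dme_whole_span_reduces_to_dme():
    rng = np.random.default_rng(6)
    a = geometry.build_coords(random_geometry(6, rng)).reshape(6, 3, 3)
    b = geometry.build_coords(random_geometry(6, rng)).reshape(6, 3, 3)
    assert geometry.local_dme(a, b, (0, 6)) == pytest.approx(
        geometry.dme(a, b), abs=1e-12)
    span = geometry.local_dme(a, b, (1, 4))
    assert span == pytest.approx(
        dme_oracle(a[1:4].reshape(-1, 3), b[1:4].reshape(-1, 3)), abs=1e-10)
    with pytest.raises(InputError):
        geometry.local_dme(a, b, (3, 3))


def test_rmsd_rigid_copy_is_zero_and_oracle_agrees():
    rng = np.random.default_rng(8)
    a = rng.normal(size=(5, 3)) * 5
    r, t = random_rigid(rng)
    assert geometry.backbone_rmsd(a @ r.T + t, a) < 1e-8
    for _ in range(20):
        b = rng.normal(size=(5, 3)) * 5
        assert geometry.backbone_rmsd(a, b) == pytest.approx(
            rmsd_quaternion_oracle(a, b), abs=1e-9)


def test_gdt_identity_and_rigid_copy():
    rng = np.random.default_rng(9)
    chain = geometry.build_cartesian(random_geometry(12, rng))
    assert geometry.gdt_ts(chain, chain) == 100.0
    r, t = random_rigid(rng)
    moved = BackboneChain(chain.coords @ r.T + t, chain.sequence)
    assert geometry.gdt_ts(moved, chain) == pytest.approx(100.0)


def test_gdt_perturbed_close_to_exhaustive_seed_oracle():
    rng = np.random.default_rng(10)
    ref = geometry.build_coords(random_geometry(10, rng)).reshape(10, 3, 3)
    model = ref + rng.normal(scale=0.8, size=ref.shape)
    ref_ca, mod_ca = ref[:, 1], model[:, 1]

    best = np.zeros(4)
    n = 10
    for w in range(3, n + 1):           # exhaustive: every window length
        for s in range(n - w + 1):
            r, t = geometry.superpose(mod_ca[s:s + w], ref_ca[s:s + w])
            d = np.linalg.norm(mod_ca @ r.T + t - ref_ca, axis=1)
            for ci, cut in enumerate((1.0, 2.0, 4.0, 8.0)):
                inl = d <= cut
                frac = inl.mean()
                if inl.sum() >= 3:
                    r2, t2 = geometry.superpose(mod_ca[inl], ref_ca[inl])
                    d2 = np.linalg.norm(mod_ca @ r2.T + t2 - ref_ca, axis=1)
                    frac = max(frac, (d2 <= cut).mean())
                best[ci] = max(best[ci], frac)
    oracle = best.mean() * 100
    got = geometry.gdt_ts(model.reshape(10, 3, 3)[:, 1], ref_ca)
    assert abs(got - oracle) <= 1.0


# ---------------------------------------------------------------------------
# fragment insertion and incremental rebuild

def test_insert_own_excision_is_identity():
    rng = np.random.default_rng(12)
    g = random_geometry(8, rng)
    frag = g[2:5].copy()
    out = geometry.apply_fragment_angles(g, frag, 2)
    np.testing.assert_array_equal(
        np.nan_to_num(out, nan=-999), np.nan_to_num(g, nan=-999))


def test_insert_modifies_exactly_the_span():
    rng = np.random.default_rng(13)
    g = random_geometry(8, rng)
    frag = random_geometry(3, np.random.default_rng(14))
    frag[0, 0] = -60.0  # defined head
    out = geometry.apply_fragment_angles(g, frag, 0)
    assert not np.allclose(np.nan_to_num(out[:3]), np.nan_to_num(g[:3]))
    np.testing.assert_array_equal(out[3:], g[3:])
    with pytest.raises(InputError):
        geometry.apply_fragment_angles(g, frag, 6)


def test_insert_nan_keeps_model_junction_angles():
    rng = np.random.default_rng(15)
    g = random_geometry(8, rng)
    frag = random_geometry(3, np.random.default_rng(16))
    frag[0, 0] = np.nan      # undefined fragment phi at head
    frag[-1, 2] = np.nan     # undefined terminal omega
    out = geometry.apply_fragment_angles(g, frag, 2)
    assert out[2, 0] == g[2, 0]
    assert out[4, 2] == g[4, 2]
    assert out[3, 0] == frag[1, 0]


def test_partial_rebuild_equals_full_rebuild():
    rng = np.random.default_rng(17)
    g = random_geometry(20, rng)
    coords = geometry.build_coords(g)
    for pos, f in ((0, 3), (5, 4), (17, 3), (10, 10)):
        g2 = g.copy()
        g2[pos:pos + f, 0:3] = np.where(
            np.isnan(g2[pos:pos + f, 0:3]), np.nan,
            rng.uniform(-179, 180, (f, 3)))
        full = geometry.build_coords(g2)
        part = geometry.rebuild_coords(coords, g2, pos, pos + f)
        np.testing.assert_allclose(part, full, atol=1e-9)
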