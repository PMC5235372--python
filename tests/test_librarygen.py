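"""Scoring functions, library construction, file formats."""

import numpy as np
import pytest

from conftest import random_fragment
from fraglib import fragdb, librarygen, synthetic
from fraglib.core import InputError
from fraglib.librarygen import SubstitutionMatrix, TargetProfile


# ---------------------------------------------------------------------------
# scoring

def test_blosum62_sequence_scores(blosum):
    assert librarygen.score_sequence("A", "A", blosum) == 4
    assert librarygen.score_sequence("AAA", "AAA", blosum) == 12
    assert librarygen.score_sequence("", "", blosum) == 0
    # spot-check off-diagonal symmetry against the published table
    assert blosum.score("W", "A") == blosum.score("A", "W") == -3
    with pytest.raises(InputError):
        librarygen.score_sequence("AA", "A", blosum)
    with pytest.raises(InputError):
        librarygen.score_sequence("AX", "AA", blosum)


def test_ss_agreement_signed_confidence_sum():
    win = TargetProfile("AAA", "HHH", np.array([1.0, 1.0, 1.0]))
    assert librarygen.score_ss_agreement(win, "HHH") == pytest.approx(3.0)
    assert librarygen.score_ss_agreement(win, "EEE") == pytest.approx(-3.0)
    win2 = TargetProfile("AAA", "HEH", np.array([0.8, 0.6, 0.9]))
    assert librarygen.score_ss_agreement(win2, "HHH") == pytest.approx(1.1)
    with pytest.raises(InputError):
        librarygen.score_ss_agreement(win, "HH")


def test_combined_score_weighted_sum(blosum):
    rng = np.random.default_rng(0)
    frag = random_fragment(3, rng)
    frag.sequence = "AAA"
    frag.ss = "HHH"
    win = TargetProfile("AAA", "HEH", np.array([0.8, 0.6, 0.9]))
    got = librarygen.combined_score("AAA", frag, blosum, win)
    assert got == pytest.approx(12 + 1.1)
    blo = librarygen.combined_score("AAA", frag, blosum, win, w_p=0.0)
    assert blo == librarygen.score_sequence("AAA", frag.sequence, blosum)
    with pytest.raises(InputError):
        librarygen.combined_score("AAA", frag, blosum, win, w_b=-1.0)


# ---------------------------------------------------------------------------
# library construction

def _bruteforce_library(profile, db, f, mode, k, blosum):
    """Score-all-and-sort oracle using the scalar scoring functions."""
    n = len(profile)
    slots = []
    for pos in range(n - f + 1):
        tw = profile.sequence[pos:pos + f]
        pw = profile.window(pos, pos + f)
        cands = []
        for entry in sorted(db.entries, key=lambda e: e.entry_id):
            for s in range(len(entry) - f + 1):
                if not np.all(librarygen._entry_window_validity(entry, f)[s]):
                    continue
                frag = librarygen.Fragment(
                    entry.entry_id, s, entry.sequence[s:s + f],
                    entry.ss[s:s + f], entry.geometry[s:s + f])
                score = librarygen.score_sequence(tw, frag.sequence, blosum)
                if mode == "PSI":
                    score += librarygen.score_ss_agreement(pw, frag.ss)
                cands.append((-score, entry.entry_id, s))
        cands.sort()
        slots.append([(eid, s, -ns) for ns, eid, s in cands[:k]])
    return slots


@pytest.fixture(scope="module")
def small_db():
    entries = synthetic.generate_source_database(
        20, length_range=(20, 30), seed=77)
    return fragdb.build_database(entries)


@pytest.fixture(scope="module")
def small_profile(small_db):
    rng = np.random.default_rng(78)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
    ss = "".join(rng.choice(list("HEC"), size=20))
    return TargetProfile(seq, ss, rng.uniform(0.3, 1.0, 20))


@pytest.mark.parametrize("mode", ["BLO", "PSI"])
def test_library_matches_bruteforce_oracle(small_db, small_profile, blosum, mode):
    lib = librarygen.build_library(small_profile, small_db, 3, mode=mode, k=25)
    assert lib.n_positions == 18  # n - f + 1
    oracle = _bruteforce_library(small_profile, small_db, 3, mode, 25, blosum)
    for slot, expect in zip(lib.slots, oracle):
        got = [(sf.fragment.entry_id, sf.fragment.start, sf.score)
               for sf in slot]
        assert [(e, s) for e, s, _ in got] == [(e, s) for e, s, _ in expect]
        np.testing.assert_allclose([x[2] for x in got],
                                   [x[2] for x in expect], atol=1e-9)
        scores = [sf.score for sf in slot]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


def test_capacity_and_fewer_than_k(small_db, small_profile):
    total_windows = sum(len(e) - 3 + 1 for e in small_db)
    lib = librarygen.build_library(small_profile, small_db, 3, "BLO", k=50)
    assert all(len(s) == 50 for s in lib.slots)
    big = librarygen.build_library(small_profile, small_db, 3, "BLO",
                                   k=10 * total_windows)
    assert all(len(s) <= total_windows for s in big.slots)
    assert all(len(s) > 50 for s in big.slots)


def test_psi_with_zero_confidence_equals_blo(small_db, small_profile):
    zero = TargetProfile(small_profile.sequence, small_profile.ss,
                         np.zeros(len(small_profile)))
    blo = librarygen.build_library(small_profile, small_db, 3, "BLO", k=20)
    psi = librarygen.build_library(zero, small_db, 3, "PSI", k=20)
    for a, b in zip(blo.slots, psi.slots):
        assert [(x.fragment.entry_id, x.fragment.start) for x in a] == \
            [(x.fragment.entry_id, x.fragment.start) for x in b]


def test_library_invariant_under_entry_order(small_db, small_profile):
    lib1 = librarygen.build_library(small_profile, small_db, 3, "BLO", k=20)
    shuffled = fragdb.SourceDatabase(list(reversed(small_db.entries)))
    lib2 = librarygen.build_library(small_profile, shuffled, 3, "BLO", k=20)
    for a, b in zip(lib1.slots, lib2.slots):
        assert [(x.fragment.entry_id, x.fragment.start) for x in a] == \
            [(x.fragment.entry_id, x.fragment.start) for x in b]


def test_build_library_input_errors(small_db, small_profile):
    with pytest.raises(InputError):
        librarygen.build_library(small_profile, small_db, 21, "BLO")
    no_conf = TargetProfile(small_profile.sequence, small_profile.ss)
    with pytest.raises(InputError):
        librarygen.build_library(no_conf, small_db, 3, "PSI")


# ---------------------------------------------------------------------------
# ss2 input

def test_read_sspred(tmp_path):
    path = tmp_path / "t.ss2"
    path.write_text(
        "# PSIPRED VFORMAT\n\n"
        "   1 M C  0.998 0.001 0.001\n"
        "   2 K H  0.050 0.900 0.050\n"
        "   3 V E  0.100 0.100 0.800\n")
    prof = librarygen.read_sspred(path)
    assert prof.sequence == "MKV"
    assert prof.ss == "CHE"
    np.testing.assert_allclose(prof.confidence, [0.998, 0.9, 0.8])


def test_read_sspred_printed_class_wins(tmp_path):
    path = tmp_path / "t.ss2"
    path.write_text("   1 M C  0.100 0.800 0.100\n")
    with pytest.warns(UserWarning):
        prof = librarygen.read_sspred(path)
    assert prof.ss == "C"
    assert prof.confidence[0] == pytest.approx(0.1)


def test_read_sspred_rejects_empty_and_bad_index(tmp_path):
    empty = tmp_path / "empty.ss2"
    empty.write_text("# header only\n")
    with pytest.raises(fragdb.ParseError):
        librarygen.read_sspred(empty)
    bad = tmp_path / "bad.ss2"
    bad.write_text("   1 M C  0.9 0.05 0.05\n   3 K H  0.1 0.8 0.1\n")
    with pytest.raises(fragdb.ParseError):
        librarygen.read_sspred(bad)


# ---------------------------------------------------------------------------
# formats

@pytest.fixture(scope="module")
def tiny_library(small_db, small_profile):
    return librarygen.build_library(small_profile, small_db, 3, "PSI", k=5)


def test_library_round_trip(tmp_path, tiny_library):
    path = tmp_path / "lib.tsv"
    librarygen.write_library(tiny_library, path)
    back = librarygen.read_library(path)
    assert (back.n, back.f, back.k, back.mode) == \
        (tiny_library.n, tiny_library.f, tiny_library.k, tiny_library.mode)
    for a, b in zip(tiny_library.slots, back.slots):
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert x.score == y.score  # exact float round trip
            assert x.fragment.entry_id == y.fragment.entry_id
            assert x.fragment.start == y.fragment.start
            assert x.fragment.sequence == y.fragment.sequence
            assert x.fragment.ss == y.fragment.ss
            np.testing.assert_array_equal(
                np.nan_to_num(x.fragment.geometry, nan=-1e9),
                np.nan_to_num(y.fragment.geometry, nan=-1e9))


def test_library_format_errors(tmp_path, tiny_library):
    path = tmp_path / "lib.tsv"
    librarygen.write_library(tiny_library, path)
    text = path.read_text().splitlines()
    bad = tmp_path / "bad.tsv"
    bad.write_text("WRONG HEADER\n")
    with pytest.raises(fragdb.ParseError):
        librarygen.read_library(bad)
    truncated = tmp_path / "trunc.tsv"
    truncated.write_text(text[0] + "\n" + text[1][:len(text[1]) // 2] + "\n")
    with pytest.raises(fragdb.ParseError):
        librarygen.read_library(truncated)


def test_rosetta_export_shape_and_reparse(tmp_path, tiny_library):
    path = tmp_path / "frags.200.3mers"
    librarygen.write_rosetta_fragments(tiny_library, path)
    lines = path.read_text().splitlines()
    headers = [l for l in lines if l.strip().startswith("position:")]
    assert len(headers) == tiny_library.n_positions
    first = headers[0].split()
    assert first[1] == "1"                       # 1-based positions
    assert int(first[3]) == len(tiny_library.slots[0])
    parsed = librarygen.read_rosetta_fragments(path)
    for pos, slot in enumerate(tiny_library.slots):
        assert len(parsed[pos]) == len(slot)
        for frag, sf in zip(parsed[pos], slot):
            assert len(frag) == tiny_library.f
            expect = np.nan_to_num(sf.fragment.geometry[:, :3])
            got = np.array([[r["phi"], r["psi"], r["omega"]] for r in frag])
            np.testing.assert_allclose(got, expect, atol=5e-4)
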