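"""Synthetic structure databases and planted targets.

The generator emulates the statistical shape of a non-redundant structure
database at desk scale: entries are random successions of helix, strand
and coil segments with canonical torsions plus Gaussian angular noise.
``plant_target`` hides a synthetic native's exact fragment windows inside
randomly chosen database entries among the decoys, which makes exact
recovery by the library builder and the assembler verifiable (the injected
window's sequence is the target's own subsequence, so its substitution
self-score is the maximum attainable at its position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AA_ALPHABET,
    BackboneChain,
    InputError,
    STRETCHED_ANG_C_N_CA,
    STRETCHED_ANG_CA_C_N,
    STRETCHED_ANG_N_CA_C,
)
from .fragdb import SourceEntry, assign_secondary_structure
from .geometry import build_cartesian
from .librarygen import TargetProfile, write_ss2

__all__ = [
    "CANONICAL_TORSIONS",
    "PlantRecord",
    "generate_source_database",
    "plant_target",
    "synth_sspred",
]

# Canonical (phi, psi) per secondary-structure class.
CANONICAL_TORSIONS = {"H": (-57.0, -47.0), "E": (-120.0, 130.0)}
# Coil torsions come from two bins: (centre_phi, centre_psi) ± half-width.
COIL_BINS = ((-80.0, 150.0), (60.0, 40.0))
COIL_HALF_WIDTH = 20.0

OMEGA_NOISE_SD = 2.0        # degrees; peptide bond stays close to trans
BOND_ANGLE_NOISE_SD = 1.5   # degrees

_SEGMENT_MIN = 3
_SEGMENT_GEOM_P = 0.25      # geometric tail beyond the minimum length


def _wrap(angle: np.ndarray) -> np.ndarray:
    """Wrap degrees into (−180, 180]."""
    a = np.mod(angle + 180.0, 360.0) - 180.0
    return np.where(a == -180.0, 180.0, a)


def _segment_classes(length: int, weights: np.ndarray,
                     rng: np.random.Generator) -> str:
    out: list[str] = []
    while len(out) < length:
        cls = rng.choice(list("HEC"), p=weights)
        seg = _SEGMENT_MIN + rng.geometric(_SEGMENT_GEOM_P) - 1
        out.extend(cls * seg)
    return "".join(out[:length])


def _random_geometry(length: int, weights: np.ndarray, noise_sd: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, str]:
    """Random internal coordinates for one chain; returns (geometry, classes)."""
    classes = _segment_classes(length, weights, rng)
    g = np.empty((length, 6))
    for i, cls in enumerate(classes):
        if cls in CANONICAL_TORSIONS:
            phi, psi = CANONICAL_TORSIONS[cls]
        else:
            cp, cs = COIL_BINS[rng.integers(len(COIL_BINS))]
            phi = cp + rng.uniform(-COIL_HALF_WIDTH, COIL_HALF_WIDTH)
            psi = cs + rng.uniform(-COIL_HALF_WIDTH, COIL_HALF_WIDTH)
        g[i, 0] = phi
        g[i, 1] = psi
    g[:, :2] += rng.normal(0.0, noise_sd, size=(length, 2))
    g[:, :2] = _wrap(g[:, :2])
    g[:, 2] = _wrap(180.0 + rng.normal(0.0, OMEGA_NOISE_SD, size=length))
    g[:, 3] = STRETCHED_ANG_N_CA_C + rng.normal(0.0, BOND_ANGLE_NOISE_SD, size=length)
    g[:, 4] = STRETCHED_ANG_CA_C_N + rng.normal(0.0, BOND_ANGLE_NOISE_SD, size=length)
    g[:, 5] = STRETCHED_ANG_C_N_CA + rng.normal(0.0, BOND_ANGLE_NOISE_SD, size=length)
    g[0, 0] = g[0, 5] = np.nan
    g[-1, 1] = g[-1, 2] = g[-1, 4] = np.nan
    return g, classes


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def generate_source_database(n_entries: int,
                             length_range: tuple[int, int] = (40, 120),
                             ss_composition: tuple[float, float, float] = (0.35, 0.25, 0.40),
                             angle_noise_sd: float = 8.0,
                             seed: int | None = None) -> list[SourceEntry]:
    """Generate a synthetic non-redundant source database.

    ``ss_composition`` gives the H/E/C segment mixture weights; segment
    lengths are geometric with a minimum of 3 residues.  Deterministic for
    a given seed.
    """
    weights = np.asarray(ss_composition, dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise InputError("ss_composition weights must be non-negative with positive sum")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise InputError(f"bad length range {length_range}")
    entries = []
    for i in range(n_entries):
        length = int(rng.integers(lo, hi + 1))
        geom, _ = _random_geometry(length, weights, angle_noise_sd, rng)
        seq = _random_sequence(length, rng)
        entries.append(SourceEntry(f"s{i:04d}", seq, geom,
                                   assign_secondary_structure(geom)))
    return entries


@dataclass(frozen=True)
class PlantRecord:
    """Provenance of one injected native window."""

    length: int
    position: int
    entry_id: str
    start: int


def plant_target(db: list[SourceEntry], target_length: int,
                 lengths: tuple[int, ...] = (3, 6, 9),
                 ss_composition: tuple[float, float, float] = (0.35, 0.25, 0.40),
                 angle_noise_sd: float = 8.0,
                 seed: int | None = None,
                 ) -> tuple[TargetProfile, BackboneChain, list[PlantRecord]]:
    """Synthesize a native target and hide its fragments in the database.

    For every position and every fragment length, the native window's exact
    geometry *and sequence* are injected into a randomly chosen entry
    (entries are modified in place; injections never overlap an earlier
    one).  Returns the target profile (predicted SS = true SS, confidence
    1), the built native backbone, and the injection provenance.
    """
    if not db:
        raise InputError("empty database")
    if target_length < max(lengths):
        raise InputError("target shorter than the longest fragment length")
    if max(len(e) for e in db) < max(lengths):
        raise InputError("no database entry can host the longest fragment")
    weights = np.asarray(ss_composition, dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    native_geom, _ = _random_geometry(target_length, weights, angle_noise_sd, rng)
    native_seq = _random_sequence(target_length, rng)
    native_ss = assign_secondary_structure(native_geom)

    used: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(db))}
    touched: set[int] = set()
    provenance: list[PlantRecord] = []
    for f in sorted(lengths, reverse=True):
        for pos in range(target_length - f + 1):
            placed = False
            for _attempt in range(10000):
                ei = int(rng.integers(len(db)))
                entry = db[ei]
                if len(entry) < f:
                    continue
                start = int(rng.integers(len(entry) - f + 1))
                span = (start, start + f)
                if any(s < span[1] and span[0] < e for s, e in used[ei]):
                    continue
                entry.geometry[start:start + f] = native_geom[pos:pos + f]
                entry.sequence = (entry.sequence[:start]
                                  + native_seq[pos:pos + f]
                                  + entry.sequence[start + f:])
                used[ei].append(span)
                touched.add(ei)
                provenance.append(PlantRecord(f, pos, entry.entry_id, start))
                placed = True
                break
            if not placed:
                raise InputError(
                    "could not place all native windows; database too small"
                )
    for ei in touched:
        db[ei].ss = assign_secondary_structure(db[ei].geometry)

    profile = TargetProfile(native_seq, native_ss,
                            np.ones(target_length, dtype=float))
    native_chain = build_cartesian(native_geom, native_seq)
    return profile, native_chain, provenance


def synth_sspred(native_ss: str, accuracy: float,
                 confidence_when_correct: float = 0.9,
                 confidence_when_wrong: float | None = None,
                 seed: int | None = None,
                 out_path=None) -> TargetProfile:
    """Emulate a secondary-structure predictor with a set success rate.

    Each residue's predicted class equals the native class with probability
    ``accuracy``, otherwise one of the two other classes uniformly.  The
    sequence field of the returned profile is unknown ('X') placeholders;
    combine with a real sequence as needed.  Writes an .ss2 file when
    ``out_path`` is given.
    """
    if not 0.0 <= accuracy <= 1.0:
        raise InputError("accuracy must lie in [0, 1]")
    if confidence_when_wrong is None:
        confidence_when_wrong = confidence_when_correct
    rng = np.random.default_rng(seed)
    pred, conf = [], []
    for cls in native_ss:
        if rng.random() < accuracy:
            pred.append(cls)
            conf.append(confidence_when_correct)
        else:
            others = [c for c in "HEC" if c != cls]
            pred.append(others[int(rng.integers(2))])
            conf.append(confidence_when_wrong)
    profile = TargetProfile("X" * len(native_ss), "".join(pred),
                            np.asarray(conf))
    if out_path is not None:
        write_ss2(profile, out_path)
    return profile
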