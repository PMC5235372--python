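"""Fragment library generation by sliding-window scoring.

For a target of length *n* and fragment length *f*, every length-*f*
window of every database entry is scored against each of the *n−f+1*
target windows, and the top *K* (default 200) fragments per position are
kept.  Two ranking modes exist:

* ``BLO`` — sequence similarity alone: the sum of BLOSUM62 entries over the
  aligned residue pairs.
* ``PSI`` — sequence similarity plus agreement between the fragment's
  observed secondary structure and the secondary structure predicted for
  the target, weighted by the per-residue prediction confidence (a residue
  contributes +c_i on agreement and −c_i on disagreement).  Default
  weights are 1:1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .core import AA_ALPHABET, InputError, as_geom_array
from .fragdb import ParseError, SourceDatabase

__all__ = [
    "SubstitutionMatrix",
    "TargetProfile",
    "Fragment",
    "ScoredFragment",
    "FragmentLibrary",
    "score_sequence",
    "score_ss_agreement",
    "combined_score",
    "build_library",
    "read_sspred",
    "write_library",
    "read_library",
    "write_rosetta_fragments",
    "read_rosetta_fragments",
]

SS_CLASSES = "HEC"


# ---------------------------------------------------------------------------
# types

class SubstitutionMatrix:
    """Symmetric 20×20 integer substitution-score table."""

    def __init__(self, table: np.ndarray, name: str = "",
                 alphabet: str = AA_ALPHABET):
        table = np.asarray(table)
        if table.shape != (len(alphabet), len(alphabet)):
            raise InputError(f"table shape {table.shape} does not match alphabet")
        if not np.array_equal(table, table.T):
            raise InputError("substitution matrix must be symmetric")
        self.table = table.astype(float)
        self.name = name
        self.alphabet = alphabet
        self._index = {aa: i for i, aa in enumerate(alphabet)}

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        raw = substitution_matrices.load("BLOSUM62")
        idx = [raw.alphabet.index(aa) for aa in AA_ALPHABET]
        table = np.asarray(raw)[np.ix_(idx, idx)]
        return cls(table, "BLOSUM62")

    def index_of(self, aa: str) -> int:
        try:
            return self._index[aa]
        except KeyError:
            raise InputError(f"unknown residue letter {aa!r}") from None

    def score(self, a: str, b: str) -> float:
        return float(self.table[self.index_of(a), self.index_of(b)])

    def encode(self, sequence: str) -> np.ndarray:
        """Integer-encode a sequence; unknown letters map to −1."""
        return np.array([self._index.get(c, -1) for c in sequence], dtype=np.int64)


@dataclass
class TargetProfile:
    """Target sequence with per-residue predicted SS class and confidence."""

    sequence: str
    ss: str
    confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.ss) != len(self.sequence):
            raise InputError("sequence and SS prediction lengths differ")
        if any(c not in SS_CLASSES for c in self.ss):
            raise InputError("SS classes must be in {H, E, C}")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != (len(self.sequence),):
                raise InputError("confidence length differs from sequence")
            if ((self.confidence < 0) | (self.confidence > 1)).any():
                raise InputError("confidences must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)

    def window(self, start: int, stop: int) -> "TargetProfile":
        conf = None if self.confidence is None else self.confidence[start:stop]
        return TargetProfile(self.sequence[start:stop], self.ss[start:stop], conf)


@dataclass
class Fragment:
    """An excised f-residue backbone geometry with source metadata."""

    entry_id: str
    start: int
    sequence: str
    ss: str
    geometry: np.ndarray  # (f, 6)

    def __post_init__(self) -> None:
        self.geometry = as_geom_array(self.geometry)
        f = self.geometry.shape[0]
        if f < 2:
            raise InputError("fragments must span at least 2 residues")
        if not (len(self.sequence) == f == len(self.ss)):
            raise InputError("fragment sequence/SS/geometry lengths differ")

    def __len__(self) -> int:
        return self.geometry.shape[0]


@dataclass
class ScoredFragment:
    fragment: Fragment
    score: float
    mode: str  # BLO or PSI

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise InputError("fragment score must be finite")


@dataclass
class FragmentLibrary:
    """Per-position ranked fragment lists for one fragment length."""

    n: int
    f: int
    k: int
    mode: str
    slots: list[list[ScoredFragment]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slots) != self.n - self.f + 1:
            raise InputError(
                f"expected {self.n - self.f + 1} slots, got {len(self.slots)}"
            )
        for pos, slot in enumerate(self.slots):
            if len(slot) > self.k:
                raise InputError(f"slot {pos} exceeds capacity K={self.k}")
            scores = [sf.score for sf in slot]
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise InputError(f"slot {pos} not sorted by descending score")

    @property
    def n_positions(self) -> int:
        return self.n - self.f + 1


# ---------------------------------------------------------------------------
# scoring

def score_sequence(target_window: str, frag_seq: str,
                   matrix: SubstitutionMatrix) -> float:
    """Sequence-similarity score: Σ_i B(t_i, f_i)."""
    if len(target_window) != len(frag_seq):
        raise InputError("window length mismatch")
    return float(sum(matrix.score(t, q) for t, q in zip(target_window, frag_seq)))


def score_ss_agreement(profile_window: TargetProfile, frag_ss: str) -> float:
    """SS-prediction agreement score: Σ_i ±c_i.

    +c_i when the fragment's observed class equals the predicted class at
    residue *i*, −c_i otherwise.
    """
    if len(profile_window) != len(frag_ss):
        raise InputError("window length mismatch")
    if profile_window.confidence is None:
        raise InputError("profile has no confidences")
    signs = np.array([1.0 if a == b else -1.0
                      for a, b in zip(frag_ss, profile_window.ss)])
    return float(np.sum(signs * profile_window.confidence))


def combined_score(target_window: str, frag: Fragment,
                   matrix: SubstitutionMatrix, profile_window: TargetProfile,
                   w_b: float = 1.0, w_p: float = 1.0) -> float:
    """Weighted sum of the sequence and SS-agreement scores (defaults 1:1)."""
    if w_b < 0 or w_p < 0:
        raise InputError("weights must be non-negative")
    total = w_b * score_sequence(target_window, frag.sequence, matrix)
    if w_p != 0:
        total += w_p * score_ss_agreement(profile_window, frag.ss)
    return float(total)


# ---------------------------------------------------------------------------
# library construction

def _window_all(flags: np.ndarray, width: int) -> np.ndarray:
    """Sliding all-true over windows of ``width`` (1-D bool array)."""
    if width <= 0:
        raise InputError("window width must be positive")
    c = np.concatenate(([0], np.cumsum(~flags)))
    return (c[width:] - c[:-width]) == 0


def _entry_window_validity(entry, f: int) -> np.ndarray:
    """Valid windows: all residues known AA, no undefined interior angle."""
    g = entry.geometry
    known = np.array([c in AA_ALPHABET for c in entry.sequence])
    ok_all = ~np.isnan(g[:, 3]) & known                      # every residue
    ok_head = ~(np.isnan(g[:, 0]) | np.isnan(g[:, 5]))       # residues 1..f-1
    ok_tail = ~(np.isnan(g[:, 1]) | np.isnan(g[:, 2]) | np.isnan(g[:, 4]))
    w = len(entry) - f + 1
    valid = _window_all(ok_all, f)
    valid &= _window_all(ok_head[1:], f - 1)[:w]
    valid &= _window_all(ok_tail[:-1], f - 1)[:w]
    return valid


def _diag_window_sums(m: np.ndarray, f: int) -> np.ndarray:
    """S[p, w] = Σ_{i<f} m[p+i, w+i] for all window alignments."""
    npos = m.shape[0] - f + 1
    nwin = m.shape[1] - f + 1
    s = np.zeros((npos, nwin))
    for i in range(f):
        s += m[i:i + npos, i:i + nwin]
    return s


def build_library(profile: TargetProfile, db: SourceDatabase, f: int,
                  mode: str = "PSI", k: int = 200,
                  matrix: SubstitutionMatrix | None = None,
                  w_b: float = 1.0, w_p: float = 1.0) -> FragmentLibrary:
    """Score every database window at every target position; keep top K.

    Ties at the K-th rank break deterministically by (score descending,
    entry id ascending, source start ascending).
    """
    mode = mode.upper()
    if mode not in ("BLO", "PSI"):
        raise InputError(f"unknown mode {mode!r}")
    n = len(profile)
    if f > n:
        raise InputError(f"fragment length {f} exceeds target length {n}")
    if f < 2:
        raise InputError("fragment length must be at least 2")
    if len(db) == 0:
        raise InputError("empty database")
    if mode == "PSI" and profile.confidence is None:
        raise InputError("PSI mode requires prediction confidences")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    tgt_idx = np.array([matrix.index_of(c) for c in profile.sequence])
    tgt_ss = np.frombuffer(profile.ss.encode(), dtype=np.uint8)
    npos = n - f + 1

    entries = sorted(db.entries, key=lambda e: e.entry_id)
    score_blocks, valid_blocks, meta_entry, meta_start = [], [], [], []
    for rank, entry in enumerate(entries):
        w = len(entry) - f + 1
        if w <= 0:
            continue
        eidx = matrix.encode(entry.sequence)
        pair = matrix.table[tgt_idx[:, None], np.where(eidx < 0, 0, eidx)[None, :]]
        s = w_b * _diag_window_sums(pair, f)
        if mode == "PSI":
            ess = np.frombuffer(entry.ss.encode(), dtype=np.uint8)
            agree = np.where(tgt_ss[:, None] == ess[None, :], 1.0, -1.0)
            agree *= profile.confidence[:, None]
            s += w_p * _diag_window_sums(agree, f)
        score_blocks.append(s)
        valid_blocks.append(_entry_window_validity(entry, f))
        meta_entry.append(np.full(w, rank, dtype=np.int64))
        meta_start.append(np.arange(w, dtype=np.int64))

    if not score_blocks:
        raise InputError(f"no database entry admits windows of length {f}")
    scores = np.concatenate(score_blocks, axis=1)        # (npos, total_windows)
    valid = np.concatenate(valid_blocks)
    entry_rank = np.concatenate(meta_entry)
    starts = np.concatenate(meta_start)

    vi = np.flatnonzero(valid)
    v_rank, v_start = entry_rank[vi], starts[vi]
    slots: list[list[ScoredFragment]] = []
    for p in range(npos):
        row = scores[p, vi]
        order = np.lexsort((v_start, v_rank, -row))[:k]
        slot = []
        for j in order:
            e = entries[v_rank[j]]
            s0 = int(v_start[j])
            frag = Fragment(e.entry_id, s0, e.sequence[s0:s0 + f],
                            e.ss[s0:s0 + f], e.geometry[s0:s0 + f].copy())
            slot.append(ScoredFragment(frag, float(row[j]), mode))
        slots.append(slot)
    return FragmentLibrary(n, f, k, mode, slots)


# ---------------------------------------------------------------------------
# PSIPRED ss2 input

def read_sspred(ss2_file) -> TargetProfile:
    """Read a PSIPRED .ss2 vertical-format prediction.

    The printed class column is authoritative; the confidence is the
    probability printed for that class.  A printed class disagreeing with
    the probability argmax triggers a warning, not an error.
    """
    path = Path(ss2_file)
    seq, ss, conf = [], [], []
    expected = 1
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 6:
            raise ParseError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
        idx = int(fields[0])
        if idx != expected:
            raise ParseError(f"{path}:{lineno}: residue index {idx}, expected {expected}")
        expected += 1
        aa, cls = fields[1], fields[2]
        if cls not in SS_CLASSES:
            raise ParseError(f"{path}:{lineno}: bad SS class {cls!r}")
        probs = {"C": float(fields[3]), "H": float(fields[4]), "E": float(fields[5])}
        argmax = max(probs, key=probs.get)
        if argmax != cls:
            warnings.warn(
                f"{path}:{lineno}: printed class {cls} disagrees with "
                f"probability argmax {argmax}; keeping printed class"
            )
        seq.append(aa)
        ss.append(cls)
        conf.append(min(1.0, max(0.0, probs[cls])))
    if not seq:
        raise ParseError(f"{path}: no prediction rows")
    return TargetProfile("".join(seq), "".join(ss), np.asarray(conf))


def write_ss2(profile: TargetProfile, path) -> None:
    """Write a profile as a PSIPRED-style .ss2 file."""
    if profile.confidence is None:
        raise InputError("profile has no confidences to write")
    lines = ["# PSIPRED VFORMAT (fraglib synthetic)", ""]
    for i, (aa, cls, c) in enumerate(
            zip(profile.sequence, profile.ss, profile.confidence), start=1):
        probs = {"C": 0.0, "H": 0.0, "E": 0.0}
        probs[cls] = c
        rest = (1.0 - c) / 2.0
        for other in probs:
            if other != cls:
                probs[other] = rest
        lines.append(f"{i:4d} {aa} {cls}  {probs['C']:6.3f} {probs['H']:6.3f} {probs['E']:6.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# native library format

_LIB_VERSION = "FRAGLIB v1"


def write_library(lib: FragmentLibrary, path) -> None:
    """Write the versioned TSV library format (lossless round trip)."""
    lines = [f"{_LIB_VERSION} n={lib.n} f={lib.f} K={lib.k} mode={lib.mode}"]
    for pos, slot in enumerate(lib.slots):
        for rank, sf in enumerate(slot):
            frag = sf.fragment
            row = [str(pos), str(rank), format(sf.score, ".17g"),
                   frag.entry_id, str(frag.start), frag.sequence, frag.ss]
            for res in frag.geometry:
                row.extend("NA" if np.isnan(v) else format(v, ".17g") for v in res)
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_library(path) -> FragmentLibrary:
    """Read a library written by :func:`write_library`."""
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith(_LIB_VERSION + " "):
        raise ParseError(f"{path}: missing or unsupported library header")
    header = dict(kv.split("=") for kv in text[0].split()[2:])
    try:
        n, f, k = int(header["n"]), int(header["f"]), int(header["K"])
        mode = header["mode"]
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: bad header fields: {exc}") from exc
    slots: list[list[ScoredFragment]] = [[] for _ in range(n - f + 1)]
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 7 + 6 * f:
            raise ParseError(f"{path}:{lineno}: truncated or malformed row")
        pos, rank = int(fields[0]), int(fields[1])
        geom = np.array(
            [np.nan if v == "NA" else float(v) for v in fields[7:]],
            dtype=float).reshape(f, 6)
        frag = Fragment(fields[3], int(fields[4]), fields[5], fields[6], geom)
        if rank != len(slots[pos]):
            raise ParseError(f"{path}:{lineno}: ranks out of order")
        slots[pos].append(ScoredFragment(frag, float(fields[2]), mode))
    return FragmentLibrary(n, f, k, mode, slots)


# ---------------------------------------------------------------------------
# Rosetta-compatible fragment files

def write_rosetta_fragments(lib: FragmentLibrary, path,
                            chain_id: str = "A") -> None:
    """Write classic Rosetta fragment format.

    Per position a ``position: … neighbors: …`` header (1-based positions),
    then one line per fragment residue (source id, chain, source residue
    number, aa, ss, phi, psi, omega) with a blank line between fragments.
    Undefined terminal torsions are written as 0.000.
    """
    if all(len(slot) == 0 for slot in lib.slots):
        raise InputError("refusing to write an empty library")
    out = []
    for pos, slot in enumerate(lib.slots):
        out.append(f" position: {pos + 1:12d} neighbors: {len(slot):10d}")
        out.append("")
        for sf in slot:
            frag = sf.fragment
            for i in range(len(frag)):
                phi, psi, omega = np.nan_to_num(frag.geometry[i, :3])
                out.append(
                    f" {frag.entry_id:>4} {chain_id} {frag.start + i + 1:5d} "
                    f"{frag.sequence[i]} {frag.ss[i]} "
                    f"{phi:9.3f} {psi:9.3f} {omega:9.3f}"
                )
            out.append("")
    Path(path).write_text("\n".join(out) + "\n")


def read_rosetta_fragments(path):
    """Parse a Rosetta fragment file back to per-position fragment records.

    Returns ``{position (0-based): [fragment, ...]}`` where each fragment is
    a list of per-residue dicts.  Used for format round-trip verification.
    """
    positions: dict[int, list] = {}
    current_pos = None
    current_frag: list = []
    for line in Path(path).read_text().splitlines():
        if line.strip().startswith("position:"):
            parts = line.split()
            current_pos = int(parts[1]) - 1
            declared = int(parts[3])
            positions[current_pos] = []
            positions[current_pos].append(("neighbors", declared))
            current_frag = []
            continue
        if not line.strip():
            if current_frag and current_pos is not None:
                positions[current_pos].append(current_frag)
                current_frag = []
            continue
        fields = line.split()
        if current_pos is None or len(fields) != 8:
            raise ParseError(f"unexpected fragment line: {line!r}")
        current_frag.append({
            "entry_id": fields[0], "chain": fields[1],
            "resnum": int(fields[2]), "aa": fields[3], "ss": fields[4],
            "phi": float(fields[5]), "psi": float(fields[6]),
            "omega": float(fields[7]),
        })
    if current_frag and current_pos is not None:
        positions[current_pos].append(current_frag)
    out = {}
    for pos, items in positions.items():
        declared = items[0][1]
        frags = items[1:]
        if len(frags) != declared:
            raise ParseError(
                f"position {pos + 1}: declared {declared} neighbors, "
                f"found {len(frags)}"
            )
        out[pos] = frags
    return out
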