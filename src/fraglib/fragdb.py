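"""Structure database: PDB backbone reading, secondary structure, storage.

The source database holds non-redundant single chains reduced to the
per-residue internal-coordinate representation plus an observed 3-class
secondary-structure string.  Homology exclusion is consumed as a list of
entry ids (the culling and homology searches that produce such lists are
external to this package).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException
from Bio.PDB.Polypeptide import protein_letters_3to1

from .core import BackboneChain, InputError, ResidueGeometry, as_geom_array
from .geometry import GAP_C_N_CUTOFF, extract_internal_coordinates, internal_coords_array

__all__ = [
    "SourceEntry",
    "SourceDatabase",
    "ParseError",
    "read_backbone",
    "assign_secondary_structure",
    "build_database",
    "entry_from_chain",
    "write_database",
    "read_database",
    "write_backbone_pdb",
]

BACKBONE_ATOMS = ("N", "CA", "C")


class ParseError(ValueError):
    """Raised for malformed or unusable structure/prediction files."""


# ---------------------------------------------------------------------------
# PDB reading / writing

def _select_altloc(residue, name: str):
    """Return the atom, honouring the keep-' '-or-'A' altloc rule."""
    if name not in residue:
        return None
    atom = residue[name]
    if atom.is_disordered():
        children = atom.child_dict
        for alt in ("A", " "):
            if alt in children:
                return children[alt]
        return None
    if atom.get_altloc() not in (" ", "A"):
        return None
    return atom


def read_backbone(structure_file, chain_id: str) -> BackboneChain:
    """Read one chain's N/Cα/C backbone from a PDB file.

    Residues missing any backbone atom are dropped; chain breaks (a dropped
    residue, a gap in numbering with a long C–N distance, or any C(i)–N(i+1)
    distance above 2.5 Å) are recorded so that internal coordinates never
    span them.  Hetero records and waters are ignored; altloc 'A' (or blank)
    is kept; insertion-coded residues are kept in file order.
    """
    path = Path(structure_file)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(PERMISSIVE=True, QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            structure = parser.get_structure(path.stem, str(path))
        except (PDBConstructionException, ValueError) as exc:
            raise ParseError(f"{path}: malformed PDB record: {exc}") from exc
    model = next(structure.get_models(), None)
    if model is None or chain_id not in model:
        raise KeyError(f"chain {chain_id!r} not found in {path}")
    chain = model[chain_id]

    coords, seq, dropped_before = [], [], []
    pending_drop = False
    for residue in chain:
        if residue.id[0] != " ":
            continue  # hetero/water
        atoms = [_select_altloc(residue, name) for name in BACKBONE_ATOMS]
        if any(a is None for a in atoms):
            pending_drop = True
            continue
        coords.append([a.get_coord() for a in atoms])
        resname = residue.get_resname().strip()
        seq.append(protein_letters_3to1.get(resname, "X"))
        dropped_before.append(pending_drop)
        pending_drop = False

    if not coords:
        raise ParseError(f"{path}: chain {chain_id!r} has no complete backbone residue")
    arr = np.asarray(coords, dtype=float)
    breaks = set()
    for i in range(len(arr) - 1):
        c_n = np.linalg.norm(arr[i + 1, 0] - arr[i, 2])
        if dropped_before[i + 1] or not np.isfinite(c_n) or c_n > GAP_C_N_CUTOFF:
            breaks.add(i)
    return BackboneChain(arr, "".join(seq), frozenset(breaks))


def write_backbone_pdb(chain: BackboneChain, path, chain_id: str = "A") -> None:
    """Write a backbone-only PDB file (ATOM records for N, Cα, C)."""
    one_to_three = {v: k for k, v in protein_letters_3to1.items()}
    lines = []
    serial = 1
    for i in range(chain.n_residues):
        resname = one_to_three.get(chain.sequence[i], "UNK")
        for j, name in enumerate(BACKBONE_ATOMS):
            x, y, z = chain.coords[i, j]
            lines.append(
                f"ATOM  {serial:>5} {name:^4} {resname:<3} {chain_id}{i + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# secondary structure

HELIX_PHI = (-100.0, -30.0)
HELIX_PSI = (-80.0, -5.0)
STRAND_PHI = (-180.0, -40.0)
STRAND_PSI_HIGH = (60.0, 180.0)
STRAND_PSI_LOW = (-180.0, -170.0)


def _in(value: float, lo_hi: tuple[float, float]) -> bool:
    """Bin membership; an undefined (NaN) angle matches any bin."""
    if np.isnan(value):
        return True
    return lo_hi[0] <= value <= lo_hi[1]


def assign_secondary_structure(geoms) -> str:
    """Torsion-bin 3-class secondary structure (H/E/C) per residue.

    H: phi in [−100, −30] and psi in [−80, −5]; E: phi in [−180, −40] and
    psi in [60, 180] ∪ [−180, −170]; else C.  An angle undefined at a
    terminus acts as a wildcard; a residue with both phi and psi undefined
    is C.  Deterministic and total.  Any callable with this signature can
    stand in (e.g. to wrap an external assigner with a 7→3 class mapping).
    """
    g = as_geom_array(geoms)
    if g.shape[0] == 0:
        raise InputError("empty geometry list")
    out = []
    for phi, psi in g[:, :2]:
        if np.isnan(phi) and np.isnan(psi):
            out.append("C")
        elif _in(phi, HELIX_PHI) and _in(psi, HELIX_PSI):
            out.append("H")
        elif _in(phi, STRAND_PHI) and (_in(psi, STRAND_PSI_HIGH)
                                       or _in(psi, STRAND_PSI_LOW)):
            out.append("E")
        else:
            out.append("C")
    return "".join(out)


# ---------------------------------------------------------------------------
# database container

@dataclass
class SourceEntry:
    """One database chain in internal-coordinate form."""

    entry_id: str
    sequence: str
    geometry: np.ndarray  # (n, 6) degrees, NaN = undefined
    ss: str

    def __post_init__(self) -> None:
        self.geometry = as_geom_array(self.geometry)
        n = self.geometry.shape[0]
        if not (len(self.sequence) == n == len(self.ss)):
            raise InputError(
                f"entry {self.entry_id}: sequence ({len(self.sequence)}), "
                f"geometry ({n}) and SS ({len(self.ss)}) lengths differ"
            )

    def __len__(self) -> int:
        return self.geometry.shape[0]

    def residue_geometries(self) -> list[ResidueGeometry]:
        from .core import array_to_geoms
        return array_to_geoms(self.geometry)


@dataclass
class SourceDatabase:
    """Non-redundant source entries with homology exclusions applied."""

    entries: list[SourceEntry]
    excluded_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate entry id(s): {dup}")
        self.excluded_ids = frozenset(self.excluded_ids)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def build_database(entries: list[SourceEntry],
                   exclusion_ids=()) -> SourceDatabase:
    """Assemble the database, removing homology-excluded entries.

    The exclusion list embodies an externally-run homology filter against
    the target (entries too similar to the target must not serve fragments).
    """
    ids = [e.entry_id for e in entries]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate entry id(s): {dup}")
    excl = frozenset(exclusion_ids)
    kept = [e for e in entries if e.entry_id not in excl]
    return SourceDatabase(kept, excl)


def entry_from_chain(entry_id: str, chain: BackboneChain) -> SourceEntry:
    """Convert a Cartesian backbone to a database entry."""
    geom = internal_coords_array(chain)
    ss = assign_secondary_structure(geom)
    return SourceEntry(entry_id, chain.sequence, geom, ss)


# ---------------------------------------------------------------------------
# TSV serialization

_DB_COLUMNS = ("res_index", "aa", "ss", "phi", "psi", "omega",
               "ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca")


def _fmt(x: float) -> str:
    return "NA" if np.isnan(x) else format(x, ".17g")


def write_database(db: SourceDatabase, out_dir) -> None:
    """Write one TSV per entry plus a manifest of entry ids."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for entry in db.entries:
        lines = ["\t".join(_DB_COLUMNS)]
        for i in range(len(entry)):
            row = [str(i), entry.sequence[i], entry.ss[i]]
            row.extend(_fmt(v) for v in entry.geometry[i])
            lines.append("\t".join(row))
        (out / f"{entry.entry_id}.tsv").write_text("\n".join(lines) + "\n")
    manifest = [e.entry_id for e in db.entries]
    manifest.extend(f"# excluded\t{i}" for i in sorted(db.excluded_ids))
    (out / "manifest.txt").write_text("\n".join(manifest) + "\n")


def read_database(in_dir) -> SourceDatabase:
    """Read a database written by :func:`write_database`."""
    src = Path(in_dir)
    manifest = src / "manifest.txt"
    if not manifest.exists():
        raise ParseError(f"missing manifest: {manifest}")
    ids, excluded = [], []
    for line in manifest.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("# excluded\t"):
            excluded.append(line.split("\t", 1)[1])
        else:
            ids.append(line.strip())
    entries = []
    for entry_id in ids:
        path = src / f"{entry_id}.tsv"
        rows = path.read_text().splitlines()
        if not rows or rows[0].split("\t") != list(_DB_COLUMNS):
            raise ParseError(f"{path}: bad header")
        seq, ss, geom = [], [], []
        for line in rows[1:]:
            fields = line.split("\t")
            if len(fields) != len(_DB_COLUMNS):
                raise ParseError(f"{path}: bad row: {line!r}")
            seq.append(fields[1])
            ss.append(fields[2])
            geom.append([np.nan if v == "NA" else float(v) for v in fields[3:]])
        entries.append(SourceEntry(entry_id, "".join(seq),
                                   np.asarray(geom, dtype=float), "".join(ss)))
    return SourceDatabase(entries, frozenset(excluded))
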