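"""Core backbone types shared across the package.

A protein backbone is represented two ways:

* Cartesian — :class:`BackboneChain`, an ``(n, 3, 3)`` array of N/Cα/C
  coordinates in Å plus the one-letter sequence.
* Internal — per-residue :class:`ResidueGeometry`: the three backbone
  dihedrals (phi, psi, omega) and the three backbone bond angles
  (N-Cα-C, Cα-C-N, C-N-Cα), all in degrees.  Bond lengths are not part of
  the representation; canonical values (Engh–Huber) are used whenever
  Cartesian coordinates are rebuilt.

Angles that are undefined at a chain terminus (or at a chain break) are
stored as NaN.  Internally, geometry lists are handled as ``(n, 6)``
float arrays with the column order ``PHI, PSI, OMEGA, ANG_N_CA_C,
ANG_CA_C_N, ANG_C_N_CA``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BOND_N_CA",
    "BOND_CA_C",
    "BOND_C_N",
    "STRETCHED_ANG_N_CA_C",
    "STRETCHED_ANG_CA_C_N",
    "STRETCHED_ANG_C_N_CA",
    "PHI",
    "PSI",
    "OMEGA",
    "ANG_N_CA_C",
    "ANG_CA_C_N",
    "ANG_C_N_CA",
    "AA_ALPHABET",
    "ResidueGeometry",
    "BackboneChain",
    "geoms_to_array",
    "array_to_geoms",
    "as_geom_array",
    "InputError",
]

# Canonical backbone bond lengths in Å (Engh & Huber).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329

# Bond angles (degrees) used for the stretched starting conformation.
STRETCHED_ANG_N_CA_C = 110.5
STRETCHED_ANG_CA_C_N = 116.6
STRETCHED_ANG_C_N_CA = 121.7

# Column indices of the (n, 6) internal-coordinate array.
PHI, PSI, OMEGA, ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA = range(6)

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"


class InputError(ValueError):
    """Raised when an operation receives arguments violating its contract."""


def _check_dihedral(name: str, value: float) -> None:
    if math.isnan(value):
        return
    if not (-180.0 < value <= 180.0):
        raise InputError(f"{name}={value!r} outside (-180, 180]")


def _check_bond_angle(name: str, value: float) -> None:
    if math.isnan(value):
        return
    if not (0.0 < value < 180.0):
        raise InputError(f"{name}={value!r} outside (0, 180)")


@dataclass(frozen=True)
class ResidueGeometry:
    """Internal coordinates of one residue (degrees; NaN = undefined)."""

    phi: float
    psi: float
    omega: float
    ang_n_ca_c: float
    ang_ca_c_n: float
    ang_c_n_ca: float

    def __post_init__(self) -> None:
        _check_dihedral("phi", self.phi)
        _check_dihedral("psi", self.psi)
        _check_dihedral("omega", self.omega)
        _check_bond_angle("ang_n_ca_c", self.ang_n_ca_c)
        _check_bond_angle("ang_ca_c_n", self.ang_ca_c_n)
        _check_bond_angle("ang_c_n_ca", self.ang_c_n_ca)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.phi, self.psi, self.omega,
             self.ang_n_ca_c, self.ang_ca_c_n, self.ang_c_n_ca],
            dtype=float,
        )

    @classmethod
    def from_array(cls, row: Sequence[float]) -> "ResidueGeometry":
        return cls(*(float(x) for x in row))


def geoms_to_array(geoms: Iterable[ResidueGeometry]) -> np.ndarray:
    """Stack residue geometries into an ``(n, 6)`` float array."""
    rows = [g.to_array() for g in geoms]
    if not rows:
        return np.empty((0, 6), dtype=float)
    return np.vstack(rows)


def array_to_geoms(arr: np.ndarray) -> list[ResidueGeometry]:
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise InputError(f"expected (n, 6) geometry array, got shape {arr.shape}")
    return [ResidueGeometry.from_array(row) for row in arr]


def as_geom_array(geoms) -> np.ndarray:
    """Coerce a geometry list or array to a validated ``(n, 6)`` float array."""
    if isinstance(geoms, np.ndarray):
        if geoms.ndim != 2 or geoms.shape[1] != 6:
            raise InputError(f"expected (n, 6) geometry array, got shape {geoms.shape}")
        return np.asarray(geoms, dtype=float)
    return geoms_to_array(list(geoms))


@dataclass
class BackboneChain:
    """Ordered backbone (N, Cα, C) coordinates plus sequence.

    Parameters
    ----------
    coords
        ``(n, 3, 3)`` array: residue, atom (N/Cα/C), xyz in Å.
    sequence
        One-letter amino-acid string of length ``n``.
    breaks
        Residue indices ``i`` after which the chain is broken (a residue
        was dropped or the C(i)–N(i+1) distance exceeds the gap cutoff).
        Internal coordinates are never computed across a break.
    """

    coords: np.ndarray
    sequence: str
    breaks: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise InputError(
                f"coords must be (n, 3, 3), got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise InputError("chain must contain at least one residue")
        if len(self.sequence) != self.coords.shape[0]:
            raise InputError(
                f"sequence length {len(self.sequence)} != residue count "
                f"{self.coords.shape[0]}"
            )
        self.breaks = frozenset(self.breaks)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    def atoms(self) -> np.ndarray:
        """Flat ``(3n, 3)`` atom coordinates in N, Cα, C order per residue."""
        return self.coords.reshape(-1, 3)

    def ca(self) -> np.ndarray:
        """``(n, 3)`` Cα coordinates."""
        return self.coords[:, 1, :]
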