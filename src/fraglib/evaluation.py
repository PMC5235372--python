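"""Diagnostic summaries over fragment libraries and assembly logs.

These reproduce, at whatever scale the inputs have, the quantities used to
characterise libraries and search behaviour: per-residue secondary-
structure correctness of a library against the native assignment, the
per-position SS composition profile, Ramachandran scatter data, and the
relative use of each fragment length per search stage.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .core import BackboneChain, InputError, as_geom_array
from .geometry import internal_coords_array
from .librarygen import FragmentLibrary

__all__ = [
    "ss_correct_ratio",
    "ss_correct_by_class",
    "library_ss_profile",
    "ramachandran_points",
    "insertion_frequency",
]


def _coverage_counts(lib: FragmentLibrary, match_ss: str | None):
    """Per-residue (covering, matching) fragment counts."""
    n = lib.n
    covering = np.zeros(n, dtype=np.int64)
    matching = np.zeros(n, dtype=np.int64)
    for pos, slot in enumerate(lib.slots):
        for sf in slot:
            for i, cls in enumerate(sf.fragment.ss):
                r = pos + i
                covering[r] += 1
                if match_ss is not None and cls == match_ss[r]:
                    matching[r] += 1
    return covering, matching


def ss_correct_ratio(lib: FragmentLibrary, native_ss: str) -> np.ndarray:
    """Percent of covering fragments with the correct SS, per residue.

    Residues covered by no fragment are NaN.
    """
    if len(native_ss) != lib.n:
        raise InputError(
            f"native SS length {len(native_ss)} != target length {lib.n}")
    covering, matching = _coverage_counts(lib, native_ss)
    with np.errstate(invalid="ignore"):
        return np.where(covering > 0,
                        100.0 * matching / np.maximum(covering, 1), np.nan)


def ss_correct_by_class(lib: FragmentLibrary, native_ss: str) -> dict[str, float]:
    """Mean per-residue correctness split by the native class (H/E/C)."""
    ratios = ss_correct_ratio(lib, native_ss)
    out: dict[str, float] = {}
    for cls in "HEC":
        vals = [r for r, c in zip(ratios, native_ss)
                if c == cls and not np.isnan(r)]
        if vals:
            out[cls] = float(np.mean(vals))
    return out


def library_ss_profile(lib: FragmentLibrary) -> np.ndarray:
    """Per-residue H/E/C percentages among covering fragments.

    Returns an ``(n, 3)`` array with columns H, E, C summing to 100 per
    row; rows with no coverage are NaN.
    """
    n = lib.n
    counts = np.zeros((n, 3), dtype=np.int64)
    idx = {"H": 0, "E": 1, "C": 2}
    for pos, slot in enumerate(lib.slots):
        for sf in slot:
            for i, cls in enumerate(sf.fragment.ss):
                counts[pos + i, idx[cls]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    out = np.full((n, 3), np.nan)
    covered = totals[:, 0] > 0
    out[covered] = 100.0 * counts[covered] / totals[covered]
    return out


def ramachandran_points(obj) -> list[tuple]:
    """All defined (phi, psi) pairs, tagged by fragment length.

    ``obj`` may be a :class:`FragmentLibrary` (tuples ``(phi, psi, f)``),
    a :class:`BackboneChain`, or a geometry array/list (tuples
    ``(phi, psi)``).
    """
    points: list[tuple] = []
    if isinstance(obj, FragmentLibrary):
        for slot in obj.slots:
            for sf in slot:
                for phi, psi in sf.fragment.geometry[:, :2]:
                    if not (np.isnan(phi) or np.isnan(psi)):
                        points.append((float(phi), float(psi), obj.f))
        return points
    geom = internal_coords_array(obj) if isinstance(obj, BackboneChain) \
        else as_geom_array(obj)
    for phi, psi in geom[:, :2]:
        if not (np.isnan(phi) or np.isnan(psi)):
            points.append((float(phi), float(psi)))
    return points


def insertion_frequency(events, accepted_only: bool = True
                        ) -> dict[str, dict[int, float]]:
    """Relative use of each fragment length per stage.

    Counts accepted insertions by default (set ``accepted_only=False`` to
    count evaluations instead); within each stage the frequencies over
    lengths sum to 1.  Stages with no counted events are omitted.
    """
    counts: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    for e in events:
        if accepted_only and not e.accepted:
            continue
        counts[e.stage][e.length] += 1
    out: dict[str, dict[int, float]] = {}
    for stage, by_len in counts.items():
        total = sum(by_len.values())
        out[stage] = {f: c / total for f, c in sorted(by_len.items())}
    return out
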