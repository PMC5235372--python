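"""Leader clustering of library slots by structural similarity.

Fragments are scanned in descending score order; a fragment joins the
first existing leader whose DME to it is within the cutoff, otherwise it
founds a new cluster.  DME is computed superposition-free on each
fragment's own built backbone, consistent with the assembly cost function.
The clustered library keeps only the leaders (the highest-scoring member
of each cluster), preserving score order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import InputError
from .geometry import build_coords
from .librarygen import FragmentLibrary, ScoredFragment

__all__ = [
    "Cluster",
    "DEFAULT_CUTOFFS",
    "leader_cluster",
    "clustered_library",
    "cluster_report",
]

# DME cutoffs (Å) by fragment length for 3-, 6- and 9-mers.
DEFAULT_CUTOFFS = {3: 0.05, 6: 0.7, 9: 1.5}


@dataclass
class Cluster:
    leader: ScoredFragment
    members: list[ScoredFragment] = field(default_factory=list)
    cutoff: float = 0.0


def leader_cluster(slot: list[ScoredFragment], cutoff: float) -> list[Cluster]:
    """Partition one ranked slot into leader clusters.

    ``slot`` must be sorted by non-increasing score and contain fragments
    of one length.  Deterministic given the slot order.
    """
    if not slot:
        return []
    lengths = {len(sf.fragment) for sf in slot}
    if len(lengths) != 1:
        raise InputError(f"mixed fragment lengths in slot: {sorted(lengths)}")
    scores = [sf.score for sf in slot]
    if any(a < b for a, b in zip(scores, scores[1:])):
        raise InputError("slot must be sorted by descending score")

    clusters: list[Cluster] = []
    leader_coords: list[np.ndarray] = []
    for sf in slot:
        coords = build_coords(sf.fragment.geometry)
        placed = False
        for cl, lc in zip(clusters, leader_coords):
            if _kernels.dme_pairs(coords, lc) <= cutoff:
                cl.members.append(sf)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(sf, [sf], cutoff))
            leader_coords.append(coords)
    return clusters


def clustered_library(lib: FragmentLibrary,
                      cutoffs: dict[int, float] | None = None) -> FragmentLibrary:
    """Replace each slot by its cluster leaders (score order preserved)."""
    if cutoffs is None:
        cutoffs = DEFAULT_CUTOFFS
    if lib.f not in cutoffs:
        raise InputError(f"no clustering cutoff configured for length {lib.f}")
    cutoff = cutoffs[lib.f]
    slots = [[cl.leader for cl in leader_cluster(slot, cutoff)]
             for slot in lib.slots]
    return FragmentLibrary(lib.n, lib.f, lib.k, lib.mode, slots)


def cluster_report(lib: FragmentLibrary,
                   cutoffs: dict[int, float] | None = None) -> list[dict]:
    """Per-position fragment and cluster counts (search-space reduction)."""
    if cutoffs is None:
        cutoffs = DEFAULT_CUTOFFS
    cutoff = cutoffs[lib.f]
    rows = []
    for pos, slot in enumerate(lib.slots):
        rows.append({
            "position": pos,
            "n_fragments": len(slot),
            "n_clusters": len(leader_cluster(slot, cutoff)),
        })
    return rows
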