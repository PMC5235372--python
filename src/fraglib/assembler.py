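"""Three-stage greedy fragment assembly under the DME cost function.

The model starts from a stretched conformation (all defined dihedrals at
180°) and is improved by fragment insertions — replacing the dihedral and
bond angles of a span by those of a library fragment — through three
stages:

1. *local*: positions are visited in random order; at each, every slot
   fragment is evaluated by the DME of the fragment span against the
   reference and the minimizer is inserted if it strictly improves the
   current local DME.  Passes repeat until a full pass accepts nothing.
2. *global*: random position pairs are drawn without replacement; for each
   pair, ``pair_trials`` random fragment pairs are evaluated jointly and
   the best pair is inserted iff it strictly improves the global DME.
   Inserting two spans at once lets the search escape local minima.
3. *refinement*: like the local stage but scored on global DME — every
   slot fragment is tested and the best inserted iff it strictly improves.

With libraries of several fragment lengths, each stage draws the lengths
in random order and runs once per length.  Every insertion is logged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .core import BackboneChain, InputError
from .geometry import build_coords, stretched_geometry
from .librarygen import FragmentLibrary

__all__ = [
    "AssemblyConfig",
    "InsertionEvent",
    "ModelState",
    "RunSummary",
    "stage_local",
    "stage_global",
    "stage_refine",
    "run_assembly",
    "run_batch",
]

STAGES = ("local", "global", "refine")


@dataclass
class AssemblyConfig:
    """Search parameters.

    ``pair_trials`` random fragment pairs are tested per position pair in
    the global stage; ``n_runs`` independent runs make up a batch.
    ``tol`` sets the strict-improvement margin (0 = any strict decrease).
    """

    seed: int = 0
    pair_trials: int = 200
    lengths: tuple[int, ...] = (3, 6, 9)
    do_local: bool = True
    do_global: bool = True
    do_refine: bool = True
    n_runs: int = 30
    tol: float = 0.0
    local_max_passes: int = 10

    def __post_init__(self) -> None:
        if self.pair_trials < 1:
            raise InputError("pair_trials must be >= 1")
        if self.local_max_passes < 1:
            raise InputError("local_max_passes must be >= 1")
        if not self.lengths:
            raise InputError("lengths schedule must be nonempty")
        if self.n_runs < 1:
            raise InputError("n_runs must be >= 1")


@dataclass(frozen=True)
class InsertionEvent:
    """One evaluated (and possibly accepted) insertion.

    ``dme_before``/``dme_after`` are in the stage's own cost (local DME for
    the local stage, global DME otherwise); the global DME before/after is
    always recorded alongside.
    """

    stage: str
    length: int
    position: int
    rank: int
    dme_before: float
    dme_after: float
    accepted: bool
    global_before: float
    global_after: float


@dataclass
class ModelState:
    """Evolving model during assembly."""

    reference: BackboneChain
    geometry: np.ndarray          # (n, 6) degrees
    coords: np.ndarray            # (3n, 3)
    global_dme: float
    events: list[InsertionEvent] = field(default_factory=list)
    geometry_rad: np.ndarray | None = None  # maintained by the stages

    def chain(self) -> BackboneChain:
        n = self.geometry.shape[0]
        return BackboneChain(self.coords.reshape(n, 3, 3),
                             self.reference.sequence)


@dataclass(frozen=True)
class RunSummary:
    run: int
    seed: int
    dme: float
    rmsd: float
    n_accepted: int


class _LibraryCache:
    """Per-(library, reference) candidate data reused across runs.

    Holds, per position: the stacked fragment geometry arrays and each
    fragment's span DME against the reference (the candidate local DME —
    the DME of a span depends only on the span's own internal geometry, so
    it can be computed on the fragment built in isolation).
    """

    def __init__(self, lib: FragmentLibrary, reference: BackboneChain):
        self.f = lib.f
        ref_atoms = reference.atoms()
        self.geoms: list[np.ndarray] = []
        self.local_cand: list[np.ndarray] = []
        f = lib.f
        self.geoms_rad: list[np.ndarray] = []
        for pos, slot in enumerate(lib.slots):
            if slot:
                stack = np.stack([sf.fragment.geometry for sf in slot])
            else:
                stack = np.empty((0, f, 6))
            self.geoms.append(stack)
            self.geoms_rad.append(np.deg2rad(stack))
            ref_span = np.ascontiguousarray(ref_atoms[3 * pos:3 * (pos + f)])
            cand = np.array([
                _kernels.dme_pairs(build_coords(stack[k]), ref_span)
                for k in range(stack.shape[0])
            ])
            self.local_cand.append(cand)


class _Runtime:
    """Reference-derived caches shared by the stages of one or more runs."""

    def __init__(self, reference: BackboneChain,
                 libs: dict[int, FragmentLibrary]):
        for f, lib in libs.items():
            if lib.f != f:
                raise InputError(f"library keyed {f} has fragment length {lib.f}")
            if lib.n != reference.n_residues:
                raise InputError(
                    f"library target length {lib.n} != reference length "
                    f"{reference.n_residues}"
                )
        self.reference = reference
        self.libs = libs
        self.ref_atoms = reference.atoms()
        self.ref_condensed = _kernels.condensed_dists(self.ref_atoms)
        self.caches = {f: _LibraryCache(lib, reference)
                       for f, lib in libs.items()}
        self._warned: set[tuple[int, int]] = set()

    def warn_empty(self, f: int, pos: int) -> None:
        if (f, pos) not in self._warned:
            self._warned.add((f, pos))
            warnings.warn(f"empty slot at position {pos} (length {f}); skipped")


def _initial_state(runtime: _Runtime) -> ModelState:
    n = runtime.reference.n_residues
    geom = stretched_geometry(n)
    coords = build_coords(geom)
    g = _kernels.dme_vs_condensed(coords, runtime.ref_condensed)
    state = ModelState(runtime.reference, geom, coords, float(g))
    state.geometry_rad = np.deg2rad(geom)
    return state


def _write_frag(geom: np.ndarray, frag_geom: np.ndarray, pos: int) -> None:
    """In-place masked angle replacement (NaN keeps the model's value)."""
    f = frag_geom.shape[0]
    window = geom[pos:pos + f]
    mask = ~np.isnan(frag_geom)
    window[mask] = frag_geom[mask]


def _commit(state: ModelState, runtime: _Runtime, geom: np.ndarray) -> float:
    """Adopt a geometry: full rebuild (avoids incremental drift)."""
    state.geometry = geom
    state.geometry_rad = np.deg2rad(geom)
    state.coords = build_coords(geom)
    state.global_dme = float(
        _kernels.dme_vs_condensed(state.coords, runtime.ref_condensed))
    return state.global_dme


def _span_local_dme(state: ModelState, runtime: _Runtime,
                    pos: int, f: int) -> float:
    a = np.ascontiguousarray(state.coords[3 * pos:3 * (pos + f)])
    b = np.ascontiguousarray(runtime.ref_atoms[3 * pos:3 * (pos + f)])
    return float(_kernels.dme_pairs(a, b))


def stage_local(state: ModelState, lib: FragmentLibrary,
                cfg: AssemblyConfig, rng: np.random.Generator,
                runtime: _Runtime | None = None) -> ModelState:
    """Greedy per-position optimization of local DME.

    Passes repeat until a full pass accepts no insertion, or at most
    ``local_max_passes`` passes.  The cap is a termination guard: the local
    objective is per-span, so insertions at overlapping positions can
    oscillate indefinitely when the library holds no mutually consistent
    fragments (the later stages, monotone in global DME, cannot cycle).
    """
    runtime = runtime or _Runtime(state.reference, {lib.f: lib})
    cache = runtime.caches[lib.f]
    f = lib.f
    for _pass in range(cfg.local_max_passes):
        accepted_any = False
        for pos in rng.permutation(lib.n_positions):
            pos = int(pos)
            cand = cache.local_cand[pos]
            if cand.size == 0:
                runtime.warn_empty(f, pos)
                continue
            current = _span_local_dme(state, runtime, pos, f)
            best = int(np.argmin(cand))
            if cand[best] < current - cfg.tol:
                geom = state.geometry.copy()
                _write_frag(geom, cache.geoms[pos][best], pos)
                g_before = state.global_dme
                g_after = _commit(state, runtime, geom)
                state.events.append(InsertionEvent(
                    "local", f, pos, best, current, float(cand[best]),
                    True, g_before, g_after))
                accepted_any = True
            else:
                state.events.append(InsertionEvent(
                    "local", f, pos, best, current, float(cand[best]),
                    False, state.global_dme, state.global_dme))
        if not accepted_any:
            break
    return state


def _try_commit(state: ModelState, runtime: _Runtime, geom: np.ndarray,
                threshold: float) -> tuple[bool, float]:
    """Commit ``geom`` iff its exactly recomputed global DME beats ``threshold``.

    The trial search scores candidates with an incremental rebuild; the
    committed value is recomputed from a full rebuild, and acceptance is
    decided on that exact value so the strict-improvement invariant holds
    without floating-point edge cases.
    """
    old = (state.geometry, state.geometry_rad, state.coords, state.global_dme)
    g_after = _commit(state, runtime, geom)
    if g_after < threshold:
        return True, g_after
    state.geometry, state.geometry_rad, state.coords, state.global_dme = old
    return False, g_after


def stage_global(state: ModelState, lib: FragmentLibrary,
                 cfg: AssemblyConfig, rng: np.random.Generator,
                 runtime: _Runtime | None = None) -> ModelState:
    """Paired random insertions accepted on strict global-DME improvement."""
    runtime = runtime or _Runtime(state.reference, {lib.f: lib})
    cache = runtime.caches[lib.f]
    f = lib.f
    npos = lib.n_positions
    if npos < 2:
        raise InputError("global stage needs at least 2 positions")
    while True:
        accepted_any = False
        order = [int(p) for p in rng.permutation(npos)]
        marked: list[int] = []
        idx = 0
        while idx < len(order):
            if idx + 1 < len(order):
                a, b = order[idx], order[idx + 1]
                idx += 2
                newly_marked = (a, b)
            else:
                # odd position count: pair the leftover with a marked one
                a = order[idx]
                idx += 1
                b = marked[int(rng.integers(len(marked)))]
                newly_marked = (a,)
            sa, sb = cache.geoms[a], cache.geoms[b]
            if sa.shape[0] == 0 or sb.shape[0] == 0:
                for p, s in ((a, sa), (b, sb)):
                    if s.shape[0] == 0:
                        runtime.warn_empty(f, p)
                marked.extend(newly_marked)
                continue
            kas = rng.integers(sa.shape[0], size=cfg.pair_trials)
            kbs = rng.integers(sb.shape[0], size=cfg.pair_trials)
            # fragment a is written first, so b overwrites any overlap
            best_g, best_t = _kernels.best_pair_trials(
                state.coords, state.geometry_rad,
                cache.geoms_rad[a], a, cache.geoms_rad[b], b,
                kas, kbs, runtime.ref_condensed)
            best_pair = (int(kas[best_t]), int(kbs[best_t]))
            g_before = state.global_dme
            accepted = False
            g_after = g_before
            if best_g < g_before - cfg.tol:
                geom = state.geometry.copy()
                _write_frag(geom, sa[best_pair[0]], a)
                _write_frag(geom, sb[best_pair[1]], b)
                accepted, g_after = _try_commit(
                    state, runtime, geom, g_before - cfg.tol)
                accepted_any = accepted_any or accepted
            for p, k in ((a, best_pair[0]), (b, best_pair[1])):
                state.events.append(InsertionEvent(
                    "global", f, p, k, g_before,
                    g_after if accepted else float(best_g),
                    accepted, g_before,
                    g_after if accepted else g_before))
            marked.extend(newly_marked)
        if not accepted_any:
            break
    return state


def stage_refine(state: ModelState, lib: FragmentLibrary,
                 cfg: AssemblyConfig, rng: np.random.Generator,
                 runtime: _Runtime | None = None) -> ModelState:
    """Per-position exhaustive slot search on global DME."""
    runtime = runtime or _Runtime(state.reference, {lib.f: lib})
    cache = runtime.caches[lib.f]
    f = lib.f
    while True:
        accepted_any = False
        for pos in rng.permutation(lib.n_positions):
            pos = int(pos)
            stack = cache.geoms[pos]
            if stack.shape[0] == 0:
                runtime.warn_empty(f, pos)
                continue
            best_g, best_k = _kernels.best_slot_insert(
                state.coords, state.geometry_rad, cache.geoms_rad[pos],
                pos, runtime.ref_condensed)
            best_g, best_k = float(best_g), int(best_k)
            g_before = state.global_dme
            accepted = False
            if best_g < g_before - cfg.tol:
                geom = state.geometry.copy()
                _write_frag(geom, stack[best_k], pos)
                accepted, g_after = _try_commit(
                    state, runtime, geom, g_before - cfg.tol)
            if accepted:
                state.events.append(InsertionEvent(
                    "refine", f, pos, best_k, g_before, g_after,
                    True, g_before, g_after))
                accepted_any = True
            else:
                state.events.append(InsertionEvent(
                    "refine", f, pos, best_k, g_before, best_g,
                    False, g_before, g_before))
        if not accepted_any:
            break
    return state


_STAGE_FNS = {"local": stage_local, "global": stage_global,
              "refine": stage_refine}


def run_assembly(reference: BackboneChain,
                 libs: dict[int, FragmentLibrary],
                 cfg: AssemblyConfig | None = None,
                 seed: int | np.random.SeedSequence | None = None,
                 runtime: _Runtime | None = None) -> ModelState:
    """One full assembly: stretched start, then local → global → refine.

    Within each stage the available fragment lengths are drawn in a seeded
    random permutation and the stage runs once per length.  The trajectory
    is fully determined by (seed, inputs).
    """
    cfg = cfg or AssemblyConfig()
    if runtime is None:
        runtime = _Runtime(reference, libs)
    if seed is None:
        seed = cfg.seed
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    stage_seeds = root.spawn(3)
    state = _initial_state(runtime)
    lengths = [f for f in cfg.lengths if f in libs]
    if not lengths:
        raise InputError("no library matches the configured lengths")
    enabled = {"local": cfg.do_local, "global": cfg.do_global,
               "refine": cfg.do_refine}
    for stage, stage_seed in zip(STAGES, stage_seeds):
        if not enabled[stage]:
            continue
        srng = np.random.default_rng(stage_seed)
        for f in [lengths[i] for i in srng.permutation(len(lengths))]:
            _STAGE_FNS[stage](state, libs[f], cfg, srng, runtime)
    return state


def run_batch(reference: BackboneChain,
              libs: dict[int, FragmentLibrary],
              cfg: AssemblyConfig | None = None,
              run_seeds: list[int] | None = None,
              ) -> tuple[ModelState, list[RunSummary]]:
    """Independent seeded runs; returns the best-of-runs model + summaries.

    The best model is the run with minimal final global DME (ties go to the
    lowest run index).  The best-of-runs model is the headline quantity.
    """
    from .geometry import backbone_rmsd

    cfg = cfg or AssemblyConfig()
    runtime = _Runtime(reference, libs)
    if run_seeds is None:
        root = np.random.SeedSequence(cfg.seed)
        run_seeds = [int(s) for s in
                     root.generate_state(cfg.n_runs, dtype=np.uint32) & 0x7FFFFFFF]
    summaries: list[RunSummary] = []
    best_state: ModelState | None = None
    for i, rs in enumerate(run_seeds):
        state = run_assembly(reference, libs, cfg, seed=rs, runtime=runtime)
        rmsd = backbone_rmsd(state.coords, runtime.ref_atoms)
        n_acc = sum(1 for e in state.events if e.accepted)
        summaries.append(RunSummary(i, rs, state.global_dme, rmsd, n_acc))
        if best_state is None or state.global_dme < best_state.global_dme:
            best_state = state
    return best_state, summaries
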