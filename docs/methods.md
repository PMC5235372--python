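# Methods

This note documents the models, algorithms, parameters and design
choices behind `fraglib`, and what its synthetic benchmarks do and do not
show about real data.

## Backbone representation

A protein backbone is the ordered set of N, Cα, C atoms per residue.
Internally each residue is reduced to six angles: the dihedrals φ
(C(i−1)–N–Cα–C), ψ (N–Cα–C–N(i+1)) and ω (Cα–C–N(i+1)–Cα(i+1)), and the
bond angles N-Cα-C, Cα-C-N and C-N-Cα, all in degrees. Angles undefined
at a terminus or across a chain break are NaN; fragments never span a
break. Bond lengths are not part of the representation: Cartesian
rebuilding always uses the Engh–Huber values N–Cα 1.458 Å, Cα–C 1.525 Å,
C–N 1.329 Å. Consequence: a chain does not round-trip to its *original
Cartesian* coordinates (experimental bond lengths vary slightly), but
internal→Cartesian→internal is the identity to ≪1e−6°, which is the
invariant the assembly relies on.

Cartesian rebuilding is sequential natural-extension-reference-frame
(NeRF) placement: the first residue is placed canonically (N at origin,
Cα on +x, C in the xy-plane) and each subsequent atom from the previous
three atoms plus its bond length, bond angle and torsion. Insertion of a
fragment at position *p* only changes atoms from Cα(p) through Cα(p+f);
everything downstream is rigid relative to the junction triad
(C(p+f−1), N(p+f), Cα(p+f)) and is moved by one rigid transform. The
assembly search exploits this: candidate evaluations re-place only the
changed span and map the tail rigidly, and the two hot loops (placement
and DME) are numba-compiled, with plain numpy/scipy routes kept as
cross-checked references. Accepted insertions trigger a full rebuild so
numerical drift cannot accumulate; the stored global DME always equals
the DME recomputed from the current coordinates to 1e−9.

## Secondary structure

Observed secondary structure is assigned from torsions with a 3-class
bin rule: H iff φ∈[−100,−30] and ψ∈[−80,−5]; E iff φ∈[−180,−40] and
ψ∈[60,180]∪[−180,−170]; else C. An angle undefined at a terminus acts
as a wildcard (a terminal residue of a helical segment still reads H); a
residue with both φ and ψ undefined is C. The assigner is deliberately
pluggable — any function mapping geometries to an H/E/C string can stand
in, e.g. a wrapper around a 7-class assigner with a G,I→H, B→E mapping —
because the bin rule is a coarse stand-in for pattern-based assigners:
it reads isolated residues and cannot use hydrogen-bonding context, so
its class boundaries differ from DSSP/STRIDE near caps and bulges.

## Library construction

For target length *n* and fragment length *f* there are *n−f+1*
position slots. Every length-*f* window of every non-excluded database
entry is scored at every slot; windows containing an unknown residue or
an undefined interior angle are skipped. The top *K* per slot are kept,
sorted by (score descending, entry id ascending, start ascending) — the
tie-break makes library files byte-stable and independent of database
order. Scoring modes:

* **BLO**: Σᵢ B(tᵢ, fᵢ) over the aligned pair, B = BLOSUM62.
* **PSI**: the BLO score plus Σᵢ ±cᵢ, positive where the fragment's
  observed class equals the predicted class for the target residue.
  Weights are 1:1 by default and configurable; with the
  secondary-structure weight at 0 (or all confidences 0) PSI reduces
  exactly to BLO.

The confidence cᵢ is read from the .ss2 class-probability column of the
printed class (0–1). Predictors also emit 0–9 integer confidences in
other formats; a scale factor is configurable if those are used instead.
Default *K* is 200 fragments per position.

## Assembly search

The cost function is the distance matrix error over backbone atoms,

DME = sqrt( Σ_{i<j} (p_ij − q_ij)² / (N(N−1)/2) ),

superposition-free and rigid-invariant. *Local* DME restricts the sum to
a span's 3·f atoms; because a span's internal geometry is fully
determined by its own six-angle rows, a fragment's local DME equals the
DME of the fragment built in isolation against the reference span and is
precomputed once per (library, reference).

The model starts stretched: all defined dihedrals 180°, bond angles at
110.5°/116.6°/121.7°. Three stages follow; "improvement" is always
strict (<), so ties never churn.

1. **Local.** Positions are visited in a seeded random permutation; at
   each, all slot fragments are ranked by local DME and the minimiser is
   inserted iff it strictly improves the span's current local DME.
   Passes repeat until a pass accepts nothing, *capped at
   `local_max_passes` (default 10)*. The cap is a termination guard, not
   a tuning knob: the local objective is per-span, so insertions at
   overlapping positions can overwrite each other indefinitely when the
   library holds no mutually consistent fragments (with consistent
   fragments the no-insertion criterion fires after 1–2 passes).
2. **Global.** Unmarked position pairs are drawn without replacement;
   for each pair, `pair_trials` (default 200) random fragment pairs are
   drawn with replacement and evaluated jointly (first position written
   first, the second overwriting any overlap), and the best pair is
   inserted iff it strictly improves the global DME. An odd leftover
   position is paired with a random already-marked one. Passes repeat
   until no pair is accepted. Testing two spans at once lets the search
   cross barriers a single insertion cannot.
3. **Refinement.** Like the local stage but scored on global DME: every
   slot fragment is tested and the best inserted iff it strictly
   improves. Stages 2 and 3 strictly decrease a bounded objective over a
   finite state space, so they terminate without a cap.

With mixed libraries each stage draws the available fragment lengths in
a seeded random permutation and runs once per length; marks reset per
length. A batch runs `n_runs` (default 30) independent seeded runs —
seeds spawned from one root seed — and reports the best-of-runs model,
the headline quantity. Every evaluation is logged as an event (stage,
length, position, rank, stage-objective before/after, accepted flag, and
global DME before/after); accepted insertions in stages 2–3 are strictly
decreasing in global DME by construction, while local-stage insertions
guarantee only local improvement — the global DME may rise transiently
within stage 1 (the lever-arm effect of rotating a span is intended).

## Leader clustering

Within a slot, fragments are scanned in descending score order; a
fragment joins the first leader (in creation order) whose DME to it is
within the cutoff, else founds a new cluster. Fragment–fragment DME is
computed superposition-free on each fragment's own built backbone,
consistent with the cost function. Leaders are therefore pairwise
separated by more than the cutoff, clusters partition the slot, and the
leaders-only library is never larger. Default cutoffs 0.05 Å (3-mers),
0.7 Å (6-mers), 1.5 Å (9-mers). The 3-mer value is unusually tight —
at that radius clusters are near-duplicates only — and is configurable.

## Synthetic benchmarks

`generate_source_database` emulates the statistical shape of a
non-redundant structure database: entries of 40–120 residues composed of
H/E/C segments (mixture weights 0.35/0.25/0.40, geometric segment
lengths, minimum 3) with canonical torsions (H −57/−47; E −120/130; coil
drawn uniformly from two bins, −80/150 and 60/40, ±20°) plus Gaussian
angular noise (default σ = 8° on φ/ψ, 2° on ω, 1.5° on bond angles), and
uniformly random sequences. `plant_target` synthesises a native the same
way and injects each of its windows — geometry *and* sequence — at a
random non-overlapping location in a random entry, so the planted
window's substitution score is the self-match maximum at its position;
provenance records every injection. `synth_sspred` emulates a
secondary-structure predictor with a set per-residue success rate.

What this shows and does not show: planted-target recovery verifies the
machinery end to end (libraries must surface the true fragments; the
exact-DME search must find and keep them — final DME < 0.1 Å, RMSD
< 0.5 Å), and host-entry exclusion yields decoy-only libraries in which
the qualitative fragment-length effects appear (3-mers beat 12-mers;
long fragments dominate the local stage, short ones refinement; PSI
libraries are more secondary-structure-correct and less diverse than
BLO). The generator has no sequence–structure covariation, no side
chains and no steric exclusion, so absolute accuracies on real proteins,
predictor-quality effects, and energy-related behaviour are out of its
reach; conclusions transfer at the level of trends, not numbers.

## Numerical and interface conventions

* Residue indexing is 0-based half-open internally; 1-based only in CLI
  and report output (and Rosetta-format files, whose positions and
  residue numbers are 1-based by that format's convention; undefined
  terminal torsions are written there as 0.000).
* Dihedrals live in (−180, 180] (IUPAC sign), bond angles in (0, 180);
  the −180 branch point maps to +180.
* PDB reading keeps altloc ' ' or 'A' and drops residues missing any
  backbone atom; chains split at drops or C–N distances over 2.5 Å.
* GDT-TS superpositions are seeded from every contiguous Cα window of
  lengths 4 and 8 plus the full chain, with one round of inlier
  re-superposition per cutoff (1/2/4/8 Å) — a deterministic, desk-scale
  approximation of the reference search, adequate for relative
  comparisons.
* Library files carry a `FRAGLIB v1` header and print floats with 17
  significant digits, so read(write(lib)) is exact.
* Problem sizes used by the test suite and `scripts/acceptance.py`
  (hundreds of entries, 60-residue targets, K = 50, 5–10 runs) are
  chosen so a full verification pass runs in minutes on one CPU; all the
  algorithmic defaults (K = 200, 200 pair trials, 30 runs) remain the
  method's standard settings.
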