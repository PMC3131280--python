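# Methods

`reifold` models how the 5' leader of a short, reinitiation-permissive uORF
— the paradigm cases being *S. cerevisiae* GCN4 uORF1 and the YAP1 uORF —
folds *progressively* while a ribosome scans across it, and provides the
downstream analyses that interpretation needs: structure-tree comparison,
detection of reinitiation-promoting structural elements (double-circle
hairpins, bulged stems), substitution design that disrupts them, and
concordance scoring against enzymatic probing data. Because the natural
yeast sequences are not bundled with the package, a first-class synthetic
generator produces leaders with the same statistical and structural
properties, including a fully specified GCN4-uORF1-like study fixture.

## Coordinates

Leader positions are 1-based internally. Anchored sequences additionally
support the negative coordinates standard in the uORF literature: position
−k is the k-th nucleotide 5' of the A of the downstream AUG, so −1 abuts the
AUG and `index = anchor_index + k`. All spans are fully closed intervals.
`T` is accepted on input (constructs are often written as DNA) and stored as
`U`; IUPAC ambiguity codes are rejected because folding energies are
undefined for them.

## Energy model

Folding uses a nearest-neighbor free-energy model at 37 °C, read from a
documented YAML parameter file (`src/reifold/data/nn_params.yaml`) so users
can swap parameter sets without touching code:

* Watson–Crick plus G·U wobble pairs; a 6×6 stacking table (kcal/mol).
* Tabulated loop initiations: hairpin (sizes 3–30), bulge (1–30), internal
  (2–30), extrapolated beyond the table as
  `E(n) = E(30) + lxc·ln(n/30)` with `lxc = 1.08` (the Jacobson–Stockmayer
  form with 1.75·R·T).
* A 1-nt bulge retains the stack across the bulge; larger bulges and
  internal loops instead pay a 0.5 kcal/mol terminal penalty for each
  closing A-U/G-U pair. Internal-loop asymmetry costs 0.6 kcal/mol per
  unpaired-nt difference, capped at 3.0 (Ninio form).
* Multiloops are affine: 9.3 closing − 0.9 per branch + 0.0 per unpaired
  nt, plus terminal penalties per branch; the exterior loop is free except
  for terminal penalties.
* Minimum hairpin loop 3 nt; bulge/internal loops capped at 30 unpaired nt
  total (the standard DP restriction).

Deliberately outside the model: dangling ends, coaxial stacking, tetraloop
bonuses, and the special 1×1/2×2 internal-loop tables. These refinements
shift energies but not the qualitative behavior this analysis rests on
(GC-rich stems fold, AU-rich G-poor stretches do not), and omitting them
keeps the model exactly as documented in one small text file. Consequently
energies are *not* comparable number-for-number with tools that include
those terms.

All arithmetic is integral in units of 0.01 kcal/mol, eliminating
floating-point tie ambiguity; the public API reports kcal/mol floats.

## MFE folding with hard constraints

`mfe_fold` is an exact Zuker-style dynamic program (`V`/`WM`/exterior
recurrences, numba-compiled) over the model above. Hard constraints are
honored exactly: forbidden pairs, forced-unpaired positions, forced pairs
(their endpoints may neither stay unpaired nor pair elsewhere), and range
blocks forbidding all pairs between two intervals. Unsatisfiable forced
constraints raise an error rather than returning a best effort.
`evaluate_energy` recomputes any structure's energy by loop decomposition,
independently of the DP fill; the test suite holds the two together by
comparing `mfe_fold` against exhaustive enumeration of all nested
structures on hundreds of short random sequences, with and without random
constraints.

Ties among co-optimal structures are broken by a fixed deterministic
traceback (hairpin first, then two-loop candidates scanned with the 5' inner
index ascending and the 3' inner index descending, then multiloop splits
ascending), so repeated runs return byte-identical structures. Lonely
(isolated) pairs are allowed by default; `--no-lonely-pairs` applies the
canonical-pair filter used by the reference folding tools (a pair is kept
only if it could stack on a neighboring pair), which is a heuristic rather
than an exact isolated-pair-free optimization.

## Progressive (emergence-constrained) folding

A scanning ribosome exposes the leader 5'→3' through its mRNA exit channel,
so upstream sequence folds before downstream sequence exists. The leader is
cut into consecutive segments (for the GCN4-like 220-nt region −229…−10 the
plan is 66 + 81 + 73 nt, boundaries being configuration, not constants;
the 3'-terminal 9 nt of the natural leader are excluded by the caller as
they sit inside the ribosome's mRNA channel). Round r folds segments 1…r
under two policies, both defaulting on:

* **cross-blocking** — a segment that emerged with zero internal pairs
  ("unstructured", threshold configurable) is blocked from pairing with
  anything downstream in all later rounds; pairing *within* it remains
  allowed. The rationale: an AU-rich stretch that stays single-stranded is
  available for protein contacts near the mRNA exit pore and is treated as
  committed to that state.
* **pair freezing** — each round's pairs are carried into later rounds as
  forced pairs ("the pre-folded prefix"). An unfrozen "refold" mode exists
  for sensitivity analysis.

A one-segment plan with these defaults reduces exactly to plain `mfe_fold`
(tested). A segment's status is fixed at the round in which it first
emerges.

## Structure trees and edit distance

Structures are compared as rooted ordered trees. The full representation
maps every pair to a `P` node (children: the enclosed elements 5'→3'),
every unpaired base to a `U` leaf, under a virtual root `R`; the coarse
representation collapses stems to `S` nodes and labels loops `H/B/I/M/E`.
Distance is the exact Zhang–Shasha ordered-tree edit distance with unit
insert/delete/relabel costs — symmetric, zero iff identical, triangle
inequality (all property-tested, and checked against a brute-force edit
recursion on small trees). Lower distance = more similar; the score is
reported raw.

## Motif detection

Helices are maximal stacked runs merged across interruptions of at most
3 nt per side (so a 9-bp stem with a 1-nt bulge is one helix); helices
partition the pair set. On top of them:

* **double-circle hairpin** — an outer helix (≥ 3 pairs) whose innermost
  pair encloses exactly one inner helix (≥ 2 pairs) across a true internal
  loop, the inner helix closing the hairpin loop: two circles in the planar
  drawing.
* **bulged stem** — a helix with ≥ 5 pairs and at least one interruption;
  the apical loop size and each bulge's side and size are reported.

These geometric floors alone do not separate signal from background: an
AU-rich leader's MFE fold genuinely contains marginal helices that satisfy
them. The elements this analysis targets are compact, *stable*, *GC-rich*
stems sitting in a G-poor leader, so when the sequence is available a call
must additionally have (i) at least half of its stem pairs G-C and (ii) a
substructure free energy no higher than the worst-case all-GC motif of the
target geometry — −6 kcal/mol for a 5+3-pair double circle, −10 kcal/mol
for a 9-pair bulged stem under the default parameters (both bounds follow
from worst-case stack arithmetic, not from fitting). Without a sequence
only the geometric criteria apply.

Candidate RPE spans (negative coordinates, configurable) are annotated
**structured** when any paired position falls inside the span. The
one-endpoint rule matters: an element like the RPE ii stem has its 3'
strand inside the mapped span but its 5' strand outside it, and is still a
structured element of that span. Segment classification in the progressive
fold, by contrast, counts only pairs with both ends inside the segment —
a helix across a segment boundary is not *internal* structure.

## Perturbation and disruptor design

Variants use construct notation (`C-129A`): reference base, negative
position, alternative. Application checks the reference base and preserves
length. Disruption is always judged on the *refolded* mutant under the
identical plan and model — substitutions can create compensatory pairings,
so nominal complementarity is not trusted. A helix is disrupted when zero
of its pairs survive the refold. `design_disruptors` searches substitution
sets over the target helices' strand positions, smallest size first —
exhaustively while the combination count is manageable (default cap 2·10⁵),
greedily beyond — and returns all minimal solutions in deterministic order.
New helices created elsewhere by a solution are visible in the refold
report but deliberately not forbidden.

## Probing concordance

RNase T1 cleaves after single-stranded G; RNase V1 cleaves within
double-stranded RNA. Digitized cut tables (position, enzyme, condition,
categorical intensity) are scored against a predicted structure:
V1(fold) cuts are concordant at paired positions; T1(denature) checks base
identity only; T1(fold) at an unpaired G is concordant, at a non-G
discordant — and at a *paired* G it is classed `metastable_consistent`,
reflecting that a folding-condition T1 cut at a predicted-paired G
indicates a structure sampling unfolded states (as expected for an element
a ribosome must scan through), not a wrong prediction. Summaries are
concordant/(concordant+discordant) per enzyme-condition; an empty
denominator is reported as undefined (`None`), never as 0 or 1.

## Synthetic leaders

The generator emulates what these leaders look like: AU-rich, G-poor
background (target composition A 0.40 / C 0.22 / G 0.07 / U 0.31), with
the few G/C residues concentrated in planted, GC-rich motifs, and flanks
that stay unstructured. One documented PRNG (numpy `default_rng`, PCG64)
drives everything; identical seeds give identical output.

* Motif sequence design: stems drawn from {G-C, C-G} per pair, loops
  A-only; the motif span's local MFE is verified by folding to equal the
  planted geometry, resampling up to a retry cap. One `A` guard base flanks
  each motif so a planted helix cannot be stacked onto directly.
* Background: i.i.d. from the *residual* composition after the planted
  letters consume their share of the budget — mirroring real G-poor
  leaders, whose G's sit in the stems. When motifs are planted, the
  background is redrawn until the whole-leader MFE equals the planted
  ground truth exactly (the "unstructured flanks" property; ~2–3 draws
  typically). Motif-free leaders are single draws and fold whatever they
  fold — the false-positive measurements run against that honest
  background.
* Default geometries mirror the study conditions: double circle with
  5-pair outer and 3-pair inner stems; 9-pair bulged stem with a 3-nt
  apical loop and a 1-nt 3'-strand bulge placed three pairs from the helix
  base (with the bulge at the terminal pair, the closing pair buys no stack
  and is thermodynamically dropped).
* `CAA` linkers (the classic structure-free spacer) contain no pairable
  combination at all over {C, A}.

`gcn4_like_leader` assembles a *synthetic stand-in* for the GCN4 uORF1
leader: 229 nt anchored at the AUG, exact letter counts making the
composition round to A 40 / C 22 / G 7 / U 31 integer percent, a
double-circle hairpin at −129…−83 whose stems land at probe positions
3–7:45–49 and 22–24:31–33 of the 79-nt probing substrate, and a 9-bp
bulged stem starting 6 nt downstream (probe 56–64:68–77), with paired G's
at probe positions 23, 31, 48 and 75 — the sites the curated synthetic
probing table (`data/probing_79mer_synthetic.tsv`) scores. The background
is resampled until the (66, 81, 73) progressive fold reproduces the
planted structure exactly, so the fixture realizes the full set of study
conditions for every seed.

What passing tests on these leaders shows — and what it does not: the
pipeline machinery (exact DP, constraint soundness, motif logic,
coordinate arithmetic) is verified on sequences with known ground truth
whose thermodynamic contrasts match the real system's. It does not show
that the shipped parameter set reproduces the published fold of the actual
yeast sequences; those sequences are not distributed here, and structure
predictions for them additionally depend on the parameter set used.
Likewise the structure-tree distances computed between the synthetic
GCN4-like window and YAP1/YAP2-like leaders characterize the synthetic
conditions, not the published cross-gene scores.

## Problem sizes and determinism

The test suite folds hundreds of sequences of 8–22 nt against the
enumeration oracle, 100 random constrained cases at ≤ 18 nt, 100 synthetic
220-nt leaders through the progressive pipeline, and 50 + 50 leaders for
recovery/false-positive rates; the acceptance script regenerates the study
fixture and all headline quantities from a single seed. Every stochastic
step takes an explicit seed; repeated runs are byte-identical.

## Known limitations

* No partition function, base-pair probabilities, suboptimal ensembles, or
  pseudoknots; kinetic folding (nucleation rates, barriers) is out of
  scope — emergence is modeled as hard constraints, not kinetics.
* The energy parameter file is a compact Turner-style set; swapping in a
  richer published set changes energies and may change predicted structures.
* `--no-lonely-pairs` is the canonical-pair heuristic, not an exact
  lonely-pair-free optimum.
* Motif quality thresholds are calibrated to the default parameter set; a
  different parameter file warrants re-deriving the two energy bounds.
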