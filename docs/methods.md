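# Methods

This note records the modeling decisions, defaults, and numerical
choices behind `sarmatrix`, and what the synthetic test conditions do
and do not establish.

## Canonicalization contract

All molecule identity is string equality of RDKit canonical isomeric
SMILES; fragments additionally carry attachment points as dummy atoms
with atom map numbers `1..level`. Multi-point keys are canonicalized
over all label permutations (lexicographically smallest SMILES wins) and
the chosen permutation re-orders the value list, so a key/value record
is invariant to both input atom order and label assignment. Salts and
mixtures reduce to the largest fragment with a warning; tautomer or
charge standardization is deliberately out of scope (a pre-processing
hook, not a matrix concern). Replicate potencies aggregate by
arithmetic mean of pKi — on the log scale, consistent with the additive
prediction model.

## Fragmentation rules

Cuttable bonds are exocyclic single bonds between two heavy atoms;
hydrogens are never cut. For a `level`-cut, every `level`-subset of
cuttable bonds is tried and kept only if exactly one fragment (the key)
carries all attachment points — the core must be able to host every
substituent of a matrix column. At level 1 both fragments qualify
structurally, and the key is the larger one (an exact heavy-atom tie
emits both orientations, which keeps enumeration symmetric and
deterministic). Symmetry-equivalent cut sets that produce an identical
canonical (key, values) record are collapsed at indexing time.

Size constraints default to: substituents ≤ 13 heavy atoms, key ≥ 5
heavy atoms, and key ≥ half the molecule. These mirror common MMP
practice; they are configuration, not fixed truth, because matrix counts
at data-set scale are sensitive to them.

The second-level cut (which groups analogous cores) is a single cut of
a core that must leave *all* first-level attachment points in the
sub-key; the removed distinguishing fragment carries none of them and
respects the substituent size cap. This is the conservative reading of
the matrix layout: the distinguishing substructure is a peripheral core
modification, and letting attachment points migrate would scramble
column semantics. Sub-keys are canonicalized with the first-level labels
frozen (only the new point gets a fresh label, `level + 1`), which keeps
column alignment across the rows of a matrix; for highly symmetric cores
this can under-group relative to a permutation-insensitive match, a
trade-off accepted for layout coherence.

## Matrix construction

Rows (cores) and columns (value combinations) are sorted by canonical
string, so layout is deterministic and exports are diffable. Matrices
need ≥ 2 rows (the analog-series comparison needs something to compare)
and ≥ 3 real cells by default; both are exposed because no canonical
production values exist. A real compound without a pKi for the chosen
target stays a real, gray cell — it is structural evidence even when
unannotated. Virtual cells get their structure by reassembling (core,
values); a virtual structure that exists elsewhere in the data set is
flagged `known_elsewhere` rather than silently promoted, which can only
happen when the key-orientation size rule indexes that compound under
the opposite fragment.

## Scores and ranking

Discontinuity is the mean |ΔpKi| over analog pairs (annotated real cells
sharing a row or a column). The score's exact functional form is an
open design point; mean pairwise difference is the simplest reading that
is permutation- and translation-invariant, and it is the pluggable
default rather than a claim of uniqueness. Continuity is its negation.
Activity cliffs use the prevailing 100-fold convention (≥ 2 pKi units,
inclusive). SAR transfer uses Spearman rank correlation (default ≥ 0.8
over ≥ 3 shared annotated columns) because the pattern of interest is a
shared potency *ordering*, not linearity; constant rows have no ordering
and are skipped. Preferred cores require every annotated cell of a row
at or above the potency cut with at least two annotated cells; the
default cut of pKi 7 (100 nM) is a conventional potency bar. Ranking is
a stable sort with ties broken by matrix id.

## Neighborhood prediction

A neighborhood of virtual cell X is any completion (E, G, D) of real
annotated cells sharing X's column, X's row, and the complementary
diagonal cell; the prediction is exactly `pE + pG − pD`. Neighborhoods
are collected across all matrices containing the same virtual structure
and deduplicated by the unordered (E, G, D) compound triple — the same
three measurements recurring in overlapping matrices are one piece of
evidence, and counting them twice would inflate `n_nbh` and shrink the
spread artificially. Consistency is the sample standard deviation
(undefined below two neighborhoods).

Prioritization defaults: ≥ 3 neighborhoods, sd ≤ 0.5 pKi, and at least
one source matrix with discontinuity ≤ 1.0 (the applicability domain —
additive mini-QSAR only holds in continuous local SAR). The sd and
continuity thresholds have no canonical values and are configuration; a
matrix whose discontinuity is undefined cannot certify continuity and
does not qualify. Near cliffs the additive formalism is wrong by
definition, so guilt-by-association candidates (virtual cells in the
potent cliff partner's row or column) carry provenance but no number.

## Multi-target matrices

"Active against" means having an annotation, optionally with a per-call
pKi floor; no default cutoff is imposed because promiscuity coloring is
a counting exercise, not a potency claim. Anti-targets are ordinary
targets. Deconvolution preserves the skeleton exactly and attaches a
pKi only where the target is in the cell's (threshold-filtered) profile,
so total annotations are conserved and profiles rebuild losslessly; a
shared skeleton hash ties the exports together.

## Synthetic libraries

The generator emulates the combinatorial structure the method assumes:
per scaffold, analogous cores (scaffold + variant group at one site)
crossed with substituents at another. True potency is Free–Wilson
additive, `pKi = mu + a_variant + b_substituent`, with per-scaffold
uniform effect draws, optional i.i.d. Gaussian observation noise, a
holdout fraction excluded from the compound set (surfacing as virtual
cells), and optional seeded cliffs (+δ on chosen cells).

Defaults — 3 scaffolds × 4 variants × 6 substituents, mu 6.5, effect
ranges (0, 1) pKi for both factors, no noise, no holdout — give a
moderately potent series whose ordinary analog-pair differences stay
below 2 log units, so only seeded cliffs (δ = 3) cross the cliff
threshold, and every pair containing a seeded cell clears it.

One template property is load-bearing: variant and substituent fragments
(halogens, small rings, multiple-bond groups) contain **no** cuttable
internal bonds, so every library compound cuts only at its two scaffold
junctions. Any matrix the engine derives then splits compounds along
fragment boundaries and the additive decomposition transfers to *every*
layout the pipeline can produce — which is what makes exact held-out
recovery a theorem about the implementation rather than a property of
one lucky matrix. The cost is realism: real substituents have interior
bonds, real potencies are not exactly additive, and real data sets are
not combinatorial grids. Passing these tests demonstrates that the
machinery (fragmentation, grouping, layout, bookkeeping, the prediction
equation) is correct, not that predictions on real chemistry will be
exact. With observation noise σ, the error of a prediction against a
held-out *observed* value is `ε_E + ε_G − ε_D − ε_X` with standard
deviation 2σ; the suite checks the pooled empirical RMSE against that
error-propagation value within 10%.

Scaffold attachment positions happen to be symmetry-equivalent on all
five templates, so the variant-side and substituent-side groupings merge
into one matrix per scaffold (rows and columns each contain both cores
and "transposed" cores). The intended variant × substituent grid is
embedded intact, recovery tests check for that embedding, and the merged
cells remain exactly additive.

## Problem sizes and numerics

Test and acceptance runs use desk-scale inputs: libraries of ~20–70
compounds, 200 random molecules ≤ 30 heavy atoms for the
engine-vs-oracle comparison (the oracle re-derives cuts from graph
bridges and connected components, independent of the engine), 10 sets
for the pairwise-MMP comparison, and ~20 seeded replicates to pool
≥ 2000 neighborhoods for the noise check. Data-set-scale matrix counts
reported for real libraries depend on fragmentation constraint settings
and on the specific compound sets, and are not asserted here. Exactness
tolerances: 1e−9 for noise-free recovery (observed error is at the
1e−15 float rounding level); formula checks are exact rationals over
small integers and compared with `==`.

## Known limitations

- Only exact canonical-key identity groups series; no fuzzy or
  maximum-common-substructure core matching.
- Ring bonds are never cut, so scaffold-hopping relationships across
  ring changes are invisible by construction.
- Multi-point key canonicalization enumerates label permutations (≤ 6
  at triple-cut) per candidate cut; fine at these sizes, quadratic
  pressure on very large, highly branched molecules.
- The HTML export shows structure strings, not depictions; rendering is
  a hook for downstream tooling, not a goal here.
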