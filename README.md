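# sarmatrix

SAR matrices for medicinal chemistry: extraction and organization of
compound series from activity data sets by a two-level matched molecular
pair (MMP) formalism, with virtual-compound design, Free–Wilson
neighborhood potency prediction, and multi-target (promiscuity)
matrices.

## The method

Structure–activity relationship (SAR) analysis of a large compound set
starts from a simple structural relationship: an **MMP** is a pair of
compounds that differ only at a single site, interconverted by exchanging
a substructure. MMPs are found at scale by systematically deleting
exocyclic single bonds — one (single-cut), two (dual-cut), or three
(triple-cut) at a time — and indexing each compound under the resulting
*key* (core fragment, carrying the attachment points) with its *values*
(substituents). All compounds sharing a key form a **matched molecular
series**.

The distinctive step is applying the same fragmentation **twice**: the
cores themselves are single-cut again, and cores that differ only by a
modification at one site (they share a second-level key) group their
series into a *structurally analogous matched molecular series*. Each
such group becomes one **SAR matrix (SARM)**: analogous cores as rows,
substituent combinations as columns. Every cell is a unique compound —
*real* (in the data set, color-coded by pKi) or *virtual* (an unexplored
core × substituent combination, generated by reassembly). SARMs look like
the R-group tables chemists already use, but cover all MMP-based
substructure relationships in a data set at once.

On top of the matrices:

- **Overlap and coverage.** Per column, the row overlap is
  `RO = (n_col − 1)/(#rows − 1)` (0 = substituent unique to one series,
  1 = shared by all); matrix overlap is the mean RO over columns, and
  coverage is `C = n_matrix/(#rows × #columns)`.
- **Ranking.** Matrices are scored by SAR discontinuity (mean |ΔpKi|
  over analog pairs sharing a row or column), its negation (continuity),
  SAR-transfer events (row pairs with parallel potency progression,
  Spearman ρ over shared columns), or consistently potent rows.
- **Potency prediction.** A virtual compound X at (r, c) with real
  neighbors E at (r′, c), G at (r, c′) and D at (r′, c′) gets the
  Free–Wilson additive estimate `pX = pE + pG − pD`. Qualifying
  neighborhoods are collected across all matrices, and candidates are
  prioritized by the number of neighborhoods, the consistency (standard
  deviation) of their predictions, and membership in matrices with
  continuous local SAR. Near activity cliffs (analog pairs ≥ 2 pKi units
  apart) the additive model is invalid; there, virtual neighbors of the
  potent cliff partner are selected by guilt-by-association instead.
- **Multi-target spaces.** The same skeleton annotated with per-compound
  target profiles gives a compound series matrix (CSM), color-coded by
  promiscuity degree, which deconvolutes losslessly into per-target
  SARMs.

## Worked example

The built-in generator produces combinatorial libraries (scaffold ×
core-variant × substituent) with known additive ground truth:

```bash
sarmatrix --seed 7 --out-dir demo simulate \
    --n-scaffolds 2 --n-core-variants 3 --n-substituents 4 \
    --holdout-fraction 0.1 --n-cliffs 1
sarmatrix --out-dir demo build demo/library.smi \
    --activities demo/activities.csv --target T1 --levels 1
sarmatrix --out-dir demo rank demo/matrices.json --criterion discontinuity
sarmatrix --out-dir demo predict demo/matrices.json
```

which prints

```
22 compounds -> 2 matrices, 54 virtual cells -> demo/matrices.json
ranked 2 matrices -> demo/ranking.tsv
2 candidates with neighborhoods, 1 prioritized -> demo/predictions.tsv; 7 cliff neighbors -> demo/cliff_neighbors.tsv
```

and the reports read

```
rank  matrix_id   criterion      score     n_real  n_virtual  n_cliffs
1     L1-0002:T1  discontinuity  0.780202  22      27         10
2     L1-0001:T1  discontinuity  0.363632  22      27         0

vc_structure     mean_pred  sd_pred  n_nbh  source_matrices
C#Cc1ccc(Br)cc1  8.0728     0.0000   6      L1-0001:T1
```

Matrix `L1-0002` ranks first because it contains the seeded activity
cliff (ten analog pairs cross the 2-log-unit threshold, driving the mean
pairwise ΔpKi to 0.78); its virtual cells around the 10.08-pKi cliff
partner are reported as guilt-by-association candidates without a
numeric prediction. Matrix `L1-0001` is a continuous region: the
held-out virtual compound `C#Cc1ccc(Br)cc1` gets six independent
neighborhood predictions agreeing to machine precision (sd 0.0000) at a
predicted pKi of 8.07 — on this noise-free additive library, exactly its
ground-truth value. `report` renders each matrix as a color-coded HTML
R-group table (red → yellow → green with potency; white cells virtual;
gray cells real but unannotated).

The same pipeline is available as a library (`sarmatrix.build_matrices`,
`find_neighborhoods`, `rank_matrices`, `build_multitarget_matrices`, …)
for programmatic use.

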