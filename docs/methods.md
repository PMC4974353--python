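# Methods

This note documents the model behind `nanorf`, the parameter choices that
matter, what the synthetic data does and does not emulate, and the numerical
conventions, so that results can be interpreted — and the package's design
decisions audited — without reading the source.

## Data model

The input is a proteins × experiments matrix of SILAC abundance ratios, one
experiment per (knockout condition, biological replicate) pair. Orientation
is normalised on read: every stored ratio means knockout/wild-type, with
label-swapped experiments (`wt_over_ko` in the design table) inverted
(x → 1/x). Ratios are treated as multiplicative throughout; all arithmetic
happens on the log2 scale.

Decoy ("reverse") and contaminant rows from the upstream search are parsed
and retained in the `QuantTable` but excluded from every analysis module by
default (`keep_flagged=True` to retain): decoys must never enter a training
set. A protein group's identifier is the first accession in its ID list,
matching the upstream razor-peptide convention; groups are kept one row per
group and never collapsed further.

## Dependence

The dependence of protein *i* on knocked-out factor *c* is the arithmetic
mean of the log2 replicate ratios — the log of the geometric mean ratio:

    D_ic = (1/n_ic) * sum_k log2 r_ick

over the replicates with a present measurement. The geometric mean is the
natural average for ratio data; it also makes `residual_percent`
(100·2^D) exactly the geometric-mean percent of wild-type remaining, which
is the scale on which depletions are reported (e.g. a residual of 8% for a
strongly dependent protein). A condition cell is missing only when *every*
replicate is missing; the replicate count matrix is carried alongside so
imputed values remain identifiable downstream.

Optional reference normalization divides every ratio by a designated
invariant protein's ratio in the same experiment (histone H4 in the
workflow this package supports) before averaging, correcting for variable
chromosome recovery between preparations. It is applied when requested via
`normalize_to_reference` / `--normalize-to`; the reference must be
quantified in every experiment.

**Imputation.** Missing dependence values are replaced by the median of the
present values of the same condition column. This is the only imputation
offered: with a large hitchhiker background the column median sits near 0
(no change), which is the conservative guess for an unquantified protein.
The operation is idempotent and never alters present cells. It must be run
before fractionation (the forest requires a complete matrix).

**Volcano tables.** Per condition, proteins with ≥ 2 present replicates get
a two-sided one-sample t test of their log2 ratios against 0, with
Benjamini–Hochberg adjustment across proteins (statsmodels `fdr_bh`).
Replicate sets with zero variance yield a *missing* p-value rather than 0:
the t statistic is undefined and reporting certainty there would be wrong.
With only 2–3 replicates these p-values have little absolute power (df = 1
caps the two-sided p at ≈ 0.057 for any effect); the volcano table is a
ranking device, not an inferential endpoint — the forest is the detector.

## nanoRF

One fractionation = one target complex. The labelled rows are the complex's
known members (positives, possibly as few as 2–10) and a shared background
set (negatives; typically curated cytoplasmic/ribosomal contaminants). When
no curated background exists, `GroundTruth.training_set` (for simulations)
or the caller samples unlabelled proteins uniformly with a recorded seed.

A forest of `n_trees` CART trees (scikit-learn `DecisionTreeClassifier`) is
grown, each on a bootstrap (with replacement, same size) of the labelled
rows. Defaults and rationale:

| Parameter | Default | Why |
| --- | --- | --- |
| `n_trees` | 1000 | out-of-bag vote fractions need many trees to be smooth; each training row is OOB in only ~37% of them. Results with < 100 trees trigger a warning. |
| `features_per_split` | √p (rounded) | the standard random-forest decorrelation rule; with ~5 knockout conditions this is 2. |
| `class_weighting` | balanced | a handful of positives against tens of negatives: per-bootstrap class reweighting instead of down-sampling, which would discard scarce positives. |
| seed | required for reported runs | per-tree seeds are drawn from one `numpy` generator; the seed is recorded in every output. |

Bootstraps that draw only one class are skipped (they cannot grow a tree);
vote denominators use the number of trees actually grown.

**Adjusted RF score.** The score of a *training* protein is the fraction of
positive votes among the trees for which it was out-of-bag; the score of an
*unlabelled* protein is the full-forest vote fraction. This adjustment is
what makes 2-D score scatters of training members and candidates
meaningful: a self-fit forest would place every training member at ~1.0
regardless of data quality. A training protein that is out-of-bag in zero
trees (vanishingly rare at 1000 trees) falls back to the full-forest vote
and is flagged in the results object.

**Quality and threshold.** ROC/AUC (scikit-learn, Mann–Whitney convention
with ties at ½) and MCC are computed over the labelled proteins' adjusted
scores only. The membership threshold is the MCC-maximizing value over the
exact grid: midpoints between consecutive distinct scores plus sentinels 0
and 1 (MCC is piecewise constant between scores, so this sweep is exhaustive).
Ties go to the smallest threshold; consequently a perfectly separating forest
whose negatives all score exactly 0 gets threshold 0.0, and the membership
rule is strictly `score > threshold` everywhere. MCC of a degenerate
confusion table (any zero marginal) is defined as 0.

**Determinism.** Rows are sorted by protein_id before fitting, so scores are
invariant to input file order; identical inputs + seed give byte-identical
outputs.

## Multi-nanoRF, branches, candidates

`MultiNanoRF` fits one independent forest per training set, with per-column
seed = base seed + column index (independent forests, reproducible matrix).
Per-complex AUC/MCC are retained so poorly separating targets can be
flagged (`poorly_fractionated`) rather than silently trusted — some targets
(in the original data, linker histones and telomere proteins) simply are
not informative under the available knockouts.

Score profiles are clustered agglomeratively (scipy): default euclidean
distance with Ward linkage, the conventional choice for heat-map
dendrograms; correlation distance and average/complete linkage are exposed.
Raw scores are clustered, not threshold-binarised ones. With correlation
distance, zero-variance profiles (common: many hitchhikers score exactly 0
everywhere) are defined to be at distance 1 from everything. The tree is
cut to exactly `n_branches` — the number of branches is data-specific and
deliberately user-set; branches are renumbered 1..k in dendrogram leaf
order so exported tables have contiguous branch blocks. Clustering is
invariant to input row order (rows canonically sorted before linkage).

**Candidates.** For a target complex, a branch qualifies if it contains at
least half of the complex's training positives present in the matrix;
candidates are the unlabelled proteins of qualifying branches, training
members excluded, ranked by their score in the target column (ties broken
by protein_id). The "≥ half" rule operationalises "in the same branch as
the complex" while tolerating one or two stray members.

## Synthetic data

`simulate_dataset` draws log2 ratios as

    log2 r_ie = mu_ic(e) + N(0, sd_i),   mu_ic = log2(residual)  if i ∈ complex with cognate knockout c, else 0

with sd 0.3 (log2 units) for planted members and 0.5 for hitchhikers —
contaminant ratios in chromosome preparations are empirically more
dispersed than those of genuine components. Cells are masked missing
independently at `missing_rate` (default 0.1 in the paper-like
configuration); an all-at-random mechanism, chosen because only the
imputation rule (median), not the missingness mechanism, is part of the
modelled workflow.

`default_paper_like_config` mirrors the knockout panel the method was
developed for: conditions SMC2, CAP-H, CAP-D3 (×2 replicates each), Scc1
(×3), SMC5 (×2) — 11 experiments — over 5,058 proteins, with five planted
complexes at the reported depletion ranges: condensin I (8 members,
residual 0.25 under SMC2 and CAP-H), condensin II (8, 0.30 under SMC2 and
CAP-D3), cohesin (8, 0.20 under Scc1), SMC5/6 (6, 0.08 under SMC5), and the
chromosome passenger complex (6, 0.35 under the condensin-I knockouts; no
published residual exists for the CPC, so a moderate dependence tracking
condensin I was chosen).

What the simulation does **not** emulate: correlated noise between
replicates of one preparation, abundance-dependent missingness, partial or
asymmetric depletion within a complex (every planted member shares one
residual), protein groups with shared peptides, and secondary/indirect
dependencies between complexes. Passing the planted-recovery tests
therefore demonstrates that the pipeline's machinery is correct and
well-calibrated on clean co-depletion signal; it does not certify
performance on real data, where these nuisances reduce separation quality —
which is exactly what the per-complex AUC/MCC diagnostics are for.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run the full 5,058-protein,
11-experiment configuration for the planted-recovery checks (10 seeds in
the suite at 500 trees; 3 seeds in the acceptance script), and a scaled
1,200-protein universe for the 20-seed cross-complex independence check —
the independence property concerns the planting structure (disjoint cognate
knockouts), not the universe size. Metric implementations are verified
against brute-force pairwise/threshold enumeration on 1,000 random labelled
score sets.

## Known limitations

- With 2 replicates the volcano t test is nearly powerless; dependence
  magnitude and forest scores carry the signal.
- The OOB score of a training protein is an average over ~37% of the
  forest, so it is noisier than an unlabelled protein's full-forest score;
  with very small positive sets, thresholds derived from a handful of OOB
  scores are correspondingly coarse.
- Branch count is user-set; there is no automatic model selection for the
  dendrogram cut.
- Candidate prediction requires the target's positives to cluster: a
  complex whose members scatter across branches (poor fractionation)
  yields no qualifying branch and an empty candidate list — by design.
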