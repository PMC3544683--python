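# Methods

## Problem and scope

`fieldmarker` implements a marker-discovery pipeline for *field
cancerization*: finding genes whose expression in histologically normal
tissue adjacent to a malignant tumor (NTAC) differs from normal tissue
adjacent to a benign tumor (NTAB). The measurement modality is
semi-quantitative RNA in situ hybridization (RISH) on tissue-microarray
cores, read out as an ordinal composite score 0–6 per gene per sample. The
pipeline has three analysis stages:

1. **Per-gene testing.** Wilcoxon rank-sum comparison of NTAC vs NTAB
   scores for each gene, with a direction-of-change call.
2. **Filter ranking.** Four per-gene class-separability criteria (absolute
   pooled t, symmetric KL divergence of Gaussian fits, Gaussian
   Bhattacharyya distance, absolute rank-sum z) order the panel best-first.
3. **Wrapper selection.** Gene groups grow from empty in filter-rank order;
   each group is scored by repeated stratified 10-fold cross-validated AUC
   of a linear SVM on held-out decision values, and the best subset is the
   one with the highest mean AUC.

Because no patient score matrix is publicly available, the package ships a
calibrated synthetic-cohort generator that emulates the study design: eight
tissue groups (hepatocellular 26, rectal 48, esophageal 34, gastric 66,
thyroid carcinoma 32, breast carcinoma 38 — NTAC; thyroid adenoma 32,
breast fibroadenoma 38 — NTAB), 314 samples, a 15-gene panel.

## Composite RISH scoring

A core contributes a positive-cell fraction and an ordinal staining-density
category (0 none, 1 light, 2 deep, 3 black). The fraction is binned into a
ratio category (0: <25%, 1: 25–50%, 2: 51–75%, 3: >75%) and the composite
score is the sum, 0–6. The printed ratio bins leave gaps on a continuous
fraction scale; we resolve the boundaries as [0, .25) → 0, [.25, .50] → 1,
(.50, .75] → 2, (.75, 1] → 3, so every fraction maps to exactly one
category and the printed anchor points are preserved. Whether the original
scorers put exactly 50% in category 1 or 2 is not recorded anywhere; our
choice is a convention, stated here rather than hidden.

## Synthetic cohorts and AUC calibration

Each gene is governed by a `GeneEffect`: a pair of probability vectors over
scores 0..6, one per class. Sampling is exact inverse-CDF per sample, so
simulated class counts equal the design counts by construction. Per-gene
random substreams are keyed by `(master seed, crc32(gene name))`, so adding
or removing a gene never perturbs the draws of the others.

Class separation is parameterized by a latent-Gaussian family: NTAB latent
values are N(0, 1), NTAC latent values N(shift, 1), both discretized at the
8 fixed cut points (−∞, −1.25, −0.75, −0.25, 0.25, 0.75, 1.25, +∞) into
scores 0..6. The exact population AUC of a `GeneEffect` — P(S₁ > S₀) + ½
P(S₁ = S₀), summed over the 7×7 score grid — is strictly increasing in the
shift, so `effect_from_auc` calibrates a target AUC by bisection (default
tolerance 0.005). The family saturates near AUC 0.947 because the NTAB
distribution keeps ~10% mass in the top bin; higher targets raise
`CalibrationError`. Point-mass effects can be constructed directly when a
near-perfectly separable gene is needed.

What the generator does **not** emulate: per-tissue heterogeneity in the
class-conditional distributions (a clipped integer score offset per tissue
exists as a robustness hook, off by default), correlation between genes
(scores are independent given class), scorer disagreement, and missing
cores. Passing tests therefore demonstrate correctness of the statistical
machinery under a clean ordinal model, not robustness to those real-data
features.

## Rank-sum testing with heavy ties

Scores 0–6 across 314 samples guarantee massive ties, so everything uses
midranks. W is the sum of NTAC midranks; the normal approximation uses the
tie-corrected variance n₁n₂/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5
continuity correction (the uncorrected variance materially overstates
significance on this scale). The exact method evaluates the full
permutation distribution of W over all C(N, n₁) group assignments via a
subset-sum dynamic program on doubled midranks (integer sums; counts stay
within int64 up to the capacity cap N = 40). Two-sided P is
min(1, 2·min(P(W≤w), P(W≥w))); `auto` uses the exact null at N ≤ 20.

The discrete exact P moves in steps of order 1/C(N, n₁), so at N ≤ 12 the
normal approximation cannot track it tightly on any continuity convention;
the gap decays with N (mean |Δp| ≈ 0.02 at N = 12, ≈ 0.003 at N = 40).

Direction of change is called from the mean score difference at raw
two-sided P < α (default 0.05); a Benjamini–Hochberg column is reported
alongside for reading but never drives the calls, matching the raw-P
reporting style of the original analysis.

## Filter criteria

All four criteria are label-symmetric, non-negative, and zero for
identically distributed groups. The Gaussian-fit criteria use ddof = 1
moments with class variances floored at ε = 1e−9 (ordinal columns can be
constant within a class). The t filter is pooled-variance by default, with
a Welch variant available. "Entropy" is the symmetric (two-directional) KL
divergence between the class Gaussians — the one-directional variant is
asymmetric in the class labels, which a ranking criterion should not be.
Ranking ties are broken by panel order for cross-platform determinism.

## Wrapper selection

- **Classifier.** A maximum-margin linear classifier with cost C = 1 and
  per-fold standardization. We solve the primal L2-loss (squared-hinge)
  linear SVM via liblinear: it is deterministic and converges in a few
  Newton steps at n ≈ 300, whereas the dual hinge solver stalls on highly
  correlated fold replicates and a kernelized solver costs ~50× more per
  fit. No kernel search or nested tuning: the wrapper's job is to compare
  gene groups, not to squeeze the classifier.
- **Folds.** Stratified by class label only (the comparison pools tissues;
  70 NTAB samples guarantee ≥ 7 per fold at k = 10). Fold assignment is a
  function of the class labels, sample ids (canonical order), seed and
  repeat number — repeat r uses `seed + r` — so CV results are invariant to
  the row order of the input and reproducible from the seed alone.
- **AUC.** Held-out *decision values* (signed distance to the boundary)
  feed a midrank Mann–Whitney AUC with half credit for ties; hard labels
  would collapse AUC to balanced accuracy. Fold AUCs are averaged into a
  repeat-level AUC; the trace reports mean ± SD (ddof = 1) over the 10
  repeat-level AUCs. Pooling decision values across folds before a single
  ROC is available as a flag.
- **Best subset.** Highest mean AUC; ties go to the smaller group, then to
  the earlier trace position.

## Numerical conventions and degenerate inputs

- Heat-map export: per-gene z-scores with the sample-SD (ddof = 1)
  convention, SD floored at 1e−12, clipped to [−3, 3]; a constant gene maps
  to all zeros.
- A constant gene inside a CV fold standardizes to all zeros and yields
  constant decision values → AUC 0.5 by the tie convention, which is the
  correct "uninformative" answer.
- Identical tied groups give z = 0, P = 1 (degenerate rank-sum variance).
- Output tables print P in scientific notation and AUC to 4 decimals so a
  rerun at the same seed is byte-identical.

## Problem sizes used by the test suite

The statistical checks run at the study's cohort composition (314 samples,
244/70): the type-I-error check uses 2,000 null genes; the
parameter-recovery check uses 100 replicates of a cohort with one gene
calibrated to AUC 0.87 among 14 nulls, full 10×10-fold CV for the
single-gene AUC, and one full wrapper trace per replicate with the four
filter criteria cycled across replicates (25 each). Exact-vs-enumeration
checks use pooled n ≤ 12 (500 datasets); the AUC oracle check is exhaustive
over all score lists of length ≤ 4 on a 3-letter alphabet.

## Known limitations

- Gene-gene independence in the generator means the wrapper's multivariate
  behavior (complementary gene pairs, redundant genes) is exercised only
  weakly; the selection machinery itself is format- and contract-tested.
- The linear-SVM decision values are monotone in a single gene's score, so
  single-gene CV AUC essentially reproduces the empirical Mann–Whitney AUC
  of that gene — by design, but worth knowing when reading the tables.
- The exact rank-sum method is capped at pooled n = 40; beyond that the
  tie-corrected normal approximation is used (its error there is far below
  the score resolution).
- Forward, filter-ranked growth never revisits a gene (no backward steps or
  floating selection), mirroring the original procedure.
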