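# Methods

This note documents the models, algorithms and numerical choices behind
`plasmapattern`, in the spirit of a statistical methods appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A cohort is a list of subjects with sex, age, height (cm), weight (kg),
BMI (kg/m², always `weight / (height/100)²`), a BMI group label, and a
named panel of clinical blood parameters (missing values are NaN and are
excluded pairwise). Group labels follow half-open intervals
[18.5, 25) → NORM, [25, 30) → OW, [30, 35) → OB1, [35, 40) → OB2,
[40, ∞) → OB3, so every admissible BMI maps to exactly one group and
values like 24.95 cannot fall into a gap; BMI below the 18.5 inclusion
floor raises an error rather than being grouped silently. When a table
supplies both BMI and anthropometrics they must agree within 0.5 kg/m².

The proteome is a binary sample × protein matrix keyed by UniProt
accessions. Matrix columns are kept in lexicographic accession order so
outputs are byte-stable across runs. Protein identification lists are
consumed as long TSV (`sample_id`, `accession`); a sample present in the
sample order but absent from the identification map is an error, because
"no proteins identified" (an empty list) and "no data" are different
things.

## Synthetic cohort generator

The generator emulates a 104-subject, five-group cohort whose group sizes
(22/21/19/21/21), BMI moments, heights, ages and sex ratios match the
published cohort table that motivated the defaults.

**BMI.** Per group, BMI is drawn from a normal truncated to the group's
BMI interval. Because truncation changes moments, the underlying (μ, σ)
are calibrated so the *truncated* distribution has the target mean and SD:
for each candidate σ, μ is found by a monotone root solve (the truncated
mean is strictly increasing in μ and spans the interval), and σ is chosen
by root-finding the SD match. Calibration residuals below 1e-6 count as
exact.

A family constraint matters here: on a bounded interval the truncated
normal's SD is capped — as σ→∞ the shape tends to the uniform
(SD = width/√12), and with the mean pinned off-centre the large-σ limit is
a tilted, exponential-like shape with an even smaller SD. Three of the
five default SD targets exceed their cap (NORM 1.90 vs ≈1.876 attainable,
OB1 1.69 vs ≈1.443, OB2 1.39 vs ≈1.343). Real cohorts can exceed the cap
because group membership is assigned from observed BMI, not drawn from a
single truncated normal. The calibrator therefore has two modes: `strict`
raises a `CalibrationError` for unattainable targets, and the generator's
non-strict mode matches the mean exactly and takes the closest attainable
SD. Group means are consequently always exact; SDs are exact for OW and
OB3 and capped for NORM/OB1/OB2 (gaps 0.02–0.25 kg/m²).

**Anthropometrics.** Height and age are plain normals (height clipped to a
120–230 cm physiological guard that is essentially never active); sex is
Bernoulli with the group's observed female fraction; weight is *derived*
as BMI × (height/100)², so anthropometric consistency is exact by
construction and the group mean weight emerges as ≈ E[BMI]·E[(h/100)²].

**Clinical panel.** Parameter k is
`intercept_k + slope_k · (BMI − 30) + N(0, sd_k)`. The default panel of 12
parameters uses plausible clinical units (glucose/lipids in mmol/L, liver
enzymes in U/L, CRP in mg/L, ...) with BMI slopes of realistic sign and
magnitude, plus two deliberately BMI-independent parameters (hemoglobin,
creatinine) so the group-difference screen has true nulls.

**Proteome.** Protein j is present in subject i with probability
`logistic(a_j + b_j · z_i)`, `z_i = (BMI_i − 30)/6`. The centring
constants are fixed (not per-cohort statistics) so an effect size b means
the same thing for any cohort size. Informative proteins have b ≠ 0; the
default panel plants 15 of them with |b| spread over [1, 3] and
alternating sign, baseline 0. Noise proteins have b = 0 and baselines
drawn uniformly in [−2, 2] (occurrence frequencies roughly 12–88%);
36 near-ubiquitous columns (baseline logit 10, presence probability
> 0.9999) and 8 singleton-like columns (expected occurrence ≈ 1 sample)
exercise the catalogue filters. The default matrix is therefore
104 × 154 before filtering. The generator returns the informative set as
ground truth, and the same seed yields bit-identical cohorts and matrices.

**What the simulation does not model.** Protein abundances (only
presence/absence), peptide-level evidence and identification error,
correlated protein modules (columns are conditionally independent given
BMI), batch effects, and any clinical-parameter/proteome dependence beyond
their shared BMI driver. Passing recovery tests on this generator shows
the pipeline recovers the planted occurrence model at realistic sizes; it
does not certify performance on real plasma data, where effects are weaker
and correlated.

## Filtering and summaries

The catalogue filter drops columns with occurrence ≤ 1 (including
all-zero columns that can appear in externally supplied matrices) and
columns present in every sample; it is idempotent, and after it every
column count c satisfies 2 ≤ c ≤ n−1. Removing a group's samples changes
occurrence counts, so subsetting re-applies the filter by default (a flag
disables this). Catalogue summaries (totals, core proteins, per-group and
merged-group unions) are computed on the unfiltered matrix.

## Clustering and pattern extraction

Clinical profiles: parameters passing the Kruskal–Wallis screen (default
α = 0.05; one-way ANOVA available; a parameter missing in > 50% of
samples is skipped; a constant parameter gets p = 1) are z-scored
(sample SD, n−1) and clustered with Ward on Euclidean distances. Protein
profiles use Jaccard distances with the both-empty convention d = 0.

Ward linkage is implemented directly via the Lance–Williams recurrence

    d(k, i∪j)² = [(nᵢ+nₖ)d(i,k)² + (nⱼ+nₖ)d(j,k)² − nₖ d(i,j)²] / (nᵢ+nⱼ+nₖ).

The default `"D2"` dialect applies the recurrence to squared distances and
reports heights on the distance scale — the classical minimum-variance
method when inputs are Euclidean (it matches scipy's `linkage(·, "ward")`
merge for merge, and a brute-force minimum-SSE-increase agglomeration in
the tests). The `"D"` dialect applies the same recurrence to raw
distances, matching the legacy unsquared variant that some clustering
environments default to; on non-Euclidean inputs such as Jaccard both are
heuristics and the dialect is an explicit, recorded choice. Ties are
broken toward the lexicographically smallest pair of cluster creation
indices, so dendrograms are deterministic. Flat partitions remove the k−1
highest merges; labels are assigned in first-leaf order.

The ARI is computed from the contingency table in its adjusted-for-chance
form; the degenerate 0/0 case (both partitions trivial in the same way) is
defined as 1. The implementation is cross-checked against an independent
library implementation in the tests.

Pattern extraction targets the cluster with the larger mean BMI: per
protein a two-sided Fisher exact test of presence × membership,
Benjamini–Hochberg adjustment across proteins, pattern = adjusted p ≤ α,
ranked by |prevalence difference| (ties by accession). This is a
reproducible statistical surrogate for reading discriminative blocks off a
clustered heatmap; it makes no claim about how any particular published
pattern was assembled. The cluster's BMI is compared to its complement
with a two-sided Mann–Whitney U test (Welch's t available): with ~100
samples a rank test is robust to the skewed BMI distribution and costs
little power.

## Penalized regression and stability selection

The LASSO objective `(1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁` is solved on
column-standardized features (centred, population-SD scale; a flag
disables scaling) by cyclic coordinate descent on the Gram matrix, with
warm starts along a descending log-spaced grid of 100 λ values from
λ_max = maxⱼ |x̃ⱼᵀ(y − ȳ)|/n down to 0.01·λ_max. Coordinate sweeps are
interleaved with exact Newton solves on the current support (the
stationarity system `G_AA β_A = c_A − λ sign(β_A)` with a line search to
the first sign-flip boundary), which keeps dense, ill-conditioned supports
fast; convergence is declared when a full sweep moves no coefficient by
1e-7 (standardized scale). Solutions satisfy the KKT conditions to ~1e-5
and agree with an independent solver to ~1e-10 in the tests. Coefficients
are reported back on the original 0/1 scale, where a coefficient is the
BMI shift (kg/m²) associated with detecting the protein. Zero-variance
columns are dropped with a warning; a constant response yields the
intercept-only model. A slow pure-Python debug path
(`lasso_fit(debug=True)`) additionally asserts the objective is
non-increasing across sweeps.

λ is selected by repeated k-fold cross-validation (default 10 folds, 10
repeats, fresh random fold assignment per repeat) minimising the mean
out-of-fold squared error (absolute error available); ties go to the
larger λ, i.e. the sparser model. Each fold standardizes on its training
split only. One property worth knowing: under a pure-noise design the
minimum-mean-error λ still admits a few spurious features with
non-negligible probability, increasingly so as p approaches n — measured
here at ~13% of null replicates carrying > 2 features at n=100/p=30 but
~40% at n=104/p=100. This is inherent to λ_min selection and is precisely
what the subsample-intersection step repairs.

Stability selection runs 10 iterations; each draws ⌊0.9·n⌋ samples
without replacement, selects λ by CV on the subsample, fits, and records
the nonzero proteins. The consensus keeps proteins selected in every
iteration; with all-noise input the consensus is empty in the large
majority of runs (flagged, intercept-only final model). The final model
refits on all samples restricted to the consensus panel with its own
CV-selected λ (an OLS refit is available by flag). Per-iteration seeds
derive from a single `SeedSequence`, so results are bit-reproducible.

MAE protocols: the published-style "median absolute error" is ambiguous
between in-sample and held-out evaluation, so both are computed —
`holdout_pooled` (each iteration's model predicts its ~10% excluded
samples; pairs pooled across iterations; the headline number) and
`refit_insample` (the consensus model's in-sample residuals, optimistic
by construction). A pooled intercept-only baseline (train-mean
prediction) accompanies the holdout number.

## Pipeline and reproducibility

`run_pipeline` executes simulate/load → filter → cluster → predict and
writes TSV artifacts plus a plain-text report embedding the config echo;
the echoed config plus the master seed fully determine the run, and each
stochastic stage derives its seed as CRC32(stage name) mixed with the
master seed, so toggling one stage never shifts another's stream. Reports
contain no timestamps; a rerun is byte-identical.

## Problem sizes used in the checks

The statistical acceptance tests run at the study scale (n = 104,
p = 100–154): planted-recovery uses 50 replicate stability-selection runs
with 5 planted proteins at |b| = 3 among 95 noise proteins; the null
checks use 30 stability runs and 50 clustering runs on signal-free
proteomes. Within these simulations the CV uses 3 repeats rather than 10
— the selection behaviour is unchanged while each replicate stays cheap —
and library defaults remain 10×10-fold everywhere. The calibration script
averages 200 independent cohorts.

## Known limitations

- Three of the five default group SD targets are family-infeasible (see
  above); simulated group SDs are capped at the attainable value while
  means are exact.
- Ward on Jaccard distances is a widely used heuristic, not a
  minimum-variance method in a Euclidean sense; dialect choice ("D2" vs
  "D") can change dendrograms on real data.
- The Fisher/BH pattern is one defensible formalisation of
  "discriminative pattern"; alternatives (e.g. block extraction from the
  column dendrogram) would select overlapping but not identical sets.
- Consensus panels from intersection are conservative: a protein missed in
  a single iteration is discarded, so recall degrades gracefully but
  panel size is sensitive to the iteration count.
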