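# Methods

## Scope and data model

The package analyses a proteins × samples matrix of non-negative relative
expression values together with per-sample metadata (patient id, tissue
class ∈ {tumor, healthy_tube, contralateral_tube}, laterality). Missing is
a first-class value throughout the pipeline (empty TSV cell ↔ NaN), always
distinct from zero. Optionally the matrix itself is derived from spot-level
RPPA data: per (protein, sample) a serial dilution series (default
fractions 1, 1/2, 1/4, 1/8, 1/16 plus a buffer blank, two replicates — 12
data points) and one total-protein stain signal per sample.

## Synthetic study generator

The generator emulates a multi-region tumor sampling cohort: by default 13
patients contributing 5–9 tumor samples each (fixed sequence
7,7,7,7,7,7,7,7,7,7,6,6,6 = 88 — the true per-patient breakdown of such
cohorts is rarely published, so this is an explicit stand-in within the
stated range and fully configurable), 10 healthy-tube and 4
contralateral-tube normal individuals with one sample each, and the
packaged 36-protein panel (15 phosphoproteins).

Expression is hierarchical lognormal:

    tumor:   x_kij = μ_k · exp(δ_k) · exp(b_ki) · exp(w_kij)
    normal:  x_km  = μ_k · exp(u_km)

with mean-zero normal log-effects whose standard deviations are tied to
target CVs by σ = √ln(1 + CV²). The lognormal choice is deliberate:
expression values are positive intensity ratios, and a multiplicative
model makes the CV independent of the baseline μ_k, matching an analysis
framed entirely in CVs. Defaults are the study conditions the analysis
targets: within-tumor CV 25%, between-patient CV 21%, normal
between-individual CV 27%, baselines spread geometrically over
200–5000 AU. Normals carry no within-individual replication (one sample
per individual), hence only a between-individual component.

With mean-zero log components, exp(δ_k) is the ratio of *typical* (median,
equivalently geometric-mean) tumor to normal expression. The arithmetic
mean ratio is exp(δ_k + (σ_b² + σ_w² − σ_n²)/2); the distinction matters
when interpreting rank-based tests on arithmetic patient means (see the
calibration note below).

The spot-level layer maps each matrix cell to expected signal
`background + value · fraction` per spot, applies multiplicative lognormal
noise with unit mean and CV `spot_cv`, optionally clips at a saturation
level, and emits a per-sample total-protein signal proportional to the
column sum of the latent matrix (a stand-in for a total-protein stain)
under the same noise model. Random-number draw order is documented in
`synthetic.py` and treated as part of the API, so seeds are stable across
releases.

What the generator does *not* emulate: spatial array artifacts, antibody
cross-reactivity, protein–protein expression correlation beyond the shared
patient effect, inter-array batch effects, and FFPE degradation gradients.
Tests passing on synthetic data therefore validate the statistical
machinery, not robustness to those real-data failure modes.

## Quantification

Per (protein, sample): the mean buffer-blank signal is subtracted (clipped
at zero), every remaining spot provides an independent estimate
`signal / dilution_fraction` of the undiluted signal, and the cell value
is the **median** of these estimates over valid spots. Validity excludes
spots below a floor threshold (default 0, i.e. keep all) and spots at or
above `saturation_fraction` (default 0.95) of the maximum observed signal
— array-wide in `quantify_study`, per-series when a series is quantified
alone. Cells with fewer than `min_valid_spots` (default 2) valid spots are
missing, with a logged reason code (floor vs. saturation).

The median estimator is robust, parameter-light, exactly recovers the
truth in the noiseless limit, and is linear in the input signals (with
floor 0). A joint parametric response-curve fit across dilution series
(logistic/"SuperCurve"-style) would pool information across samples and is
a known alternative; it is out of scope here.

Normalization rescales each sample by `reference / total_protein_signal`
with the cohort **median** total as reference, making results invariant to
global staining intensity. Round-trip accuracy of the dilution-series
estimator is assessed with normalization disabled: the generator emits a
single noisy total per sample, so normalizing by it adds that stain noise
(~`spot_cv`) to every cell of the sample — a property of the
normalization input, not of the estimator under test. Noiseless round
trips with normalization are exercised on matrices with equal column
totals, where the reference ratio is a global constant.

## Heterogeneity statistics

- `cv`: 100 · sd/mean with the n−1 (sample) standard deviation — the
  small-sample context (5–9 samples per patient) argues for the unbiased
  variance; requires ≥ 2 finite values and a positive mean.
- Intratumoral CV: per (protein, patient) over that patient's tumor
  samples; patients with < 2 non-missing values are skipped and logged.
  Pooled per protein by the RMS average √(mean CV²) (≥ the arithmetic
  mean, equality iff all equal).
- Inter-patient CV: per protein, the CV across per-patient mean expression
  (means, not pooled samples — pooling would weight patients by sample
  count); for normal tissue classes, the CV across individuals directly.
- Group summaries report mean and (min, max) of the per-protein summaries
  for all / phosphorylated / non-phosphorylated proteins; empty groups are
  absent, never zero.
- Friedman test on the patient × protein CV table (blocks = patients —
  the only layout in which "do proteins differ in heterogeneity?" is a
  within-block comparison), midranks with the standard tie correction,
  p from the χ²(k−1) upper tail, incomplete blocks deleted listwise with a
  logged count. The statistic is computed in-package (scipy's
  implementation refuses k < 3) and cross-checked against scipy and a full
  permutation enumeration in the tests.
- Mann–Whitney U, two-sided: exact enumeration (scipy) when n_x + n_y ≤ 16
  without ties, otherwise the normal approximation with tie and continuity
  corrections; the method used is recorded in the result.
- Box-plot summaries use linear-interpolation quartiles and whiskers at
  the most extreme points within 1.5 · IQR of the quartiles; the
  convention is fixed so outputs are reproducible bit for bit.
- No multiple-testing correction by default (single-protein inference is
  reported as such); a Benjamini–Hochberg helper exists behind an
  explicit, off-by-default flag.

## Clustering

Preprocessing is log2 followed by per-protein median centering (the
Cluster/TreeView convention; log base unstated in most descriptions — base
2 chosen and documented). Sample distance is 1 − Spearman ρ over
pairwise-complete proteins (midrank ties, ≥ 3 shared proteins required),
i.e. signed correlation: anti-correlated samples are maximally distant
(distance 2), not similar. Agglomeration is UPGMA (average linkage), whose
merge heights are provably monotone; samples are sorted lexicographically
before agglomeration so distance ties resolve deterministically toward the
smallest sample id. Trees serialize to Newick with ultrametric branch
lengths (parent height − child height).

The co-clustering score cuts the tree into k flat clusters (k defaults to
the number of patients) and reports the fraction of same-patient tumor
sample pairs assigned to the same cluster, plus a per-patient "scattered"
flag (samples spanning > 1 cluster). Rank-based distances make the whole
construction invariant to strictly monotone per-sample transformations.

## Sampling-bias experiment

The mean-based analysis tests, per protein, the 13 per-patient tumor means
against all 14 normal sample values (never 88 samples vs. 14 — that would
pseudo-replicate patients). Single-sample analyses repeat the same test
with one randomly selected sample per patient; by default the three
repetitions partition a random permutation of each patient's samples, so
no sample is reused (maximally independent repetitions; a reuse mode
serves designs with fewer samples than repetitions). Direction is the sign
of the difference of medians — robust and consistent with the rank-based
test. α = 0.05 two-sided, no multiplicity correction, matching the
single-biomarker reporting convention.

Concordance categories partition the panel with precedence all_four >
mean_only_strict > singles_only > partial > none; a stricter singles-only
variant (significant in *every* repetition) and direction-conflict flags
are reported alongside, as are both operational counts of "missed by
single sampling" (non-significant in every repetition vs. in at least
one) — the published narrative count is ambiguous between the two, so
neither is privileged.

### Calibration note

Null proteins (δ = 0) in the single-sample analyses are exactly null for
the Mann–Whitney test (both log distributions are symmetric about the same
median). The mean-based analysis is only approximately null: the
arithmetic mean of n lognormal within-tumor replicates concentrates at
exp(σ_w²/2) times the median, so patient means are shifted upward relative
to single normal samples by a factor growing with the within-tumor CV
(≈ 3% at CV 25%, ≈ 8% at CV 40%). At the default study conditions the
empirical size of both analyses stays within 0.05 ± 0.02 (verified over
200 simulated cohorts); at within-tumor CV ≥ 40% *on the null proteins*
the mean-based rejection rate rises to ≈ 0.08. This is a genuine property
of comparing means of skewed replicates against single references with a
rank test, not an implementation artifact; the power stress test therefore
applies the elevated CV to the effect-carrying proteins while leaving null
proteins at study conditions.

## Problem sizes and numerical choices

Simulation-backed checks use the full default cohort (36 proteins, 102
samples): 20 seeds for CV parameter recovery, 200 cohorts for
power/type-I calibration, 10 seeds per noise level for co-clustering —
sizes at which Monte-Carlo error is comfortably below the asserted
tolerances (±3 CV percentage points, ±0.02 on rejection rates). All
simulations, selections and tie-breaks are driven by explicit integer
seeds through `numpy.random.default_rng`; reruns are bit-identical.

## Known limitations

- No parametric variance-component estimation (mixed models) or
  confidence intervals on CVs; CV recovery is validated by simulation.
- The quantification estimator treats spots independently; no shared
  response-curve fit, no inter-array normalization beyond total protein.
- The packaged differential-expression panel supports the classification
  layer only; the underlying patient-level raw data are not public, so its
  p-values are inputs, not reproduced quantities.
- Phospho status is curated panel metadata, not parsed from protein names
  (name heuristics misclassify e.g. total p38 MAPK).
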