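"""Intratumoral and inter-patient variation statistics.

The central quantity is the coefficient of variation (CV): the sample
standard deviation divided by the mean, times 100.  Being scale-free, it
lets proteins with very different absolute expression levels be compared on
one axis.  Intratumoral heterogeneity of a protein is the CV over the
spatially distinct samples of one patient's tumor; the per-protein cohort
summary is the root-mean-square (RMS) average of those per-patient CVs.
Inter-patient variation is the CV, across patients, of per-patient mean
expression; for normal reference tissue (one sample per individual) it is
the CV across individuals.

Hypothesis tests: a Friedman test (blocks = patients, treatments =
proteins) asks whether the extent of intratumoral heterogeneity differs
between proteins; the Mann-Whitney U test compares expression (or CVs)
between unrelated groups, two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .synthetic import TISSUE_TUMOR, TISSUE_CLASSES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    sided: str
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class BoxplotStats:
    median: float
    q25: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def cv(values) -> float:
    """Coefficient of variation in percent: 100 * sd / mean.

    Uses the n-1 (sample) standard deviation.  Requires at least two finite
    values and a positive mean; expression values are positive by
    construction, so a non-positive mean signals corrupted input.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValidationError(f"cv: need >= 2 finite values, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError(f"cv: mean must be > 0, got {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def rms_average(cvs) -> float:
    """Root-mean-square average: sqrt(mean of squares).

    Pools per-patient CVs into one per-protein summary; never smaller than
    the arithmetic mean, with equality iff all inputs are equal.
    """
    arr = np.asarray(cvs, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 1:
        raise ValidationError("rms_average: need >= 1 value")
    return float(np.sqrt(np.mean(np.square(arr))))


def _check_meta(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "patient_id", "tissue_class"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata: missing columns {sorted(missing)}")
    bad = set(meta["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValidationError(f"metadata: unknown tissue_class values {sorted(bad)}")
    return meta.set_index("sample_id", drop=False)


def intratumoral_cvs(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-(protein, patient) CV over that patient's tumor samples.

    Patients with fewer than two non-missing values for a protein are
    skipped with a logged notice.  Returns a long DataFrame with columns
    protein, patient_id, cv_percent, n_values.
    """
    meta = _check_meta(meta)
    tumor = meta[meta["tissue_class"] == TISSUE_TUMOR]
    if tumor.empty:
        raise ValidationError("intratumoral_cvs: no tumor samples in metadata")
    records = []
    for patient_id, grp in tumor.groupby("patient_id", sort=False):
        cols = [s for s in grp["sample_id"] if s in matrix.columns]
        sub = matrix[cols]
        for protein, row in sub.iterrows():
            vals = row.to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size < 2:
                logger.info("intratumoral_cvs: skipped protein=%s patient=%s "
                            "reason=insufficient_values n=%d", protein, patient_id,
                            vals.size)
                continue
            records.append({"protein": protein, "patient_id": patient_id,
                            "cv_percent": cv(vals), "n_values": int(vals.size)})
    return pd.DataFrame(records, columns=["protein", "patient_id", "cv_percent",
                                          "n_values"])


def interpatient_cv(matrix: pd.DataFrame, meta: pd.DataFrame,
                    tissue_class: str = TISSUE_TUMOR) -> pd.DataFrame:
    """Per-protein CV of per-patient summaries within one tissue class.

    For tumors the summaries are per-patient means over that patient's
    samples; normal tissue classes contribute one sample per individual, so
    the CV runs directly over individuals.  Returns columns protein, scope,
    cv_percent, n_values.
    """
    meta = _check_meta(meta)
    sel = meta[meta["tissue_class"] == tissue_class]
    groups = list(sel.groupby("patient_id", sort=False))
    if len(groups) < 2:
        raise ValidationError(
            f"interpatient_cv: need >= 2 individuals in class {tissue_class!r}, "
            f"got {len(groups)}")
    records = []
    for protein in matrix.index:
        summaries = []
        for _, grp in groups:
            cols = [s for s in grp["sample_id"] if s in matrix.columns]
            vals = matrix.loc[protein, cols].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size:
                summaries.append(vals.mean())
        if len(summaries) < 2:
            logger.info("interpatient_cv: skipped protein=%s class=%s "
                        "reason=insufficient_groups", protein, tissue_class)
            continue
        records.append({"protein": protein, "scope": tissue_class,
                        "cv_percent": cv(summaries), "n_values": len(summaries)})
    return pd.DataFrame(records, columns=["protein", "scope", "cv_percent", "n_values"])


def heterogeneity_table(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-protein heterogeneity summary.

    Columns: one ``cv_<patient>`` column per tumor patient (intratumoral
    CVs), ``rms_cv_percent`` pooling them, ``interpatient_cv_percent``
    (tumors), and one ``<class>_cv_percent`` column per normal tissue class
    present.  All values in percent.
    """
    intra = intratumoral_cvs(matrix, meta)
    wide = intra.pivot(index="protein", columns="patient_id", values="cv_percent")
    wide = wide.reindex(matrix.index)
    wide.columns = [f"cv_{p}" for p in wide.columns]
    rms = intra.groupby("protein")["cv_percent"].apply(lambda v: rms_average(v.to_numpy()))
    wide["rms_cv_percent"] = rms.reindex(matrix.index)
    inter = interpatient_cv(matrix, meta, TISSUE_TUMOR).set_index("protein")
    wide["interpatient_cv_percent"] = inter["cv_percent"].reindex(matrix.index)
    for cls in TISSUE_CLASSES[1:]:
        if (meta["tissue_class"] == cls).sum() >= 2:
            sub = interpatient_cv(matrix, meta, cls).set_index("protein")
            wide[f"{cls}_cv_percent"] = sub["cv_percent"].reindex(matrix.index)
    wide.index.name = "protein"
    return wide


def group_summary(table: pd.DataFrame, phospho_flags) -> pd.DataFrame:
    """Mean and range of per-protein CV summaries by phospho status.

    ``phospho_flags`` is a boolean sequence or Series covering every protein
    in ``table``.  One row per (statistic, group); empty groups are absent
    rather than reported as zero.
    """
    flags = pd.Series(np.asarray(phospho_flags, dtype=bool), index=table.index) \
        if not isinstance(phospho_flags, pd.Series) else phospho_flags.astype(bool)
    if not set(table.index) <= set(flags.index):
        raise ValidationError("group_summary: phospho_flags do not cover all proteins")
    flags = flags.reindex(table.index)
    stat_cols = [c for c in table.columns if c.endswith("_cv_percent")]
    groups = {"overall": table.index,
              "phospho": table.index[flags],
              "non_phospho": table.index[~flags]}
    rows = []
    for col in stat_cols:
        for gname, idx in groups.items():
            vals = table.loc[idx, col].dropna()
            if vals.empty:
                continue
            rows.append({"statistic": col.replace("_cv_percent", ""),
                         "group": gname, "mean_cv_percent": float(vals.mean()),
                         "min_cv_percent": float(vals.min()),
                         "max_cv_percent": float(vals.max()),
                         "n_proteins": int(vals.size)})
    return pd.DataFrame(rows)


def friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from an (n blocks, k treatments) rank array."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    ties = 0.0
    for block in ranks:
        _, counts = np.unique(block, return_counts=True)
        ties += np.sum(counts**3 - counts)
    correction = 1.0 - ties / (n * (k**3 - k))
    if correction == 0.0:
        return 0.0  # every block fully tied: no information, statistic 0
    return float(chisq / correction)


def friedman_cv_test(cv_records: pd.DataFrame) -> TestResult:
    """Friedman test of whether intratumoral heterogeneity differs between proteins.

    Blocks are patients, treatments are proteins, observations the
    per-(patient, protein) intratumoral CVs.  Patients missing a CV for any
    protein are dropped (listwise block deletion, logged).  The statistic
    uses midranks with the standard tie correction; p comes from the
    chi-square upper tail with k-1 degrees of freedom.
    """
    wide = cv_records.pivot(index="patient_id", columns="protein", values="cv_percent")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("friedman_cv_test: dropped %d incomplete patient blocks", dropped)
    n, k = complete.shape
    if k < 2:
        raise ValidationError(f"friedman_cv_test: need >= 2 proteins, got {k}")
    if n < 2:
        raise ValidationError(f"friedman_cv_test: need >= 2 complete blocks, got {n}")
    ranks = np.apply_along_axis(stats.rankdata, 1, complete.to_numpy())
    statistic = friedman_statistic(ranks)
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return TestResult("friedman", statistic, p, sided="upper-tail",
                      method=f"chi-square approximation, df={k - 1}, "
                             f"{n} blocks, tie-corrected midranks")


#: Largest combined sample size for which the exact Mann-Whitney null
#: distribution is enumerated (only tie-free data admit the exact method).
EXACT_MW_LIMIT = 16


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test between two unrelated groups.

    Exact p-value (full enumeration of the null distribution) when the
    combined sample size is at most ``EXACT_MW_LIMIT`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.  The method actually used is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney: both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= EXACT_MW_LIMIT and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact enumeration"
    else:
        if np.all(combined == combined[0]):
            # all observations identical: no evidence either way
            return TestResult("mann-whitney", float(x.size * y.size / 2.0), 1.0,
                              sided="two-sided", method="degenerate (all values equal)")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
        method = "normal approximation, tie and continuity corrected"
    return TestResult("mann-whitney", float(res.statistic),
                      float(min(res.pvalue, 1.0)), sided="two-sided", method=method)


def boxplot_stats(values) -> BoxplotStats:
    """Five-number box-plot summary with 1.5 * IQR whiskers.

    Quartiles use linear interpolation between order statistics; whiskers
    sit at the most extreme data points within ``q -/+ 1.5 * IQR``; points
    beyond are outliers.  A single value yields a degenerate box.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 1:
        raise ValidationError("boxplot_stats: need >= 1 value")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    iqr = q75 - q25
    low_fence, high_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = arr[(arr >= low_fence) & (arr <= high_fence)]
    outliers = np.sort(arr[(arr < low_fence) | (arr > high_fence)])
    return BoxplotStats(float(med), float(q25), float(q75),
                        float(inside.min()), float(inside.max()), outliers)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; off by default upstream)."""
    arr = np.asarray(p_values, dtype=float)
    return stats.false_discovery_control(arr, method="bh")
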