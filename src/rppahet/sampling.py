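"""Sampling-bias experiment: mean-based vs single-sample differential expression.

When protein expression varies across regions of a tumor, a differential
analysis built on one randomly chosen sample per patient can reach
different conclusions than one built on each patient's mean over several
regions.  This module runs both designs side by side: the mean-based
analysis compares per-patient tumor means against all normal-tissue
samples with a two-sided Mann-Whitney test, and the single-sample analysis
repeats the same comparison several times with freshly drawn single
samples per patient.  A concordance report then classifies every protein
by which analyses called it differential.

Concordance categories (mutually exclusive, in precedence order):

- ``all_four``         significant in the mean-based analysis and in every
                       single-sample repetition (the name reflects the
                       default of three repetitions: four analyses total);
- ``mean_only_strict`` significant by mean, non-significant in every
                       single-sample repetition;
- ``singles_only``     non-significant by mean, significant in at least one
                       repetition;
- ``partial``          significant by mean and in some but not all
                       repetitions;
- ``none``             significant nowhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .heterogeneity import mann_whitney, _check_meta
from .synthetic import TISSUE_TUMOR

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["protein", "analysis", "p_value", "direction", "significant"]
CATEGORIES = ("all_four", "mean_only_strict", "singles_only", "partial", "none")


def _direction(tumor_vals: np.ndarray, normal_vals: np.ndarray) -> str | None:
    diff = np.median(tumor_vals) - np.median(normal_vals)
    if diff > 0:
        return "up"
    if diff < 0:
        return "down"
    return None


def _de_table(tumor_by_protein: pd.DataFrame, normal_by_protein: pd.DataFrame,
              label: str, alpha: float) -> pd.DataFrame:
    rows = []
    for protein in tumor_by_protein.index:
        x = tumor_by_protein.loc[protein].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        y = normal_by_protein.loc[protein].to_numpy(dtype=float)
        y = y[np.isfinite(y)]
        if y.size == 0:
            logger.info("differential: skipped protein=%s analysis=%s "
                        "reason=missing_in_all_normals", protein, label)
            continue
        res = mann_whitney(x, y)
        rows.append({"protein": protein, "analysis": label,
                     "p_value": res.p_value,
                     "direction": _direction(x, y),
                     "significant": bool(res.p_value <= alpha)})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _split(matrix: pd.DataFrame, meta: pd.DataFrame):
    meta = _check_meta(meta)
    tumor = meta[meta["tissue_class"] == TISSUE_TUMOR]
    normal = meta[meta["tissue_class"] != TISSUE_TUMOR]
    tumor = tumor[tumor["sample_id"].isin(matrix.columns)]
    normal = normal[normal["sample_id"].isin(matrix.columns)]
    if tumor["patient_id"].nunique() < 2:
        raise ValidationError("differential: need >= 2 tumor patients")
    if len(normal) < 2:
        raise ValidationError("differential: need >= 2 normal samples")
    return tumor, normal


def mean_based_de(matrix: pd.DataFrame, meta: pd.DataFrame,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Differential expression from per-patient mean tumor profiles.

    Per protein: each tumor patient contributes the mean over their samples
    (never the pooled samples, which would pseudo-replicate patients);
    these means are compared against all normal-tissue sample values with a
    two-sided Mann-Whitney test.  Direction is the sign of the difference
    of medians.
    """
    tumor, normal = _split(matrix, meta)
    patient_means = pd.DataFrame({
        patient: matrix[[s for s in grp["sample_id"]]].mean(axis=1)
        for patient, grp in tumor.groupby("patient_id", sort=False)})
    normals = matrix[list(normal["sample_id"])]
    return _de_table(patient_means, normals, "mean", alpha)


def select_single_samples(meta: pd.DataFrame, n_repetitions: int, seed: int,
                          allow_reuse: bool = False) -> list[list[str]]:
    """Randomly select one tumor sample per patient for each repetition.

    Without reuse (default) the repetitions partition a random permutation
    of each patient's samples, so no sample is analyzed twice; this
    requires every patient to have at least ``n_repetitions`` samples.
    With ``allow_reuse`` each repetition draws independently.
    """
    meta = _check_meta(meta)
    tumor = meta[meta["tissue_class"] == TISSUE_TUMOR]
    rng = np.random.default_rng(seed)
    per_patient: list[list[str]] = []
    for patient_id, grp in tumor.groupby("patient_id", sort=False):
        ids = list(grp["sample_id"])
        if allow_reuse:
            picks = [ids[i] for i in rng.integers(0, len(ids), size=n_repetitions)]
        else:
            if n_repetitions > len(ids):
                raise ValidationError(
                    f"select_single_samples: patient {patient_id!r} has "
                    f"{len(ids)} samples < {n_repetitions} repetitions; "
                    "pass allow_reuse=True for small designs")
            perm = rng.permutation(len(ids))
            picks = [ids[i] for i in perm[:n_repetitions]]
        per_patient.append(picks)
    return [[picks[rep] for picks in per_patient] for rep in range(n_repetitions)]


def single_sample_de(matrix: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.05,
                     n_repetitions: int = 3, seed: int = 0,
                     allow_reuse: bool = False) -> pd.DataFrame:
    """Differential expression from one randomly selected sample per patient.

    Repeats the analysis ``n_repetitions`` times with fresh selections
    (labels ``single_1`` ...), each repetition comparing the selected
    per-patient values against all normal-tissue samples.  Fully
    reproducible given the seed.
    """
    if n_repetitions < 1:
        raise ValidationError("single_sample_de: n_repetitions must be >= 1")
    tumor, normal = _split(matrix, meta)
    selections = select_single_samples(meta, n_repetitions, seed, allow_reuse)
    normals = matrix[list(normal["sample_id"])]
    frames = []
    for rep, sample_ids in enumerate(selections, start=1):
        singles = matrix[sample_ids]
        frames.append(_de_table(singles, normals, f"single_{rep}", alpha))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ConcordanceReport:
    """Protein-level concordance between the mean-based and single-sample analyses."""

    table: pd.DataFrame        # protein, category, direction_conflict, singles_only_all
    counts: dict[str, int]
    n_missed_by_all_singles: int   # significant by mean, n.s. in every repetition
    n_missed_by_any_single: int    # significant by mean, n.s. in >= 1 repetition

    @property
    def proteins(self, ) -> dict[str, list[str]]:
        return {c: list(self.table.loc[self.table["category"] == c, "protein"])
                for c in CATEGORIES}


def classify_concordance(mean_results: pd.DataFrame, single_results: pd.DataFrame,
                         alpha: float = 0.05) -> ConcordanceReport:
    """Assign every protein to exactly one concordance category.

    Also flags direction conflicts (a protein significant in several
    analyses with opposite directions) and reports the stricter
    singles-only variant (significant in *every* repetition while
    non-significant by mean).
    """
    mean_panel = set(mean_results["protein"])
    single_panel = set(single_results["protein"])
    if mean_panel != single_panel:
        raise ValidationError(
            "classify_concordance: protein panels differ between analyses: "
            f"{sorted(mean_panel ^ single_panel)}")
    singles_by_protein = single_results.groupby("protein", sort=False)
    mean_by_protein = mean_results.set_index("protein")
    rows = []
    for protein in mean_results["protein"]:
        m = mean_by_protein.loc[protein]
        s = singles_by_protein.get_group(protein)
        sig_mean = bool(m["significant"])
        sig_singles = s["significant"].to_numpy(dtype=bool)
        if sig_mean and sig_singles.all():
            category = "all_four"
        elif sig_mean and not sig_singles.any():
            category = "mean_only_strict"
        elif not sig_mean and sig_singles.any():
            category = "singles_only"
        elif sig_mean:
            category = "partial"
        else:
            category = "none"
        directions = set()
        if sig_mean and m["direction"] is not None and pd.notna(m["direction"]):
            directions.add(m["direction"])
        sig_dirs = s.loc[s["significant"], "direction"].dropna()
        directions.update(sig_dirs)
        rows.append({"protein": protein, "category": category,
                     "direction_conflict": directions == {"up", "down"},
                     "singles_only_all": (not sig_mean) and bool(sig_singles.all())
                                         and sig_singles.size > 0})
    table = pd.DataFrame(rows)
    counts = {c: int((table["category"] == c).sum()) for c in CATEGORIES}
    n_all = counts["mean_only_strict"]
    n_any = int(((table["category"] == "mean_only_strict")
                 | (table["category"] == "partial")).sum())
    return ConcordanceReport(table=table, counts=counts,
                             n_missed_by_all_singles=n_all,
                             n_missed_by_any_single=n_any)


def run_sampling_bias_experiment(matrix: pd.DataFrame, meta: pd.DataFrame,
                                 alpha: float = 0.05, n_repetitions: int = 3,
                                 seed: int = 0, allow_reuse: bool = False
                                 ) -> tuple[pd.DataFrame, ConcordanceReport]:
    """End-to-end experiment: mean-based + repeated single-sample analyses.

    Returns the stacked per-protein result table (one row per protein per
    analysis) and the concordance report.  Deterministic given the seed.
    """
    mean_res = mean_based_de(matrix, meta, alpha)
    single_res = single_sample_de(matrix, meta, alpha, n_repetitions, seed,
                                  allow_reuse)
    report = classify_concordance(mean_res, single_res, alpha)
    return pd.concat([mean_res, single_res], ignore_index=True), report
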