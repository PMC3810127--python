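"""Quantification of dilution-series spot signals into per-sample expression values.

Each (protein, sample) series carries replicate spots at several dilution
fractions plus buffer blanks.  After background subtraction, every valid
spot provides an independent estimate ``signal / dilution_fraction`` of the
undiluted signal; the sample value is the median of these estimates — a
robust, parameter-light estimator that recovers the truth exactly in the
noiseless case and is linear in the input signals.  Spots are invalid when
they sit below the detection floor or inside the saturation band near the
top of the dynamic range.  Values are finally rescaled to a common
total-protein level (total-protein stain normalization).

Missing is a first-class value throughout: a cell with too few valid spots
is reported as missing (NaN), never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .synthetic import SpotTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantificationSettings:
    """Validity rules and normalization switches for quantification.

    floor_threshold
        Background-subtracted signals strictly below this are excluded
        (detection floor, same units as the raw signals).  Default 0 keeps
        every non-negative spot.
    saturation_fraction
        Spots at or above this fraction of the maximum observed signal
        (array-wide in :func:`quantify_study`, per series otherwise) are
        excluded as saturated.
    min_valid_spots
        Below this number of valid spots the cell is reported missing.
    """

    subtract_background: bool = True
    floor_threshold: float = 0.0
    saturation_fraction: float = 0.95
    min_valid_spots: int = 2
    normalize_total_protein: bool = True

    def __post_init__(self):
        if self.floor_threshold < 0:
            raise ValidationError("floor_threshold must be >= 0")
        if not 0.0 <= self.saturation_fraction <= 1.0:
            raise ValidationError("saturation_fraction must be in [0, 1]")
        if self.min_valid_spots < 1:
            raise ValidationError("min_valid_spots must be >= 1")


@dataclass(frozen=True)
class DilutionSeries:
    """All spots of one (protein, sample) pair."""

    protein: str
    sample_id: str
    dilution_fractions: np.ndarray
    replicates: np.ndarray
    signals: np.ndarray
    blank_signals: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        d = np.asarray(self.dilution_fractions, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if d.size < 1:
            raise ValidationError(
                f"series ({self.protein}, {self.sample_id}): needs >= 1 non-blank record")
        if d.shape != s.shape:
            raise ValidationError(
                f"series ({self.protein}, {self.sample_id}): "
                "dilution_fractions and signals differ in length")
        if np.any(d <= 0) or np.any(d > 1):
            raise ValidationError(
                f"series ({self.protein}, {self.sample_id}): dilution fractions "
                "must be in (0, 1]")
        if np.any(s < 0) or np.any(np.asarray(self.blank_signals, dtype=float) < 0):
            raise ValidationError(
                f"series ({self.protein}, {self.sample_id}): signals must be >= 0")
        object.__setattr__(self, "dilution_fractions", d)
        object.__setattr__(self, "replicates", np.asarray(self.replicates))
        object.__setattr__(self, "signals", s)
        object.__setattr__(self, "blank_signals",
                           np.asarray(self.blank_signals, dtype=float))


def subtract_background(series: DilutionSeries) -> DilutionSeries:
    """Subtract the mean buffer-blank signal from every spot, clipping at zero.

    Blanks are consumed: the returned series has none.  A series without
    blanks cannot be corrected; disable background subtraction instead.
    """
    if series.blank_signals.size == 0:
        raise ValidationError(
            f"series ({series.protein}, {series.sample_id}) has no buffer blanks; "
            "set subtract_background=False to skip background correction")
    background = float(series.blank_signals.mean())
    corrected = np.clip(series.signals - background, 0.0, None)
    return DilutionSeries(series.protein, series.sample_id,
                          series.dilution_fractions, series.replicates,
                          corrected, np.array([]))


def estimate_sample_value(
    series: DilutionSeries,
    settings: QuantificationSettings = QuantificationSettings(),
    saturation_cutoff: float | None = None,
) -> float:
    """Median of ``signal / dilution_fraction`` over valid spots.

    A spot is valid when its signal is >= the floor threshold and strictly
    below the saturation cutoff (``saturation_fraction`` times the series
    maximum unless an array-wide cutoff is supplied).  Returns NaN — with a
    logged reason code — when fewer than ``min_valid_spots`` remain.
    Background is assumed already subtracted.
    """
    s = series.signals
    if s.size == 0:
        raise ValidationError(
            f"series ({series.protein}, {series.sample_id}) is empty")
    if saturation_cutoff is None:
        saturation_cutoff = settings.saturation_fraction * float(s.max())
    below_floor = s < settings.floor_threshold
    saturated = s >= saturation_cutoff
    valid = ~below_floor & ~saturated
    if int(valid.sum()) < settings.min_valid_spots:
        reason = "floor" if below_floor.sum() >= saturated.sum() else "saturation"
        logger.info("quantify: missing cell protein=%s sample=%s reason=%s "
                    "n_valid=%d", series.protein, series.sample_id, reason,
                    int(valid.sum()))
        return float("nan")
    return float(np.median(s[valid] / series.dilution_fractions[valid]))


def normalize_total_protein(value: float, total_protein_signal: float,
                            reference_total: float) -> float:
    """Rescale a value to a reference total-protein level.

    ``value * reference_total / total_protein_signal``; the reference is
    conventionally the cohort median total, which makes the result invariant
    to global staining intensity.
    """
    if not total_protein_signal > 0:
        raise ValidationError(
            f"total_protein_signal must be > 0, got {total_protein_signal}")
    if not reference_total > 0:
        raise ValidationError(f"reference_total must be > 0, got {reference_total}")
    return value * reference_total / total_protein_signal


def quantify_study(
    spots: SpotTable,
    settings: QuantificationSettings = QuantificationSettings(),
) -> pd.DataFrame:
    """Quantify a whole spot table into a proteins x samples expression matrix.

    Per (protein, sample): background subtraction (when enabled and blanks
    are present), median dilution-corrected estimate with validity rules
    applied against an array-wide saturation cutoff, then total-protein
    normalization to the cohort median total.  Missing cells propagate as
    NaN.  Duplicate (protein, sample, dilution, replicate) records are
    rejected.
    """
    df = spots.spots
    required = {"protein", "sample_id", "dilution_fraction", "replicate", "signal"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"spot table: missing columns {sorted(missing_cols)}")
    dup = df.duplicated(["protein", "sample_id", "dilution_fraction", "replicate"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise ValidationError(
            "spot table: duplicate record for protein="
            f"{first['protein']} sample={first['sample_id']} "
            f"dilution={first['dilution_fraction']} replicate={first['replicate']}")

    is_blank = df["dilution_fraction"] == 0.0
    nonblank = df[~is_blank]
    array_max = float(nonblank["signal"].max()) if len(nonblank) else 0.0

    proteins = list(dict.fromkeys(df["protein"]))
    samples = list(dict.fromkeys(df["sample_id"]))
    matrix = pd.DataFrame(np.nan, index=pd.Index(proteins, name="protein"),
                          columns=samples)

    background_by_key: dict = {}
    if settings.subtract_background:
        blanks = df[is_blank]
        background_by_key = blanks.groupby(["protein", "sample_id"])["signal"].mean().to_dict()

    for (protein, sample_id), grp in nonblank.groupby(["protein", "sample_id"], sort=False):
        signals = grp["signal"].to_numpy(dtype=float)
        cutoff = settings.saturation_fraction * array_max
        if settings.subtract_background:
            key = (protein, sample_id)
            if key not in background_by_key:
                raise ValidationError(
                    f"series ({protein}, {sample_id}) has no buffer blanks; "
                    "set subtract_background=False to skip background correction")
            bg = background_by_key[key]
            signals = np.clip(signals - bg, 0.0, None)
            cutoff = max(cutoff - bg, 0.0)
        series = DilutionSeries(protein, sample_id,
                                grp["dilution_fraction"].to_numpy(dtype=float),
                                grp["replicate"].to_numpy(), signals)
        matrix.loc[protein, sample_id] = estimate_sample_value(
            series, settings, saturation_cutoff=cutoff)

    if settings.normalize_total_protein:
        totals = spots.totals.reindex(matrix.columns)
        if totals.isna().any():
            missing = list(totals.index[totals.isna()])
            raise ValidationError(f"totals: no total-protein signal for samples {missing}")
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValidationError(f"totals: non-positive total-protein signal for {bad}")
        reference = float(totals.median())
        matrix = matrix * (reference / totals)

    return matrix
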