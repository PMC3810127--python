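"""Synthetic RPPA study generator with a hierarchical lognormal variance model.

The generator emulates a multi-region tumor sampling study measured by
reverse phase protein arrays (RPPA): each patient contributes several
spatially distinct tumor samples, plus a reference panel of normal-tissue
individuals with one sample each.  Expression values are strictly positive
and their dispersion is summarised throughout the package by the
coefficient of variation (CV), so variation is modelled multiplicatively:

    tumor value   (protein k, patient i, sample j)
        = mu_k * exp(delta_k) * exp(b_ki) * exp(w_kij)
    normal value  (protein k, individual m)
        = mu_k * exp(u_km)

with b_ki ~ N(0, sigma_b,k^2) a patient-level random effect, w_kij ~
N(0, sigma_w,k^2) the within-tumor (intratumoral) effect, u_km ~
N(0, sigma_n,k^2) the between-individual effect for normal tissue, and
delta_k a natural-log fold change applied to tumor tissue only.  Each
log-scale standard deviation is tied to a target CV by the lognormal
identity sigma = sqrt(ln(1 + CV^2)), which makes the CV of the generated
values independent of the baseline mean mu_k.

An optional second layer turns the expression matrix into spot-level
dilution-series signals mimicking the physical array (serial dilutions,
duplicate spots, buffer blanks, a total-protein stain signal per sample),
so the quantification stage can be exercised end to end.

Random number usage order (stable across releases; bump the package major
version if it ever changes):

1. patient-level effects ``b``, one (n_proteins, n_patients) block;
2. within-tumor effects ``w``, one (n_proteins, n_samples) block per
   patient, patients in design order;
3. normal-tissue effects ``u``, one (n_proteins, n_normals) block,
   healthy tubes first, then contralateral tubes;
4. tumor/contralateral laterality labels.

``generate_spot_data`` uses its own seed with the order: spot noise (one
block per (dilution, replicate) level, levels in declared order, blanks
last), then total-protein noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

TISSUE_TUMOR = "tumor"
TISSUE_HEALTHY = "healthy_tube"
TISSUE_CONTRALATERAL = "contralateral_tube"
TISSUE_CLASSES = (TISSUE_TUMOR, TISSUE_HEALTHY, TISSUE_CONTRALATERAL)

#: Default per-patient tumor sample counts: 13 patients, 88 samples total,
#: every count within the 5-9 range typical of multi-region FFPE studies.
DEFAULT_SAMPLES_PER_PATIENT = (7, 7, 7, 7, 7, 7, 7, 7, 7, 7, 6, 6, 6)


def cv_to_sigma(cv):
    """Log-scale standard deviation for a lognormal with coefficient of variation ``cv``.

    Inverse of :func:`sigma_to_cv`; both implement the bijection
    sigma = sqrt(ln(1 + cv^2)) <=> cv = sqrt(exp(sigma^2) - 1).
    """
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0):
        raise ValidationError("cv must be >= 0")
    return np.sqrt(np.log1p(np.square(cv)))


def sigma_to_cv(sigma):
    """Coefficient of variation of a lognormal with log-scale sd ``sigma``."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValidationError("sigma must be >= 0")
    return np.sqrt(np.expm1(np.square(sigma)))


def _broadcast(name: str, value, n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(n, arr.item())
    if arr.shape != (n,):
        raise ValidationError(
            f"{name}: expected a scalar or length-{n} sequence, got shape {arr.shape}"
        )
    return arr


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: patients, per-patient sample counts, normals, protein panel."""

    n_patients: int
    samples_per_patient: tuple[int, ...]
    n_healthy_tubes: int
    n_contralateral_tubes: int
    n_proteins: int
    phospho_flags: tuple[bool, ...]
    protein_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if len(self.samples_per_patient) != self.n_patients:
            raise ValidationError(
                "samples_per_patient: length "
                f"{len(self.samples_per_patient)} != n_patients {self.n_patients}"
            )
        if any(s < 1 for s in self.samples_per_patient):
            raise ValidationError("samples_per_patient: every count must be >= 1")
        if self.n_healthy_tubes < 0 or self.n_contralateral_tubes < 0:
            raise ValidationError("normal-tissue counts must be >= 0")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if len(self.phospho_flags) != self.n_proteins:
            raise ValidationError(
                f"phospho_flags: length {len(self.phospho_flags)} != n_proteins "
                f"{self.n_proteins}"
            )
        if self.protein_ids is not None:
            if len(self.protein_ids) != self.n_proteins:
                raise ValidationError(
                    f"protein_ids: length {len(self.protein_ids)} != n_proteins "
                    f"{self.n_proteins}"
                )
            if len(set(self.protein_ids)) != self.n_proteins:
                raise ValidationError("protein_ids: duplicate protein ids")

    @property
    def proteins(self) -> tuple[str, ...]:
        if self.protein_ids is not None:
            return self.protein_ids
        return tuple(f"protein_{k + 1:02d}" for k in range(self.n_proteins))

    @property
    def n_tumor_samples(self) -> int:
        return int(sum(self.samples_per_patient))

    @property
    def n_samples(self) -> int:
        return self.n_tumor_samples + self.n_healthy_tubes + self.n_contralateral_tubes

    @classmethod
    def default(cls) -> "StudyDesign":
        """The default cohort: 13 tumors (88 samples), 10 healthy + 4
        contralateral fallopian-tube references, and the packaged 36-protein
        signaling panel (15 phosphoproteins)."""
        from .io import load_table2_fixture

        panel = load_table2_fixture()
        return cls(
            n_patients=13,
            samples_per_patient=DEFAULT_SAMPLES_PER_PATIENT,
            n_healthy_tubes=10,
            n_contralateral_tubes=4,
            n_proteins=len(panel),
            phospho_flags=tuple(bool(v) for v in panel["is_phospho"]),
            protein_ids=tuple(panel["protein"]),
        )


@dataclass(frozen=True)
class VarianceModel:
    """Per-protein baseline means and CV targets for each variance component.

    CVs are fractions (0.25 means 25%).  Scalars broadcast over the panel.
    """

    baseline_mean: np.ndarray
    between_patient_cv: np.ndarray
    within_tumor_cv: np.ndarray
    normal_between_individual_cv: np.ndarray

    def __init__(self, baseline_mean, between_patient_cv, within_tumor_cv,
                 normal_between_individual_cv, n_proteins: int | None = None):
        if n_proteins is None:
            n_proteins = max(
                np.atleast_1d(np.asarray(v)).size
                for v in (baseline_mean, between_patient_cv, within_tumor_cv,
                          normal_between_individual_cv)
            )
        object.__setattr__(self, "baseline_mean",
                           _broadcast("baseline_mean", baseline_mean, n_proteins))
        object.__setattr__(self, "between_patient_cv",
                           _broadcast("between_patient_cv", between_patient_cv, n_proteins))
        object.__setattr__(self, "within_tumor_cv",
                           _broadcast("within_tumor_cv", within_tumor_cv, n_proteins))
        object.__setattr__(self, "normal_between_individual_cv",
                           _broadcast("normal_between_individual_cv",
                                      normal_between_individual_cv, n_proteins))
        if np.any(self.baseline_mean <= 0):
            raise ValidationError("baseline_mean: all values must be > 0")
        for name in ("between_patient_cv", "within_tumor_cv",
                     "normal_between_individual_cv"):
            if np.any(getattr(self, name) < 0):
                raise ValidationError(f"{name}: CVs must be >= 0")

    @property
    def n_proteins(self) -> int:
        return self.baseline_mean.size

    @classmethod
    def default(cls, n_proteins: int = 36) -> "VarianceModel":
        """Study-condition defaults: intratumoral CV 25%, between-patient CV
        21%, normal between-individual CV 27%, baselines spread over ~1.5
        decades of arbitrary intensity units."""
        baselines = np.geomspace(200.0, 5000.0, n_proteins)
        return cls(baselines, 0.21, 0.25, 0.27, n_proteins=n_proteins)


@dataclass(frozen=True)
class EffectModel:
    """Tumor-vs-normal effects: a natural-log fold change per differential protein."""

    log_fold_change: dict[str, float] = field(default_factory=dict)

    @classmethod
    def null(cls) -> "EffectModel":
        return cls({})

    def as_array(self, proteins: tuple[str, ...]) -> np.ndarray:
        unknown = set(self.log_fold_change) - set(proteins)
        if unknown:
            raise ValidationError(
                f"log_fold_change: proteins not in panel: {sorted(unknown)}"
            )
        return np.array([self.log_fold_change.get(p, 0.0) for p in proteins])

    @property
    def differential_proteins(self) -> tuple[str, ...]:
        return tuple(p for p, d in self.log_fold_change.items() if d != 0.0)


@dataclass(frozen=True)
class SpotNoiseModel:
    """Noise and layout of the spot-level dilution-series layer.

    Defaults (five dilution steps, duplicate spots, a buffer blank pair)
    yield 12 data points per (protein, sample).
    """

    dilution_fractions: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625)
    n_replicates: int = 2
    include_buffer_blank: bool = True
    spot_cv: float = 0.0
    background_mean: float = 0.0
    saturation_level: float | None = None
    total_protein_scale: float = 1.0

    def __post_init__(self):
        fr = np.asarray(self.dilution_fractions, dtype=float)
        if fr.size < 1 or np.any(fr <= 0) or np.any(fr > 1):
            raise ValidationError("dilution_fractions: values must be in (0, 1]")
        if np.any(np.diff(fr) >= 0):
            raise ValidationError("dilution_fractions: must be strictly decreasing")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.spot_cv < 0:
            raise ValidationError("spot_cv must be >= 0")
        if self.background_mean < 0:
            raise ValidationError("background_mean must be >= 0")
        if self.saturation_level is not None and self.saturation_level <= 0:
            raise ValidationError("saturation_level must be > 0 when set")
        if self.total_protein_scale <= 0:
            raise ValidationError("total_protein_scale must be > 0")

    @property
    def n_spots_per_sample(self) -> int:
        n = len(self.dilution_fractions) * self.n_replicates
        if self.include_buffer_blank:
            n += self.n_replicates
        return n


@dataclass(frozen=True)
class GroundTruth:
    """Latent quantities that fully determine a generated study."""

    latent: pd.DataFrame                 # proteins x samples, noiseless-layer values
    patient_effects: pd.DataFrame        # proteins x patients, b_ki on log scale
    realized_within_cv: pd.DataFrame     # proteins x patients, empirical CV (fraction)
    log_fold_change: pd.Series           # per protein, delta_k


@dataclass(frozen=True)
class SpotTable:
    """Long-format spot records plus one total-protein signal per sample.

    ``spots`` columns: protein, sample_id, dilution_fraction, replicate,
    signal.  Buffer blanks are encoded with dilution_fraction 0.
    """

    spots: pd.DataFrame
    totals: pd.Series  # indexed by sample_id


def generate_study(
    design: StudyDesign,
    variance: VarianceModel,
    effects: EffectModel,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate an expression matrix, sample metadata and the ground truth.

    Returns ``(matrix, metadata, truth)`` where ``matrix`` is a proteins x
    samples DataFrame of positive values, and ``metadata`` has one row per
    matrix column with columns sample_id, patient_id, tissue_class, side.
    Identical arguments (including seed) reproduce bit-identical output.
    """
    if variance.n_proteins != design.n_proteins:
        raise ValidationError(
            f"variance model covers {variance.n_proteins} proteins, "
            f"design has {design.n_proteins}"
        )
    proteins = design.proteins
    delta = effects.as_array(proteins)
    rng = np.random.default_rng(seed)

    sigma_b = cv_to_sigma(variance.between_patient_cv)
    sigma_w = cv_to_sigma(variance.within_tumor_cv)
    sigma_n = cv_to_sigma(variance.normal_between_individual_cv)
    mu = variance.baseline_mean

    patient_ids = [f"patient_{i + 1:02d}" for i in range(design.n_patients)]
    b = rng.standard_normal((design.n_proteins, design.n_patients)) * sigma_b[:, None]

    columns: list[str] = []
    values: list[np.ndarray] = []
    meta_rows: list[dict] = []
    realized_cv = np.full((design.n_proteins, design.n_patients), np.nan)

    for i, (pid, n_s) in enumerate(zip(patient_ids, design.samples_per_patient)):
        w = rng.standard_normal((design.n_proteins, n_s)) * sigma_w[:, None]
        block = (mu * np.exp(delta))[:, None] * np.exp(b[:, i])[:, None] * np.exp(w)
        if n_s >= 2:
            realized_cv[:, i] = block.std(axis=1, ddof=1) / block.mean(axis=1)
        for j in range(n_s):
            sid = f"{pid}_s{j + 1}"
            columns.append(sid)
            values.append(block[:, j])
            meta_rows.append({"sample_id": sid, "patient_id": pid,
                              "tissue_class": TISSUE_TUMOR, "side": None})

    n_norm = design.n_healthy_tubes + design.n_contralateral_tubes
    if n_norm:
        u = rng.standard_normal((design.n_proteins, n_norm)) * sigma_n[:, None]
        normal_block = mu[:, None] * np.exp(u)
        for m in range(design.n_healthy_tubes):
            sid = f"healthy_{m + 1:02d}"
            columns.append(sid)
            values.append(normal_block[:, m])
            meta_rows.append({"sample_id": sid, "patient_id": sid,
                              "tissue_class": TISSUE_HEALTHY, "side": "na"})
        for m in range(design.n_contralateral_tubes):
            sid = f"contra_{m + 1:02d}"
            columns.append(sid)
            values.append(normal_block[:, design.n_healthy_tubes + m])
            meta_rows.append({"sample_id": sid, "patient_id": sid,
                              "tissue_class": TISSUE_CONTRALATERAL, "side": None})

    # laterality labels: ten of thirteen default patients had bilateral tumors,
    # but side plays no role in any statistic, so a random label suffices
    for row in meta_rows:
        if row["side"] is None:
            row["side"] = str(rng.choice(["left", "right"]))

    matrix = pd.DataFrame(np.column_stack(values), index=pd.Index(proteins, name="protein"),
                          columns=columns)
    metadata = pd.DataFrame(meta_rows)
    truth = GroundTruth(
        latent=matrix.copy(),
        patient_effects=pd.DataFrame(b, index=matrix.index, columns=patient_ids),
        realized_within_cv=pd.DataFrame(realized_cv, index=matrix.index,
                                        columns=patient_ids),
        log_fold_change=pd.Series(delta, index=matrix.index, name="log_fold_change"),
    )
    return matrix, metadata, truth


def generate_spot_data(matrix: pd.DataFrame, noise: SpotNoiseModel, seed: int) -> SpotTable:
    """Expand an expression matrix into spot-level dilution-series signals.

    Each (protein, sample) cell becomes ``n_replicates`` spots per dilution
    fraction with expected signal ``background + value * fraction`` under
    multiplicative lognormal noise of CV ``spot_cv``, optionally clipped at
    ``saturation_level``; buffer blanks carry the background alone.  One
    total-protein signal per sample is emitted, proportional to the column
    sum of the latent matrix (a stand-in for a total-protein stain), subject
    to the same noise model.  Missing matrix cells produce no spots.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] < 0):
        raise ValidationError("matrix: negative expression values are not allowed")
    rng = np.random.default_rng(seed)
    sigma = cv_to_sigma(noise.spot_cv).item()

    def _noisy(expected: np.ndarray) -> np.ndarray:
        if sigma == 0.0:
            return expected.copy()
        eps = np.exp(rng.standard_normal(expected.shape) * sigma - sigma**2 / 2.0)
        return expected * eps

    n_prot, n_samp = vals.shape
    frames = []
    levels = [(d, r) for d in noise.dilution_fractions for r in range(1, noise.n_replicates + 1)]
    if noise.include_buffer_blank:
        levels += [(0.0, r) for r in range(1, noise.n_replicates + 1)]
    prot_idx, samp_idx = np.nonzero(np.isfinite(vals))
    for d, r in levels:
        expected = noise.background_mean + vals[prot_idx, samp_idx] * d
        signal = _noisy(expected)
        if noise.saturation_level is not None:
            signal = np.minimum(signal, noise.saturation_level)
        frames.append(pd.DataFrame({
            "protein": matrix.index.to_numpy()[prot_idx],
            "sample_id": matrix.columns.to_numpy()[samp_idx],
            "dilution_fraction": d,
            "replicate": r,
            "signal": signal,
        }))
    spots = pd.concat(frames, ignore_index=True)
    spots = spots.sort_values(
        ["protein", "sample_id", "dilution_fraction", "replicate"],
        ascending=[True, True, False, True], kind="stable").reset_index(drop=True)

    expected_totals = noise.total_protein_scale * np.nansum(vals, axis=0)
    totals = pd.Series(_noisy(expected_totals), index=matrix.columns, name="total_signal")
    totals.index.name = "sample_id"
    return SpotTable(spots=spots, totals=totals)
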