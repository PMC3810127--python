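"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and sample metadata travel as TSV (proteins as rows —
the RPPA convention — with the protein id in the first column; empty cells
are missing values, never zero).  Spot-level data and per-sample
total-protein signals travel as long-format CSV.  Trees are written as
Newick.  The packaged differential-expression fixture (36 signaling
proteins with p-values and directions for a mean-based and three
single-sample analyses, plus curated phospho flags) is integrity-checked
against a SHA-256 digest on load.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ChecksumError, ValidationError
from .synthetic import SpotTable, TISSUE_CLASSES

_TABLE2_SHA256 = "3fb1c3afbf31d8e283dcd1e017da4cfdcc6c44926067105adeb7160bfce7a920"

SIDE_VALUES = ("left", "right", "na")


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a proteins x samples TSV; empty cells become missing (NaN).

    Rejects duplicate protein or sample ids and names the exact cell of any
    malformed numeric value.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index.name = "protein"
    if raw.index.duplicated().any():
        dupes = sorted(set(raw.index[raw.index.duplicated()]))
        raise ValidationError(f"matrix {path}: duplicate protein ids {dupes}")
    if raw.columns.duplicated().any():
        dupes = sorted(set(raw.columns[raw.columns.duplicated()]))
        raise ValidationError(f"matrix {path}: duplicate sample ids {dupes}")
    out = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        for prot, cell in raw[col].items():
            cell = cell.strip()
            if cell == "":
                continue
            try:
                out.loc[prot, col] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"matrix {path}: malformed value {cell!r} at "
                    f"protein={prot!r} sample={col!r}") from None
    return out


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="", index_label="protein")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata TSV (sample_id, patient_id, tissue_class[, side])."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "patient_id", "tissue_class"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata {path}: missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dupes = sorted(set(meta.loc[meta["sample_id"].duplicated(), "sample_id"]))
        raise ValidationError(f"metadata {path}: duplicate sample ids {dupes}")
    bad = set(meta["tissue_class"]) - set(TISSUE_CLASSES)
    if bad:
        raise ValidationError(
            f"metadata {path}: unknown tissue_class values {sorted(bad)}; "
            f"expected one of {TISSUE_CLASSES}")
    if "side" not in meta.columns:
        meta["side"] = "na"
    meta.loc[meta["side"] == "", "side"] = "na"
    bad_side = set(meta["side"]) - set(SIDE_VALUES)
    if bad_side:
        raise ValidationError(
            f"metadata {path}: unknown side values {sorted(bad_side)}")
    return meta[["sample_id", "patient_id", "tissue_class", "side"]]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def check_consistency(matrix: pd.DataFrame, meta: pd.DataFrame) -> dict[str, list[str]]:
    """Samples present in only one of matrix/metadata, by side."""
    matrix_only = sorted(set(matrix.columns) - set(meta["sample_id"]))
    meta_only = sorted(set(meta["sample_id"]) - set(matrix.columns))
    return {"matrix_only": matrix_only, "metadata_only": meta_only}


def write_spot_table(spots: SpotTable, spots_path, totals_path) -> None:
    spots.spots.to_csv(spots_path, index=False)
    spots.totals.rename("total_signal").to_csv(totals_path, index_label="sample_id")


def read_spot_table(spots_path, totals_path) -> SpotTable:
    spots = pd.read_csv(spots_path)
    required = {"protein", "sample_id", "dilution_fraction", "replicate", "signal"}
    missing = required - set(spots.columns)
    if missing:
        raise ValidationError(f"spot table {spots_path}: missing columns {sorted(missing)}")
    totals = pd.read_csv(totals_path, index_col="sample_id")["total_signal"]
    return SpotTable(spots=spots, totals=totals)


def load_table2_fixture() -> pd.DataFrame:
    """Load the packaged 36-protein differential-expression panel.

    Columns: protein, protein_ascii (lossless alias for restricted
    terminals), is_phospho (bool), and (p, direction) pairs for the
    mean-based analysis and three single-sample repetitions.  Missing p
    means non-significant at the 5% level (the source reports 'n.s.'
    without a value); a printed p of 0.000 means < 0.0005 and is stored as
    0.0.  The file's SHA-256 digest is verified on every load.
    """
    ref = resources.files("rppahet.data").joinpath("table2_fixture.csv")
    payload = ref.read_bytes()
    digest = hashlib.sha256(payload).hexdigest()
    if digest != _TABLE2_SHA256:
        raise ChecksumError(
            f"table2_fixture.csv is corrupted: sha256 {digest} != {_TABLE2_SHA256}")
    from io import BytesIO

    df = pd.read_csv(BytesIO(payload), dtype={"protein": str, "protein_ascii": str},
                     keep_default_na=False)
    df["is_phospho"] = df["is_phospho"].astype(int).astype(bool)
    for col in ("p_mean", "p_s1", "p_s2", "p_s3"):
        df[col] = pd.to_numeric(df[col].replace("", np.nan))
    for col in ("dir_mean", "dir_s1", "dir_s2", "dir_s3"):
        df[col] = df[col].replace("", None)
    return df


def fixture_differential_results(alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reshape the packaged panel into (mean_results, single_results) tables.

    A recorded 'n.s.' entry is non-significant by definition; numeric
    p-values are thresholded at ``alpha``.
    """
    fx = load_table2_fixture()
    frames = {"mean": ("p_mean", "dir_mean"), "single_1": ("p_s1", "dir_s1"),
              "single_2": ("p_s2", "dir_s2"), "single_3": ("p_s3", "dir_s3")}
    tables = []
    for label, (p_col, d_col) in frames.items():
        tables.append(pd.DataFrame({
            "protein": fx["protein"],
            "analysis": label,
            "p_value": fx[p_col],
            "direction": fx[d_col],
            "significant": fx[p_col].notna() & (fx[p_col] <= alpha),
        }))
    mean_results = tables[0]
    single_results = pd.concat(tables[1:], ignore_index=True)
    return mean_results, single_results
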