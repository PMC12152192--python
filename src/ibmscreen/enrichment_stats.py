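"""Label-free pull-down / IP enrichment statistics.

The quantitative pipeline mirrors the standard Perseus workflow for peptide
pull-down interactomics: log-transform LFQ intensities, require quantification
in a minimum number of replicates, impute the remaining missing values from a
down-shifted normal distribution (missingness in label-free proteomics is
concentrated at low intensities), test each protein with an equal-variance
two-sample Student t-test, and call hits at a fixed -log10(p) cut-off.

Two presets are provided: peptide pull-downs (quantified in >=2 of 3
replicates, imputation downshift 1.8, width 0.3) and immunoprecipitations
(3 of 3, downshift 2.0, width 0.3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PRESETS = {
    "pulldown": {"min_valid": 2, "downshift": 1.8, "width": 0.3},
    "ip": {"min_valid": 3, "downshift": 2.0, "width": 0.3},
}

DEFAULT_CUTOFF_NEG_LOG10_P = 2.0


class ImputationError(ValueError):
    """Raised when the observed-value distribution cannot parameterize imputation."""


@dataclass
class LFQMatrix:
    """Protein × sample intensity table with group labels.

    ``intensities`` holds strictly positive raw intensities (NaN = missing)
    until :func:`prepare` log-transforms them; ``groups`` maps each sample
    column to one of two group labels, each with at least two samples.
    """

    intensities: pd.DataFrame
    groups: Mapping[str, str]
    log_transformed: bool = False

    def __post_init__(self) -> None:
        missing_cols = set(self.intensities.columns) - set(self.groups)
        if missing_cols:
            raise ValueError(f"samples without group labels: {sorted(missing_cols)}")
        counts = pd.Series({s: g for s, g in self.groups.items()
                            if s in self.intensities.columns}).value_counts()
        if len(counts) != 2:
            raise ValueError(f"expected exactly 2 groups, got {list(counts.index)}")
        if (counts < 2).any():
            raise ValueError("each group needs at least 2 samples")
        if not self.log_transformed:
            vals = self.intensities.to_numpy(dtype=float)
            present = vals[~np.isnan(vals)]
            if present.size and present.min() <= 0:
                raise ValueError("raw intensities must be strictly positive where present")

    def group_columns(self, label: str) -> list[str]:
        return [s for s in self.intensities.columns if self.groups[s] == label]

    @property
    def group_labels(self) -> tuple[str, str]:
        labels = sorted({self.groups[s] for s in self.intensities.columns})
        return labels[0], labels[1]


def prepare(
    matrix: LFQMatrix,
    min_valid: int = 2,
    mode: str = "any_group",
    log_base: float = 2.0,
) -> LFQMatrix:
    """Log-transform and filter on the minimum-valid-values rule.

    A protein is retained iff it has at least ``min_valid`` present values in
    at least one group (``mode='any_group'``, the default) or in each group
    (``mode='each_group'``).
    """
    if mode not in ("any_group", "each_group"):
        raise ValueError(f"unknown filter mode {mode!r}")
    vals = matrix.intensities.to_numpy(dtype=float)
    present = ~np.isnan(vals)
    if np.any(vals[present] <= 0):
        raise ValueError("raw intensities must be strictly positive where present")

    logged = matrix.intensities.apply(lambda col: np.log(col) / math.log(log_base)) \
        if not matrix.log_transformed else matrix.intensities.copy()

    a, b = matrix.group_labels
    counts_a = logged[matrix.group_columns(a)].notna().sum(axis=1)
    counts_b = logged[matrix.group_columns(b)].notna().sum(axis=1)
    if mode == "any_group":
        keep = (counts_a >= min_valid) | (counts_b >= min_valid)
    else:
        keep = (counts_a >= min_valid) & (counts_b >= min_valid)

    return LFQMatrix(
        intensities=logged.loc[keep].copy(),
        groups=dict(matrix.groups),
        log_transformed=True,
    )


def impute_lower_tail(
    matrix: LFQMatrix,
    downshift: float = 1.8,
    width: float = 0.3,
    scope: str = "matrix",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[LFQMatrix, pd.DataFrame]:
    """Replace missing cells with draws from a down-shifted normal.

    With μ, σ the mean and standard deviation of the present values in scope
    (whole matrix by default, per sample column with ``scope='column'``), each
    missing cell is drawn independently from Normal(μ − downshift·σ,
    (width·σ)²).  Present cells are untouched.  Returns the completed matrix
    and the boolean imputed-cell mask.
    """
    if downshift <= 0 or width <= 0:
        raise ValueError("downshift and width must be positive")
    if scope not in ("matrix", "column"):
        raise ValueError(f"unknown imputation scope {scope!r}")
    if not matrix.log_transformed:
        raise ValueError("impute on the log-transformed matrix (run prepare first)")
    if rng is None:
        rng = np.random.default_rng(seed)

    df = matrix.intensities.copy()
    mask = df.isna()

    def _draw(values: np.ndarray, n_missing: int) -> np.ndarray:
        present = values[~np.isnan(values)]
        if present.size < 2:
            raise ImputationError("fewer than 2 present values in imputation scope")
        mu, sigma = float(np.mean(present)), float(np.std(present, ddof=1))
        if sigma == 0:
            raise ImputationError("present values are constant; sd of scope is 0")
        return rng.normal(mu - downshift * sigma, width * sigma, size=n_missing)

    if scope == "matrix":
        flat = df.to_numpy(dtype=float)
        n_missing = int(mask.to_numpy().sum())
        if n_missing:
            draws = _draw(flat, n_missing)
            flat[mask.to_numpy()] = draws
            df = pd.DataFrame(flat, index=df.index, columns=df.columns)
    else:
        for col in df.columns:
            col_missing = int(mask[col].sum())
            if col_missing:
                df.loc[mask[col], col] = _draw(df[col].to_numpy(dtype=float), col_missing)

    completed = LFQMatrix(intensities=df, groups=dict(matrix.groups), log_transformed=True)
    return completed, mask


def t_test_two_sample(
    matrix: LFQMatrix, group_order: Optional[tuple[str, str]] = None
) -> pd.DataFrame:
    """Equal-variance two-sample Student t-test per protein.

    ``difference`` is mean(A) − mean(B) in log units, with (A, B) either
    ``group_order`` or the sorted group labels.  The matrix must be completed
    (no missing values).
    """
    if matrix.intensities.isna().any().any():
        raise ValueError("matrix contains missing values; impute before testing")
    a, b = group_order if group_order is not None else matrix.group_labels
    cols_a, cols_b = matrix.group_columns(a), matrix.group_columns(b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs at least 2 samples")

    xa = matrix.intensities[cols_a].to_numpy(dtype=float)
    xb = matrix.intensities[cols_b].to_numpy(dtype=float)
    t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p)

    rows = pd.DataFrame(
        {
            "protein": matrix.intensities.index,
            "difference": xa.mean(axis=1) - xb.mean(axis=1),
            "t": t,
            "p": p,
            "neg_log10_p": neg_log10_p,
        }
    ).set_index("protein")
    rows["df"] = len(cols_a) + len(cols_b) - 2
    return rows


def attach_imputation_counts(
    rows: pd.DataFrame, imputed_mask: pd.DataFrame, matrix: LFQMatrix
) -> pd.DataFrame:
    """Add n_imputed_A / n_imputed_B columns (A, B = sorted group labels)."""
    a, b = matrix.group_labels
    rows = rows.copy()
    rows["n_imputed_A"] = imputed_mask[matrix.group_columns(a)].sum(axis=1).reindex(rows.index)
    rows["n_imputed_B"] = imputed_mask[matrix.group_columns(b)].sum(axis=1).reindex(rows.index)
    return rows


def classify_hits(
    rows: pd.DataFrame,
    cutoff_neg_log10_p: float = DEFAULT_CUTOFF_NEG_LOG10_P,
    require_positive_difference: bool = True,
) -> pd.DataFrame:
    """Flag significant enrichment and sort the volcano table by p.

    A protein is a hit iff -log10(p) >= cutoff and (if required) the mean
    difference is positive.  A Benjamini-Hochberg FDR column is emitted for
    reference but never used for the hit call.
    """
    out = rows.copy()
    out["significant"] = out["neg_log10_p"] >= cutoff_neg_log10_p
    if require_positive_difference:
        out["significant"] &= out["difference"] > 0
    out["bh_fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p", kind="mergesort")


@dataclass
class EnrichmentResult:
    table: pd.DataFrame
    hits: tuple
    manifest: dict = field(default_factory=dict)


def run_enrichment(
    matrix: LFQMatrix,
    preset: str = "pulldown",
    seed: Optional[int] = None,
    scope: str = "matrix",
    filter_mode: str = "any_group",
    cutoff_neg_log10_p: float = DEFAULT_CUTOFF_NEG_LOG10_P,
    require_positive_difference: bool = True,
    group_order: Optional[tuple[str, str]] = None,
) -> EnrichmentResult:
    """Full pipeline: prepare → impute → t-test → hit classification."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[preset]
    prepared = prepare(matrix, min_valid=params["min_valid"], mode=filter_mode)
    completed, mask = impute_lower_tail(
        prepared, downshift=params["downshift"], width=params["width"], scope=scope, seed=seed
    )
    rows = t_test_two_sample(completed, group_order=group_order)
    rows = attach_imputation_counts(rows, mask, completed)
    table = classify_hits(
        rows,
        cutoff_neg_log10_p=cutoff_neg_log10_p,
        require_positive_difference=require_positive_difference,
    )
    hits = tuple(table.index[table["significant"]])
    manifest = {
        "preset": preset,
        "seed": seed,
        "scope": scope,
        "filter_mode": filter_mode,
        "min_valid": params["min_valid"],
        "downshift": params["downshift"],
        "width": params["width"],
        "cutoff_neg_log10_p": cutoff_neg_log10_p,
        "require_positive_difference": require_positive_difference,
    }
    return EnrichmentResult(table=table, hits=hits, manifest=manifest)


def read_lfq_tsv(
    intensities_path: Union[str, Path], groups_path: Union[str, Path]
) -> LFQMatrix:
    """Load an intensity TSV (first column = protein id) and a sample→group TSV."""
    intensities = pd.read_csv(intensities_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", dtype=str)
    if groups_df.shape[1] != 2:
        raise ValueError(f"{groups_path}: expected two columns (sample, group)")
    groups = dict(zip(groups_df.iloc[:, 0], groups_df.iloc[:, 1]))
    return LFQMatrix(intensities=intensities, groups=groups)


def write_volcano_tsv(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, sep="\t")
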