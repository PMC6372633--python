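"""Feature-table filtering: background removal, zero->NA, presence filter,
fence-based outlier nulling, log2 transform and the per-genotype
testability (ANOVA presence) filter.

The canonical order is background -> zeros-to-missing -> presence ->
outliers; ``run_qc`` enforces it and logs counts at every step. Quartiles
use linear interpolation between order statistics (numpy's default,
"type 7"), computed per feature within each genotype x regime x tissue
cell over non-missing values. Outlier fences are strict inequalities:
value > Q3 + m*IQR or value < Q1 - m*IQR.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .tables import FeatureTable


@dataclass(frozen=True)
class OutlierRule:
    """Fence multipliers around the interquartile range."""

    lower_mult: float = 3.0
    upper_mult: float = 3.0

    def validate(self) -> None:
        if self.lower_mult < 0 or self.upper_mult < 0:
            raise ValueError("fence multipliers must be non-negative")


def remove_background(
    table: FeatureTable, blanks: pd.DataFrame, ratio_threshold: float = 0.5
) -> FeatureTable:
    """Drop features whose mean blank abundance >= threshold x mean sample abundance."""
    shared = table.features.intersection(blanks.columns)
    if len(shared) == 0:
        raise SchemaError("blanks share no features with the table")
    out = table.copy()
    blank_mean = blanks[shared].mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sample_mean = out.values[shared].mean(axis=0, skipna=True)
    drop = shared[(blank_mean >= ratio_threshold * sample_mean).to_numpy()]
    out.values = out.values.drop(columns=drop)
    return out.logged(
        step="remove_background",
        ratio_threshold=ratio_threshold,
        removed=sorted(drop.tolist()),
        n_removed=len(drop),
    )


def zeros_to_missing(table: FeatureTable) -> FeatureTable:
    """Replace every exact-zero cell with missing (NaN); idempotent."""
    out = table.copy()
    n_zero = int((out.values == 0).sum().sum())
    out.values = out.values.mask(out.values == 0)
    return out.logged(step="zeros_to_missing", n_nulled=n_zero)


def presence_filter(table: FeatureTable, min_present: int = 3) -> FeatureTable:
    """Remove features with < min_present values in *every* design cell.

    A feature survives as soon as one genotype x regime x tissue cell holds
    at least ``min_present`` non-missing values.
    """
    if table.n_samples == 0 or table.n_features == 0:
        raise SchemaError("presence_filter requires a non-empty table")
    out = table.copy()
    present = out.values.notna().to_numpy()
    keep = np.zeros(out.n_features, dtype=bool)
    for _cell, rows in out.cell_groups():
        keep |= present[rows].sum(axis=0) >= min_present
    removed = out.features[~keep]
    out.values = out.values.loc[:, keep]
    return out.logged(
        step="presence_filter",
        min_present=min_present,
        removed=sorted(removed.tolist()),
        n_removed=len(removed),
    )


def _nanquantile_type7(a: np.ndarray, q: float) -> np.ndarray:
    """Column-wise type-7 (linear-interpolation) quantile ignoring NaNs.

    Vectorized for many short columns; numpy's nanquantile falls back to a
    per-column Python loop when NaNs are present, which is far too slow for
    thousands of features.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    s = np.sort(a, axis=0)  # NaNs sort to the end
    counts = (~np.isnan(a)).sum(axis=0)
    h = (counts - 1) * q
    lo = np.floor(h).astype(int)
    hi = np.ceil(h).astype(int)
    lo_c = np.clip(lo, 0, a.shape[0] - 1)
    hi_c = np.clip(hi, 0, a.shape[0] - 1)
    vlo = np.take_along_axis(s, lo_c[None, :], axis=0)[0]
    vhi = np.take_along_axis(s, hi_c[None, :], axis=0)[0]
    out = vlo + (h - lo) * (vhi - vlo)
    out[counts == 0] = np.nan
    return out


def compute_fences(
    cell_values: np.ndarray, rule: OutlierRule = OutlierRule()
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (lower, upper) fences for one design cell.

    ``cell_values`` is (n_samples_in_cell, n_features); NaNs are ignored.
    Columns with no observed value get (-inf, inf) fences.
    """
    rule.validate()
    q1 = _nanquantile_type7(cell_values, 0.25)
    q3 = _nanquantile_type7(cell_values, 0.75)
    iqr = q3 - q1
    lower = q1 - rule.lower_mult * iqr
    upper = q3 + rule.upper_mult * iqr
    lower = np.where(np.isnan(lower), -np.inf, lower)
    upper = np.where(np.isnan(upper), np.inf, upper)
    return lower, upper


def flag_outliers(
    table: FeatureTable, rule: OutlierRule = OutlierRule()
) -> FeatureTable:
    """Replace strict fence violations with missing, per feature per cell."""
    out = table.copy()
    vals = out.values.to_numpy(dtype=float, copy=True)
    per_cell: dict[str, int] = {}
    total = 0
    for cell, rows in out.cell_groups():
        sub = vals[rows]
        lower, upper = compute_fences(sub, rule)
        bad = (sub > upper[None, :]) | (sub < lower[None, :])
        bad &= ~np.isnan(sub)
        n_bad = int(bad.sum())
        if n_bad:
            sub[bad] = np.nan
            vals[rows] = sub
        per_cell["|".join(map(str, cell))] = n_bad
        total += n_bad
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out.logged(
        step="flag_outliers",
        lower_mult=rule.lower_mult,
        upper_mult=rule.upper_mult,
        n_nulled=total,
        per_cell=per_cell,
    )


def log2_transform(table: FeatureTable, pseudocount: float = 0.0) -> FeatureTable:
    """Elementwise log2 of abundances; missing cells stay missing."""
    out = table.copy()
    vals = out.values.to_numpy(dtype=float, copy=True)
    shifted = vals + pseudocount
    bad = (shifted <= 0) & ~np.isnan(vals)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            "non-positive abundance at sample "
            f"'{out.values.index[r]}', feature '{out.values.columns[c]}' "
            "with pseudocount 0"
            if pseudocount == 0
            else f"non-positive shifted abundance at ('{out.values.index[r]}', "
            f"'{out.values.columns[c]}')"
        )
    out.values = pd.DataFrame(
        np.log2(shifted), index=out.values.index, columns=out.values.columns
    )
    out.log_scale = True
    return out.logged(step="log2_transform", pseudocount=pseudocount)


@dataclass
class TestabilityReport:
    """Which metabolites are testable for which genotype, per tissue.

    ``testable[tissue]`` is a genotypes x features boolean DataFrame; a
    metabolite is testable for genotype g iff both its control and drought
    groups hold >= min_per_group non-missing values. ``removed[tissue]``
    lists metabolites testable for no genotype, with counts mirrored in
    ``n_removed``.
    """

    testable: dict[str, pd.DataFrame]
    removed: dict[str, list[str]]
    n_removed: dict[str, int]
    min_per_group: int


def anova_presence_filter(
    table: FeatureTable, min_per_group: int = 2
) -> TestabilityReport:
    """Per-tissue testability of every metabolite for every genotype."""
    testable: dict[str, pd.DataFrame] = {}
    removed: dict[str, list[str]] = {}
    n_removed: dict[str, int] = {}
    present = table.values.notna()
    for tissue in sorted(table.meta["tissue"].unique()):
        rows_t = table.meta["tissue"] == tissue
        genos = sorted(table.meta.loc[rows_t, "genotype"].unique())
        mat = pd.DataFrame(False, index=genos, columns=table.features)
        for g in genos:
            ok = None
            for regime in sorted(table.meta["regime"].unique()):
                rows = rows_t & (table.meta["genotype"] == g) & (
                    table.meta["regime"] == regime
                )
                counts = present.loc[rows.to_numpy()].sum(axis=0)
                cond = counts >= min_per_group
                ok = cond if ok is None else (ok & cond)
            mat.loc[g] = ok.to_numpy()
        testable[tissue] = mat
        dropped = [f for f in table.features if not mat[f].any()]
        removed[tissue] = dropped
        n_removed[tissue] = len(dropped)
    return TestabilityReport(testable, removed, n_removed, min_per_group)


def run_qc(
    table: FeatureTable,
    blanks: pd.DataFrame | None = None,
    ratio_threshold: float = 0.5,
    min_present: int = 3,
    rule: OutlierRule = OutlierRule(),
) -> FeatureTable:
    """Apply the canonical filter order on raw abundances."""
    out = table
    if blanks is not None:
        out = remove_background(out, blanks, ratio_threshold)
    out = zeros_to_missing(out)
    out = presence_filter(out, min_present=min_present)
    out = flag_outliers(out, rule)
    return out


def filter_report(table: FeatureTable) -> list[dict]:
    """The provenance log of a filtered table (JSON-serializable)."""
    return list(table.log)
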