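"""Per-genotype drought-vs-control metabolite tests with Holm correction.

Each genotype x metabolite combination (within one tissue) gets a
two-group one-way ANOVA (pooled-variance F test, identical to the squared
two-sample t test) of drought against control on log2 abundances. The
Holm step-down adjustment is applied within each genotype x tissue family
of testable metabolites.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import TestabilityReport
from .tables import FeatureTable

ALPHA_DEFAULT = 0.01


@dataclass
class DifferentialResult:
    """Tidy per tissue x genotype x metabolite test results."""

    results: pd.DataFrame
    # columns: tissue, genotype, metabolite, lfc, p_value, p_holm,
    #          significant, testable
    alpha: float = ALPHA_DEFAULT


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm adjustment, original order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    mult = m - np.arange(m)
    # step-down: running maximum of p_(i) * (m - i + 1), capped at 1
    adj_sorted = np.maximum.accumulate(p[order] * mult)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_metabolites(
    table: FeatureTable,
    tissue: str,
    testability: TestabilityReport | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> DifferentialResult:
    """Drought-vs-control ANOVA per genotype per metabolite within a tissue.

    ``table`` must hold log2-transformed abundances. Untestable
    combinations (fewer than two values in either group, or zero pooled
    variance) are flagged, not errored. Holm families are per genotype.
    """
    rows_t = table.meta["tissue"] == tissue
    vals = table.values.loc[rows_t.to_numpy()]
    meta = table.meta.loc[rows_t.to_numpy()]
    feats = table.features
    frames = []
    for g in sorted(meta["genotype"].unique()):
        sub_c = vals[((meta["genotype"] == g) & (meta["regime"] == "control")).to_numpy()]
        sub_d = vals[((meta["genotype"] == g) & (meta["regime"] == "drought")).to_numpy()]
        xc = sub_c.to_numpy(dtype=float)
        xd = sub_d.to_numpy(dtype=float)
        n1 = (~np.isnan(xc)).sum(axis=0)
        n2 = (~np.isnan(xd)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            m1 = np.nanmean(np.where(np.isnan(xc), np.nan, xc), axis=0)
            m2 = np.nanmean(np.where(np.isnan(xd), np.nan, xd), axis=0)
            s1 = np.nansum((xc - m1) ** 2, axis=0)
            s2 = np.nansum((xd - m2) ** 2, axis=0)
        testable = (n1 >= 2) & (n2 >= 2)
        if testability is not None and tissue in testability.testable:
            mat = testability.testable[tissue]
            if g in mat.index:
                testable &= mat.loc[g].reindex(feats).fillna(False).to_numpy(dtype=bool)
        dof = n1 + n2 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = (s1 + s2) / np.where(dof > 0, dof, np.nan)
            fstat = (m2 - m1) ** 2 / (sp2 * (1.0 / n1 + 1.0 / n2))
        pvals = np.full(len(feats), np.nan)
        ok = testable & np.isfinite(fstat)
        pvals[ok] = stats.f.sf(fstat[ok], 1, dof[ok])
        # zero pooled variance with a nonzero difference: perfectly separated
        degen = testable & ~np.isfinite(fstat)
        zero_diff = degen & np.isclose(m2 - m1, 0.0)
        pvals[zero_diff] = 1.0
        testable = testable & (ok | zero_diff)
        p_holm = np.full(len(feats), np.nan)
        fam = np.where(testable)[0]
        if fam.size:
            p_holm[fam] = holm_adjust(pvals[fam])
        significant = np.zeros(len(feats), dtype=bool)
        significant[fam] = p_holm[fam] < alpha
        frames.append(
            pd.DataFrame(
                {
                    "tissue": tissue,
                    "genotype": g,
                    "metabolite": feats,
                    "lfc": m2 - m1,
                    "p_value": pvals,
                    "p_holm": p_holm,
                    "significant": significant,
                    "testable": testable,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return DifferentialResult(out, alpha=alpha)


def logfold_heatmap_matrix(
    diff: DifferentialResult,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Metabolite x genotype z-standardized log-fold matrix + significance mask.

    Rows (metabolites) are standardized across genotypes with the n-1 SD
    convention; zero-SD rows are set to zero and their ids returned as
    flagged.
    """
    res = diff.results
    if res["genotype"].nunique() < 2:
        raise ValueError("heatmap standardization needs >= 2 genotypes")
    lfc = res.pivot_table(index="metabolite", columns="genotype", values="lfc")
    sig = (
        res.pivot_table(
            index="metabolite", columns="genotype", values="significant", aggfunc="any"
        )
        .reindex(index=lfc.index, columns=lfc.columns)
        .fillna(False)
        .astype(bool)
    )
    mean = lfc.mean(axis=1)
    sd = lfc.std(axis=1, ddof=1)
    flagged = lfc.index[(sd == 0) | sd.isna()].tolist()
    z = lfc.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0)
    z.loc[flagged] = 0.0
    return z, sig, flagged


def count_significant(diff: DifferentialResult) -> pd.DataFrame:
    """Holm-significant metabolite counts per genotype and tissue."""
    res = diff.results
    counts = (
        res.groupby(["tissue", "genotype"], as_index=False)["significant"]
        .sum()
        .rename(columns={"significant": "n_significant"})
    )
    counts["n_significant"] = counts["n_significant"].astype(int)
    return counts
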