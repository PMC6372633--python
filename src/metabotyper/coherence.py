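"""Genotype-metabotype coherence: the bubble-plot contingency and the
fraction of genotypes whose replicates map to a single metabotype cluster.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CoherenceTable:
    """Genotype x cluster plant counts plus derived summaries."""

    counts: pd.DataFrame  # index = genotype, columns = cluster label
    occupied: pd.Series  # clusters occupied per genotype

    def tidy(self) -> pd.DataFrame:
        """Bubble-plot data: one row per (genotype, cluster) with n_plants > 0."""
        long = self.counts.stack().rename("n_plants").reset_index()
        long.columns = ["genotype", "cluster", "n_plants"]
        return long[long["n_plants"] > 0].reset_index(drop=True)


def build_coherence_table(cluster_labels, genotype_labels) -> CoherenceTable:
    """Exact contingency counts of plants per genotype per cluster."""
    cluster_labels = np.asarray(cluster_labels)
    genotype_labels = np.asarray(genotype_labels)
    if len(cluster_labels) != len(genotype_labels):
        raise ValueError("cluster and genotype label vectors must have equal length")
    counts = pd.crosstab(pd.Series(genotype_labels, name="genotype"),
                         pd.Series(cluster_labels, name="cluster"))
    occupied = (counts > 0).sum(axis=1)
    return CoherenceTable(counts, occupied)


def coherence_fraction(
    table: CoherenceTable, require_pure: bool = True
) -> tuple[float, list]:
    """Fraction of genotypes linked to a unique metabotype cluster.

    A genotype is coherent iff all its plants share one cluster and - with
    the default purity rule - no other genotype's plant occupies that
    cluster. ``require_pure=False`` gives the unanimity-only variant.
    """
    coherent = []
    col_sums = table.counts.sum(axis=0)
    for g in table.counts.index:
        row = table.counts.loc[g]
        nz = row[row > 0]
        if len(nz) != 1:
            continue
        cluster = nz.index[0]
        if require_pure and col_sums[cluster] != nz.iloc[0]:
            continue
        coherent.append(g)
    frac = len(coherent) / len(table.counts.index) if len(table.counts.index) else 0.0
    return float(frac), coherent
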