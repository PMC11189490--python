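"""Cluster-composition enrichment and gene-set comparison statistics.

Under the null that injury does not change a cluster's relative abundance,
the number of TBI cells in a cluster of size n is Binomial(n, p0), where p0
is the TBI share of the whole analysed cell set.  Each cluster is scored
with an exact two-sided binomial test (minimum-likelihood two-sidedness,
the convention of R's binom.test); no multiple-testing correction is
applied, matching how such abundance panels are conventionally reported.

Also provided: percentage overlap matrices between two sets of population
marker genes, pairwise common-gene count matrices for cross-study
comparison (input to standard agglomerative clustering), and
case-insensitive keyword filtering of pathway/GO term tables.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Conventional keyword panel for nervous-system / injury-related terms.
DEFAULT_KEYWORDS: tuple[str, ...] = (
    "Synapse", "Axon", "Neuron", "Nervous", "Glia", "Astrocyte", "Microglia",
    "Injury", "Growth", "Tnf", "Neuro", "Age", "Myelin", "Sheath", "Reactive",
    "Ion", "Proliferation", "Genesis", "Development", "Morphology",
    "Formation", "Circuit", "Axonogenesis",
)


def expected_fraction(cell_meta: pd.DataFrame, tbi_label: str = "TBI") -> float:
    """TBI share p0 of the analysed cell set.

    p0 = (# TBI cells) / (# all cells); both conditions must be present
    so that p0 is strictly inside (0, 1).
    """
    cond = cell_meta["condition"]
    n = len(cond)
    k = int((cond == tbi_label).sum())
    if k == 0 or k == n:
        raise ValueError("both conditions must be represented to define p0")
    return k / n


def binomial_enrichment(
    table: pd.DataFrame,
    p0: float,
    tbi_col: str = "cells_tbi",
    control_col: str = "cells_control",
) -> pd.DataFrame:
    """Exact two-sided binomial test of TBI abundance per cluster.

    For each cluster, k = cells_tbi out of n = cells_control + cells_tbi is
    tested against Binomial(n, p0) using the minimum-likelihood two-sided
    p-value (sum of P(X=k') over all k' with P(X=k') <= P(X=k)), i.e. the
    default of R's binom.test / scipy's binomtest.  Empty clusters are
    reported not-testable (p = NaN) rather than raised.
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly inside (0, 1)")
    if (table[[tbi_col, control_col]] < 0).any().any():
        raise ValueError("cell counts must be nonnegative")
    recs = []
    for _, row in table.iterrows():
        k = int(row[tbi_col])
        n = k + int(row[control_col])
        rec = dict(row)
        if n == 0:
            rec.update(n=0, observed_tbi_fraction=float("nan"),
                       p_value=float("nan"), direction="not-testable")
        else:
            frac = k / n
            p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
            rec.update(
                n=n,
                observed_tbi_fraction=frac,
                p_value=float(p),
                direction=(
                    "enriched" if frac > p0 else ("depleted" if frac < p0 else "none")
                ),
            )
        recs.append(rec)
    out = pd.DataFrame(recs)
    if (table[[tbi_col, control_col]].sum(axis=1) == 0).all():
        raise ValueError("at least one cluster must be nonempty")
    return out


def composition_table(
    cell_meta: pd.DataFrame,
    cluster_col: str = "population",
    tbi_label: str = "TBI",
) -> pd.DataFrame:
    """Per-cluster Control/TBI cell counts from tidy cell metadata."""
    tab = (
        cell_meta.assign(_is_tbi=cell_meta["condition"] == tbi_label)
        .groupby(cluster_col)["_is_tbi"]
        .agg(cells_tbi="sum", n="count")
        .reset_index()
        .rename(columns={cluster_col: "cluster"})
    )
    tab["cells_control"] = tab["n"] - tab["cells_tbi"]
    return tab[["cluster", "cells_control", "cells_tbi"]]


def overlap_matrix(
    marker_sets_a: Mapping[str, Iterable[str]],
    marker_sets_b: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Percentage of each A-population's genes found in each B-population.

    Entry (a, b) = 100 * |A_a intersect B_b| / |A_a|; rows with an empty
    A-set are NaN (undefined, flagged rather than raised).
    """
    rows = {}
    for a, genes_a in marker_sets_a.items():
        sa = set(genes_a)
        if not sa:
            rows[a] = {b: float("nan") for b in marker_sets_b}
            continue
        rows[a] = {
            b: 100.0 * len(sa & set(genes_b)) / len(sa)
            for b, genes_b in marker_sets_b.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def similarity_counts(
    gene_lists: Mapping[str, Iterable[str]] | Sequence[tuple[str, Iterable[str]]],
) -> pd.DataFrame:
    """Symmetric matrix of pairwise common-gene counts between populations.

    The diagonal holds each set's own size.  Suitable as a similarity input
    to standard agglomerative clustering (e.g. scipy's linkage + cut at
    k = 3 groups).  Duplicate population names are rejected.
    """
    if not isinstance(gene_lists, Mapping):
        names = [n for n, _ in gene_lists]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        gene_lists = dict(gene_lists)
    if len(gene_lists) < 2:
        raise ValueError("need at least 2 populations")
    names = list(gene_lists)
    sets = {n: set(g) for n, g in gene_lists.items()}
    mat = np.zeros((len(names), len(names)), dtype=int)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            mat[i, j] = len(sets[a] & sets[b])
    return pd.DataFrame(mat, index=names, columns=names)


def keyword_filter(
    term_table: pd.DataFrame,
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    description_col: str = "description",
) -> pd.DataFrame:
    """Retain term rows whose description matches any keyword.

    Matching is case-insensitive substring (GO/KEGG descriptions capitalise
    inconsistently).  An empty keyword list is the identity, returning the
    unbiased table unchanged.
    """
    if len(keywords) == 0:
        return term_table.copy()
    desc = term_table[description_col].astype(str).str.lower()
    mask = np.zeros(len(term_table), dtype=bool)
    for kw in keywords:
        mask |= desc.str.contains(kw.lower(), regex=False).to_numpy()
    return term_table.loc[mask].copy()
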