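"""Embedding transition probabilities and per-population fate statistics.

Given the "current" (pooled spliced) and "deltaE" (extrapolated change)
matrices of a steady-state velocity fit, each cell's likely movement in the
2-D embedding is scored against its n nearest embedding neighbours: the
velocity-correlation matrix cc holds the Pearson correlation (across genes,
optionally after a signed-sqrt variance-stabilising transform) between the
expression displacement toward a neighbour and the cell's own predicted
change, and an exponential kernel exp(cc/sigma), row-normalised, turns cc
into a row-stochastic transition-probability matrix tp.

Per-population fate readouts sum each source cell's tp mass over the
neighbours belonging to every target population; mass directed at the
cell's own population is its (population-level) self-renewal.  Control vs
TBI distributions of these per-cell masses are compared by a two-sided
Wilcoxon rank-sum test, exact below a configurable sample size and
normal-approximated (with midrank tie correction and continuity correction)
above it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors


def signed_sqrt(x: np.ndarray) -> np.ndarray:
    """Elementwise sign(x) * sqrt(|x|)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.sqrt(np.abs(x))


def choose_neighborhood(labels: np.ndarray, population: str, minimum: int = 300) -> int:
    """Neighbourhood size for one source population.

    n = max(minimum, population size), capped at n_cells - 1 (a cell cannot
    neighbour itself).
    """
    labels = np.asarray(labels)
    n_cells = labels.size
    if n_cells <= 1:
        raise ValueError("need at least 2 cells to define neighbourhoods")
    size = int((labels == population).sum())
    return min(max(minimum, size), n_cells - 1)


def build_neighbor_index(embedding: np.ndarray, n: int) -> np.ndarray:
    """Indices of each cell's n nearest embedding neighbours, self excluded,
    ordered by increasing Euclidean distance (cells x n)."""
    emb = np.asarray(embedding, dtype=float)
    if n >= emb.shape[0]:
        raise ValueError("n must be < number of cells")
    nn = NearestNeighbors(n_neighbors=n + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    return idx[:, 1:]


def velocity_correlation(
    current: np.ndarray,
    delta_e: np.ndarray,
    neighbor_idx: np.ndarray,
    scale: str = "sqrt",
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """Velocity-correlation entries cc[i, j] for neighbour pairs.

    cc[i, j] is the Pearson correlation across genes between
    transform(current[:, j] - current[:, i]) and transform(deltaE[:, i]),
    with transform = signed sqrt ("sqrt") or identity ("none").  Undefined
    correlations (zero variance on either side) are set to 0.  ``rows``
    restricts computation to those source cells; the result is aligned with
    ``neighbor_idx[rows]``.
    """
    if scale not in ("none", "sqrt"):
        raise ValueError(f"unknown scale {scale!r}")
    if rows is None:
        rows = np.arange(neighbor_idx.shape[0])
    rows = np.asarray(rows)
    n_nbrs = neighbor_idx.shape[1]
    if n_nbrs == 0:
        raise ValueError("empty neighbour sets")
    cc = np.zeros((rows.size, n_nbrs))
    for out, i in enumerate(rows):
        nbrs = neighbor_idx[i]
        D = current[:, nbrs] - current[:, [i]]
        v = delta_e[:, i]
        if scale == "sqrt":
            D = signed_sqrt(D)
            v = signed_sqrt(v)
        Dc = D - D.mean(axis=0, keepdims=True)
        vc = v - v.mean()
        dn = np.sqrt((Dc * Dc).sum(axis=0))
        vn = math.sqrt(float(vc @ vc))
        denom = dn * vn
        ok = denom > 0
        cc[out, ok] = (Dc[:, ok].T @ vc) / denom[ok]
    return np.clip(cc, -1.0, 1.0)


def transition_probabilities(cc: np.ndarray, sigma: float = 0.05) -> np.ndarray:
    """Row-stochastic kernel tp[i, j] = softmax_j(cc[i, j] / sigma).

    Computed with a per-row max shift for numerical stability; rows of the
    returned array sum to 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    z = cc / sigma
    z = z - z.max(axis=1, keepdims=True)
    w = np.exp(z)
    return w / w.sum(axis=1, keepdims=True)


def population_mass(
    tp: np.ndarray,
    neighbor_idx: np.ndarray,
    labels: np.ndarray,
    rows: np.ndarray | None = None,
    per_neighbor_mean: bool = False,
) -> pd.DataFrame:
    """Per source cell, transition mass to each target population.

    m_i(P) = sum of tp[i, j] over neighbours j with label P (default), or
    the mean of those per-neighbour probabilities when
    ``per_neighbor_mean`` is set.  In the default (sum) reading the masses
    partition each row: sum_P m_i(P) = 1.  Returns a cells x populations
    frame (columns sorted by population label).
    """
    labels = np.asarray(labels)
    if pd.isna(labels).any():
        raise ValueError("every cell must carry a population label")
    if rows is None:
        rows = np.arange(neighbor_idx.shape[0])
    rows = np.asarray(rows)
    pops = np.unique(labels)
    code = {p: k for k, p in enumerate(pops)}
    codes = np.array([code[p] for p in labels])
    nbr_codes = codes[neighbor_idx[rows]]  # (n_rows, n_nbrs)
    out = np.zeros((rows.size, pops.size))
    for k in range(pops.size):
        sel = nbr_codes == k
        masked = np.where(sel, tp, 0.0)
        if per_neighbor_mean:
            counts = sel.sum(axis=1)
            with np.errstate(invalid="ignore"):
                out[:, k] = np.where(counts > 0, masked.sum(axis=1) / counts, 0.0)
        else:
            out[:, k] = masked.sum(axis=1)
    return pd.DataFrame(out, columns=list(pops))


@dataclass(frozen=True)
class TransitionConfig:
    """Knobs of the transition-probability analysis.

    sigma : exponential-kernel bandwidth on the velocity correlation.
    min_neighborhood : floor on the per-population neighbourhood size.
    scale : "sqrt" (signed square root, variance stabilising) or "none".
    exclude_populations : labels removed from the model entirely (terminal
        populations outside the NSC-derived lineage in the original use).
    per_neighbor_mean : report the mean per-neighbour probability instead
        of the summed mass (alternative reading; default off).
    """

    sigma: float = 0.05
    min_neighborhood: int = 300
    scale: str = "sqrt"
    exclude_populations: tuple[str, ...] = ()
    per_neighbor_mean: bool = False


@dataclass
class TransitionModel:
    """Per-population transition model for one condition."""

    neighbor_idx: np.ndarray
    n_by_population: dict[str, int]
    cc_by_population: dict[str, np.ndarray]
    tp_by_population: dict[str, np.ndarray]
    rows_by_population: dict[str, np.ndarray]
    config: TransitionConfig


def fit_transition_model(
    embedding: np.ndarray,
    labels: np.ndarray,
    current: np.ndarray,
    delta_e: np.ndarray,
    config: TransitionConfig | None = None,
) -> TransitionModel:
    """Build cc and tp per source population.

    The neighbourhood size follows max(min_neighborhood, population size),
    capped at n_cells - 1, per source population; a single kNN query at the
    largest size is sliced per population (neighbours are distance-ordered,
    so the first n are the n nearest).
    """
    if config is None:
        config = TransitionConfig()
    labels = np.asarray(labels)
    pops = [p for p in np.unique(labels) if p not in config.exclude_populations]
    n_by_pop = {p: choose_neighborhood(labels, p, config.min_neighborhood) for p in pops}
    n_max = max(n_by_pop.values())
    idx = build_neighbor_index(embedding, n_max)
    cc_by, tp_by, rows_by = {}, {}, {}
    for p in pops:
        rows = np.flatnonzero(labels == p)
        n_p = n_by_pop[p]
        cc = velocity_correlation(
            current, delta_e, idx[:, :n_p], scale=config.scale, rows=rows
        )
        cc_by[p] = cc
        tp_by[p] = transition_probabilities(cc, config.sigma)
        rows_by[p] = rows
    return TransitionModel(
        neighbor_idx=idx,
        n_by_population=n_by_pop,
        cc_by_population=cc_by,
        tp_by_population=tp_by,
        rows_by_population=rows_by,
        config=config,
    )


def population_transition_summary(
    embedding: np.ndarray,
    labels: np.ndarray,
    current: np.ndarray,
    delta_e: np.ndarray,
    condition: str,
    cell_ids: np.ndarray | None = None,
    config: TransitionConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-cell transition masses for one condition.

    Returns one row per (source cell, target population) with columns
    cell_id, source, target, condition, mass.  Cells of excluded
    populations contribute neither as sources nor as targets.
    """
    if config is None:
        config = TransitionConfig()
    labels = np.asarray(labels)
    if config.exclude_populations:
        keep = ~np.isin(labels, config.exclude_populations)
        labels = labels[keep]
        embedding = np.asarray(embedding)[keep]
        current = current[:, keep]
        delta_e = delta_e[:, keep]
        if cell_ids is not None:
            cell_ids = np.asarray(cell_ids)[keep]
    if cell_ids is None:
        cell_ids = np.array([f"c{i}" for i in range(labels.size)], dtype=object)
    inner = TransitionConfig(**{**config.__dict__, "exclude_populations": ()})
    model = fit_transition_model(embedding, labels, current, delta_e, inner)
    frames = []
    for p, rows in model.rows_by_population.items():
        n_p = model.n_by_population[p]
        masses = population_mass(
            model.tp_by_population[p],
            model.neighbor_idx[:, :n_p],
            labels,
            rows=rows,
            per_neighbor_mean=config.per_neighbor_mean,
        )
        masses.insert(0, "cell_id", np.asarray(cell_ids)[rows])
        tidy = masses.melt(id_vars="cell_id", var_name="target", value_name="mass")
        tidy.insert(1, "source", p)
        tidy.insert(3, "condition", condition)
        frames.append(tidy)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _exact_ranksum_p(ranks_x: np.ndarray, ranks_all: np.ndarray) -> float:
    """Exact two-sided p for the rank-sum statistic under random assignment.

    Midranks are doubled to integers; a subset-count dynamic programme over
    the pooled doubled ranks gives the null distribution of the sum of the
    x-group's ranks.  Two-sided p = P(|T - E| >= |t_obs - E|).
    """
    dr = np.rint(2 * ranks_all).astype(np.int64)
    n1 = ranks_x.size
    t_obs = int(np.rint(2 * ranks_x.sum()))
    total = int(dr.sum())
    # f[k, s] = number of k-subsets of the pooled ranks with doubled sum s;
    # 0/1-knapsack update, k descending so each item is used at most once
    f = np.zeros((n1 + 1, total + 1))
    f[0, 0] = 1.0
    for r in dr:
        r = int(r)
        for k in range(n1, 0, -1):
            f[k, r:] += f[k - 1, : total + 1 - r]
    mean2 = n1 * total / dr.size
    dev = abs(t_obs - mean2)
    sums = np.arange(total + 1)
    tail = np.abs(sums - mean2) >= dev - 1e-9
    return float(f[n1, tail].sum() / f[n1].sum())


def wilcoxon_rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    mode: str = "auto",
    exact_limit: int = 20,
) -> tuple[float, float]:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum test.

    Ranks use midranks for ties.  ``mode`` is "exact" (full null
    distribution of the rank sum over assignments, exact also under ties),
    "normal" (tie- and continuity-corrected normal approximation) or "auto"
    (exact when n_x + n_y <= exact_limit).  Returns (U statistic of x,
    two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rx = ranks[:n1]
    w = rx.sum()
    u = w - n1 * (n1 + 1) / 2.0

    if mode == "auto":
        mode = "exact" if n1 + n2 <= exact_limit else "normal"
    if mode == "exact":
        p = _exact_ranksum_p(rx, ranks)
    elif mode == "normal":
        mu = n1 * n2 / 2.0
        nt = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (nt * (nt - 1))
        var = n1 * n2 / 12.0 * ((nt + 1) - tie_term)
        if var <= 0:
            return float(u), 1.0
        diff = u - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(u), float(p)


def compare_conditions(
    summary: pd.DataFrame,
    conditions: tuple[str, str] = ("Control", "TBI"),
    min_cells: int = 2,
    exact_limit: int = 20,
) -> pd.DataFrame:
    """Control-vs-TBI Wilcoxon comparison of per-cell transition masses.

    One row per (source, target) pair with the U statistic, two-sided p,
    per-condition cell counts, medians, quartiles and data extremes
    (box-plot summaries with whiskers at the minima/maxima), the direction
    of the TBI shift, and a Benjamini-Hochberg-adjusted p column (reported
    for transparency; the primary readout is the raw p).  Pairs with fewer
    than ``min_cells`` source cells in either condition are flagged
    not-comparable (p = NaN), not raised.
    """
    ca, cb = conditions
    rows = []
    for (src, tgt), grp in summary.groupby(["source", "target"], sort=True):
        xa = grp.loc[grp["condition"] == ca, "mass"].to_numpy()
        xb = grp.loc[grp["condition"] == cb, "mass"].to_numpy()
        rec: dict = {
            "source": src,
            "target": tgt,
            f"n_{ca}": xa.size,
            f"n_{cb}": xb.size,
        }
        for name, v in ((ca, xa), (cb, xb)):
            if v.size:
                rec[f"median_{name}"] = float(np.median(v))
                rec[f"q1_{name}"] = float(np.quantile(v, 0.25))
                rec[f"q3_{name}"] = float(np.quantile(v, 0.75))
                rec[f"min_{name}"] = float(v.min())
                rec[f"max_{name}"] = float(v.max())
            else:
                for stat_name in ("median", "q1", "q3", "min", "max"):
                    rec[f"{stat_name}_{name}"] = float("nan")
        if xa.size < min_cells or xb.size < min_cells:
            rec.update(comparable=False, statistic=float("nan"), p_value=float("nan"),
                       direction="not-comparable")
        else:
            u, p = wilcoxon_rank_sum(xa, xb, mode="auto", exact_limit=exact_limit)
            delta = float(np.mean(xb) - np.mean(xa))
            rec.update(
                comparable=True,
                statistic=u,
                p_value=p,
                direction="up" if delta > 0 else ("down" if delta < 0 else "none"),
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    mask = out["comparable"] & out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if mask.any():
        from statsmodels.stats.multitest import multipletests

        adj[mask.to_numpy()] = multipletests(
            out.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["p_adj_bh"] = adj
    return out
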