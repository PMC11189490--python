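"""Steady-state RNA velocity estimation.

The steady-state model assumes du/dt = alpha - beta*u, ds/dt = beta*u -
gamma*s, so cells at transcriptional steady state satisfy u = (gamma/beta)*s.
Per gene, the degradation-to-splicing ratio gamma is fitted as the
origin-constrained least-squares slope of unspliced on spliced over the
cells at extreme (bottom/top quantile) spliced expression, which are assumed
nearest steady state.  The residual u - gamma*s is the velocity: positive
where unspliced abundance exceeds its steady-state expectation (expression
rising), negative where it falls short.

The workflow is: kNN pooling of raw counts in PC space (kCells = 20),
gene filtering on mean pooled spliced expression (spliced.average = 0.5,
with Malat1 excluded by convention), extreme-quantile gamma fit
(fit.quantile = 0.02), then the "current" (pooled spliced) and "deltaE"
(delta_t * velocity) matrices consumed by the transition analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .synthetic import SplicedUnsplicedDataset


class EmptyGenePanelError(ValueError):
    """Raised when the expression filter removes every gene."""


@dataclass(frozen=True)
class VelocityConfig:
    """Parameters of the steady-state velocity fit.

    k_cells : pooling neighbourhood size (self included).
    fit_quantile : fraction defining each extreme tail of pooled spliced
        expression used for the gamma fit.
    spliced_average_min : minimum mean pooled spliced expression for a gene
        to enter the fit.
    delta_t : extrapolation horizon multiplying the velocity into deltaE.
    excluded_genes : identifiers dropped regardless of expression (Malat1
        by default: its dominant read pileup distorts the fit).
    n_pcs : dimensionality of the PC space in which pooling neighbours are
        found (log1p library-normalised spliced counts).
    fit_intercept : allow an intercept in the gamma fit instead of forcing
        the line through the origin.
    """

    k_cells: int = 20
    fit_quantile: float = 0.02
    spliced_average_min: float = 0.5
    delta_t: float = 1.0
    excluded_genes: tuple[str, ...] = ("Malat1",)
    n_pcs: int = 30
    fit_intercept: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fit_quantile < 0.5:
            raise ValueError("fit_quantile must be in (0, 0.5)")
        if self.k_cells < 1:
            raise ValueError("k_cells must be >= 1")
        if self.spliced_average_min < 0:
            raise ValueError("spliced_average_min must be >= 0")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be > 0")


@dataclass
class VelocityResult:
    """Fitted velocity model over the kept gene panel.

    ``current`` is the pooled spliced matrix and ``delta_e`` the scaled
    residual velocity, both restricted to ``kept_genes``; ``extrapolated``
    is max(current + delta_e, 0).
    """

    pooled_spliced: np.ndarray
    pooled_unspliced: np.ndarray
    gamma_hat: np.ndarray
    velocity: np.ndarray
    current: np.ndarray
    delta_e: np.ndarray
    extrapolated: np.ndarray
    kept_genes: np.ndarray
    dropped_degenerate: np.ndarray
    config: VelocityConfig


def pool_neighbors(
    dataset: SplicedUnsplicedDataset, k_cells: int, n_pcs: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Average raw profiles over each cell's k nearest neighbours (self included).

    Neighbours are found by Euclidean distance in the top principal
    components of log1p library-size-normalised spliced counts.  With
    k_cells = 1 pooling is the identity.
    """
    n_cells = dataset.n_cells
    if k_cells > n_cells:
        raise ValueError(f"k_cells={k_cells} exceeds the number of cells ({n_cells})")
    if k_cells == 1:
        return dataset.spliced.astype(float), dataset.unspliced.astype(float)

    S = dataset.spliced.astype(float)
    totals = S.sum(axis=0)
    totals[totals == 0] = 1.0
    norm = S / totals * np.median(totals)
    X = np.log1p(norm.T)
    n_comp = min(n_pcs, n_cells - 1, dataset.n_genes)
    if n_comp >= 1:
        X = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    nn = NearestNeighbors(n_neighbors=k_cells).fit(X)
    _, idx = nn.kneighbors(X)
    pooled_s = S[:, idx].mean(axis=2)
    pooled_u = dataset.unspliced.astype(float)[:, idx].mean(axis=2)
    return pooled_s, pooled_u


def filter_genes(
    pooled_spliced: np.ndarray,
    gene_ids: np.ndarray,
    spliced_average_min: float = 0.5,
    excluded_genes: tuple[str, ...] = ("Malat1",),
) -> np.ndarray:
    """Boolean mask of genes passing the mean-expression filter.

    Keeps genes whose mean pooled spliced expression is >= the threshold
    and whose identifier is not excluded.  Raises
    :class:`EmptyGenePanelError` if nothing survives.
    """
    means = pooled_spliced.mean(axis=1)
    keep = means >= spliced_average_min
    if len(excluded_genes):
        keep &= ~np.isin(np.asarray(gene_ids), np.asarray(excluded_genes))
    if not keep.any():
        raise EmptyGenePanelError(
            "every gene fell below spliced_average_min or was excluded"
        )
    return keep


def _extreme_mask(s: np.ndarray, fit_quantile: float) -> np.ndarray:
    """Cells in the bottom or top ``fit_quantile`` of spliced expression.

    Tied values at either boundary are all included, so membership does not
    depend on cell ordering.
    """
    lo = np.quantile(s, fit_quantile)
    hi = np.quantile(s, 1.0 - fit_quantile)
    return (s <= lo) | (s >= hi)


def fit_gamma(
    pooled_spliced_g: np.ndarray,
    pooled_unspliced_g: np.ndarray,
    fit_quantile: float = 0.02,
    fit_intercept: bool = False,
) -> float:
    """Extreme-quantile steady-state slope for one gene.

    gamma_hat = sum(u*s) / sum(s^2) over the extreme cells (least squares
    through the origin); NaN when the extreme set carries no spliced signal
    (undefined slope — caller flags and excludes the gene).
    """
    s = np.asarray(pooled_spliced_g, dtype=float)
    u = np.asarray(pooled_unspliced_g, dtype=float)
    mask = _extreme_mask(s, fit_quantile)
    if mask.sum() < 2:
        return float("nan")
    se, ue = s[mask], u[mask]
    if fit_intercept:
        A = np.c_[se, np.ones_like(se)]
        denom = np.linalg.det(A.T @ A)
        if denom == 0:
            return float("nan")
        slope, _ = np.linalg.lstsq(A, ue, rcond=None)[0]
        return float(slope)
    denom = float((se * se).sum())
    if denom == 0.0:
        return float("nan")
    return float((ue * se).sum() / denom)


def estimate_velocity(
    dataset: SplicedUnsplicedDataset, config: VelocityConfig | None = None
) -> VelocityResult:
    """Full steady-state velocity fit: pool, filter, fit gamma, extrapolate.

    Genes whose gamma is undefined (no spliced signal on the extreme set)
    or non-positive are dropped from the kept panel and recorded in
    ``dropped_degenerate``.
    """
    if config is None:
        config = VelocityConfig()
    pooled_s, pooled_u = pool_neighbors(dataset, config.k_cells, config.n_pcs)
    keep = filter_genes(
        pooled_s,
        dataset.gene_ids,
        config.spliced_average_min,
        config.excluded_genes,
    )
    kept_idx = np.flatnonzero(keep)
    gammas = np.array(
        [
            fit_gamma(pooled_s[g], pooled_u[g], config.fit_quantile, config.fit_intercept)
            for g in kept_idx
        ]
    )
    good = np.isfinite(gammas) & (gammas > 0)
    dropped = dataset.gene_ids[kept_idx[~good]]
    kept_idx = kept_idx[good]
    gammas = gammas[good]
    if kept_idx.size == 0:
        raise EmptyGenePanelError("no gene yielded a defined positive gamma")

    current = pooled_s[kept_idx]
    velocity = pooled_u[kept_idx] - gammas[:, None] * current
    delta_e = config.delta_t * velocity
    extrapolated = np.maximum(current + delta_e, 0.0)
    return VelocityResult(
        pooled_spliced=pooled_s,
        pooled_unspliced=pooled_u,
        gamma_hat=gammas,
        velocity=velocity,
        current=current,
        delta_e=delta_e,
        extrapolated=extrapolated,
        kept_genes=dataset.gene_ids[kept_idx],
        dropped_degenerate=dropped,
        config=config,
    )
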