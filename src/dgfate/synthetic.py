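"""Synthetic branching-lineage data generator.

Emulates the statistical structure of a dentate-gyrus neural-stem-cell (NSC)
dataset: a trunk of NSC populations feeding, through a radial-glia-like
(RG-like) bipotent state, a neuronal and an astrocytic branch.  Two
experimental conditions (Control, TBI) may differ in the probability that a
post-branch cell commits to the neuronal arm (the *fate bias*) and in
per-population abundance.  Per-gene expression follows the standard splicing
kinetics model

    du/dt = alpha - beta * u        (unspliced)
    ds/dt = beta * u - gamma * s    (spliced)

with a transcription rate ``alpha`` that switches at lineage-segment
boundaries while (u, s) are carried continuously across them; this produces
the induction / repression phases that an extreme-quantile steady-state fit
requires.  Counts are Poisson (optionally negative-binomial) draws from the
kinetic means after per-cell capture-efficiency scaling.

A companion generator produces 1-D spatial offsets for a layered
dentate-gyrus-like geometry (hilus / SGZ / granule-cell layer / molecular
layer), expressed in nucleus-width units relative to the GCL–hilus boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


class DegenerateRatesError(ValueError):
    """Raised when gamma == beta, where the analytic spliced solution is singular."""


# ---------------------------------------------------------------------------
# Kinetic gene programs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticGeneProgram:
    """One gene's transcription/splicing/degradation rates.

    Parameters
    ----------
    gene_id
        Gene identifier.
    alpha_by_segment
        Transcription rate (molecules per unit time) for each lineage
        segment label.
    beta
        Splicing rate (1 / unit time).  Normalised to 1 by default across
        the package so that ``gamma`` is directly the degradation-to-splicing
        ratio recovered by the steady-state fit.
    gamma
        Degradation rate (1 / unit time).
    """

    gene_id: str
    alpha_by_segment: Mapping[str, float]
    beta: float = 1.0
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError(f"{self.gene_id}: beta must be > 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"{self.gene_id}: gamma must be > 0, got {self.gamma}")
        if abs(self.gamma - self.beta) <= 1e-12 * max(self.gamma, self.beta):
            raise DegenerateRatesError(
                f"{self.gene_id}: gamma == beta ({self.gamma}) is degenerate; "
                "the spliced solution requires gamma != beta"
            )
        for seg, a in self.alpha_by_segment.items():
            if a < 0:
                raise ValueError(f"{self.gene_id}: alpha[{seg}] must be >= 0, got {a}")


def _kinetics(alpha, beta, gamma, u0, s0, tau):
    """Vectorised analytic solution of the splicing ODE at elapsed time tau."""
    eb = np.exp(-beta * tau)
    eg = np.exp(-gamma * tau)
    u = alpha / beta + (u0 - alpha / beta) * eb
    s = (
        s0 * eg
        + (alpha / gamma) * (1.0 - eg)
        + ((alpha - beta * u0) / (gamma - beta)) * (eg - eb)
    )
    return np.clip(u, 0.0, None), np.clip(s, 0.0, None)


def solve_kinetics(
    program: KineticGeneProgram,
    u0: float,
    s0: float,
    alpha: float,
    tau: float,
) -> tuple[float, float]:
    """Evaluate the splicing-kinetics ODE analytically at elapsed time ``tau``.

    Solves du/dt = alpha - beta*u, ds/dt = beta*u - gamma*s from the initial
    condition (u0, s0), for the transcription rate ``alpha`` (the program's
    per-segment alphas are resolved by the simulator; this primitive takes
    the active rate explicitly).  Results are clipped at zero against
    floating-point underflow.

    Raises
    ------
    DegenerateRatesError
        If the program has gamma == beta (checked at construction).
    ValueError
        If tau, alpha, u0 or s0 is negative.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    if alpha < 0 or u0 < 0 or s0 < 0:
        raise ValueError("alpha, u0 and s0 must be >= 0")
    u, s = _kinetics(alpha, program.beta, program.gamma, u0, s0, tau)
    return float(u), float(s)


# ---------------------------------------------------------------------------
# Lineage and noise specification
# ---------------------------------------------------------------------------

#: Default condition labels used throughout the package.
CONTROL = "Control"
TBI = "TBI"


@dataclass(frozen=True)
class LineageSpec:
    """A branching NSC lineage: trunk segments followed by a fate split.

    The trunk runs ``segments[0] -> ... -> segments[-1]``; the last trunk
    segment (``branch_point``) splits into a neuronal and an astrocytic arm.
    Each cell draws its branch with probability ``fate_bias_by_condition``
    of taking the neuronal arm, then lands uniformly in one segment of its
    path with a uniform latent time inside that segment.
    """

    segments: tuple[str, ...] = ("NSC-stage1", "NSC-stage2", "RG-like")
    neuronal_branch: tuple[str, ...] = ("N-stage1", "N-stage2")
    astrocytic_branch: tuple[str, ...] = ("A-stage1", "A-stage2")
    fate_bias_by_condition: Mapping[str, float] = field(
        default_factory=lambda: {CONTROL: 0.5, TBI: 0.75}
    )
    cells_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {CONTROL: 6000, TBI: 6000}
    )
    animals_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {CONTROL: 5, TBI: 6}
    )
    segment_duration: float = 3.0
    time_grid: int | None = None  # discrete latent-time samples per segment; None = continuous

    def __post_init__(self) -> None:
        labels = list(self.segments) + list(self.neuronal_branch) + list(self.astrocytic_branch)
        if len(set(labels)) != len(labels):
            raise ValueError("segment labels must be unique")
        if not self.segments:
            raise ValueError("lineage needs at least one trunk segment")
        if not self.neuronal_branch or not self.astrocytic_branch:
            raise ValueError("both branches need at least one segment")
        for cond, b in self.fate_bias_by_condition.items():
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"fate bias for {cond} outside [0, 1]: {b}")
        for cond, n in self.cells_per_condition.items():
            if n < 1:
                raise ValueError(f"cells_per_condition[{cond}] must be >= 1")
        if self.segment_duration <= 0:
            raise ValueError("segment_duration must be > 0")

    @property
    def branch_point(self) -> str:
        return self.segments[-1]

    @property
    def all_populations(self) -> tuple[str, ...]:
        return tuple(self.segments) + tuple(self.neuronal_branch) + tuple(self.astrocytic_branch)

    def path(self, neuronal: bool) -> tuple[str, ...]:
        arm = self.neuronal_branch if neuronal else self.astrocytic_branch
        return tuple(self.segments) + tuple(arm)


@dataclass(frozen=True)
class NoiseConfig:
    """Count-noise model applied to kinetic means.

    ``model``: "poisson" (default), "negative_binomial", or "none" (matrices
    then hold the continuous kinetic means — used for noiseless oracles).
    ``capture_sigma``: SD of the per-cell log-normal capture efficiency
    LogNormal(0, capture_sigma^2).  ``target_counts_per_cell`` rescales all
    kinetic means so that the mean total spliced count per cell hits this
    depth (None disables rescaling).  ``nb_dispersion`` is the
    negative-binomial shape theta (variance = m + m^2/theta).
    """

    model: str = "poisson"
    capture_sigma: float = 0.3
    target_counts_per_cell: float | None = 3000.0
    nb_dispersion: float = 10.0

    def __post_init__(self) -> None:
        if self.model not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise model: {self.model!r}")
        if self.capture_sigma < 0:
            raise ValueError("capture_sigma must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")


@dataclass
class SplicedUnsplicedDataset:
    """Paired spliced/unspliced matrices with cell metadata and a 2-D embedding.

    ``spliced`` and ``unspliced`` are genes x cells arrays (integer counts,
    or continuous means when generated with noise model "none").
    ``cell_meta`` has one row per cell with columns ``cell_id``,
    ``condition``, ``population``, ``animal`` and (simulation only)
    ``latent_time``.  ``embedding`` is cells x 2.
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    cell_meta: pd.DataFrame
    embedding: np.ndarray
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        n_genes, n_cells = self.spliced.shape
        if self.unspliced.shape != (n_genes, n_cells):
            raise ValueError("spliced and unspliced dimensions disagree")
        if len(self.cell_meta) != n_cells:
            raise ValueError("cell_meta length does not match matrix columns")
        if self.embedding.shape != (n_cells, 2):
            raise ValueError("embedding must be cells x 2")
        if len(self.gene_meta) != n_genes:
            raise ValueError("gene_meta length does not match matrix rows")
        if (self.spliced < 0).any() or (self.unspliced < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_meta["gene_id"].to_numpy()

    def subset_condition(self, condition: str) -> "SplicedUnsplicedDataset":
        """Return the cells of one condition (velocity is fitted per condition)."""
        mask = (self.cell_meta["condition"] == condition).to_numpy()
        if not mask.any():
            raise ValueError(f"no cells with condition {condition!r}")
        return SplicedUnsplicedDataset(
            spliced=self.spliced[:, mask],
            unspliced=self.unspliced[:, mask],
            cell_meta=self.cell_meta.loc[mask].reset_index(drop=True),
            embedding=self.embedding[mask],
            gene_meta=self.gene_meta,
        )


# ---------------------------------------------------------------------------
# Gene-program construction
# ---------------------------------------------------------------------------

def default_gene_programs(
    lineage: LineageSpec,
    n_genes: int = 100,
    seed: int = 0,
    marker_fraction: float = 0.7,
    include_malat1: bool = True,
) -> list[KineticGeneProgram]:
    """Random gene programs with population structure.

    A ``marker_fraction`` of genes peak (high alpha) in one randomly chosen
    segment and idle at a low baseline elsewhere, giving each population a
    distinguishable profile plus induction/repression transients at segment
    boundaries; the rest are constitutive.  gamma is log-uniform on
    [0.1, 2], beta = 1.  When ``include_malat1`` is set, one extra
    high-expression constitutive gene named "Malat1" is appended so the
    default panel exercises the conventional exclusion of that gene.
    """
    if n_genes < 20:
        raise ValueError("need at least 20 genes")
    rng = np.random.default_rng(seed)
    segments = list(lineage.all_populations)
    programs: list[KineticGeneProgram] = []
    for g in range(n_genes):
        gamma = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
        base = float(np.exp(rng.uniform(np.log(0.5), np.log(4.0))))
        if rng.random() < marker_fraction:
            peak = segments[rng.integers(len(segments))]
            alphas = {seg: base * (8.0 if seg == peak else 0.4) for seg in segments}
        else:
            alphas = {seg: base for seg in segments}
        programs.append(
            KineticGeneProgram(
                gene_id=f"Gene{g:04d}", alpha_by_segment=alphas, beta=1.0, gamma=gamma
            )
        )
    if include_malat1:
        programs.append(
            KineticGeneProgram(
                gene_id="Malat1",
                alpha_by_segment={seg: 40.0 for seg in segments},
                beta=1.0,
                gamma=0.8,
            )
        )
    return programs


def cycle_gene_programs(
    gammas: Sequence[float],
    alpha_on: float = 5.0,
    beta: float = 1.0,
) -> tuple[LineageSpec, list[KineticGeneProgram]]:
    """Programs tracing one full induction-repression cycle per gene.

    Returns a two-segment linear lineage ("induction" -> "repression";
    branch arms are placeholders receiving no cells when used with
    :func:`simulate_cycle`) where every gene transcribes at ``alpha_on``
    during induction and is silent during repression.  The per-phase
    duration is 40 time units (beta = 1), at least 4/gamma for the slowest
    supported gamma (0.1), so late-induction cells genuinely approach the
    steady state u*/s* = gamma/beta that the extreme-quantile fit assumes.
    """
    lineage = LineageSpec(
        segments=("induction", "repression"),
        neuronal_branch=("unused-N",),
        astrocytic_branch=("unused-A",),
        fate_bias_by_condition={CONTROL: 1.0},
        cells_per_condition={CONTROL: 2000},
        animals_per_condition={CONTROL: 1},
        segment_duration=40.0,
    )
    segs = lineage.all_populations
    programs = [
        KineticGeneProgram(
            gene_id=f"CycleGene{i:03d}",
            alpha_by_segment={
                s: (alpha_on if s == "induction" else 0.0) for s in segs
            },
            beta=beta,
            gamma=float(g),
        )
        for i, g in enumerate(gammas)
    ]
    return lineage, programs


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _segment_boundary_states(
    lineage: LineageSpec, programs: Sequence[KineticGeneProgram], path: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(u, s) at the start of every segment of a path, carried continuously.

    Returns (alpha[seg, gene], u0[seg, gene], s0[seg, gene]).
    """
    n_seg, n_gene = len(path), len(programs)
    alpha = np.array([[p.alpha_by_segment[seg] for p in programs] for seg in path])
    beta = np.array([p.beta for p in programs])
    gamma = np.array([p.gamma for p in programs])
    u0 = np.zeros((n_seg, n_gene))
    s0 = np.zeros((n_seg, n_gene))
    for k in range(1, n_seg):
        u0[k], s0[k] = _kinetics(
            alpha[k - 1], beta, gamma, u0[k - 1], s0[k - 1], lineage.segment_duration
        )
    return alpha, u0, s0


def _pca_embedding(spliced: np.ndarray) -> np.ndarray:
    """First two principal components of log1p spliced counts (deterministic)."""
    X = np.log1p(spliced.T)
    pca = PCA(n_components=2, svd_solver="full")
    return pca.fit_transform(X)


def simulate_dataset(
    lineage: LineageSpec,
    programs: Sequence[KineticGeneProgram],
    noise: NoiseConfig | None = None,
    seed: int = 0,
) -> SplicedUnsplicedDataset:
    """Draw a seeded spliced/unspliced dataset along the branching lineage.

    For each condition, ``cells_per_condition`` cells are generated: each
    draws its branch (neuronal with the condition's fate bias), a segment
    uniformly along its path, and a latent time uniform within that segment;
    kinetic means come from the analytic ODE solution with the segment's
    alpha and continuous (u, s) carried across boundaries.  Counts are
    sampled per :class:`NoiseConfig`; the embedding is the first two
    principal components of log1p spliced counts.  Identical arguments and
    seed give bit-identical output.
    """
    if noise is None:
        noise = NoiseConfig()
    if len(programs) < 20:
        raise ValueError("need at least 20 gene programs")
    rng = np.random.default_rng(seed)

    # boundary states for the two paths (trunk shared by construction)
    paths = {True: lineage.path(True), False: lineage.path(False)}
    states = {br: _segment_boundary_states(lineage, programs, p) for br, p in paths.items()}
    beta = np.array([p.beta for p in programs])
    gamma = np.array([p.gamma for p in programs])

    rows = []
    cols_u, cols_s = [], []
    cell_counter = 0
    for cond in lineage.cells_per_condition:
        n = int(lineage.cells_per_condition[cond])
        bias = float(lineage.fate_bias_by_condition[cond])
        n_animals = int(lineage.animals_per_condition.get(cond, 1))
        if n_animals < 1:
            raise ValueError(f"animals_per_condition[{cond}] must be >= 1")
        branch = rng.random(n) < bias
        n_seg = {br: len(paths[br]) for br in (True, False)}
        seg_idx = np.empty(n, dtype=int)
        for br in (True, False):
            m = branch == br
            seg_idx[m] = rng.integers(n_seg[br], size=m.sum())
        if lineage.time_grid is not None:
            grid = (np.arange(lineage.time_grid) + 0.5) / lineage.time_grid
            tau = grid[rng.integers(lineage.time_grid, size=n)] * lineage.segment_duration
        else:
            tau = rng.uniform(0.0, lineage.segment_duration, size=n)

        U = np.empty((len(programs), n))
        S = np.empty((len(programs), n))
        for br in (True, False):
            alpha, u0, s0 = states[br]
            for k in range(n_seg[br]):
                m = (branch == br) & (seg_idx == k)
                if not m.any():
                    continue
                u, s = _kinetics(
                    alpha[k][:, None], beta[:, None], gamma[:, None],
                    u0[k][:, None], s0[k][:, None], tau[m][None, :],
                )
                U[:, m], S[:, m] = u, s

        pops = np.where(
            branch,
            np.array(paths[True], dtype=object)[seg_idx],
            np.array(paths[False], dtype=object)[seg_idx],
        )
        # global latent time in [0, 1] along the cell's own path
        path_len = np.where(branch, n_seg[True], n_seg[False]).astype(float)
        latent = (seg_idx + tau / lineage.segment_duration) / path_len
        animals = np.array(
            [f"{cond}-A{(i % n_animals) + 1}" for i in range(n)], dtype=object
        )
        ids = np.array(
            [f"cell{cell_counter + i:06d}" for i in range(n)], dtype=object
        )
        cell_counter += n
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": ids,
                    "condition": cond,
                    "population": pops,
                    "animal": animals,
                    "latent_time": latent,
                }
            )
        )
        cols_u.append(U)
        cols_s.append(S)

    cell_meta = pd.concat(rows, ignore_index=True)
    U = np.concatenate(cols_u, axis=1)
    S = np.concatenate(cols_s, axis=1)

    if noise.target_counts_per_cell is not None:
        depth = S.sum(axis=0).mean()
        if depth > 0:
            scale = noise.target_counts_per_cell / depth
            U *= scale
            S *= scale

    if noise.model == "none":
        spliced, unspliced = S, U
    else:
        capture = rng.lognormal(mean=0.0, sigma=noise.capture_sigma, size=S.shape[1])
        mu_s = S * capture
        mu_u = U * capture
        if noise.model == "negative_binomial":
            th = noise.nb_dispersion
            mu_s = rng.gamma(th, mu_s / th)
            mu_u = rng.gamma(th, mu_u / th)
        spliced = rng.poisson(mu_s).astype(np.int64)
        unspliced = rng.poisson(mu_u).astype(np.int64)

    gene_meta = pd.DataFrame({"gene_id": [p.gene_id for p in programs]})
    return SplicedUnsplicedDataset(
        spliced=spliced,
        unspliced=unspliced,
        cell_meta=cell_meta,
        embedding=_pca_embedding(spliced),
        gene_meta=gene_meta,
    )


def simulate_cycle(
    gammas: Sequence[float],
    n_cells: int = 2000,
    noise: NoiseConfig | None = None,
    alpha_on: float = 5.0,
    seed: int = 0,
) -> tuple[SplicedUnsplicedDataset, np.ndarray]:
    """Simulate genes through a full induction-repression cycle.

    Convenience wrapper around :func:`cycle_gene_programs` /
    :func:`simulate_dataset` used for degradation-rate (gamma) recovery
    studies.  Returns the dataset and the true gamma vector.
    """
    lineage, programs = cycle_gene_programs(gammas, alpha_on=alpha_on)
    lineage = dataclasses.replace(
        lineage, cells_per_condition={CONTROL: int(n_cells)}
    )
    if noise is None:
        noise = NoiseConfig(model="none", target_counts_per_cell=None)
    ds = simulate_dataset(lineage, programs, noise=noise, seed=seed)
    return ds, np.asarray(gammas, dtype=float)


# ---------------------------------------------------------------------------
# Spatial simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationPlacement:
    """Normal placement distribution for one population's signed offsets."""

    mean: float
    sd: float = 0.8


@dataclass(frozen=True)
class SpatialLayoutConfig:
    """Zone-placement distributions per population and condition.

    ``placements[condition][population]`` gives the offset distribution in
    nucleus-width units (0 = GCL/hilus boundary, positive toward the
    molecular layer).  Defaults emulate the observed TBI displacements:
    N-stage3 moves from the SGZ up into the granule-cell layer and A-stage1
    from the SGZ down toward the hilus, while NSC populations stay put.
    """

    placements: Mapping[str, Mapping[str, PopulationPlacement]] = field(
        default_factory=lambda: {
            CONTROL: {
                "RG-like": PopulationPlacement(-1.0, 0.6),
                "N-stage3": PopulationPlacement(-1.0, 0.8),
                "A-stage1": PopulationPlacement(-1.0, 0.8),
            },
            TBI: {
                "RG-like": PopulationPlacement(-1.0, 0.6),
                "N-stage3": PopulationPlacement(0.8, 1.2),
                "A-stage1": PopulationPlacement(-2.6, 0.9),
            },
        }
    )
    animals_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {CONTROL: 4, TBI: 5}
    )
    cells_per_population_per_animal: int = 40
    gcl_thickness_range: tuple[float, float] = (4.0, 8.0)

    def __post_init__(self) -> None:
        for cond, n in self.animals_per_condition.items():
            if n < 1:
                raise ValueError(f"zero animals for condition {cond}")
        for cond, pops in self.placements.items():
            if not pops:
                raise ValueError(f"no populations placed for condition {cond}")
        lo, hi = self.gcl_thickness_range
        if lo < 4.0 or hi < lo:
            raise ValueError("GCL thickness range must lie within [4, inf) and be ordered")


def simulate_spatial(layout: SpatialLayoutConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Sample a spatial cell set (tidy frame) from the layout config.

    Columns: cell_id, population, condition, animal, signed_offset,
    gcl_thickness.  Animal IDs are assigned round-robin within each
    condition; each animal gets one local GCL thickness drawn uniformly
    from ``gcl_thickness_range`` (the granule-cell layer is 4-8 nuclei
    thick).  Deterministic given config + seed.
    """
    if layout is None:
        layout = SpatialLayoutConfig()
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    lo, hi = layout.gcl_thickness_range
    for cond, pops in layout.placements.items():
        n_animals = layout.animals_per_condition[cond]
        thick = rng.uniform(lo, hi, size=n_animals)
        for pop, placement in pops.items():
            n = layout.cells_per_population_per_animal * n_animals
            offs = rng.normal(placement.mean, placement.sd, size=n)
            for i in range(n):
                a = i % n_animals
                rows.append(
                    (
                        f"scell{counter:06d}",
                        pop,
                        cond,
                        f"{cond}-A{a + 1}",
                        float(offs[i]),
                        float(thick[a]),
                    )
                )
                counter += 1
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id", "population", "condition", "animal", "signed_offset", "gcl_thickness",
        ],
    )
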