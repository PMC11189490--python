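"""Splicing-kinetics solver and the branching-lineage / spatial simulators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from dgfate import (
    CONTROL,
    TBI,
    DegenerateRatesError,
    KineticGeneProgram,
    LineageSpec,
    NoiseConfig,
    PopulationPlacement,
    SpatialLayoutConfig,
    default_gene_programs,
    simulate_dataset,
    simulate_spatial,
    solve_kinetics,
)
from dgfate.spatial import assign_zone


def prog(beta=1.0, gamma=0.5):
    return KineticGeneProgram("g", {"seg": 1.0}, beta=beta, gamma=gamma)


class TestSolveKinetics:
    def test_null_initial_condition_stays_at_zero(self):
        p = prog()
        for tau in (0.0, 0.5, 3.0):
            assert solve_kinetics(p, 0.0, 0.0, 0.0, tau) == (0.0, 0.0)

    def test_steady_state_is_fixed_point(self):
        alpha, beta, gamma = 2.0, 1.0, 0.5
        p = prog(beta, gamma)
        u_star, s_star = alpha / beta, alpha / gamma
        for tau in (0.1, 1.0, 10.0):
            u, s = solve_kinetics(p, u_star, s_star, alpha, tau)
            assert u == pytest.approx(u_star, abs=1e-12)
            assert s == pytest.approx(s_star, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0])
    def test_matches_numerical_integration(self, tau):
        alpha, beta, gamma = 2.0, 1.0, 0.5
        p = prog(beta, gamma)
        sol = solve_ivp(
            lambda t, y: [alpha - beta * y[0], beta * y[0] - gamma * y[1]],
            (0.0, tau), [0.0, 0.0], rtol=1e-11, atol=1e-13,
        )
        u, s = solve_kinetics(p, 0.0, 0.0, alpha, tau)
        assert u == pytest.approx(sol.y[0, -1], abs=1e-8)
        assert s == pytest.approx(sol.y[1, -1], abs=1e-8)

    def test_randomized_grid_against_ode_oracle(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            beta = rng.uniform(0.2, 3.0)
            gamma = rng.uniform(0.1, 2.0)
            if abs(gamma - beta) < 0.05:
                gamma = beta + 0.05  # stay clear of the degenerate-rate region
            alpha = rng.uniform(0.0, 5.0)
            u0, s0 = rng.uniform(0, 4, 2)
            tau = rng.uniform(0.0, 5.0)
            p = prog(beta, gamma)
            sol = solve_ivp(
                lambda t, y: [alpha - beta * y[0], beta * y[0] - gamma * y[1]],
                (0.0, tau), [u0, s0], rtol=1e-11, atol=1e-13,
            )
            u, s = solve_kinetics(p, u0, s0, alpha, tau)
            worst = max(worst, abs(u - sol.y[0, -1]), abs(s - sol.y[1, -1]))
        assert worst <= 1e-8

    def test_equal_rates_rejected(self):
        with pytest.raises(DegenerateRatesError):
            KineticGeneProgram("g", {"seg": 1.0}, beta=1.0, gamma=1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_kinetics(prog(), 0.0, 0.0, 1.0, -1.0)
        with pytest.raises(ValueError):
            KineticGeneProgram("g", {"seg": -1.0})


class TestSimulateDataset:
    def test_cell_counts_exact(self, small_lineage):
        programs = default_gene_programs(small_lineage, n_genes=25, seed=0)
        ds = simulate_dataset(small_lineage, programs, seed=1)
        counts = ds.cell_meta["condition"].value_counts()
        assert counts[CONTROL] == 300 and counts[TBI] == 300
        assert ds.n_cells == 600  # conservation

    def test_determinism_bit_identical(self, small_lineage):
        programs = default_gene_programs(small_lineage, n_genes=25, seed=0)
        a = simulate_dataset(small_lineage, programs, seed=3)
        b = simulate_dataset(small_lineage, programs, seed=3)
        assert np.array_equal(a.spliced, b.spliced)
        assert np.array_equal(a.unspliced, b.unspliced)
        assert np.array_equal(a.embedding, b.embedding)
        assert a.cell_meta.equals(b.cell_meta)

    def test_branch_fraction_within_binomial_interval(self):
        # 99% binomial interval for the neuronal fraction at bias 0.5
        lineage = LineageSpec(
            cells_per_condition={CONTROL: 2500},
            fate_bias_by_condition={CONTROL: 0.5},
            animals_per_condition={CONTROL: 1},
        )
        programs = default_gene_programs(lineage, n_genes=25, seed=0)
        ds = simulate_dataset(lineage, programs, seed=1)
        pops = ds.cell_meta["population"]
        neuronal = pops.isin(lineage.neuronal_branch).sum()
        post_branch = neuronal + pops.isin(lineage.astrocytic_branch).sum()
        from scipy.stats import binom

        lo, hi = binom.ppf([0.005, 0.995], post_branch, 0.5)
        assert lo <= neuronal <= hi

    def test_steady_state_ratio_without_noise(self):
        # hold one constitutive gene at steady state: u/s == gamma/beta per cell
        lineage = LineageSpec(
            segments=("only",),
            neuronal_branch=("n1",),
            astrocytic_branch=("a1",),
            cells_per_condition={CONTROL: 50},
            fate_bias_by_condition={CONTROL: 1.0},
            animals_per_condition={CONTROL: 1},
            segment_duration=200.0,  # long enough to converge for all cells
        )
        programs = [
            KineticGeneProgram(
                f"g{i}", {s: 2.0 for s in lineage.all_populations},
                beta=1.0, gamma=0.4,
            )
            for i in range(20)
        ]
        ds = simulate_dataset(
            lineage, programs,
            noise=NoiseConfig(model="none", target_counts_per_cell=None), seed=0,
        )
        trunk = (ds.cell_meta["population"] == "only").to_numpy()
        late = trunk & (ds.cell_meta["latent_time"].to_numpy() > 0.2)
        ratio = ds.unspliced[:, late] / ds.spliced[:, late]
        assert np.allclose(ratio, 0.4, atol=1e-6)

    def test_fate_bias_validation(self):
        with pytest.raises(ValueError, match="fate bias"):
            LineageSpec(fate_bias_by_condition={CONTROL: 1.2})

    def test_too_few_genes_rejected(self, small_lineage):
        programs = default_gene_programs(small_lineage, n_genes=25, seed=0)[:5]
        with pytest.raises(ValueError, match="20 gene"):
            simulate_dataset(small_lineage, programs, seed=0)

    def test_negative_binomial_noise_runs(self, small_lineage):
        programs = default_gene_programs(small_lineage, n_genes=25, seed=0)
        lineage = dataclasses.replace(
            small_lineage, cells_per_condition={CONTROL: 100, TBI: 100}
        )
        ds = simulate_dataset(
            lineage, programs,
            noise=NoiseConfig(model="negative_binomial", nb_dispersion=5.0), seed=0,
        )
        assert np.issubdtype(ds.spliced.dtype, np.integer)
        # NB should overdisperse relative to Poisson at matched mean
        assert (ds.spliced >= 0).all()


class TestSimulateSpatial:
    def test_animal_cardinalities(self):
        layout = SpatialLayoutConfig(
            animals_per_condition={CONTROL: 4, TBI: 5},
        )
        cells = simulate_spatial(layout, seed=1)
        by_cond = cells.groupby("condition")["animal"].nunique()
        assert by_cond[CONTROL] == 4 and by_cond[TBI] == 5

    def test_forced_sgz_placement(self):
        layout = SpatialLayoutConfig(
            placements={CONTROL: {"P": PopulationPlacement(-1.0, 1e-9)}},
            animals_per_condition={CONTROL: 2},
        )
        cells = simulate_spatial(layout, seed=0)
        assert (assign_zone(cells)["zone"] == "SGZ").all()

    def test_zero_animals_rejected(self):
        with pytest.raises(ValueError, match="zero animals"):
            SpatialLayoutConfig(animals_per_condition={CONTROL: 0})

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="no populations"):
            SpatialLayoutConfig(placements={CONTROL: {}})

    def test_determinism(self):
        a = simulate_spatial(seed=5)
        b = simulate_spatial(seed=5)
        pd.testing.assert_frame_equal(a, b)
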