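"""Velocity correlations, transition kernels, population masses, Wilcoxon."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgfate import (
    CONTROL,
    TBI,
    LineageSpec,
    NoiseConfig,
    TransitionConfig,
    VelocityConfig,
    build_neighbor_index,
    choose_neighborhood,
    compare_conditions,
    default_gene_programs,
    estimate_velocity,
    population_mass,
    population_transition_summary,
    signed_sqrt,
    simulate_dataset,
    transition_probabilities,
    velocity_correlation,
    wilcoxon_rank_sum,
)


class TestSignedSqrt:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.0), (4.0, 2.0), (-4.0, -2.0)],
    )
    def test_scalars(self, x, expected):
        assert signed_sqrt(np.array(x)) == pytest.approx(expected)

    def test_elementwise_matrix(self):
        out = signed_sqrt(np.array([-9.0, 1.0, 0.25]))
        assert np.allclose(out, [-3.0, 1.0, 0.5])


class TestVelocityCorrelation:
    def _single_pair(self, current, delta_e, scale="none"):
        nbr = np.array([[1], [0]])
        return velocity_correlation(current, delta_e, nbr, scale=scale)[0, 0]

    def test_perfect_alignment(self):
        rng = np.random.default_rng(0)
        c0 = rng.uniform(0, 5, 8)
        disp = rng.normal(0, 1, 8)
        current = np.c_[c0, c0 + disp]
        delta_e = np.c_[2.5 * disp, np.zeros(8)]  # positive multiple of displacement
        assert self._single_pair(current, delta_e) == pytest.approx(1.0, abs=1e-12)

    def test_anti_alignment(self):
        rng = np.random.default_rng(1)
        c0 = rng.uniform(0, 5, 8)
        disp = rng.normal(0, 1, 8)
        current = np.c_[c0, c0 + disp]
        delta_e = np.c_[-disp, np.zeros(8)]
        assert self._single_pair(current, delta_e) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(2)
        current = rng.uniform(0, 3, (5, 4))
        delta_e = rng.normal(0, 1, (5, 4))
        nbr = build_neighbor_index(rng.normal(0, 1, (4, 2)), 3)
        cc = velocity_correlation(current, delta_e, nbr, scale="none")
        for i in range(4):
            for k, j in enumerate(nbr[i]):
                d = current[:, j] - current[:, i]
                expected = stats.pearsonr(d, delta_e[:, i]).statistic
                assert cc[i, k] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_set_to_zero(self):
        current = np.ones((5, 2))
        delta_e = np.zeros((5, 2))
        assert self._single_pair(current, delta_e) == 0.0


class TestTransitionProbabilities:
    def test_uniform_for_equal_correlations(self):
        cc = np.full((3, 5), 0.37)
        tp = transition_probabilities(cc, sigma=0.05)
        assert np.allclose(tp, 0.2)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        tp = transition_probabilities(rng.uniform(-1, 1, (20, 7)), sigma=0.05)
        assert np.allclose(tp.sum(axis=1), 1.0, atol=1e-12)
        assert (tp >= 0).all()

    def test_matches_direct_softmax(self):
        cc = np.array([[0.5, -0.5]])
        sigma = 0.05
        tp = transition_probabilities(cc, sigma=sigma)
        w = np.exp(cc[0] / sigma - cc[0].max() / sigma)
        assert np.allclose(tp[0], w / w.sum(), atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(np.zeros((1, 2)), sigma=0.0)


class TestPopulationMass:
    def test_single_population_gets_all_mass(self):
        rng = np.random.default_rng(4)
        nbr = build_neighbor_index(rng.normal(0, 1, (6, 2)), 3)
        tp = transition_probabilities(rng.uniform(-1, 1, (6, 3)))
        m = population_mass(tp, nbr, np.array(["P"] * 6))
        assert np.allclose(m["P"], 1.0)

    def test_toy_masses_match_enumeration(self):
        # 4 cells, 2 populations, handcrafted tp rows over 2 neighbours
        labels = np.array(["A", "A", "B", "B"])
        nbr = np.array([[1, 2], [0, 3], [3, 0], [2, 1]])
        tp = np.array([[0.7, 0.3], [0.6, 0.4], [0.9, 0.1], [0.25, 0.75]])
        m = population_mass(tp, nbr, labels)
        expected_a = [0.7, 0.6, 0.1, 0.75]  # per-row mass to label A
        assert np.allclose(m["A"], expected_a)
        assert np.allclose(m["B"], 1.0 - np.array(expected_a))

    def test_masses_partition_rows(self):
        rng = np.random.default_rng(5)
        labels = rng.choice(["A", "B", "C"], size=30)
        nbr = build_neighbor_index(rng.normal(0, 1, (30, 2)), 10)
        tp = transition_probabilities(rng.uniform(-1, 1, (30, 10)))
        m = population_mass(tp, nbr, labels)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_label_rejected(self):
        nbr = np.array([[1], [0]])
        tp = np.ones((2, 1))
        with pytest.raises(ValueError):
            population_mass(tp, nbr, np.array(["A", None], dtype=object))


class TestChooseNeighborhood:
    def test_minimum_applies_to_small_population(self):
        labels = np.array(["P"] * 120 + ["Q"] * 500)
        assert choose_neighborhood(labels, "P", minimum=300) == 300

    def test_large_population_uses_own_size(self):
        labels = np.array(["P"] * 950 + ["Q"] * 500)
        assert choose_neighborhood(labels, "P", minimum=300) == 950

    def test_capped_at_n_cells_minus_one(self):
        labels = np.array(["P"] * 120 + ["Q"] * 80)
        assert choose_neighborhood(labels, "P", minimum=300) == 199

    def test_single_cell_dataset_rejected(self):
        with pytest.raises(ValueError):
            choose_neighborhood(np.array(["P"]), "P")


class TestWilcoxonRankSum:
    def test_identical_samples_give_p_one(self):
        x = [1.0, 2.0, 3.0]
        _, p = wilcoxon_rank_sum(x, x, mode="exact")
        assert p == pytest.approx(1.0)

    def test_textbook_separation_case(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8], mode="exact")
        assert p == pytest.approx(2 / 70, abs=1e-12)

    def test_exact_matches_full_permutation_enumeration(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            n1, n2 = rng.integers(3, 8, 2)
            pooled = np.round(rng.normal(0, 1, n1 + n2), 1)  # rounding makes ties
            x, y = pooled[:n1], pooled[n1:]
            _, p = wilcoxon_rank_sum(x, y, mode="exact")
            ranks = stats.rankdata(pooled)
            obs = ranks[:n1].sum()
            mean = n1 * ranks.sum() / (n1 + n2)
            hits = total = 0
            for comb in itertools.combinations(range(n1 + n2), n1):
                t = ranks[list(comb)].sum()
                total += 1
                if abs(t - mean) >= abs(obs - mean) - 1e-9:
                    hits += 1
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.5, 1, 7)
        u, p = wilcoxon_rank_sum(x, y, mode="exact")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_n30(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.3, 1, 30)
        _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
        _, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
        assert abs(p_exact - p_norm) < 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def _summary_frame(masses_by_cond, source="S", target="T"):
    rows = []
    for cond, masses in masses_by_cond.items():
        for i, m in enumerate(masses):
            rows.append(
                {"cell_id": f"{cond}{i}", "source": source, "target": target,
                 "condition": cond, "mass": m}
            )
    return pd.DataFrame(rows)


class TestCompareConditions:
    def test_identical_distributions(self):
        vals = [0.1, 0.2, 0.3, 0.4]
        out = compare_conditions(_summary_frame({CONTROL: vals, TBI: vals}))
        row = out.iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row[f"median_{CONTROL}"] == row[f"median_{TBI}"]

    def test_single_cell_condition_flagged_not_comparable(self):
        out = compare_conditions(
            _summary_frame({CONTROL: [0.5], TBI: [0.1, 0.2, 0.3]})
        )
        row = out.iloc[0]
        assert not row["comparable"]
        assert row["direction"] == "not-comparable"
        assert np.isnan(row["p_value"])

    def test_boxplot_whiskers_are_data_extremes(self):
        out = compare_conditions(
            _summary_frame({CONTROL: [0.1, 0.9, 0.4], TBI: [0.2, 0.3, 0.8]})
        )
        row = out.iloc[0]
        assert row[f"min_{CONTROL}"] == 0.1 and row[f"max_{CONTROL}"] == 0.9


class TestEndToEnd:
    def _summary_for_bias(self, bias, seed=21, n=400):
        lineage = LineageSpec(
            cells_per_condition={CONTROL: n},
            fate_bias_by_condition={CONTROL: bias},
            animals_per_condition={CONTROL: 2},
        )
        programs = default_gene_programs(lineage, n_genes=60, seed=seed)
        ds = simulate_dataset(lineage, programs, noise=NoiseConfig(), seed=seed)
        res = estimate_velocity(ds, VelocityConfig())
        return population_transition_summary(
            ds.embedding, ds.cell_meta["population"].to_numpy(),
            res.current, res.delta_e, condition=CONTROL,
            config=TransitionConfig(),
        )

    def test_directional_recovery_monotone_in_fate_bias(self):
        means = []
        for bias in (0.25, 0.5, 0.8):
            s = self._summary_for_bias(bias)
            sel = s[(s["source"] == "RG-like") & (s["target"] == "N-stage1")]
            means.append(sel["mass"].mean())
        assert means[0] < means[1] < means[2]

    def test_label_permutation_invariance(self, small_dataset):
        sub = small_dataset.subset_condition(CONTROL)
        res = estimate_velocity(sub, VelocityConfig())
        labels = sub.cell_meta["population"].to_numpy()
        base = population_transition_summary(
            sub.embedding, labels, res.current, res.delta_e, condition=CONTROL,
            cell_ids=sub.cell_meta["cell_id"].to_numpy(),
            config=TransitionConfig(),
        )
        rng = np.random.default_rng(0)
        perm = rng.permutation(sub.n_cells)
        permuted = population_transition_summary(
            sub.embedding[perm], labels[perm],
            res.current[:, perm], res.delta_e[:, perm], condition=CONTROL,
            cell_ids=sub.cell_meta["cell_id"].to_numpy()[perm],
            config=TransitionConfig(),
        )
        a = base.groupby(["source", "target"])["mass"].mean()
        b = permuted.groupby(["source", "target"])["mass"].mean()
        pd.testing.assert_series_equal(a, b, atol=1e-9, rtol=0)

    def test_excluded_populations_absent_from_summary(self, small_dataset):
        sub = small_dataset.subset_condition(CONTROL)
        res = estimate_velocity(sub, VelocityConfig())
        summary = population_transition_summary(
            sub.embedding, sub.cell_meta["population"].to_numpy(),
            res.current, res.delta_e, condition=CONTROL,
            config=TransitionConfig(exclude_populations=("A-stage2", "N-stage2")),
        )
        assert "A-stage2" not in set(summary["source"]) | set(summary["target"])
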