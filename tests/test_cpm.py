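"""CPM core: edge selection, LOOCV, permutation inference, robust networks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpmtrial.connectome import AtlasLabels, EdgeIndexMap
from cpmtrial.cpm import (
    CPMResult,
    correlate_edges,
    evaluate_spearman,
    network_strength,
    overlap_with_networks,
    permutation_test,
    robust_edges,
    run_loocv,
    select_edges,
)
from cpmtrial.simulate import ConnectomeSimConfig, simulate_connectome_cohort


def _random_problem(rng, n=20, e=30):
    return rng.standard_normal((n, e)), rng.standard_normal(n)


class TestCorrelateEdges:
    def test_matches_per_edge_pearsonr_loop(self, rng):
        x, y = _random_problem(rng)
        res = correlate_edges(x, y)
        for k in range(x.shape[1]):
            r, p = stats.pearsonr(x[:, k], y)
            assert res.r[k] == pytest.approx(r, abs=1e-12)
            assert res.p[k] == pytest.approx(p, abs=1e-12)

    def test_perfect_correlation(self, rng):
        y = rng.standard_normal(10)
        x = np.column_stack([3 * y + 1, rng.standard_normal(10)])
        res = correlate_edges(x, y)
        assert res.r[0] == pytest.approx(1.0)
        assert res.p[0] < 1e-15

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            correlate_edges(rng.standard_normal((8, 3)), np.ones(8))

    def test_nan_rejected(self, rng):
        x, y = _random_problem(rng, n=8, e=3)
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            correlate_edges(x, y)

    def test_zero_variance_edge_warns_r0_p1(self, rng):
        x, y = _random_problem(rng, n=10, e=3)
        x[:, 1] = 7.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = correlate_edges(x, y)
        assert res.r[1] == 0.0 and res.p[1] == 1.0


class TestSelectEdges:
    def test_all_null_and_single_hit(self, rng):
        x, y = _random_problem(rng, n=30, e=50)
        x[:, 7] = y + 0.01 * rng.standard_normal(30)     # strong positive edge
        masks = select_edges(correlate_edges(x, y), alpha_edge=1e-6)
        assert masks.positive.tolist() == [7]
        assert np.intersect1d(masks.positive, masks.negative).size == 0

    def test_null_selection_fraction_near_alpha(self):
        """With no planted signal, ~1% of edges pass the P<.01 screen."""
        hits = total = 0
        for seed in range(20):
            cfg = ConnectomeSimConfig(
                n_subjects=40, n_nodes=40, coupling=0.0, behavior_slope=0.0, seed=seed
            )
            coh = simulate_connectome_cohort(cfg)
            masks = select_edges(correlate_edges(coh.edge_matrix(), coh.behavior))
            hits += masks.positive.size + masks.negative.size
            total += coh.edge_matrix().shape[1]
        frac = hits / total
        assert 0.006 < frac < 0.015      # 0.01 +/- binomial noise (~15600 edges)


class TestNetworkStrength:
    def test_empty_and_simple_sum(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        assert network_strength(v, np.array([], dtype=int)) == 0.0
        assert network_strength(v, np.array([0, 1, 2])) == pytest.approx(0.6)

    def test_matches_loop_oracle_and_matrix_form(self, rng):
        x = rng.standard_normal((15, 80))
        mask = rng.choice(80, 50, replace=False)
        s = network_strength(x, mask)
        for i in range(15):
            assert s[i] == pytest.approx(sum(x[i, k] for k in mask), rel=1e-12)

    def test_out_of_range_mask(self):
        with pytest.raises(ValueError):
            network_strength(np.zeros(4), np.array([4]))


class TestLOOCV:
    def test_no_leakage(self, rng):
        """Changing a held-out subject's score never changes its prediction."""
        emap = EdgeIndexMap(30)
        x = rng.standard_normal((20, emap.n_edges))
        y = rng.standard_normal(20)
        base = run_loocv(x, y, alpha_edge=0.05)
        for i in [0, 7, 19]:
            y2 = y.copy()
            y2[i] += 5.0
            again = run_loocv(x, y2, alpha_edge=0.05)
            assert again.predicted[i] == base.predicted[i]

    def test_empty_mask_predicts_training_mean(self, rng):
        x, y = _random_problem(rng, n=10, e=5)
        res = run_loocv(x, y, alpha_edge=1e-12)     # nothing can pass selection
        for fold in res.folds:
            assert fold.empty_mask
            i = fold.held_out
            assert fold.prediction == pytest.approx(np.delete(y, i).mean(), rel=1e-12)

    def test_selection_frequency_denominator_is_n(self, rng):
        x, y = _random_problem(rng, n=12, e=6)
        x[:, 2] = y                                # selected in every fold
        res = run_loocv(x, y, alpha_edge=0.01)
        assert res.selection_frequency[2] == pytest.approx(1.0)

    def test_tail_symmetry_under_negated_behavior(self, rng):
        x, y = _random_problem(rng, n=25, e=40)
        corr_pos = select_edges(correlate_edges(x, y), 0.05)
        corr_neg = select_edges(correlate_edges(x, -y), 0.05)
        assert np.array_equal(corr_pos.positive, corr_neg.negative)
        assert np.array_equal(corr_pos.negative, corr_neg.positive)
        res_p = run_loocv(x, y, alpha_edge=0.05, tail="positive")
        res_n = run_loocv(x, -y, alpha_edge=0.05, tail="negative")
        assert np.allclose(res_p.predicted, -res_n.predicted, atol=1e-10)

    def test_planted_cohort_recovery(self, planted_cohort, planted_edge_matrix):
        res = run_loocv(planted_edge_matrix, planted_cohort.behavior, tail="positive")
        assert res.rho >= 0.5

    def test_null_rho_centered_near_zero(self):
        rhos = []
        for seed in range(60):
            cfg = ConnectomeSimConfig(
                n_subjects=40, n_nodes=60, coupling=0.0, behavior_slope=0.0,
                seed=20_000 + seed,
            )
            coh = simulate_connectome_cohort(cfg)
            rhos.append(run_loocv(coh.edge_matrix(), coh.behavior).rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            run_loocv(*_random_problem(rng, n=4, e=5))


class TestSpearman:
    def test_endpoints(self, rng):
        obs = rng.standard_normal(10)
        assert evaluate_spearman(obs, obs)[0] == pytest.approx(1.0)
        assert evaluate_spearman(-obs, obs)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        a = rng.integers(0, 4, 15).astype(float)    # heavy ties
        b = rng.integers(0, 4, 15).astype(float)
        rho, _ = evaluate_spearman(a, b)
        ra, rb = stats.rankdata(a), stats.rankdata(b)
        assert rho == pytest.approx(stats.pearsonr(ra, rb)[0], abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            evaluate_spearman(np.ones(6), np.arange(6.0))


class TestPermutation:
    def test_add_one_bound_and_determinism(self, planted_cohort, planted_edge_matrix):
        x = planted_edge_matrix
        y = planted_cohort.behavior
        obs = run_loocv(x, y, tail="positive")
        p1 = permutation_test(x, y, tail="positive", b=99, seed=11, observed=obs)
        p2 = permutation_test(x, y, tail="positive", b=99, seed=11, observed=obs)
        assert p1.p_value == p2.p_value
        assert p1.count_ge == 0                       # strong planted signal
        assert p1.p_value == pytest.approx(1 / 100)

    def test_proportion_convention_flag(self, planted_cohort, planted_edge_matrix):
        obs = run_loocv(planted_edge_matrix, planted_cohort.behavior, tail="positive")
        pr = permutation_test(planted_edge_matrix, planted_cohort.behavior,
                              tail="positive", b=49, seed=3, observed=obs, add_one=False)
        assert pr.p_value == pr.count_ge / 49

    def test_invalid_b(self, rng):
        with pytest.raises(ValueError):
            permutation_test(*_random_problem(rng, n=8, e=4), b=0)


class TestRobustEdges:
    def _result_with_freq(self, freq):
        n = len(freq)
        return CPMResult("positive", np.arange(5.0), np.arange(5.0), 0.0, 1.0,
                         np.asarray(freq, dtype=float))

    def test_inclusive_at_half(self):
        res = self._result_with_freq([30 / 60, 29 / 60, 1.0])
        net = robust_edges(res, threshold=0.5)
        assert net.edges.tolist() == [0, 2]

    def test_threshold_validation(self):
        res = self._result_with_freq([0.4])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                robust_edges(res, threshold=bad)

    def test_planted_cohort_recall_and_precision(self, planted_cohort, planted_edge_matrix):
        truth = planted_cohort.ground_truth
        hits = found = 0
        for tail, planted in (("positive", truth.planted_pos_edges),
                              ("negative", truth.planted_neg_edges)):
            res = run_loocv(planted_edge_matrix, planted_cohort.behavior, tail=tail)
            net = robust_edges(res)
            hits += np.intersect1d(net.edges, planted).size
            found += net.edges.size
        assert hits / 30 >= 0.8           # recall of the planted edges
        assert hits / found >= 0.5        # precision among robust edges


class TestOverlap:
    @staticmethod
    def _net(edges):
        edges = np.asarray(edges, dtype=int)
        from cpmtrial.cpm import RobustNetwork
        return RobustNetwork("positive", edges, np.ones(edges.size))

    @staticmethod
    def _labels(mapping):
        table = pd.DataFrame(
            {"node_id": list(mapping), "network_label": list(mapping.values())}
        ).set_index("node_id")
        return AtlasLabels(table)

    def test_hand_enumeration(self):
        emap = EdgeIndexMap(4)
        labels = self._labels({1: "A", 2: "A", 3: "B", 4: "B"})
        edges = [emap.to_index(1, 2), emap.to_index(1, 3), emap.to_index(3, 4)]
        om = overlap_with_networks(self._net(edges), labels, emap)
        assert om.loc["A", "A"] == 1
        assert om.loc["B", "B"] == 1
        assert om.loc["A", "B"] == om.loc["B", "A"] == 1

    def test_empty_and_conservation(self, rng):
        emap = EdgeIndexMap(10)
        labels = self._labels({i: "net%d" % (i % 3) for i in range(1, 11)})
        empty = overlap_with_networks(self._net([]), labels, emap)
        assert empty.to_numpy().sum() == 0
        edges = rng.choice(emap.n_edges, 12, replace=False)
        om = overlap_with_networks(self._net(edges), labels, emap).to_numpy()
        assert np.triu(om).sum() == 12    # upper triangle + diagonal

    def test_unlabeled_node_rejected(self):
        from cpmtrial.connectome import ConnectomeError
        emap = EdgeIndexMap(4)
        labels = self._labels({1: "A", 2: "A", 3: "B"})
        with pytest.raises(ConnectomeError, match=r"\[4\]"):
            overlap_with_networks(self._net([emap.to_index(3, 4)]), labels, emap)
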