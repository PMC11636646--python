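import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import dartfdr
from dartfdr import (
    DistanceMatrix,
    HypothesisPValues,
    RunConfig,
    TreeConfig,
    aggregate_pvalues,
    build_tree,
    construct_tree,
    default_alpha_m,
    form_dynamic_nodes,
    layer_threshold,
    run_dart,
    stouffer_node_pvalue,
)
from dartfdr.recursive_testing import DynamicNode, LayerResult

from conftest import random_distance_matrix
from oracles import bh_oracle, bh_threshold_oracle, eq3_criterion, eq3_scan_oracle, stouffer_oracle


def quiet_config(**kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return TreeConfig(**kw)


# ---------------------------------------------------------------------------
# Node P-value aggregation
# ---------------------------------------------------------------------------


class TestStouffer:
    def test_symmetric_pair_is_exact_half(self):
        assert stouffer_node_pvalue([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_marginally_significant_pvalues(self):
        # z(0.05) = 1.6449; combined z = 2*1.6449/sqrt(2) = 2.3262
        got = stouffer_node_pvalue([0.05, 0.05])
        assert round(got, 4) == 0.0100
        assert got == pytest.approx(stouffer_oracle([0.05, 0.05]), rel=1e-10)

    @pytest.mark.parametrize("p", [0.2, 0.8])
    def test_singleton_is_identity(self, p):
        assert stouffer_node_pvalue([p]) == pytest.approx(p, rel=1e-12)

    def test_extreme_inputs_are_clipped(self):
        assert 0.0 < stouffer_node_pvalue([0.0, 0.0]) < 1e-20
        assert 1.0 - stouffer_node_pvalue([1.0, 1.0]) < 1e-12

    def test_empty_input_is_a_logic_error(self):
        with pytest.raises(dartfdr.TestingError):
            stouffer_node_pvalue([])

    def test_alternative_aggregators_behave(self):
        for method in ("fisher", "cauchy"):
            lo = aggregate_pvalues([0.01, 0.02], method)
            hi = aggregate_pvalues([0.6, 0.9], method)
            assert 0 < lo < 0.05 < hi < 1

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1 - 1e-6),
            min_size=1,
            max_size=8,
        ),
        st.randoms(use_true_random=False),
    )
    def test_matches_oracle_and_permutation_invariant(self, ps, rnd):
        got = stouffer_node_pvalue(ps)
        assert got == pytest.approx(stouffer_oracle(ps), rel=1e-10)
        shuffled = list(ps)
        rnd.shuffle(shuffled)
        assert stouffer_node_pvalue(shuffled) == pytest.approx(got, rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-4, max_value=1 - 1e-4), min_size=1, max_size=5
        ),
        st.integers(min_value=0, max_value=4),
    )
    def test_strictly_decreasing_in_each_input(self, ps, which):
        which = which % len(ps)
        smaller = list(ps)
        smaller[which] = ps[which] * 0.5
        assert stouffer_node_pvalue(smaller) < stouffer_node_pvalue(ps)

    def test_null_pairs_are_uniform(self):
        """Stouffer combination of independent uniform pairs stays uniform."""
        rng = np.random.default_rng(123)
        p = rng.uniform(size=(10_000, 2))
        z = stats.norm.isf(p)
        combined = stats.norm.sf(z.sum(axis=1) / np.sqrt(2))
        assert stats.kstest(combined, "uniform").pvalue > 1e-3


# ---------------------------------------------------------------------------
# Dynamic nodes
# ---------------------------------------------------------------------------


class TestDynamicNodes:
    @pytest.fixture()
    def small_tree(self):
        # {1,2} and {3,4,5} as layer-2 nodes (1-D positions)
        dm = DistanceMatrix.from_coordinates(
            ["1", "2", "3", "4", "5"], [0.0, 0.5, 3.0, 3.4, 3.8]
        )
        return build_tree(dm, quiet_config(max_node_size=3, min_top_nodes=1), [1.0])

    def test_pair_losing_one_member_is_not_candidate(self, small_tree):
        p = np.full(5, 0.5)
        rejected = np.array([True, False, False, False, False])
        cands = form_dynamic_nodes(small_tree, 2, rejected, p, RunConfig(alpha=0.3).resolve(5))
        sources = {c.source for c in cands}
        members = {c.members for c in cands}
        assert (1,) not in members  # {2} alone: single effective child
        assert all(c.effective_children >= 2 for c in cands)

    def test_triple_losing_one_member_stays_candidate(self, small_tree):
        p = np.full(5, 0.5)
        rejected = np.array([False, False, True, False, False])
        cands = form_dynamic_nodes(small_tree, 2, rejected, p, RunConfig(alpha=0.3).resolve(5))
        assert (3, 4) in {c.members for c in cands}
        node = next(c for c in cands if c.members == (3, 4))
        assert node.effective_children == 2
        assert node.node_pvalue == pytest.approx(stouffer_oracle([0.5, 0.5]), rel=1e-10)

    def test_without_rejections_full_nodes_are_candidates(self, small_tree):
        p = np.full(5, 0.5)
        cands = form_dynamic_nodes(
            small_tree, 2, np.zeros(5, bool), p, RunConfig(alpha=0.3).resolve(5)
        )
        assert {c.members for c in cands} == {(0, 1), (2, 3, 4)}

    def test_layer_one_candidates_are_unrejected_singletons(self, small_tree):
        p = np.linspace(0.1, 0.5, 5)
        rejected = np.array([False, True, False, False, False])
        cands = form_dynamic_nodes(small_tree, 1, rejected, p, RunConfig(alpha=0.3).resolve(5))
        assert [c.members for c in cands] == [(0,), (2,), (3,), (4,)]
        assert [c.node_pvalue for c in cands] == pytest.approx([p[0], p[2], p[3], p[4]])


# ---------------------------------------------------------------------------
# Layer thresholds
# ---------------------------------------------------------------------------


def _singleton_candidates(p):
    return tuple(
        DynamicNode(source=f"L1N{i}", members=(i,), effective_children=1,
                    node_pvalue=float(v))
        for i, v in enumerate(p)
    )


def _fake_layer(layer, sizes, threshold, n_rejected):
    cands = tuple(
        DynamicNode(
            source=f"L{layer}N{i}",
            members=tuple(range(s)),  # only the size matters here
            effective_children=2,
            node_pvalue=0.5,
        )
        for i, s in enumerate(sizes)
    )
    return LayerResult(
        layer=layer,
        candidates=cands,
        threshold=threshold,
        rejected_nodes=(),
        rejected_hypotheses=tuple(range(n_rejected)),
    )


class TestLayerThreshold:
    def test_layer1_equals_step_up_over_interval(self):
        rng = np.random.default_rng(42)
        p = np.concatenate([np.full(5, 0.001), rng.uniform(0.25, 1.0, 15)])
        config = RunConfig(alpha=0.2).resolve(20)
        t = layer_threshold(1, [], _singleton_candidates(p), config)
        oracle = eq3_scan_oracle(0.0, 0, np.ones(20), p, 0.2, config.alpha_m)
        assert t is not None and oracle is not None
        # same rejection set, and t is feasible and maximal
        assert set(np.flatnonzero(p <= t)) == set(np.flatnonzero(p <= oracle))
        assert eq3_criterion(t, 0.0, 0, np.ones(20), p, 0.2)
        assert t >= oracle - 1e-12

    def test_hopeless_pvalues_give_no_threshold(self):
        p = np.ones(10)
        config = RunConfig(alpha=0.05).resolve(10)
        assert layer_threshold(1, [], _singleton_candidates(p), config) is None

    def test_no_candidates_gives_no_threshold(self):
        config = RunConfig(alpha=0.05).resolve(100)
        assert layer_threshold(2, [], (), config) is None

    def test_matches_exhaustive_scan_on_fabricated_histories(self):
        rng = np.random.default_rng(2024)
        config_m = 400
        for trial in range(120):
            alpha = float(rng.choice([0.05, 0.1, 0.2]))
            config = RunConfig(alpha=alpha).resolve(config_m)
            am = config.alpha_m
            history = [
                _fake_layer(1, [1] * 10, float(rng.uniform(am, 0.01)), int(rng.integers(0, 4)))
            ]
            if rng.random() < 0.5:
                history.append(
                    _fake_layer(
                        2,
                        list(rng.integers(2, 4, size=6)),
                        None if rng.random() < 0.3 else float(rng.uniform(am, 0.02)),
                        int(rng.integers(0, 3)),
                    )
                )
            layer = len(history) + 1
            k = int(rng.integers(1, 12))
            sizes = rng.integers(2, 5, size=k)
            pvals = np.where(
                rng.random(k) < 0.4,
                rng.uniform(0, 0.05, k),
                rng.uniform(0, 1, k),
            )
            cands = tuple(
                DynamicNode(
                    source=f"L{layer}N{i}",
                    members=tuple(range(int(s))),
                    effective_children=2,
                    node_pvalue=float(pv),
                )
                for i, (s, pv) in enumerate(zip(sizes, pvals))
            )
            got = layer_threshold(layer, history, cands, config)
            carry = sum(
                lr.candidate_size_total * (lr.threshold if lr.threshold is not None else am)
                for lr in history
            )
            r_prev = sum(len(lr.rejected_hypotheses) for lr in history)
            oracle = eq3_scan_oracle(carry, r_prev, sizes.astype(float), pvals, alpha, am)
            if oracle is None:
                assert got is None
            else:
                assert got is not None
                assert got >= oracle - 1e-12
                assert eq3_criterion(got, carry, r_prev, sizes.astype(float), pvals, alpha)
                assert set(np.flatnonzero(pvals <= got)) == set(
                    np.flatnonzero(pvals <= oracle)
                )


# ---------------------------------------------------------------------------
# Full procedure
# ---------------------------------------------------------------------------


class TestRunDart:
    def test_all_ones_rejects_nothing(self):
        dm = random_distance_matrix(np.random.default_rng(1), 20)
        tree = construct_tree(dm, quiet_config(min_top_nodes=2))
        res = run_dart(np.ones(20), tree, RunConfig(alpha=0.1))
        assert res.n_rejections == 0
        assert all(not lr.rejected_hypotheses for lr in res.layers)

    def test_id_mismatch_rejected(self):
        dm = random_distance_matrix(np.random.default_rng(1), 10)
        tree = construct_tree(dm, quiet_config(min_top_nodes=2))
        pv = HypothesisPValues(ids=tuple(f"x{i}" for i in range(10)),
                               values=np.full(10, 0.5))
        with pytest.raises(dartfdr.TestingError):
            run_dart(pv, tree)

    def test_wrong_length_rejected(self):
        dm = random_distance_matrix(np.random.default_rng(1), 10)
        tree = construct_tree(dm, quiet_config(min_top_nodes=2))
        with pytest.raises(dartfdr.TestingError):
            run_dart(np.full(9, 0.5), tree)

    def test_alpha_m_must_stay_below_alpha(self):
        dm = random_distance_matrix(np.random.default_rng(1), 7)
        tree = construct_tree(dm, quiet_config(min_top_nodes=1))
        with pytest.raises(dartfdr.TestingError, match="alpha_m"):
            run_dart(np.full(7, 0.5), tree, RunConfig(alpha=0.05))

    def test_single_layer_tree_is_pure_step_up(self):
        rng = np.random.default_rng(8)
        m = 60
        dm = random_distance_matrix(rng, m)
        tree = construct_tree(dm, quiet_config(num_layers=1, min_top_nodes=1))
        p = np.concatenate([rng.uniform(0, 1e-4, 6), rng.uniform(0.3, 1, m - 6)])
        res = run_dart(p, tree, RunConfig(alpha=0.05))
        assert len(res.layers) == 1
        assert set(res.rejected_indices) == set(np.flatnonzero(bh_oracle(p, 0.05)))

    def test_layer1_matches_bh_on_random_instances(self):
        rng = np.random.default_rng(77)
        agree = 0
        applicable = 0
        for _ in range(120):
            m = int(rng.integers(20, 200))
            dm = random_distance_matrix(rng, m)
            tree = construct_tree(dm, quiet_config(min_top_nodes=2))
            n_sig = int(rng.integers(0, m // 4))
            p = np.concatenate(
                [rng.uniform(0, 0.01, n_sig), rng.uniform(0, 1, m - n_sig)]
            )
            rng.shuffle(p)
            alpha = 0.1
            res = run_dart(p, tree, RunConfig(alpha=alpha))
            bh_mask = bh_oracle(p, alpha)
            t_bh = bh_threshold_oracle(p, alpha)
            if bh_mask.any() and not (default_alpha_m(m) <= t_bh <= alpha):
                continue  # BH threshold outside the search interval
            applicable += 1
            layer1 = set(res.layers[0].rejected_hypotheses)
            assert layer1 == set(np.flatnonzero(bh_mask))
            agree += 1
        assert applicable >= 100  # the comparison must actually exercise BH

    def test_decreasing_a_pvalue_never_shrinks_layer1(self):
        rng = np.random.default_rng(13)
        m = 50
        dm = random_distance_matrix(rng, m)
        tree = construct_tree(dm, quiet_config(min_top_nodes=2))
        p = rng.uniform(0, 0.3, m)
        base = set(run_dart(p, tree, RunConfig(alpha=0.1)).layers[0].rejected_hypotheses)
        for idx in rng.integers(0, m, size=10):
            p2 = p.copy()
            p2[idx] *= 0.1
            new = set(
                run_dart(p2, tree, RunConfig(alpha=0.1)).layers[0].rejected_hypotheses
            )
            assert base - {int(idx)} <= new

    def test_audit_criterion_holds_at_every_threshold(self):
        rng = np.random.default_rng(55)
        m = 120
        dm = random_distance_matrix(rng, m)
        tree = construct_tree(dm, quiet_config(min_top_nodes=4))
        p = np.concatenate([rng.uniform(0, 5e-4, 12), rng.uniform(0, 1, m - 12)])
        config = RunConfig(alpha=0.1).resolve(m)
        res = run_dart(p, tree, config)
        assert res.n_rejections > 0
        carry, n_rej = 0.0, 0
        for lr in res.layers:
            if lr.threshold is not None:
                num = carry + lr.candidate_size_total * lr.threshold
                den = max(
                    n_rej
                    + sum(c.size for c in lr.candidates if c.node_pvalue <= lr.threshold),
                    1,
                )
                assert num / den <= config.alpha + 1e-12
            t_eff = lr.threshold if lr.threshold is not None else config.alpha_m
            carry += lr.candidate_size_total * t_eff
            n_rej += len(lr.rejected_hypotheses)
        # per-layer rejection sets are pairwise disjoint
        all_rej = [i for lr in res.layers for i in lr.rejected_hypotheses]
        assert len(all_rej) == len(set(all_rej))

    def test_global_null_family_error_is_controlled(self):
        """With uniform P-values the chance of any rejection stays near alpha."""
        rng = np.random.default_rng(99)
        m = 100
        dm = random_distance_matrix(rng, m)
        tree = construct_tree(dm, quiet_config(min_top_nodes=4))
        alpha = 0.05
        n_runs = 500
        any_rej = 0
        for _ in range(n_runs):
            res = run_dart(rng.uniform(size=m), tree, RunConfig(alpha=alpha))
            any_rej += res.n_rejections > 0
        rate = any_rej / n_runs
        mc_err = 3 * math.sqrt(alpha * (1 - alpha) / n_runs)
        assert rate <= alpha + mc_err
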