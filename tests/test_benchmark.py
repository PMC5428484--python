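import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gofunsim.benchmark import (
    OrthologSet,
    compare_corpora,
    make_controls,
    optimal_threshold,
    repeat_benchmark,
)


def brute_force_best_error(cases, controls):
    """Oracle: try every observed score as threshold under both the
    >= and > classification conventions and return the smallest error."""
    pool = list(cases) + list(controls)
    total = len(pool)
    best = min(len(cases), len(controls)) / total  # all-one-class extremes
    for h in pool:
        for op in (lambda s: s >= h, lambda s: s > h):
            fn = sum(1 for s in cases if not op(s))
            fp = sum(1 for s in controls if op(s))
            best = min(best, (fn + fp) / total)
    return best


class TestMakeControls:
    def test_n2_is_the_unique_swap(self):
        pairs = [("a1", "b1"), ("a2", "b2")]
        assert make_controls(pairs, seed=0) == [("a1", "b2"), ("a2", "b1")]

    def test_n1_has_no_derangement(self):
        with pytest.raises(ValueError):
            make_controls([("a1", "b1")], seed=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_derangement_properties_n3(self, seed):
        pairs = [(f"a{i}", f"b{i}") for i in range(3)]
        ctrl = make_controls(pairs, seed=seed)
        bs = [b for _, b in ctrl]
        assert sorted(bs) == [f"b{i}" for i in range(3)]
        assert all(ctrl[i] != pairs[i] for i in range(3))

    def test_n20_bijection_without_fixed_points(self):
        pairs = [(f"a{i:02d}", f"b{i:02d}") for i in range(20)]
        ctrl = make_controls(pairs, seed=7)
        assert sorted(b for _, b in ctrl) == sorted(b for _, b in pairs)
        for (a, b), (ca, cb) in zip(pairs, ctrl):
            assert a == ca
            assert b != cb

    def test_every_offdiagonal_position_reachable(self):
        # sanity over repeats: each non-identity assignment occurs
        pairs = [(f"a{i}", f"b{i}") for i in range(4)]
        seen = set()
        for seed in range(200):
            for i, (_, b) in enumerate(make_controls(pairs, seed=seed)):
                seen.add((i, b))
        assert seen == {(i, f"b{j}") for i in range(4) for j in range(4) if i != j}


class TestOptimalThreshold:
    def test_separable_scores_give_zero_error_at_midpoint(self):
        res = optimal_threshold([0.8, 0.9], [0.1, 0.2])
        assert res.error_rate == 0.0
        assert res.h_star == pytest.approx(0.5)
        assert (res.tp, res.fp, res.tn, res.fn) == (2, 0, 2, 0)

    def test_one_misclassification_case(self):
        res = optimal_threshold([0.6, 0.2], [0.5, 0.1])
        assert res.error_rate == pytest.approx(0.25)

    def test_identical_lists_give_half(self):
        res = optimal_threshold([0.3, 0.7], [0.3, 0.7])
        assert res.error_rate == pytest.approx(0.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, width=16), min_size=1, max_size=8),
        st.lists(st.floats(0, 1, width=16), min_size=1, max_size=8),
    )
    def test_matches_brute_force_scan(self, cases, controls):
        res = optimal_threshold(cases, controls)
        assert res.error_rate == pytest.approx(
            brute_force_best_error(cases, controls), abs=1e-12
        )
        # confusion counts are self-consistent
        assert res.tp + res.fn == len(cases)
        assert res.tn + res.fp == len(controls)
        err = (res.fp + res.fn) / (len(cases) + len(controls))
        assert err == pytest.approx(res.error_rate)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, width=16), min_size=2, max_size=8, unique=True),
        st.lists(st.floats(0, 1, width=16), min_size=2, max_size=8, unique=True),
    )
    def test_balanced_classes_never_exceed_half(self, cases, controls):
        n = min(len(cases), len(controls))
        res = optimal_threshold(cases[:n], controls[:n])
        assert res.error_rate <= 0.5

    def test_label_swap_mirrors_threshold_direction(self):
        cases, controls = [0.7, 0.9, 0.4], [0.1, 0.3, 0.5]
        fwd = optimal_threshold(cases, controls)
        # swapping labels turns ">= h predicts positive" into the <= rule;
        # negating scores restores the >= convention
        rev = optimal_threshold([-s for s in controls], [-s for s in cases])
        assert rev.error_rate == pytest.approx(fwd.error_rate)


class TestRepeatBenchmark:
    def test_perfect_scorer_gives_zero_error(self):
        pairs = OrthologSet(pairs=[(f"a{i}", f"b{i}") for i in range(10)])
        truth = {p: 1.0 for p in pairs.pairs}
        scorer = lambda a, b: 1.0 if (a, b) in truth else 0.0
        run = repeat_benchmark(pairs, scorer, R=20, seed=0)
        assert run.mean_error == 0.0
        assert run.ci99 == (0.0, 0.0)

    def test_constant_scorer_gives_half(self):
        pairs = OrthologSet(pairs=[(f"a{i}", f"b{i}") for i in range(10)])
        run = repeat_benchmark(pairs, lambda a, b: 0.5, R=10, seed=0)
        assert (run.per_repeat["error_rate"] == 0.5).all()

    def test_unscorable_cases_dropped_with_count(self):
        pairs = OrthologSet(pairs=[(f"a{i}", f"b{i}") for i in range(6)])
        scorer = lambda a, b: None if a == "a0" else 1.0
        run = repeat_benchmark(pairs, scorer, R=3, seed=0)
        assert run.n_dropped_cases == 1
        assert len(run.case_pairs) == 5

    def test_same_seed_gives_identical_control_sets(self):
        # the raw-vs-z comparison relies on paired control sets
        pairs = OrthologSet(pairs=[(f"a{i}", f"b{i}") for i in range(12)])
        rng = np.random.default_rng(3)
        values = {
            (a, b): float(rng.uniform())
            for a in [p[0] for p in pairs.pairs]
            for b in [p[1] for p in pairs.pairs]
        }
        raw = repeat_benchmark(pairs, lambda a, b: values[(a, b)], R=8, seed=5)
        shifted = repeat_benchmark(pairs, lambda a, b: 2 * values[(a, b)] + 1, R=8, seed=5)
        # monotone rescoring leaves every per-repeat error untouched
        assert np.allclose(
            raw.per_repeat["error_rate"], shifted.per_repeat["error_rate"]
        )

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(0)
        pairs = OrthologSet(pairs=[(f"a{i}", f"b{i}") for i in range(40)])
        vals = {}
        def scorer(a, b):
            key = (a, b)
            if key not in vals:
                bias = 0.3 if a[1:] == b[1:] else 0.0
                vals[key] = float(np.clip(rng.normal(0.4 + bias, 0.1), 0, 1))
            return vals[key]
        run = repeat_benchmark(pairs, scorer, R=30, seed=1)
        assert run.ci99[0] <= run.mean_error <= run.ci99[1]


class TestCompareCorpora:
    def test_strict_dominance_is_significant(self):
        base = np.linspace(0.02, 0.08, 225)
        res = compare_corpora(base, base + 0.01)
        assert res.pvalue < 1e-10
        assert res.significant
        assert not res.degenerate

    def test_identical_vectors_flagged_degenerate(self):
        base = np.full(225, 0.05)
        res = compare_corpora(base, base)
        assert not res.significant
        assert res.degenerate

    def test_null_rejection_rate_near_nominal(self):
        """Under exchangeable paired noise the one-sided test should
        reject at roughly its nominal (uncorrected) level."""
        rng = np.random.default_rng(0)
        alpha = 0.05
        n_sim, R = 400, 40
        rejections = 0
        for _ in range(n_sim):
            a = rng.normal(0.05, 0.01, R)
            b = a + rng.normal(0.0, 0.005, R)
            res = compare_corpora(a, b, n_tests=1, alpha=alpha)
            rejections += res.pvalue < alpha
        rate = rejections / n_sim
        mc_err = 3 * np.sqrt(alpha * (1 - alpha) / n_sim)
        assert abs(rate - alpha) <= mc_err + 0.01


class TestOrthologSet:
    def test_identity_filter_drops_80_and_above(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text(
            "idA\tidB\tpct_identity\n"
            "a1\tb1\t79.9\na2\tb2\t80.0\na3\tb3\t95.2\n"
        )
        s = OrthologSet.from_tsv(p).filter_identity(80.0)
        assert s.pairs == [("a1", "b1")]

    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError, match="one-to-one"):
            OrthologSet(pairs=[("a1", "b1"), ("a1", "b2")])

    def test_tsv_round_trip(self, tmp_path):
        s = OrthologSet(pairs=[("a1", "b1"), ("a2", "b2")], pct_identity=[50.0, 60.0])
        out = tmp_path / "o.tsv"
        s.to_tsv(out)
        loaded = OrthologSet.from_tsv(out)
        assert loaded.pairs == s.pairs
        assert loaded.pct_identity == s.pct_identity
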