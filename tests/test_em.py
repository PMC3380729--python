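import numpy as np
import pytest

from pepsl.em import (
    EMState,
    InteractionSet,
    canonical_pair,
    count_K,
    e_step,
    enumerate_cluster_pairs,
    init_em,
    m_step,
    predict_pair,
    rank_predictions,
    roc_auc,
    run_em,
)


def _assignment(d):
    return {k: frozenset(v) for k, v in d.items()}


class TestInteractionSet:
    def test_rejects_self_pairs_and_conflicts(self):
        with pytest.raises(ValueError):
            InteractionSet(frozenset({("a", "a")}))
        with pytest.raises(ValueError):
            InteractionSet(frozenset({("a", "b")}), frozenset({("a", "b")}))

    def test_from_pairs_canonicalizes(self):
        s = InteractionSet.from_pairs([("b", "a")], [("d", "c")])
        assert s.positives == {("a", "b")}
        assert s.negatives == {("c", "d")}


class TestEnumerateClusterPairs:
    def test_cartesian_with_self_pairs(self):
        a = _assignment({"m": {"1", "2"}, "n": {"2", "3"}})
        assert enumerate_cluster_pairs("m", "n", a) == {
            ("1", "2"), ("1", "3"), ("2", "2"), ("2", "3"),
        }

    def test_absent_protein_contributes_nothing(self):
        a = _assignment({"m": {"1"}})
        assert enumerate_cluster_pairs("m", "x", a) == set()

    def test_bound_by_product_of_set_sizes(self):
        a = _assignment({"m": {"1", "2", "3"}, "n": {"4", "5"}})
        assert len(enumerate_cluster_pairs("m", "n", a)) <= 6


class TestCountK:
    def test_noninteracting_pair_counted(self):
        a = _assignment({"m": {"1"}, "n": {"2"}})
        assert count_K(a, frozenset()) == {("1", "2"): 1}

    def test_interacting_pair_excluded(self):
        a = _assignment({"m": {"1"}, "n": {"2"}})
        assert count_K(a, frozenset({("m", "n")})) == {}

    def test_double_counting_identity(self):
        rng = np.random.default_rng(4)
        clusters = [f"C{i}" for i in range(6)]
        a = {
            f"P{i}": frozenset(
                rng.choice(clusters, size=int(rng.integers(1, 4)), replace=False)
            )
            for i in range(10)
        }
        positives = frozenset({("P0", "P1"), ("P2", "P5")})
        K = count_K(a, positives)
        prots = sorted(a)
        expected = sum(
            len(enumerate_cluster_pairs(x, y, a))
            for i, x in enumerate(prots)
            for y in prots[i + 1 :]
            if canonical_pair(x, y) not in positives
        )
        assert sum(K.values()) == expected


class TestInitEM:
    def test_initial_probability_closed_form(self):
        a = _assignment({f"m{i}": {"1"} for i in range(3)} | {f"n{i}": {"2"} for i in range(3)})
        positives = frozenset(
            canonical_pair(f"m{i}", f"n{i}") for i in range(3)
        )
        # M = 3 positives contain {1,2}; with K = 7 the initial estimate is
        # M / (M + N + K) = 3 / 10
        state = init_em(positives, a, {("1", "2"): 7})
        assert state.prob(("1", "2")) == pytest.approx(3 / 10)

    def test_no_scorable_positive_rejected(self):
        with pytest.raises(ValueError):
            init_em(frozenset({("x", "y")}), _assignment({"z": {"1"}}), {})

    def test_unsupported_pair_initializes_to_zero(self):
        a = _assignment({"m": {"1"}, "n": {"2"}, "o": {"1"}, "p": {"2"}})
        positives = frozenset({("m", "n")})
        K = count_K(a, positives)
        state = init_em(positives, a, K)
        # (1,2) occurs in the positive once and in 3 non-positives
        assert state.prob(("1", "2")) == pytest.approx(1 / 4)
        # cluster pairs appearing only in non-positives start at 0
        for k in (("1", "1"), ("2", "2")):
            assert state.prob(k) == 0.0


class TestESten:
    def test_single_cluster_pair_posterior_is_one(self):
        a = _assignment({"m": {"1"}, "n": {"2"}})
        state = init_em(frozenset({("m", "n")}), a, {("1", "2"): 3})
        M, N = e_step(state, frozenset({("m", "n")}), a)
        assert M[("1", "2")] == pytest.approx(1.0)
        assert N[("1", "2")] == pytest.approx(0.0)

    def test_two_pair_posterior_split(self):
        a = _assignment({"m": {"1", "2"}, "n": {"1", "2"}})
        keys = sorted(enumerate_cluster_pairs("m", "n", a))
        state = EMState(
            keys=keys,
            M=np.zeros(len(keys)),
            N=np.zeros(len(keys)),
            K=np.zeros(len(keys)),
            p=np.zeros(len(keys)),
        )
        # keep only two active cluster pairs at p = 0.5 each
        for k in (("1", "2"), ("2", "2")):
            state.p[state.index[k]] = 0.5
        M, N = e_step(state, frozenset({("m", "n")}), a)
        # Pr(L) = 1 - 0.25 = 0.75, each posterior 0.5/0.75 = 2/3
        assert M[("1", "2")] == pytest.approx(2 / 3)
        assert M[("2", "2")] == pytest.approx(2 / 3)
        assert N[("1", "2")] == pytest.approx(1 / 3)

    def test_expected_counts_bounded_by_cluster_pairs(self):
        a = _assignment({"m": {"1", "2"}, "n": {"3"}})
        positives = frozenset({("m", "n")})
        state = init_em(positives, a, {})
        M, N = e_step(state, positives, a)
        assert sum(M.values()) <= len(enumerate_cluster_pairs("m", "n", a)) + 1e-12


class TestMStep:
    @pytest.mark.parametrize(
        "M,N,K,expected",
        [(0.0, 0.0, 0, 0.5), (9.0, 0.0, 0, 10 / 11), (3.0, 2.0, 5, 4 / 12)],
    )
    def test_closed_forms(self, M, N, K, expected):
        p = m_step({("1", "2"): M}, {("1", "2"): N}, {("1", "2"): K})
        assert p[("1", "2")] == pytest.approx(expected)

    def test_monotone_in_counts(self):
        base = m_step({("a", "b"): 3.0}, {("a", "b"): 2.0}, {("a", "b"): 4})[("a", "b")]
        up_m = m_step({("a", "b"): 4.0}, {("a", "b"): 2.0}, {("a", "b"): 4})[("a", "b")]
        up_n = m_step({("a", "b"): 3.0}, {("a", "b"): 3.0}, {("a", "b"): 4})[("a", "b")]
        up_k = m_step({("a", "b"): 3.0}, {("a", "b"): 2.0}, {("a", "b"): 5})[("a", "b")]
        assert up_m > base > up_n and base > up_k


class TestRunEM:
    def test_fixed_point_when_every_positive_has_one_cluster_pair(self):
        # distinct cluster pair per positive, K = 0:
        # posteriors are all 1, so p converges to (M + 1) / (M + 2)
        a = _assignment(
            {"m1": {"1"}, "n1": {"2"}, "m2": {"3"}, "n2": {"4"}}
        )
        positives = frozenset({("m1", "n1"), ("m2", "n2")})
        state = run_em(positives, a, {}, tol=1e-12)
        assert state.converged
        assert state.iteration <= 3
        assert state.prob(("1", "2")) == pytest.approx(2 / 3)
        assert state.prob(("3", "4")) == pytest.approx(2 / 3)

    def test_loglik_nondecreasing_on_random_fixture(self):
        rng = np.random.default_rng(8)
        clusters = [f"C{i}" for i in range(8)]
        a = {
            f"P{i:02d}": frozenset(
                rng.choice(clusters, size=int(rng.integers(1, 4)), replace=False)
            )
            for i in range(30)
        }
        prots = sorted(a)
        all_pairs = [
            canonical_pair(x, y) for i, x in enumerate(prots) for y in prots[i + 1 :]
        ]
        positives = frozenset(
            all_pairs[i] for i in rng.choice(len(all_pairs), 60, replace=False)
        )
        K = count_K(a, positives)
        state = run_em(positives, a, K)
        diffs = np.diff(state.loglik_history)
        assert np.all(diffs >= -1e-9)

    def test_result_independent_of_positive_ordering(self):
        a = _assignment({"m": {"1"}, "n": {"2"}, "o": {"1", "2"}, "q": {"2"}})
        p1 = frozenset({("m", "n"), ("n", "o"), ("m", "q")})
        s1 = run_em(p1, a, count_K(a, p1))
        s2 = run_em(frozenset(sorted(p1, reverse=True)), a, count_K(a, p1))
        assert np.allclose(s1.p, s2.p)


class TestPrediction:
    def _trained_state(self, probs):
        keys = sorted(probs)
        return EMState(
            keys=keys,
            M=np.zeros(len(keys)),
            N=np.zeros(len(keys)),
            K=np.zeros(len(keys)),
            p=np.array([probs[k] for k in keys]),
        )

    def test_single_cluster_pair_passthrough(self):
        a = _assignment({"m": {"1"}, "n": {"2"}})
        state = self._trained_state({("1", "2"): 0.4})
        assert predict_pair("m", "n", state, a) == pytest.approx(0.4)

    def test_noisy_or_combination(self):
        a = _assignment({"m": {"1", "2"}, "n": {"3"}})
        state = self._trained_state({("1", "3"): 0.5, ("2", "3"): 0.5})
        assert predict_pair("m", "n", state, a) == pytest.approx(0.75)

    def test_unseen_cluster_pair_uses_pseudocount_prior(self):
        a = _assignment({"m": {"9"}, "n": {"8"}})
        state = self._trained_state({("1", "2"): 0.4})
        assert predict_pair("m", "n", state, a) == pytest.approx(0.5)

    def test_no_cluster_pairs_is_unscorable(self):
        a = _assignment({"m": {"1"}})
        state = self._trained_state({("1", "2"): 0.4})
        assert predict_pair("m", "x", state, a) is None

    def test_adding_cluster_pair_never_decreases_probability(self):
        state = self._trained_state({("1", "3"): 0.3, ("2", "3"): 0.2})
        a1 = _assignment({"m": {"1"}, "n": {"3"}})
        a2 = _assignment({"m": {"1", "2"}, "n": {"3"}})
        assert predict_pair("m", "n", state, a2) >= predict_pair("m", "n", state, a1)

    def test_rank_predictions_threshold_behavior(self):
        a = _assignment({"m": {"1"}, "n": {"2"}, "o": {"1"}})
        state = self._trained_state({("1", "2"): 0.4})
        cands = [("m", "n"), ("n", "o"), ("m", "q")]  # q carries no cluster
        r0 = rank_predictions(state, a, cands, threshold=0.0)
        r1 = rank_predictions(state, a, cands, threshold=1.0)
        rm = rank_predictions(state, a, cands, threshold=0.41)
        assert set(r0.flagged) == set(r0.probabilities)
        assert r1.flagged == frozenset()
        assert rm.flagged <= r0.flagged
        assert ("m", "q") in r0.unscorable


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_midrank(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_three_of_four_concordant(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_matches_brute_force_concordance(self, rng):
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, labels) == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
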