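import itertools
import math

import numpy as np
import pytest

from demarg.arg import ARG, LocalTree
from demarg.threading import (
    EmissionContext,
    backward_sample,
    emission_likelihood,
    enumerate_states,
    forward_filter,
    sample_threading,
    span_emissions,
    transition_terms,
)
from tests.conftest import make_ctx


def trunk(model, lineage=0):
    pops = model.lineage_pops
    ages = model.lineage_ages
    return LocalTree.single_lineage(
        len(pops), lineage, ages[lineage], model.resident_path_id(pops[lineage])
    )


def exhaustive_posterior(w, E, T):
    """Brute-force sum over all state paths of a small chain."""
    L, S = E.shape
    tot = 0.0
    marg = np.zeros((L, S))
    for path in itertools.product(range(S), repeat=L):
        p = w[path[0]] * E[0, path[0]]
        for c in range(1, L):
            p *= T[path[c - 1], path[c]] * E[c, path[c]]
        tot += p
        for c in range(L):
            marg[c, path[c]] += p
    return tot, marg / tot


class TestStateSpace:
    def test_one_population_reduces_to_branch_time(self, one_pop_model):
        """P = 1: the space is exactly the branch-by-time enumeration."""
        m = one_pop_model
        t = trunk(m, 0)
        st = enumerate_states(t, m, 1)
        assert st.P == 1
        K = m.K
        expected = {(0, j) for j in range(1, K)}  # trunk branch, any time > 0
        assert {(int(b), int(tt)) for b, tt in zip(st.branch, st.time)} == expected

    def test_state_bound(self, two_pop_model_3lin):
        from tests.test_arg import small_arg

        m = two_pop_model_3lin
        arg, _ = small_arg(m, seed=1)
        for _, _, tree in arg.segments():
            for lin in range(4):
                stripped, _ = tree.detach(lin)
                st = enumerate_states(stripped, m, lin)
                n = len(stripped.leaves) + 1
                assert st.S <= n * st.k * st.P

    def test_hand_enumerated_count(self, two_pop_model):
        """2-lineage instance: every (branch, time, path) triple by hand.

        Threading b onto a's trunk (a in A, ages 0): resident path of b is in
        B until the 450 ky join, so resident coalescence only at the top
        (index 4); the migrant path enters A at 150 ky and may coalesce at
        indices 2, 3, 4.
        """
        m = two_pop_model
        st = enumerate_states(trunk(m, 0), m, 1)
        triples = {(int(b), int(t), m.paths[p].is_migrant)
                   for b, t, p in zip(st.branch, st.time, st.path)}
        assert triples == {(0, 4, False), (0, 2, True), (0, 3, True), (0, 4, True)}

    def test_migrant_prior_mass_is_pm(self, two_pop_model):
        st = enumerate_states(trunk(m := two_pop_model, 0), m, 1)
        mig = np.array([m.paths[p].is_migrant for p in st.path])
        assert st.w[mig].sum() == pytest.approx(0.01, rel=1e-9)
        assert st.w.sum() == pytest.approx(1.0)

    def test_constraint_prunes_migrant_paths(self, two_pop_model_3lin):
        """A fixed migrant branch removes migrant paths from the state space
        (but resident coalescence below it stays available)."""
        m = two_pop_model_3lin
        mig_pid = [p for p in m.path_ids_for("B") if m.paths[p].is_migrant][0]
        res_a = m.resident_path_id("A")
        t = trunk(m, 0)
        t = t.attach_leaf(1, 0, 0, 4, res_a)
        t = t.attach_leaf(2, 0, t.root, 3, mig_pid)  # fixed migrant branch
        st = enumerate_states(t, m, 3, max_one_migration=True)
        assert st.P == 1
        assert not any(m.paths[int(p)].is_migrant for p in st.path)
        # without the constraint, migrant paths reappear
        st2 = enumerate_states(t, m, 3, max_one_migration=False)
        assert any(m.paths[int(p)].is_migrant for p in st2.path)


class TestTransitions:
    def test_rows_sum_to_one(self, two_pop_model_3lin, rng):
        from tests.test_arg import small_arg

        m = two_pop_model_3lin
        arg, _ = small_arg(m, seed=2)
        tree = arg.trees[0]
        stripped, _ = tree.detach(3)
        st = enumerate_states(stripped, m, 3)
        T = transition_terms(st, st, 5e-9, 10.0)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_recombination_identity(self, two_pop_model):
        m = two_pop_model
        st = enumerate_states(trunk(m, 0), m, 1)
        T = transition_terms(st, st, 0.0, 10.0)
        assert np.allclose(T, np.eye(st.S))

    def test_cross_span_rows_sum_to_one(self, two_pop_model_3lin):
        from tests.test_arg import small_arg

        m = two_pop_model_3lin
        arg, _ = small_arg(m, seed=3)
        assert arg.n_trees >= 2
        s1, _ = arg.trees[0].detach(2)
        s2, _ = arg.trees[1].detach(2)
        st1 = enumerate_states(s1, m, 2)
        st2 = enumerate_states(s2, m, 2)
        T = transition_terms(st1, st2, 5e-9, 10.0)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-9)


class TestEmissions:
    def test_all_missing_column_is_one(self, two_pop_model):
        m = two_pop_model
        t = trunk(m, 0).attach_leaf(1, 0, 0, 4, m.path_ids_for("B")[0])
        assert emission_likelihood(t, m, np.array([-1, -1], np.int8), 1e-7) \
            == pytest.approx(1.0)

    def test_zero_rate_invariant_column_is_one(self, two_pop_model):
        m = two_pop_model
        t = trunk(m, 0).attach_leaf(1, 0, 0, 4, m.path_ids_for("B")[0])
        assert emission_likelihood(t, m, np.array([0, 0], np.int8), 0.0) \
            == pytest.approx(1.0)

    def test_two_leaf_closed_form(self, two_pop_model):
        """2-leaf tree with one SNP: pruning equals the closed-form
        probability of an odd number of substitutions on the connecting path."""
        m = two_pop_model
        t_idx = 4
        t = trunk(m, 0).attach_leaf(1, 0, 0, t_idx, m.path_ids_for("B")[0])
        mu = 2e-7
        tg = m.time_gens(t_idx)
        p = 0.5 * (1 - math.exp(-2 * mu * tg))  # per-branch flip probability
        p_diff = p * (1 - p)   # the derived-allele branch changed, not the other
        p_same = (1 - p) ** 2  # ancestral state observed at both leaves
        got = emission_likelihood(t, m, np.array([0, 1], np.int8), mu)
        assert got == pytest.approx(p_diff, rel=1e-12)
        got_same = emission_likelihood(t, m, np.array([0, 0], np.int8), mu)
        assert got_same == pytest.approx(p_same, rel=1e-12)

    def test_span_emissions_match_single_column(self, two_pop_model, rng):
        m = two_pop_model
        tr = trunk(m, 0)
        st = enumerate_states(tr, m, 1)
        ctx = make_ctx(2, 5, rng=rng, mu=1.3e-7)
        E = span_emissions(tr, m, 1, st, ctx)
        for i in range(st.S):
            full = tr.attach_leaf(1, 0, int(st.branch[i]), int(st.time[i]),
                                  int(st.path[i]))
            for c in range(5):
                want = emission_likelihood(full, m, ctx.alleles[:, c],
                                           ctx.mu_eff[c])
                # per-column pruning includes the same constant factors
                assert E[c, i] == pytest.approx(want, rel=1e-12)


class TestForwardBackward:
    def test_forward_matches_exhaustive(self, two_pop_model, rng):
        """Likelihood agrees with brute-force path enumeration to 1e-8."""
        m = two_pop_model
        tr = trunk(m, 0)
        st = enumerate_states(tr, m, 1)
        L = 4
        ctx = make_ctx(2, L, rng=rng)
        E = span_emissions(tr, m, 1, st, ctx)
        T = transition_terms(st, st, 5e-9, 10.0)
        tot, _ = exhaustive_posterior(st.w, E, T)
        _, ll = forward_filter(list(E), [T] * (L - 1), st.w)
        assert ll == pytest.approx(math.log(tot), rel=1e-10, abs=1e-8)

    def test_single_state_chain(self):
        E = [np.array([0.3]), np.array([0.5]), np.array([0.2])]
        T = [np.array([[1.0]])] * 2
        _, ll = forward_filter(E, T, np.array([1.0]))
        assert ll == pytest.approx(math.log(0.3 * 0.5 * 0.2))

    def test_emission_scaling_offset(self, two_pop_model, rng):
        m = two_pop_model
        tr = trunk(m, 0)
        st = enumerate_states(tr, m, 1)
        ctx = make_ctx(2, 4, rng=rng)
        E = span_emissions(tr, m, 1, st, ctx)
        T = transition_terms(st, st, 5e-9, 10.0)
        _, ll = forward_filter(list(E), [T] * 3, st.w)
        E2 = E.copy()
        E2[2] *= 7.5
        _, ll2 = forward_filter(list(E2), [T] * 3, st.w)
        assert ll2 - ll == pytest.approx(math.log(7.5))

    def test_forward_matches_log_space(self, two_pop_model, rng):
        """The scaled recursion agrees with a log-space implementation."""
        m = two_pop_model
        tr = trunk(m, 0)
        st = enumerate_states(tr, m, 1)
        L = 6
        ctx = make_ctx(2, L, rng=rng)
        E = span_emissions(tr, m, 1, st, ctx)
        T = transition_terms(st, st, 5e-9, 10.0)
        _, ll = forward_filter(list(E), [T] * (L - 1), st.w)
        logf = np.log(st.w) + np.log(E[0])
        for c in range(1, L):
            prev = logf[:, None] + np.log(T)
            logf = np.log(E[c]) + np.logaddexp.reduce(prev, axis=0)
        assert np.logaddexp.reduce(logf) == pytest.approx(ll, rel=1e-12)

    def test_deterministic_single_state_path(self, rng):
        f = [np.array([1.0])] * 3
        T = [np.array([[1.0]])] * 2
        assert backward_sample(f, T, rng) == [0, 0, 0]

    def test_backward_sample_matches_exact_posterior(self, two_pop_model):
        """Empirical path frequencies match the exhaustive posterior within
        Monte-Carlo error (3 standard errors)."""
        m = two_pop_model
        tr = trunk(m, 0)
        st = enumerate_states(tr, m, 1)
        L = 3
        rng = np.random.default_rng(5)
        ctx = make_ctx(2, L, rng=rng)
        E = span_emissions(tr, m, 1, st, ctx)
        T = transition_terms(st, st, 1e-7, 10.0)  # inflate recomb for mixing
        _, marg = exhaustive_posterior(st.w, E, T)
        fwd, _ = forward_filter(list(E), [T] * (L - 1), st.w)
        n = 10_000
        counts = np.zeros((L, st.S))
        for _ in range(n):
            p = backward_sample(fwd, [T] * (L - 1), rng)
            for c in range(L):
                counts[c, p[c]] += 1
        freq = counts / n
        se = np.sqrt(np.maximum(marg * (1 - marg), 1e-12) / n)
        assert np.all(np.abs(freq - marg) <= 3 * se + 3e-3)

    def test_sample_threading_loglik_matches_dense(self, two_pop_model, rng):
        m = two_pop_model
        tr = trunk(m, 0)
        st = enumerate_states(tr, m, 1)
        L = 5
        ctx = make_ctx(2, L, rng=rng)
        E = span_emissions(tr, m, 1, st, ctx)
        T = transition_terms(st, st, 5e-9, 10.0)
        _, ll = forward_filter(list(E), [T] * (L - 1), st.w)
        arg = ARG(L, [0], [tr])
        _, ll2 = sample_threading(arg, m, ctx, 1, np.random.default_rng(0), 5e-9)
        assert ll2 == pytest.approx(ll, rel=1e-10)


class TestPriorRecovery:
    def test_all_missing_band_posterior_equals_prior(self, two_pop_model):
        """With no data, the posterior probability that the threaded lineage
        crosses the band equals the DP-computed prior (p_M-weighted paths)."""
        m = two_pop_model
        tr = trunk(m, 0)
        st = enumerate_states(tr, m, 1)
        L = 5
        ctx = make_ctx(2, L, missing=True)
        E = span_emissions(tr, m, 1, st, ctx)
        assert np.allclose(E, E[0, 0])  # uninformative everywhere
        T = transition_terms(st, st, 1e-7, 10.0)
        mig = np.array([m.paths[p].is_migrant for p in st.path])
        # DP prior of "any migrant column": 1 - restricted forward mass
        ones = [np.ones(st.S)] * L
        _, ll_all = forward_filter(ones, [T] * (L - 1), st.w)
        resident_only = [np.where(mig, 0.0, 1.0)] * L
        _, ll_res = forward_filter(resident_only, [T] * (L - 1), st.w)
        p_any_prior = 1 - math.exp(ll_res - ll_all)
        # empirical over threading draws
        arg = ARG(L, [0], [tr])
        rng = np.random.default_rng(17)
        n = 4000
        hits = 0
        for _ in range(n):
            pieces, _ = sample_threading(arg, m, ctx, 1, rng, 1e-7)
            if any(m.paths[pid].is_migrant for _, _, (_, _, pid) in pieces):
                hits += 1
        se = math.sqrt(p_any_prior * (1 - p_any_prior) / n)
        assert abs(hits / n - p_any_prior) <= 3 * se + 1e-3
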