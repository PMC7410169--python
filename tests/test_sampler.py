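import math

import numpy as np
import pytest

from demarg.arg import validate_tree
from demarg.io import write_arg_sample
from demarg.sampler import ChainConfig, initialize_arg, resample_phase, run_chain
from demarg.threading import (
    EmissionContext,
    enumerate_states,
    forward_filter,
    transition_terms,
)
from tests.conftest import make_ctx
import io as _io


def serialize(arg, model):
    buf = _io.StringIO()
    write_arg_sample(arg, model, buf, 0)
    return buf.getvalue()


class TestInitialize:
    def test_valid_and_migrant_free(self, two_pop_model_3lin, rng):
        m = two_pop_model_3lin
        ctx = make_ctx(4, 40, rng=rng, mu=1e-6)
        arg = initialize_arg(ctx, m, np.random.default_rng(0), recomb_rate=2e-7)
        for _, _, tree in arg.segments():
            assert validate_tree(tree, m) == []
            assert tree.crossing_nodes(m) == []

    def test_two_lineages_one_column(self, two_pop_model):
        m = two_pop_model
        ctx = make_ctx(2, 1, missing=True)
        arg = initialize_arg(ctx, m, np.random.default_rng(1))
        assert arg.n_trees == 1
        tree = arg.trees[0]
        assert validate_tree(tree, m) == []
        assert len(tree.leaves) == 2

    def test_seed_determinism(self, two_pop_model_3lin, rng):
        m = two_pop_model_3lin
        ctx = make_ctx(4, 30, rng=rng, mu=1e-6)
        a = initialize_arg(ctx, m, np.random.default_rng(7), 2e-7)
        b = initialize_arg(ctx, m, np.random.default_rng(7), 2e-7)
        assert a == b


class TestChain:
    def run(self, model, ctx, **kw):
        cfg = ChainConfig(**kw)
        return list(run_chain(ctx, model, cfg))

    def test_retention_schedule(self, two_pop_model):
        """The production schedule (2000/500/20) retains 75 samples."""
        m = two_pop_model
        ctx = make_ctx(2, 2, missing=True)
        res = self.run(m, ctx, n_iter=2000, burnin=500, thin=20,
                       start_mig=100, seed=1)
        assert sum(r.sample is not None for r in res) == 75
        assert [r.iteration for r in res if r.sample is not None][0] == 520

    def test_no_samples_when_burnin_equals_niter(self, two_pop_model):
        m = two_pop_model
        ctx = make_ctx(2, 2, missing=True)
        res = self.run(m, ctx, n_iter=20, burnin=20, thin=5, start_mig=0, seed=1)
        assert all(r.sample is None for r in res)

    def test_start_mig_blocks_migrants(self, two_pop_model):
        m = two_pop_model
        ctx = make_ctx(2, 10, missing=True)
        res = self.run(m, ctx, n_iter=30, burnin=0, thin=1, start_mig=30, seed=2)
        for r in res:
            if r.sample is not None:
                for _, _, tree in r.sample.segments():
                    assert tree.crossing_nodes(m) == []

    def test_sampled_trees_validate(self, two_pop_model_3lin, rng):
        m = two_pop_model_3lin
        ctx = make_ctx(4, 30, rng=rng, mu=1e-6)
        res = self.run(m, ctx, n_iter=12, burnin=4, thin=2, start_mig=3, seed=3)
        n_samples = 0
        for r in res:
            if r.sample is None:
                continue
            n_samples += 1
            for _, _, tree in r.sample.segments():
                assert validate_tree(tree, m) == []
        assert n_samples == 4

    def test_reproducible_stream(self, two_pop_model_3lin, rng):
        m = two_pop_model_3lin
        ctx = make_ctx(4, 25, rng=rng, mu=1e-6)
        kw = dict(n_iter=10, burnin=2, thin=2, start_mig=2, seed=11)
        a = [serialize(r.sample, m) for r in self.run(m, ctx, **kw) if r.sample]
        b = [serialize(r.sample, m) for r in self.run(m, ctx, **kw) if r.sample]
        assert a == b and len(a) == 4

    def test_bad_config(self):
        with pytest.raises(ValueError):
            ChainConfig(n_iter=10, burnin=20)

    def test_prior_recovery_through_chain(self, two_pop_model):
        """All-missing data, start_mig 0: the long-run fraction of samples
        whose trees contain a migrant branch matches the DP prior."""
        m = two_pop_model
        L = 5
        ctx = make_ctx(2, L, missing=True)
        # DP expectation for the final rethreading of the sweep: lineage b
        # threads onto a's trunk; P(any migrant column) from restricted
        # forward masses
        from demarg.arg import LocalTree

        tr = LocalTree.single_lineage(2, 0, 0, m.resident_path_id("A"))
        st = enumerate_states(tr, m, 1)
        T = transition_terms(st, st, 5e-9, 10.0)
        mig = np.array([m.paths[p].is_migrant for p in st.path])
        ones = [np.ones(st.S)] * L
        _, ll_all = forward_filter(ones, [T] * (L - 1), st.w)
        resident = [np.where(mig, 0.0, 1.0)] * L
        _, ll_res = forward_filter(resident, [T] * (L - 1), st.w)
        expect = 1 - math.exp(ll_res - ll_all)
        res = self.run(m, ctx, n_iter=3000, burnin=100, thin=1, start_mig=0,
                       seed=5)
        hits = [
            any(tree.crossing_nodes(m) for _, _, tree in r.sample.segments())
            for r in res if r.sample is not None
        ]
        freq = np.mean(hits)
        se = math.sqrt(expect * (1 - expect) / len(hits))
        assert abs(freq - expect) <= 4 * se + 5e-3


class TestPhase:
    def test_phased_individuals_not_resampled(self, rng):
        from demarg.demography import (
            DemographicModel, Population, SampleConfig, build_time_grid,
        )

        m = DemographicModel(
            grid=build_time_grid([0, 100e3, 400e3]),
            populations=[Population("A", sizes=1e4)],
            samples=[SampleConfig("d", "A", ploidy=2, phased=True)],
        )
        from demarg.sampler import _unphased_pairs

        assert _unphased_pairs(m) == {}

    def test_homozygous_columns_unchanged(self, two_pop_model, rng):
        from demarg.demography import (
            DemographicModel, Population, SampleConfig, build_time_grid,
        )

        m = DemographicModel(
            grid=build_time_grid([0, 100e3, 400e3]),
            populations=[Population("A", sizes=1e4)],
            samples=[SampleConfig("d", "A", ploidy=2, phased=False),
                     SampleConfig("h", "A", ploidy=1)],
        )
        ctx = make_ctx(3, 20, mu=1e-6)
        ctx.alleles[:2, :] = 1  # homozygous derived everywhere
        arg = initialize_arg(ctx, m, np.random.default_rng(0))
        before = ctx.alleles.copy()
        swapped = resample_phase(arg, m, ctx, (0, 1), np.random.default_rng(1))
        assert swapped == 0
        np.testing.assert_array_equal(ctx.alleles, before)

    def test_symmetric_data_long_run_half(self):
        """Two exchangeable lineages with symmetric data end up with each
        phase assignment about half the time."""
        from demarg.demography import (
            DemographicModel, Population, SampleConfig, build_time_grid,
        )

        m = DemographicModel(
            grid=build_time_grid([0, 100e3, 400e3]),
            populations=[Population("A", sizes=1e4)],
            samples=[SampleConfig("d", "A", ploidy=2, phased=False),
                     SampleConfig("h", "A", ploidy=1)],
        )
        ctx = make_ctx(3, 1, mu=1e-6)
        ctx.alleles[0, 0] = 0
        ctx.alleles[1, 0] = 1
        ctx.alleles[2, 0] = -1
        rng = np.random.default_rng(2)
        arg = initialize_arg(ctx, m, rng)
        n = 2000
        ones = 0
        for _ in range(n):
            resample_phase(arg, m, ctx, (0, 1), rng)
            ones += int(ctx.alleles[0, 0] == 1)
        se = 0.5 / math.sqrt(n)
        assert abs(ones / n - 0.5) <= 4 * se
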