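import numpy as np
import pytest

from demarg.arg import ARG, LocalTree
from demarg.calling import (
    PosteriorTrack,
    RegionCall,
    call_regions,
    coverage,
    frequency_classify,
    migrant_indicator,
    posterior_tracks,
)
from demarg.demography import (
    DemographicModel,
    MigrationBand,
    Population,
    SampleConfig,
    build_time_grid,
)


@pytest.fixture(scope="module")
def diploid_model():
    """One diploid recipient in B plus one haploid in A, with a band."""
    return DemographicModel(
        grid=build_time_grid([0, 100e3, 200e3, 300e3, 500e3]),
        populations=[
            Population("Anc", sizes=10_000),
            Population("A", parent="Anc", divergence_time=450e3, sizes=10_000),
            Population("B", parent="Anc", divergence_time=450e3, sizes=5_000),
        ],
        bands=[MigrationBand("A", "B", 150e3, 0.01)],
        samples=[
            SampleConfig("out", "A", ploidy=1),
            SampleConfig("ind", "B", ploidy=2, phased=False),
        ],
    )


def _trees(m):
    """none / het (one migrant lineage) / hom (shared migrant ancestor)."""
    res_a = m.resident_path_id("A")
    res_b = m.resident_path_id("B")
    mig = [p for p in m.path_ids_for("B") if m.paths[p].is_migrant][0]
    base = LocalTree.single_lineage(3, 0, 0, res_a)
    t_none = base.attach_leaf(1, 0, 0, 4, res_b)
    t_none = t_none.attach_leaf(2, 0, 1, 1, res_b)
    t_het = base.attach_leaf(1, 0, 0, 3, mig)
    t_het = t_het.attach_leaf(2, 0, 0, 4, res_b)
    # hom: the two B lineages coalesce below the band; their shared ancestral
    # branch crosses it
    t_hom = base.attach_leaf(1, 0, 0, 3, mig)
    t_hom = t_hom.attach_leaf(2, 0, 1, 1, res_b)
    return t_none, t_het, t_hom


def one_tree_arg(tree, L=10):
    return ARG(L, [0], [tree])


class TestPosteriorTracks:
    def test_fraction_arithmetic(self, diploid_model):
        """30 het + 15 hom out of 75 samples -> P_het .4, P_hom .2, P_any .6."""
        m = diploid_model
        t_none, t_het, t_hom = _trees(m)
        samples = [one_tree_arg(t_het)] * 30 + [one_tree_arg(t_hom)] * 15 \
            + [one_tree_arg(t_none)] * 30
        starts = np.arange(10) * 10
        ends = starts + 10
        tr = posterior_tracks(samples, m, "A->B", "ind", starts, ends)
        assert np.allclose(tr.p_het, 0.4)
        assert np.allclose(tr.p_hom, 0.2)
        assert np.allclose(tr.p_any, 0.6)

    def test_hom_when_both_lineages_migrant(self, diploid_model):
        m = diploid_model
        _, _, t_hom = _trees(m)
        assert migrant_indicator(one_tree_arg(t_hom), m, "A->B", 1).all()
        assert migrant_indicator(one_tree_arg(t_hom), m, "A->B", 2).all()
        tr = posterior_tracks([one_tree_arg(t_hom)], m, "A->B", "ind",
                              np.arange(10) * 10, np.arange(10) * 10 + 10)
        assert np.allclose(tr.p_hom, 1.0) and np.allclose(tr.p_het, 0.0)

    def test_no_migrants_zero_track(self, diploid_model):
        m = diploid_model
        t_none, _, _ = _trees(m)
        tr = posterior_tracks([one_tree_arg(t_none)], m, "A->B", "ind",
                              np.arange(10) * 10, np.arange(10) * 10 + 10)
        assert not tr.p_any.any()

    def test_identity_enforced(self):
        with pytest.raises(ValueError):
            PosteriorTrack("b", "i", np.array([0.5]), np.array([0.1]),
                           np.array([0.1]), np.array([0]), np.array([10]))

    def test_unknown_band_rejected(self, diploid_model):
        m = diploid_model
        t_none, _, _ = _trees(m)
        with pytest.raises(Exception):
            posterior_tracks([one_tree_arg(t_none)], m, "X->Y", "ind",
                             np.arange(10), np.arange(10) + 1)


def make_track(p_any, p_hom=None, width=10):
    p_any = np.asarray(p_any, dtype=float)
    p_hom = np.zeros_like(p_any) if p_hom is None else np.asarray(p_hom)
    starts = np.arange(len(p_any)) * width
    return PosteriorTrack("A->B", "ind", p_any, p_any - p_hom, p_hom,
                          starts, starts + width)


class TestCallRegions:
    def test_all_below_threshold(self):
        assert call_regions(make_track([0.2, 0.4, 0.1])) == []

    def test_step_track_bp_extent(self):
        """10 columns at 0.9 with compression 10 call exactly 100 bp."""
        p = [0.0] * 5 + [0.9] * 10 + [0.0] * 5
        calls = call_regions(make_track(p))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (50, 150)

    def test_threshold_inclusive(self):
        calls = call_regions(make_track([0.0, 0.5, 0.0]))
        assert len(calls) == 1 and calls[0].length == 10

    def test_zygosity_majority(self):
        p_any = np.array([0.9] * 4)
        p_hom = np.array([0.8, 0.8, 0.8, 0.1])
        (call,) = call_regions(make_track(p_any, p_hom))
        assert call.zygosity == "hom"

    def test_no_merging_across_gap(self):
        calls = call_regions(make_track([0.9, 0.1, 0.9]))
        assert len(calls) == 2
        merged = call_regions(make_track([0.9, 0.1, 0.9]), merge_distance=15)
        assert len(merged) == 1

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            call_regions(make_track([0.5]), threshold=0.0)


class TestCoverage:
    def test_half_het_plus_hom(self):
        assert coverage(0.02, 0.01, 1.0) == pytest.approx(0.02)

    def test_no_calls(self):
        assert coverage(0, 0, 1e6) == 0.0

    def test_whole_window_hom(self):
        assert coverage(0, 2e6, 2e6) == 1.0

    def test_zero_callable(self):
        with pytest.raises(ValueError):
            coverage(1, 1, 0)

    def test_overflow_rejected(self):
        with pytest.raises(ValueError):
            coverage(900, 200, 1000)


class TestFrequencyClassify:
    def c(self, s, e, zyg, ind):
        return RegionCall("chr", s, e, "A->B", ind, zyg, 0.9)

    def test_doubly_homozygous(self):
        atoms, frac = frequency_classify(
            {"x": [self.c(0, 100, "hom", "x")], "y": [self.c(0, 100, "hom", "y")]},
            "A->B",
        )
        assert frac == {("hom", "hom"): 1.0}

    def test_singleton_het(self):
        atoms, frac = frequency_classify(
            {"x": [self.c(0, 50, "het", "x")], "y": []}, "A->B"
        )
        assert frac == {("het", "none"): 1.0}

    def test_fractions_match_direct_count(self):
        calls = {
            "x": [self.c(0, 100, "hom", "x"), self.c(200, 260, "het", "x")],
            "y": [self.c(50, 150, "het", "y")],
        }
        atoms, frac = frequency_classify(calls, "A->B")
        # direct tally: [0,50) hom/none, [50,100) hom/het, [100,150) none/het,
        # [200,260) het/none -> 210 called bp in total
        assert frac[("hom", "none")] == pytest.approx(50 / 210)
        assert frac[("hom", "het")] == pytest.approx(50 / 210)
        assert frac[("none", "het")] == pytest.approx(50 / 210)
        assert frac[("het", "none")] == pytest.approx(60 / 210)
        assert sum(frac.values()) == pytest.approx(1.0)
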