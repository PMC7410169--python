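import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demarg.demography import (
    DemographicModel,
    MigrationBand,
    ModelError,
    Population,
    SampleConfig,
    build_time_grid,
    enumerate_paths,
    scale_model,
    snap_to_half_time,
)
from demarg.demography import default_time_grid
from demarg.presets import deep_introgression_model


class TestTimeGrid:
    def test_default_grid_half_times(self):
        """The 20-point grid yields half times 50/150/250/350 ky near the leaves."""
        g = default_time_grid()
        assert g.K == 20
        assert [t / 1e3 for t in g.half_times[:4]] == [50, 150, 250, 350]

    @pytest.mark.parametrize(
        "times,expected_half",
        [
            ([0, 100e3], [50e3]),
            ([0, 100e3, 300e3], [50e3, 200e3]),
        ],
    )
    def test_midpoints(self, times, expected_half):
        g = build_time_grid(times)
        assert list(g.half_times) == expected_half

    @pytest.mark.parametrize("bad", [[100, 200], [0, 200, 100], [0, 100, 100], [0]])
    def test_invalid_grids_rejected(self, bad):
        with pytest.raises(ModelError):
            build_time_grid(bad)


class TestSnapping:
    def test_exact_half_time_fixed_point(self):
        m = deep_introgression_model()
        assert snap_to_half_time(m, 250e3) == 250e3

    def test_nearest(self):
        m = deep_introgression_model()
        assert snap_to_half_time(m, 240e3) == 250e3

    def test_tie_breaks_younger(self):
        m = deep_introgression_model()
        # 100 ky is equidistant from the 50 and 150 ky half time-points
        assert snap_to_half_time(m, 100e3) == 50e3

    def test_out_of_range(self):
        m = deep_introgression_model()
        with pytest.raises(ModelError):
            snap_to_half_time(m, 20e9)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=0, max_value=15e6, allow_nan=False))
    def test_idempotent(self, t):
        m = deep_introgression_model()
        once = snap_to_half_time(m, t)
        assert snap_to_half_time(m, once) == once


class TestPaths:
    def test_no_bands_single_path(self, one_pop_model):
        paths = enumerate_paths(one_pop_model, "A")
        assert len(paths) == 1 and not paths[0].is_migrant

    def test_no_bands_path_equals_lineage_map(self):
        m = deep_introgression_model(include_controls=False)
        m_noband = DemographicModel(
            grid=m.grid, populations=m.populations, bands=[], samples=m.samples
        )
        for pop in ("Afr", "Nea", "Den"):
            (p,) = enumerate_paths(m_noband, pop)
            assert list(p.pops) == list(m_noband.resident_map(pop))

    def test_denisovan_two_paths_with_single_band(self):
        """With only the Sup->Den band, a Denisovan lineage has a resident and
        a migrant path into the super-archaic branch."""
        m = deep_introgression_model(include_controls=False)
        paths = enumerate_paths(m, "Den")
        den_paths = [p for p in paths if p.band is None or
                     m.bands[p.band].name == "Sup->Den"]
        assert len(den_paths) == 2
        mig = [p for p in den_paths if p.is_migrant][0]
        assert m.pop_names[mig.pops[mig.band_j + 1]] == "Sup"

    def test_neanderthal_three_paths(self):
        """Hum->Nea plus Sup->Nea bands give a Neanderthal lineage 3 paths."""
        m = deep_introgression_model(include_controls=True)
        nea = enumerate_paths(m, "Nea")
        assert len(nea) == 3

    def test_path_count_bound(self):
        m = deep_introgression_model(include_controls=True)
        for i, p in enumerate(m.populations):
            if p.is_ghost:
                continue
            resident = m.resident_map(i)
            n_dest = sum(
                1 for bi, b in enumerate(m.bands)
                if resident[m._band_j[bi]] == m.pop_index[b.dest]
            )
            assert len(m.path_ids_for(i)) <= 1 + n_dest

    def test_unknown_population(self, two_pop_model):
        with pytest.raises(ModelError):
            enumerate_paths(two_pop_model, "Zzz")

    def test_ghost_start_rejected(self):
        m = deep_introgression_model()
        with pytest.raises(ModelError):
            enumerate_paths(m, "Sup")


class TestScaling:
    def test_african_size_scaled(self):
        m = deep_introgression_model()
        s = scale_model(m, 0.75)
        afr = s.populations[s.pop_index["Afr"]]
        assert afr.sizes == pytest.approx(17_775)

    def test_identity(self, two_pop_model):
        s = scale_model(two_pop_model, 1.0)
        assert np.array_equal(s._size, two_pop_model._size)

    def test_piecewise_scaled(self):
        m = deep_introgression_model()
        s = scale_model(m, 0.5)
        assert s.size_at(s.pop_index["Nea"], 0) == \
            m.size_at(m.pop_index["Nea"], 0) * 0.5

    def test_bad_factor(self, two_pop_model):
        with pytest.raises(ModelError):
            scale_model(two_pop_model, 0.0)


class TestModelValidation:
    def test_ancient_ages_snap_to_grid(self):
        """Sampling ages of 52/115/72 ky all map to the 100 ky grid point."""
        m = deep_introgression_model()
        ages = dict(zip(m.lineage_names, m.lineage_ages))
        assert ages["Altai_1"] == ages["Vindija_1"] == ages["Denisova_1"] == 1
        assert ages["Afr1_1"] == 0 and ages["Chimp"] == 0

    def test_exactly_one_root(self):
        with pytest.raises(ModelError):
            DemographicModel(
                grid=build_time_grid([0, 100e3]),
                populations=[Population("A", sizes=1e4), Population("B", sizes=1e4)],
            )

    def test_band_must_predate_divergence(self):
        with pytest.raises(ModelError):
            DemographicModel(
                grid=build_time_grid([0, 100e3, 200e3, 400e3]),
                populations=[
                    Population("Anc", sizes=1e4),
                    Population("A", parent="Anc", divergence_time=150e3, sizes=1e4),
                    Population("B", parent="Anc", divergence_time=150e3, sizes=1e4),
                ],
                bands=[MigrationBand("A", "B", 300e3)],
            )

    def test_ghost_cannot_carry_samples(self):
        with pytest.raises(ModelError):
            DemographicModel(
                grid=build_time_grid([0, 100e3, 400e3]),
                populations=[
                    Population("Anc", sizes=1e4),
                    Population("G", parent="Anc", divergence_time=250e3,
                               is_ghost=True),
                ],
                samples=[SampleConfig("g", "G", ploidy=1)],
            )

    def test_prior_rate_bounds(self):
        with pytest.raises(ModelError):
            DemographicModel(
                grid=build_time_grid([0, 100e3, 200e3, 400e3]),
                populations=[
                    Population("Anc", sizes=1e4),
                    Population("A", parent="Anc", divergence_time=350e3, sizes=1e4),
                    Population("B", parent="Anc", divergence_time=350e3, sizes=1e4),
                ],
                bands=[MigrationBand("A", "B", 150e3, prior_rate=1.5)],
            )

    def test_non_ghost_needs_sizes(self):
        with pytest.raises(ModelError):
            DemographicModel(
                grid=build_time_grid([0, 100e3]),
                populations=[Population("A")],
            )
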