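import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dungsight.survey_data import (
    DEFAULT_CUTPOINTS, SchemaError, ValidationError, aggregate_quadrats,
    bin_distances, filter_middens, load_survey,
)


class TestLoadSurvey:
    def test_round_trip_preserves_design(self, survey_csvs, default_survey):
        ds = load_survey(*survey_csvs)
        assert ds.n_transects == 36
        assert ds.n_pairs == 18
        assert ds.n_wadi_systems == 8
        pd.testing.assert_frame_equal(ds.transects, default_survey.transects)
        pd.testing.assert_frame_equal(ds.events, default_survey.events)

    def test_distance_beyond_half_width_rejected(self, tmp_path, default_survey):
        ds = default_survey
        events = ds.events.copy()
        events.loc[0, "distance_m"] = 5.0
        paths = (tmp_path / "e.csv", tmp_path / "t.csv", tmp_path / "q.csv")
        events.to_csv(paths[0], index=False)
        ds.transects.to_csv(paths[1], index=False)
        ds.quadrats.to_csv(paths[2], index=False)
        with pytest.raises(ValidationError, match="half-width"):
            load_survey(*paths)

    def test_missing_column_names_it(self, tmp_path, default_survey):
        ds = default_survey
        paths = (tmp_path / "e.csv", tmp_path / "t.csv", tmp_path / "q.csv")
        ds.events.drop(columns=["distance_m"]).to_csv(paths[0], index=False)
        ds.transects.to_csv(paths[1], index=False)
        ds.quadrats.to_csv(paths[2], index=False)
        with pytest.raises(SchemaError, match="distance_m"):
            load_survey(*paths)

    def test_unknown_species_rejected(self, tmp_path, default_survey):
        ds = default_survey
        events = ds.events.copy()
        events.loc[0, "species"] = "ibex"
        paths = (tmp_path / "e.csv", tmp_path / "t.csv", tmp_path / "q.csv")
        events.to_csv(paths[0], index=False)
        ds.transects.to_csv(paths[1], index=False)
        ds.quadrats.to_csv(paths[2], index=False)
        with pytest.raises(ValidationError, match="ibex"):
            load_survey(*paths)

    def test_short_quadrat_set_tolerated_with_warning(self, tmp_path,
                                                      default_survey, caplog):
        ds = default_survey
        tid = ds.transects["transect_id"].iloc[0]
        quads = ds.quadrats[~((ds.quadrats.transect_id == tid)
                              & (ds.quadrats.quadrat_idx == 11))]
        paths = (tmp_path / "e.csv", tmp_path / "t.csv", tmp_path / "q.csv")
        ds.events.to_csv(paths[0], index=False)
        ds.transects.to_csv(paths[1], index=False)
        quads.to_csv(paths[2], index=False)
        with caplog.at_level("WARNING"):
            out = load_survey(*paths)
        assert out.n_transects == 36
        assert any("10 quadrats" in r.message for r in caplog.records)


class TestFilterMiddens:
    def test_study_scale_accounting(self, study_scale_events):
        retained, bk = filter_middens(study_scale_events)
        assert bk.loc["oryx", "retained"] == 628
        assert bk.loc["gazelle", "retained"] == 132
        assert bk.loc["combined", "recorded"] == 825
        assert bk.loc["combined", "middens"] == 65
        assert len(retained) == 760

    def test_no_middens_is_identity(self, default_survey):
        clean = default_survey.events[default_survey.events.is_midden == 0]
        retained, bk = filter_middens(clean)
        pd.testing.assert_frame_equal(retained, clean.reset_index(drop=True))
        assert (bk["middens"] == 0).all()

    def test_empty_input_gives_zeros(self):
        empty = pd.DataFrame(columns=["transect_id", "species", "distance_m",
                                      "n_pellets", "is_midden"])
        retained, bk = filter_middens(empty)
        assert len(retained) == 0
        assert (bk == 0).all().all()


class TestBinDistances:
    def test_one_event_per_interval(self, default_survey):
        tr = default_survey.transects.iloc[:1]
        ev = pd.DataFrame({
            "transect_id": tr.transect_id.iloc[0], "species": "oryx",
            "distance_m": [0.5, 1.5, 3.0], "n_pellets": 10, "is_midden": 0})
        out = bin_distances(ev, tr, DEFAULT_CUTPOINTS)
        row = out[(out.species == "oryx")].iloc[0]
        assert (row[["bin_1", "bin_2", "bin_3"]] == [1, 1, 1]).all()

    def test_interior_cutpoint_goes_to_farther_interval(self, default_survey):
        tr = default_survey.transects.iloc[:1]
        ev = pd.DataFrame({
            "transect_id": tr.transect_id.iloc[0], "species": "oryx",
            "distance_m": [DEFAULT_CUTPOINTS[1]], "n_pellets": 10,
            "is_midden": 0})
        out = bin_distances(ev, tr, DEFAULT_CUTPOINTS)
        row = out[out.species == "oryx"].iloc[0]
        assert (row[["bin_1", "bin_2", "bin_3"]] == [0, 1, 0]).all()

    def test_outer_boundary_included(self, default_survey):
        tr = default_survey.transects.iloc[:1]
        ev = pd.DataFrame({
            "transect_id": tr.transect_id.iloc[0], "species": "gazelle",
            "distance_m": [4.0], "n_pellets": 10, "is_midden": 0})
        out = bin_distances(ev, tr, DEFAULT_CUTPOINTS)
        assert out[out.species == "gazelle"].iloc[0]["bin_3"] == 1

    def test_no_events_all_zero(self, default_survey):
        empty = default_survey.events.iloc[:0]
        out = bin_distances(empty, default_survey.transects)
        assert (out.filter(like="bin_") == 0).all().all()

    def test_totals_conserved_after_midden_filter(self, default_survey,
                                                  default_binned):
        """Sum of bins equals recorded minus middens, per species."""
        _, bk = filter_middens(default_survey.events)
        bins = default_binned.filter(like="bin_").sum(axis=1)
        for sp in ("oryx", "gazelle"):
            total = bins[default_binned.species == sp].sum()
            assert total == bk.loc[sp, "retained"]

    def test_out_of_range_distance_raises(self, default_survey):
        tr = default_survey.transects.iloc[:1]
        ev = pd.DataFrame({
            "transect_id": tr.transect_id.iloc[0], "species": "oryx",
            "distance_m": [4.5], "n_pellets": 10, "is_midden": 0})
        with pytest.raises(ValidationError):
            bin_distances(ev, tr, DEFAULT_CUTPOINTS)


def _two_quadrat_frame(rock=(20.0, 40.0), wet=(10.0, 10.0), dry=(4.0, 4.0),
                       species=("a;b", "b;c")):
    n = len(rock)
    return pd.DataFrame({
        "transect_id": ["T1"] * n, "quadrat_idx": range(1, n + 1),
        "rock_pct": rock, "litter_pct": 5.0, "herb_pct": 10.0,
        "shrub_pct": 5.0, "tree_pct": 1.0, "herb_height_cm": 12.0,
        "shrub_height_cm": 50.0, "tree_height_cm": 150.0,
        "richness": [len(s.split(";")) for s in species],
        "species_list": species,
        "nonwoody_wet_g": wet, "nonwoody_dry_g": dry, "woody_g": 3.0,
    })


def _one_transect_frame():
    return pd.DataFrame({
        "transect_id": ["T1"], "pair_id": ["P1"], "wadi_system": ["W1"],
        "habitat": ["wadi"], "length_m": [200.0], "half_width_m": [4.0],
        "north_south": [0.0], "east_west": [0.0], "predator_scats": [2]})


class TestAggregateQuadrats:
    def test_cover_is_mean_over_quadrats(self):
        out = aggregate_quadrats(_two_quadrat_frame(), _one_transect_frame())
        assert out.loc[0, "rock_cover"] == pytest.approx(30.0)

    def test_water_content_from_masses(self):
        out = aggregate_quadrats(_two_quadrat_frame(), _one_transect_frame())
        assert out.loc[0, "plant_water"] == pytest.approx(60.0)

    def test_richness_pooled_vs_mean(self):
        q, t = _two_quadrat_frame(), _one_transect_frame()
        pooled = aggregate_quadrats(q, t, richness_mode="pooled")
        mean = aggregate_quadrats(q, t, richness_mode="mean")
        assert pooled.loc[0, "richness"] == 3
        assert mean.loc[0, "richness"] == 2

    def test_zero_dry_mass_warns_and_gives_full_water(self, caplog):
        q = _two_quadrat_frame(dry=(0.0, 0.0))
        with caplog.at_level("WARNING"):
            out = aggregate_quadrats(q, _one_transect_frame())
        assert out.loc[0, "plant_water"] == pytest.approx(100.0)
        assert any("dry mass" in r.message for r in caplog.records)

    def test_permutation_invariant(self, default_survey):
        q = default_survey.quadrats
        shuffled = q.sample(frac=1.0, random_state=3)
        a = aggregate_quadrats(q, default_survey.transects)
        b = aggregate_quadrats(shuffled, default_survey.transects)
        a = a.sort_values("transect_id").reset_index(drop=True)
        b = b.sort_values("transect_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


@settings(deadline=None, max_examples=25)
@given(st.lists(st.floats(min_value=0.0, max_value=4.0), min_size=0,
                max_size=60))
def test_binning_conserves_count(distances):
    """Every retained event lands in exactly one interval."""
    tr = _one_transect_frame()
    ev = pd.DataFrame({"transect_id": "T1", "species": "oryx",
                       "distance_m": distances, "n_pellets": 10,
                       "is_midden": 0})
    out = bin_distances(ev, tr, DEFAULT_CUTPOINTS)
    assert out.filter(like="bin_").to_numpy().sum() == len(distances)
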