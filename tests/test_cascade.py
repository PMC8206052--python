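"""Identification cascade: filters, database matching, quality, confirmation."""

import numpy as np
import pandas as pd
import pytest

from polarscreen import cascade as casc
from polarscreen.core import CompoundRecord, Feature, FeatureMember
from polarscreen.extraction import FactorSettings, extract_features
from polarscreen.io import load_candidate_table, load_compound_database
from polarscreen.simulate import TrueCompound, generate_campaign
from tests.conftest import ZERO_DRIFT, small_config, small_truth


def make_feature(mass, rt, fid=1, samples=("s1",), intensity=1e4, n_ions=1, iso=False):
    f = Feature(
        feature_id=fid,
        members=[FeatureMember(s, mass, rt, intensity, n_ions=n_ions,
                               has_isotope_pattern=iso) for s in samples],
        target_mass=mass,
    )
    return f.refresh()


class TestBlankExclusion:
    def test_empty_blank_removes_nothing(self):
        feats = [make_feature(100.0, 5.0), make_feature(200.0, 6.0)]
        assert casc.exclude_blank_masses(feats, []) == feats

    def test_matching_mass_removed_regardless_of_rt(self):
        feats = [make_feature(100.0, 5.0), make_feature(200.0, 6.0)]
        blank = [make_feature(100.0, 12.0)]  # very different RT
        kept = casc.exclude_blank_masses(feats, blank, mass_tolerance_ppm=10.0)
        assert [f.median_mass for f in kept] == [200.0]

    def test_planted_contaminants_are_exactly_the_removed_features(self):
        truth = small_truth() + [
            TrueCompound("contam1", 180.0500, 7.2, is_contaminant=True),
            TrueCompound("contam2", 240.1200, 12.3, is_contaminant=True),
        ]
        camp = generate_campaign(small_config(), truth, ZERO_DRIFT)
        settings = FactorSettings(f6_post_targeted_height_filter=1000.0,
                                  f7_post_integration_height_filter=1000.0)
        feats = extract_features(camp.sample_runs, settings)
        blank_feats = extract_features([camp.blank_run], settings)
        report = casc.FilterReport()
        kept = casc.exclude_blank_masses(feats, blank_feats, 50.0, report)
        removed = {round(f.median_mass, 2) for f in feats} - {
            round(f.median_mass, 2) for f in kept
        }
        assert removed == {180.05, 240.12}
        assert report.stages[0]["n_in"] - report.stages[0]["n_out"] == 2


class TestRtWindow:
    @pytest.mark.parametrize("rt, kept", [(16.9, True), (17.0, True), (17.1, False)])
    def test_boundary_is_inclusive_at_17(self, rt, kept):
        feats = casc.filter_rt_window([make_feature(100.0, rt)])
        assert bool(feats) == kept

    def test_rplc_features_are_removed_from_the_reference_preset(self, reference_campaign):
        led = reference_campaign.ledger
        rplc_ids = {c.compound_id for c in reference_campaign.truth if c.base_rt > 20}
        feats = [
            make_feature(row.mz - 1.00728, row.apex_rt, fid=i)
            for i, row in enumerate(
                led[(~led.is_noise)].groupby("compound_id").first().itertuples()
            )
        ]
        kept = casc.filter_rt_window(feats)
        assert all(f.median_rt <= 17.0 for f in kept)


class TestDetectionFrequency:
    def test_three_sample_threshold(self):
        f3 = make_feature(100.0, 5.0, samples=("a", "b", "c"))
        f2 = make_feature(100.5, 5.0, samples=("a", "b"))
        assert casc.filter_detection_frequency([f3, f2]) == [f3]

    def test_min_one_is_identity(self):
        feats = [make_feature(100.0, 5.0), make_feature(101.0, 6.0)]
        assert casc.filter_detection_frequency(feats, min_samples=1) == feats

    def test_rt_and_frequency_filters_commute(self):
        feats = [
            make_feature(100.0, 10.0, samples=("a", "b", "c")),
            make_feature(110.0, 20.0, samples=("a", "b", "c", "d")),
            make_feature(120.0, 12.0, samples=("a",)),
            make_feature(130.0, 25.0, samples=("a", "b")),
        ]
        ab = casc.filter_detection_frequency(casc.filter_rt_window(feats))
        ba = casc.filter_rt_window(casc.filter_detection_frequency(feats))
        assert ab == ba


class TestDatabaseMatching:
    def test_guanylurea_matches_at_4_9_ppm(self):
        db = load_compound_database()
        feats = [make_feature(102.0547, 14.6)]
        matches = casc.match_database(feats, db)
        guanylurea = [m for m in matches if "uanylurea" in m.record.name]
        assert guanylurea
        from polarscreen.core import round_reported

        assert round_reported(guanylurea[0].ppm) == 4.9

    def test_feature_outside_tolerance_finds_nothing(self):
        db = [CompoundRecord("x", "KEY", 200.0000, -1.0)]
        feats = [make_feature(200.0 * (1 + 11e-6), 8.0)]
        assert casc.match_database(feats, db, tolerance_ppm=10.0) == []

    def test_three_features_all_match_melamine(self):
        db = load_compound_database()
        feats = [
            make_feature(126.0651, 7.2),
            make_feature(126.0655, 6.9),
            make_feature(126.0665, 8.4),
        ]
        matches = casc.match_database(feats, db)
        mel = [m for m in matches if m.record.name == "Melamine"]
        assert len(mel) == 3

    def test_empty_database_is_an_error(self):
        with pytest.raises(ValueError):
            casc.match_database([make_feature(100.0, 5.0)], [])


class TestLogDFilter:
    def _match(self, logd):
        record = CompoundRecord("c", "KEY", 100.0, logd)
        return casc.CandidateMatch(make_feature(100.0, 5.0), record, 0.0)

    @pytest.mark.parametrize("logd, kept", [(-2.1, True), (0.0, False), (1.5, False)])
    def test_strict_negative_threshold(self, logd, kept):
        result = casc.filter_logd([self._match(logd)])
        assert bool(result) == kept

    def test_missing_logd_is_flagged_and_excluded(self):
        m = self._match(None)
        report = casc.FilterReport()
        assert casc.filter_logd([m], report=report) == []
        assert m.passes_logd is False
        assert "missing log D" in report.stages[0]["note"]


class TestPeakQuality:
    def test_clean_isotope_feature_passes_all_criteria(self, clean_campaign,
                                                       permissive_settings):
        feats = extract_features(clean_campaign.sample_runs, permissive_settings)
        assert feats
        for f in feats:
            q = casc.assess_peak_quality(f)
            assert q.mass_spread_ok and q.gaussian_ok
            assert q.min_two_ions_ok and q.isotope_pattern_ok
            assert q.overall

    def test_single_ion_feature_fails(self):
        f = make_feature(100.0, 5.0, n_ions=1)
        q = casc.assess_peak_quality(f)
        assert not q.min_two_ions_ok and not q.overall

    def test_wide_mass_spread_fails(self):
        f = Feature(
            feature_id=1,
            members=[
                FeatureMember("a", 100.0000, 5.0, 1e4, n_ions=2, has_isotope_pattern=True),
                FeatureMember("b", 100.0 * (1 + 12e-6), 5.0, 1e4, n_ions=2,
                              has_isotope_pattern=True),
            ],
        ).refresh()
        assert not casc.assess_peak_quality(f).mass_spread_ok


class TestDedupe:
    def test_reference_candidate_table_counts(self):
        n_compounds, n_features, _ = casc.dedupe_candidates(load_candidate_table())
        assert (n_compounds, n_features) == (64, 46)

    def test_shared_compound_counted_once(self):
        record = CompoundRecord("c", "KEY", 100.0, -1.0)
        matches = [
            casc.CandidateMatch(make_feature(100.0, 5.0), record, 0.0),
            casc.CandidateMatch(make_feature(100.0005, 9.0), record, 5.0),
        ]
        n_compounds, n_features, _ = casc.dedupe_candidates(matches)
        assert (n_compounds, n_features) == (1, 2)

    def test_empty_matches(self):
        assert casc.dedupe_candidates([])[:2] == (0, 0)


class TestConfirmation:
    def test_guanylurea_is_confirmed(self):
        r = casc.confirm_with_standard(102.0547, 14.6, reference_rt=14.4,
                                       reference_mass=102.0542)
        from polarscreen.core import round_reported

        assert round_reported(r.delta_rt_pct) == 1.4
        assert round_reported(r.delta_mass_ppm) == 4.9
        assert r.confirmed

    def test_large_rt_deviation_fails(self):
        r = casc.confirm_with_standard(102.0542, 14.4 * 1.06, 14.4, 102.0542)
        assert not r.confirmed

    def test_melamine_ambiguity_resolves_to_feature_a(self):
        features = [
            (126.0655, 6.9),  # A
            (126.0651, 7.2),  # B
            (126.0665, 8.4),  # C
        ]
        best, result = casc.best_feature_for_standard(features, reference_rt=7.0,
                                                      reference_mass=126.0654)
        assert best == 0
        assert result.confirmed


class TestSpatialReport:
    def _manifest(self):
        return pd.DataFrame(
            [
                {"sample_id": "u1", "location_id": 1, "campaign_date": "m1", "is_blank": False},
                {"sample_id": "u2", "location_id": 2, "campaign_date": "m1", "is_blank": False},
                {"sample_id": "d1", "location_id": 3, "campaign_date": "m1", "is_blank": False},
                {"sample_id": "d2", "location_id": 4, "campaign_date": "m1", "is_blank": False},
            ]
        )

    def test_flat_intensities_give_ratio_one(self):
        f = make_feature(100.0, 5.0, samples=("u1", "u2", "d1", "d2"), intensity=5e4)
        report = casc.spatial_report([f], self._manifest(), split_location=2)
        assert report.loc[0, "intensity_ratio"] == pytest.approx(1.0)

    def test_planted_downstream_step_is_recovered(self):
        f = Feature(
            feature_id=1,
            members=[
                FeatureMember("u1", 100.0, 5.0, 1e4),
                FeatureMember("u2", 100.0, 5.0, 1e4),
                FeatureMember("d1", 100.0, 5.0, 34e4),
                FeatureMember("d2", 100.0, 5.0, 34e4),
            ],
        ).refresh()
        report = casc.spatial_report([f], self._manifest(), split_location=2)
        assert report.loc[0, "intensity_ratio"] == pytest.approx(34.0)

    def test_downstream_only_feature_is_flagged(self):
        f = make_feature(100.0, 5.0, samples=("d1", "d2"))
        report = casc.spatial_report([f], self._manifest(), split_location=2)
        assert bool(report.loc[0, "downstream_only"])
        assert np.isnan(report.loc[0, "intensity_ratio"])

    def test_unknown_sample_raises(self):
        f = make_feature(100.0, 5.0, samples=("nope",))
        with pytest.raises(KeyError):
            casc.spatial_report([f], self._manifest(), split_location=2)


class TestFilterReport:
    def test_counts_must_not_increase(self):
        report = casc.FilterReport()
        report.add("a", 10, 8)
        with pytest.raises(ValueError):
            report.add("b", 8, 9)
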