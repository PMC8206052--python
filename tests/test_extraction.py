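"""Two-pass feature extraction: EICs, peaks, ion grouping, binning, recursion."""

import numpy as np
import pytest

from polarscreen.core import PROTON_MASS, SampleRun
from polarscreen.extraction import (
    EIC,
    FactorSettings,
    align_features,
    build_eics,
    detect_peaks,
    extract_features,
    group_ion_species,
    recursive_extraction,
    untargeted_components,
)
from polarscreen.simulate import DriftModel, TrueCompound, generate_campaign
from tests.conftest import ZERO_DRIFT, small_config, small_truth


def gaussian_run(mzs, rts, heights, fwhm=0.2, dt=0.5 / 60, sample_id="s1", length=18.0):
    """Plant exact Gaussian profiles on a scan grid (1% truncation)."""
    scan = np.arange(0.0, length, dt)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    rows = []
    for mz, rt, h in zip(mzs, rts, heights):
        y = h * np.exp(-0.5 * ((scan - rt) / sigma) ** 2)
        keep = y >= 0.01 * h
        for t, inten in zip(scan[keep], y[keep]):
            rows.append((t, mz, inten))
    import pandas as pd

    return SampleRun(sample_id, peaks=pd.DataFrame(rows, columns=["rt", "mz", "intensity"]))


class TestBuildEics:
    def test_isolated_profile_yields_one_complete_eic(self):
        run = gaussian_run([150.0], [8.0], [1000.0])
        eics = build_eics(run, mz_tolerance_ppm=10.0)
        assert len(eics) == 1
        assert len(eics[0]) == len(run)

    def test_well_separated_masses_stay_in_separate_eics(self):
        # 100 ppm apart at the same RT, chained at 10 ppm
        run = gaussian_run([150.0, 150.0 + 150.0 * 100e-6], [8.0, 8.0], [1000.0, 800.0])
        eics = build_eics(run, mz_tolerance_ppm=10.0)
        assert len(eics) == 2
        assert {len(e) for e in eics} == {len(run) // 2}

    def test_eic_count_matches_planted_ledger(self, clean_campaign):
        run = clean_campaign.sample_runs[0]
        n_planted = (clean_campaign.ledger.sample_id == run.sample_id).sum()
        eics = build_eics(run, mz_tolerance_ppm=20.0)
        assert len(eics) == n_planted


class TestDetectPeaks:
    def test_detects_height_and_respects_threshold(self):
        run = gaussian_run([150.0], [8.0], [1000.0])
        eic = build_eics(run, 10.0)[0]
        peaks = detect_peaks(eic, f1_abs_height_threshold=0.0)
        assert len(peaks) == 1
        assert peaks[0].height == pytest.approx(1000.0, rel=0.01)
        assert detect_peaks(eic, f1_abs_height_threshold=2000.0) == []

    def test_recovers_planted_fwhm_within_ten_percent(self):
        run = gaussian_run([150.0], [8.0], [50000.0], fwhm=0.2)
        eic = build_eics(run, 10.0)[0]
        (peak,) = detect_peaks(eic)
        assert peak.fwhm == pytest.approx(0.2, rel=0.10)
        assert peak.rt_start <= 8.0 <= peak.rt_end

    def test_resolves_two_separated_peaks_on_one_trace(self):
        run = gaussian_run([150.0, 150.0], [6.0, 10.0], [1000.0, 2000.0])
        eic = build_eics(run, 10.0)[0]
        peaks = detect_peaks(eic)
        assert len(peaks) == 2
        assert sorted(round(p.apex_rt, 1) for p in peaks) == [6.0, 10.0]


class TestGroupIonSpecies:
    def test_isotope_pair_merges_into_one_component(self):
        run = gaussian_run([150.0, 151.00336], [8.0, 8.0], [1000.0, 120.0])
        peaks = [p for e in build_eics(run, 10.0) for p in detect_peaks(e)]
        comps = group_ion_species(peaks, FactorSettings())
        assert len(comps) == 1
        assert comps[0].n_ions == 2
        assert comps[0].has_isotope_pattern
        assert comps[0].neutral_mass == pytest.approx(150.0 - PROTON_MASS, abs=1e-4)

    def test_charge_gate_controls_half_dalton_spacing(self):
        run = gaussian_run([300.0, 300.0 + 1.00336 / 2], [8.0, 8.0], [1000.0, 300.0])
        peaks = [p for e in build_eics(run, 10.0) for p in detect_peaks(e)]
        two = group_ion_species(peaks, FactorSettings(f2_max_charge=2))
        assert len(two) == 1 and two[0].charge == 2
        one = group_ion_species(peaks, FactorSettings(f2_max_charge=1))
        assert len(one) == 2

    def test_all_planted_isotope_pairs_merge_at_zero_mass_error(self, clean_campaign):
        settings = FactorSettings()
        for run in clean_campaign.sample_runs:
            comps = untargeted_components(run, settings)
            n_compounds = clean_campaign.ledger[
                (clean_campaign.ledger.sample_id == run.sample_id)
            ].compound_id.nunique()
            assert len(comps) == n_compounds
            assert all(c.n_ions == 2 and c.has_isotope_pattern for c in comps)


class TestAlignFeatures:
    def _components(self, campaign, settings):
        comps = []
        for run in campaign.sample_runs:
            comps.extend(untargeted_components(run, settings))
        return comps

    def test_rt_jitter_within_tolerance_gives_one_feature_per_compound(self):
        camp = generate_campaign(
            small_config(n_locations=3, n_dates=1, include_blank=False),
            small_truth(),
            DriftModel(rt_shift_sd=0.3, mass_error_sd_ppm=0.0, intensity_cv=0.0),
        )
        settings = FactorSettings(f3_rt_bin_tolerance=0.87)
        feats = align_features(self._components(camp, settings), settings)
        assert len(feats) == 3
        assert all(f.n_samples == 3 for f in feats)

    def test_tolerance_below_jitter_fragments_features(self):
        camp = generate_campaign(
            small_config(n_locations=5, n_dates=2, include_blank=False, seed=3),
            small_truth(),
            DriftModel(rt_shift_sd=0.4, mass_error_sd_ppm=0.0, intensity_cv=0.0),
        )
        settings = FactorSettings(f3_rt_bin_tolerance=0.1)
        feats = align_features(self._components(camp, settings), settings)
        assert len(feats) > 3  # fragmented bins

    def test_matches_brute_force_nearest_bin_assignment(self, drift_campaign):
        settings = FactorSettings()
        comps = self._components(drift_campaign, settings)[:50]
        feats = align_features(comps, settings)

        # independent re-implementation: plain-python greedy nearest-bin pass
        order = sorted(range(len(comps)),
                       key=lambda i: (-comps[i].height, comps[i].neutral_mass, comps[i].rt))
        bins = []
        for i in order:
            c = comps[i]
            best, best_score = None, None
            for b in bins:
                cm = float(np.median([x.neutral_mass for x in b]))
                cr = float(np.median([x.rt for x in b]))
                dm = abs(c.neutral_mass - cm) / cm * 1e6
                dr = abs(c.rt - cr)
                if dm <= settings.f4_mass_bin_tolerance_ppm and dr <= settings.f3_rt_bin_tolerance:
                    score = (dm / settings.f4_mass_bin_tolerance_ppm) ** 2 + (
                        dr / settings.f3_rt_bin_tolerance) ** 2
                    if best_score is None or score < best_score:
                        best, best_score = b, score
            if best is None:
                bins.append([c])
            else:
                best.append(c)
        expected = sorted(
            sorted((c.sample_id, round(c.neutral_mass, 6), round(c.rt, 6)) for c in b)
            for b in bins
        )
        got = sorted(
            sorted((m.sample_id, round(m.neutral_mass, 6), round(m.rt, 6)) for m in f.members)
            for f in feats
        )
        assert got == expected


class TestRecursiveExtraction:
    def test_recovers_peak_suppressed_by_untargeted_threshold(self):
        # the compound is weak in sample s2: pass 1 at f1 > 0 misses it there,
        # pass 2 re-extracts it because its height clears F6/F7
        import pandas as pd

        r1 = gaussian_run([150.0, 151.00336], [8.0, 8.0], [10000.0, 1500.0], sample_id="s1")
        r2 = gaussian_run([150.0], [8.1], [3000.0], sample_id="s2")
        settings = FactorSettings(
            f1_abs_height_threshold=5000.0,
            f6_post_targeted_height_filter=1000.0,
            f7_post_integration_height_filter=1000.0,
        )
        feats = extract_features([r1, r2], settings)
        assert len(feats) == 1
        assert feats[0].n_samples == 2

    def test_eic_tolerance_gates_mass_errors(self):
        # 5 ppm error is recovered at F8 = 10 ppm; 25 ppm error is not
        good = gaussian_run([150.0 * (1 + 5e-6)], [8.0], [20000.0], sample_id="s2")
        bad = gaussian_run([150.0 * (1 + 25e-6)], [8.0], [20000.0], sample_id="s3")
        anchor = gaussian_run([150.0, 151.00336], [8.0, 8.0], [20000.0, 3000.0], sample_id="s1")
        settings = FactorSettings(
            f4_mass_bin_tolerance_ppm=8.0,
            f6_post_targeted_height_filter=1000.0,
            f7_post_integration_height_filter=1000.0,
        )
        feats = extract_features([anchor, good, bad], settings)
        by_samples = {f.n_samples for f in feats}
        anchor_feature = next(f for f in feats if "s1" in f.sample_ids)
        assert "s2" in anchor_feature.sample_ids
        assert "s3" not in anchor_feature.sample_ids

    def test_second_application_is_a_fixed_point(self, clean_campaign, permissive_settings):
        feats = extract_features(clean_campaign.sample_runs, permissive_settings)
        again = recursive_extraction(feats, clean_campaign.sample_runs, permissive_settings)
        assert len(again) == len(feats)
        for a, b in zip(feats, again):
            assert a.median_mass == pytest.approx(b.median_mass, abs=1e-9)
            assert a.median_rt == pytest.approx(b.median_rt, abs=1e-9)
            assert a.sample_ids == b.sample_ids

    def test_extraction_is_deterministic(self, drift_campaign, permissive_settings):
        a = extract_features(drift_campaign.sample_runs, permissive_settings)
        b = extract_features(drift_campaign.sample_runs, permissive_settings)
        assert [(f.median_mass, f.median_rt, f.sample_ids) for f in a] == [
            (f.median_mass, f.median_rt, f.sample_ids) for f in b
        ]

    def test_empty_runs_give_empty_feature_list(self, permissive_settings):
        assert extract_features([], permissive_settings) == []


class TestInvariants:
    def test_raising_height_filters_never_adds_features(self, drift_campaign):
        base = dict(f6_post_targeted_height_filter=500.0,
                    f7_post_integration_height_filter=500.0)
        counts = []
        for f1 in (0.0, 2000.0, 20000.0):
            settings = FactorSettings(f1_abs_height_threshold=f1, **base)
            counts.append(len(extract_features(drift_campaign.sample_runs, settings)))
        assert counts == sorted(counts, reverse=True)
        counts = []
        for f67 in (500.0, 5000.0, 50000.0):
            settings = FactorSettings(
                f6_post_targeted_height_filter=f67, f7_post_integration_height_filter=f67
            )
            counts.append(len(extract_features(drift_campaign.sample_runs, settings)))
        assert counts == sorted(counts, reverse=True)

    def test_widening_binning_tolerances_only_merges(self, drift_campaign):
        counts = []
        for f3 in (0.1, 0.4, 0.87):
            settings = FactorSettings(
                f3_rt_bin_tolerance=f3,
                f6_post_targeted_height_filter=500.0,
                f7_post_integration_height_filter=500.0,
            )
            counts.append(len(extract_features(drift_campaign.sample_runs, settings)))
        assert counts == sorted(counts, reverse=True)

    def test_feature_medians_equal_member_medians(self, drift_campaign, permissive_settings):
        feats = extract_features(drift_campaign.sample_runs, permissive_settings)
        assert feats
        for f in feats:
            assert f.median_mass == pytest.approx(
                float(np.median([m.neutral_mass for m in f.members]))
            )
            assert f.median_rt == pytest.approx(float(np.median([m.rt for m in f.members])))
            assert f.n_samples == len({m.sample_id for m in f.members})
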