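"""Centroiding, chromatogram building, deconvolution and the filters."""

import numpy as np
import pytest

from nanorapids.features import (
    EIC,
    DetectionParams,
    Feature,
    build_chromatograms,
    deconvolve_local_minimum,
    detect_features,
    detect_mass_peaks,
    filter_duplicates,
    filter_rows_with_ms2,
    group_isotopes,
    pair_ms2,
)
from nanorapids.simulate import SyntheticCompound, SyntheticRunSpec, simulate_run
from nanorapids.spectra import Scan

from conftest import gaussian_scans


def _feature(fid, mz, rt, height=1e6, **kw):
    return Feature(id=fid, mz=mz, rt_apex=rt, rt_start=rt - 0.1,
                   rt_end=rt + 0.1, height=height, area=height * 0.1, **kw)


class TestDetectMassPeaks:
    def test_empty_scan(self):
        scan = Scan(1, 0.0, np.array([]), np.array([]))
        mz, inten = detect_mass_peaks(scan, 1e4)
        assert mz.size == 0

    def test_centroided_threshold(self):
        scan = Scan(1, 0.0, np.array([200.0, 300.0]),
                    np.array([9e3, 2e4]))
        mz, inten = detect_mass_peaks(scan, 1e4)
        assert mz.tolist() == [300.0]  # 9e3 is below the MS1 noise level

    def test_profile_centroid_weighted_mean(self):
        # 3-point profile peak: weighted m/z = (499.99*1 + 500*4 + 500.01*1)/6
        scan = Scan(1, 0.0,
                    np.array([499.99, 500.00, 500.01]),
                    np.array([1e5, 4e5, 1e5]), centroided=False)
        mz, inten = detect_mass_peaks(scan, 1e4)
        assert mz.size == 1
        assert mz[0] == pytest.approx(500.0)
        assert inten[0] == 4e5
        scan2 = Scan(1, 0.0, np.array([499.99, 500.0, 500.03]),
                     np.array([1e5, 4e5, 3e5]), centroided=False)
        mz2, _ = detect_mass_peaks(scan2, 1e4)
        expected = np.average([499.99, 500.0, 500.03],
                              weights=[1e5, 4e5, 3e5])
        assert mz2[0] == pytest.approx(expected)


class TestBuildChromatograms:
    def test_gaussian_peak_retained(self, params):
        scans = gaussian_scans(500.0, 1.25, 1e6)
        eics = build_chromatograms(scans, params)
        assert len(eics) == 1
        assert eics[0].representative_mz == pytest.approx(500.0)

    def test_short_group_rejected(self, params):
        # only 5 scans above the group threshold (min_group_size is 10)
        scans = []
        for k in range(20):
            h = 1e6 if 8 <= k < 13 else 0.0
            mzs = np.array([500.0]) if h else np.array([])
            scans.append(Scan(1, k * 0.02, mzs,
                              np.array([h]) if h else np.array([])))
        assert build_chromatograms(scans, params) == []

    def test_low_apex_rejected(self, params):
        scans = gaussian_scans(500.0, 1.25, 4e4)  # < min_height 5e4
        assert build_chromatograms(scans, params) == []

    def test_unordered_scans_raise(self, params):
        scans = gaussian_scans(500.0, 1.25, 1e6)
        with pytest.raises(ValueError):
            build_chromatograms(scans[::-1], params)

    def test_two_mz_channels_stay_separate(self, params):
        base = gaussian_scans(500.0, 1.25, 1e6)
        scans = []
        for s in base:
            if s.mz.size:
                scans.append(Scan(1, s.rt,
                                  np.array([s.mz[0], s.mz[0] + 0.01]),
                                  np.array([s.intensity[0], s.intensity[0]])))
            else:
                scans.append(s)
        eics = build_chromatograms(scans, params)
        assert len(eics) == 2


class TestDeconvolution:
    def test_single_gaussian_single_feature(self, params):
        scans = gaussian_scans(500.0, 1.25, 1e6)
        eic = build_chromatograms(scans, params)[0]
        feats = deconvolve_local_minimum(eic, params)
        assert len(feats) == 1
        f = feats[0]
        assert f.rt_apex == pytest.approx(1.25, abs=1.25 / 60.0)
        assert f.height == pytest.approx(1e6, rel=0.01)
        assert f.rt_start <= f.rt_apex <= f.rt_end
        assert params.duration_min <= f.duration <= params.duration_max

    def test_two_gaussians_split_at_valley(self, params):
        dt = 1.25 / 60.0
        t = np.arange(0, 3.0, dt)
        prof = 1e6 * np.exp(-0.5 * ((t - 1.0) / 0.06) ** 2) + \
            8e5 * np.exp(-0.5 * ((t - 1.6) / 0.06) ** 2)
        eic = EIC(500.0, t, np.full_like(t, 500.0), prof,
                  np.arange(t.size))
        feats = deconvolve_local_minimum(eic, params)
        assert len(feats) == 2
        assert feats[0].rt_apex == pytest.approx(1.0, abs=dt)
        assert feats[1].rt_apex == pytest.approx(1.6, abs=dt)

    def test_shallow_shoulder_not_split(self, params):
        # valley at only apex/1.5 — top/edge ratio below 2 on that side
        dt = 1.25 / 60.0
        t = np.arange(0, 2.0, dt)
        prof = np.full_like(t, 1.0)
        prof += 1e6 * np.exp(-0.5 * ((t - 0.8) / 0.08) ** 2)
        prof += 9.8e5 * np.exp(-0.5 * ((t - 1.05) / 0.08) ** 2)
        eic = EIC(500.0, t, np.full_like(t, 500.0), prof,
                  np.arange(t.size))
        feats = deconvolve_local_minimum(eic, params)
        assert len(feats) == 1

    def test_apex_below_absolute_floor_dropped(self, params):
        dt = 1.25 / 60.0
        t = np.arange(0, 1.0, dt)
        prof = 9e3 * np.exp(-0.5 * ((t - 0.5) / 0.06) ** 2)
        eic = EIC(500.0, t, np.full_like(t, 500.0), prof,
                  np.arange(t.size))
        assert deconvolve_local_minimum(eic, params) == []


class TestPairMs2:
    def _ms2(self, prec, rt, inten=1e4):
        return Scan(2, rt, np.array([100.0, 200.0]),
                    np.array([50.0, 100.0]), precursor_mz=prec,
                    precursor_intensity=inten)

    def test_within_both_windows(self, params):
        feats = [_feature(1, 500.0, 10.0)]
        out = pair_ms2(feats, [self._ms2(500.04, 10.5)], params)
        assert out[0].ms2 is not None
        assert out[0].ms2.precursor_mz == pytest.approx(500.04)

    def test_outside_mz_window(self, params):
        feats = [_feature(1, 500.0, 10.0)]
        out = pair_ms2(feats, [self._ms2(500.06, 10.5)], params)
        assert out[0].ms2 is None

    def test_outside_rt_window(self, params):
        feats = [_feature(1, 500.0, 10.0)]
        out = pair_ms2(feats, [self._ms2(500.0, 11.5)], params)
        assert out[0].ms2 is None

    def test_no_ms2_scans(self, params):
        feats = [_feature(1, 500.0, 10.0)]
        assert pair_ms2(feats, [], params)[0].ms2 is None

    def test_representative_is_most_intense_precursor(self, params):
        feats = [_feature(1, 500.0, 10.0)]
        scans = [self._ms2(500.01, 10.1, inten=1e3),
                 self._ms2(500.02, 10.2, inten=5e4)]
        out = pair_ms2(feats, scans, params)
        assert out[0].n_ms2 == 2
        assert out[0].ms2.precursor_mz == pytest.approx(500.02)

    def test_tie_breaks_by_smallest_dmz(self, params):
        feats = [_feature(1, 500.0, 10.0), _feature(2, 500.03, 10.0)]
        out = pair_ms2(feats, [self._ms2(500.01, 10.0)], params)
        assert out[0].ms2 is not None and out[1].ms2 is None


class TestGroupIsotopes:
    def test_coeluting_c13_pair_grouped(self, params):
        feats = [_feature(1, 500.0, 10.0), _feature(2, 501.00335, 10.02)]
        out = group_isotopes(feats, params)
        assert out[0].isotope_group == out[1].isotope_group
        assert out[0].is_monoisotopic and not out[1].is_monoisotopic

    def test_rt_separated_pair_not_grouped(self, params):
        feats = [_feature(1, 500.0, 10.0), _feature(2, 501.00335, 10.2)]
        out = group_isotopes(feats, params)
        assert out[0].isotope_group != out[1].isotope_group
        assert all(f.is_monoisotopic for f in out)

    def test_charge_two_spacing(self, params):
        feats = [_feature(1, 500.0, 10.0),
                 _feature(2, 500.0 + 1.00335 / 2, 10.0)]
        out = group_isotopes(feats, params)
        assert out[0].isotope_group == out[1].isotope_group

    def test_chain_groups_transitively(self, params):
        feats = [_feature(1, 500.0, 10.0),
                 _feature(2, 501.00335, 10.0),
                 _feature(3, 502.0067, 10.0)]
        out = group_isotopes(feats, params)
        assert len({f.isotope_group for f in out}) == 1
        assert sum(f.is_monoisotopic for f in out) == 1

    def test_singleton_is_its_own_group(self, params):
        out = group_isotopes([_feature(1, 500.0, 10.0)], params)
        assert out[0].isotope_group is not None
        assert out[0].is_monoisotopic


class TestFilters:
    def test_pass1_merges_close_duplicates(self, params):
        feats = [_feature(1, 500.0, 10.0, height=1e6),
                 _feature(2, 500.0005, 10.02, height=5e5)]
        out = filter_duplicates(feats, params)
        assert [f.id for f in out] == [1]  # taller survives

    def test_pass2_merges_within_one_dalton(self, params):
        feats = [_feature(1, 500.0, 10.0, height=1e6),
                 _feature(2, 500.5, 10.02, height=5e5)]
        out = filter_duplicates(feats, params)
        assert [f.id for f in out] == [1]

    def test_rt_separated_rows_kept(self, params):
        feats = [_feature(1, 500.0, 10.0), _feature(2, 500.5, 10.2)]
        assert len(filter_duplicates(feats, params)) == 2

    def test_filters_are_contractive(self, params):
        rng = np.random.default_rng(0)
        feats = [
            _feature(i, float(rng.uniform(200, 1200)),
                     float(rng.uniform(0, 40)),
                     height=float(rng.uniform(1e5, 1e7)))
            for i in range(40)
        ]
        out = filter_duplicates(feats, params)
        assert {f.id for f in out} <= {f.id for f in feats}

    def test_ms2_row_filter(self):
        spec = Scan(2, 1.0, np.array([100.0]), np.array([10.0]),
                    precursor_mz=500.0)
        from nanorapids.spectra import FragmentSpectrum

        feats = [_feature(1, 500.0, 10.0,
                          ms2=FragmentSpectrum.from_scan(spec)),
                 _feature(2, 600.0, 11.0)]
        assert [f.id for f in filter_rows_with_ms2(feats)] == [1]
        assert filter_rows_with_ms2([_feature(3, 700.0, 1.0)]) == []


class TestEndToEnd:
    def test_recovery_and_threshold_invariants(self, params):
        spec = SyntheticRunSpec(run_length=8.0, seed=2)
        compounds = [
            SyntheticCompound(name="big", mz=500.1234, rt=3.0, apex=2e6,
                              fragments=((150.0, 100.0), (250.0, 50.0))),
            SyntheticCompound(name="small", mz=700.4321, rt=5.0, apex=3e4,
                              fragments=((180.0, 100.0),)),  # < min_height
        ]
        scans, _ = simulate_run(spec, compounds)
        feats = detect_features(scans, params, require_ms2=False)
        assert len(feats) == 1
        f = feats[0]
        assert abs(f.mz - 500.1234) <= 0.002
        assert abs(f.rt_apex - 3.0) <= spec.ms1_interval / 60.0
        assert f.height >= params.min_height
        assert params.duration_min <= f.duration <= params.duration_max

    def test_pipeline_is_deterministic(self, params):
        spec = SyntheticRunSpec(run_length=6.0, seed=4)
        comp = [SyntheticCompound(name="x", mz=432.1, rt=3.0, apex=1e6,
                                  fragments=((120.0, 100.0), (210.0, 40.0)))]
        scans, _ = simulate_run(spec, comp)
        a = detect_features(scans, params)
        b = detect_features(scans, params)
        assert [(f.id, f.mz, f.rt_apex, f.height, f.area) for f in a] == [
            (f.id, f.mz, f.rt_apex, f.height, f.area) for f in b
        ]

    def test_noise_only_run_yields_nothing(self, params):
        spec = SyntheticRunSpec(run_length=4.0, seed=6)
        scans, _ = simulate_run(spec, [])
        assert detect_features(scans, params, require_ms2=False) == []
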