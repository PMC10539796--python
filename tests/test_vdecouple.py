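"""Noise estimation, peak picking, pairing, back-shifting and the full
virtual-decoupling pipeline."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vdhsqc as v

F1_SMALL = v.FrequencyAxis(60.0, 176.05, 79.98, 16)
# 1 Hz per point: sw 10 ppm at 100 MHz over 1000 points
AX1HZ = v.FrequencyAxis(10.0, 100.0, 5.0, 1000)


def peak_at_hz(hz, sign, intensity, axis=AX1HZ, row=0):
    ppm = float(axis.hz_to_ppm(hz))
    return v.Peak(f1_index=row, f2_index_lowres=float(axis.ppm_to_index(ppm)),
                  f2_ppm=ppm, sign=sign, intensity=intensity)


class TestEstimateNoise:
    def test_all_zero(self):
        f = v.FrequencyAxis(10.0, 100.0, 5.0, 64)
        spec = v.Spectrum2D(np.zeros((64, 64)),
                            v.FrequencyAxis(60.0, 176.05, 80.0, 64), f)
        assert v.estimate_noise(spec) == 0.0

    def test_gaussian_noise_recovered(self):
        rng = np.random.default_rng(5)
        spec = v.Spectrum2D(rng.normal(0, 1.0, (256, 1024)),
                            v.FrequencyAxis(60.0, 176.05, 80.0, 256),
                            v.FrequencyAxis(10.0, 100.0, 5.0, 1024))
        assert 0.9 <= v.estimate_noise(spec) <= 1.1

    def test_robust_to_sparse_peaks(self):
        rng = np.random.default_rng(6)
        data = rng.normal(0, 1.0, (256, 1024))
        rows = rng.integers(0, 256, 10)
        cols = rng.integers(0, 1024, 10)
        data[rows, cols] = 50.0
        spec = v.Spectrum2D(data, v.FrequencyAxis(60.0, 176.05, 80.0, 256),
                            v.FrequencyAxis(10.0, 100.0, 5.0, 1024))
        assert 0.85 <= v.estimate_noise(spec) <= 1.15

    def test_empty_region_rejected(self):
        spec = v.Spectrum2D(np.zeros((16, 16)),
                            v.FrequencyAxis(60.0, 176.05, 80.0, 16),
                            v.FrequencyAxis(10.0, 100.0, 5.0, 16))
        with pytest.raises(ValueError):
            v.estimate_noise(spec, region=((4, 4), (0, 8)))


class TestPickPeaks:
    @pytest.fixture
    def lorentzian_spec(self):
        f1 = v.FrequencyAxis(60.0, 176.05, 80.0, 32)
        f2 = v.FrequencyAxis(10.0, 100.0, 5.0, 256)
        cols = np.arange(256)
        data = np.outer(np.exp(-0.5 * ((np.arange(32) - 16) / 1.5) ** 2),
                        4.0 / ((cols - 100.0) ** 2 + 4.0))
        return v.Spectrum2D(data, f1, f2)

    def test_single_positive_peak(self, lorentzian_spec):
        peaks = v.pick_peaks(lorentzian_spec, threshold=0.1)
        assert len(peaks) == 1
        assert peaks[0].f1_index == 16
        assert peaks[0].f2_index_lowres == pytest.approx(100.0, abs=0.05)
        assert peaks[0].sign == 1

    def test_negated_spectrum_mirror(self, lorentzian_spec):
        neg = v.Spectrum2D(-lorentzian_spec.data, lorentzian_spec.f1_axis,
                           lorentzian_spec.f2_axis)
        pos_peaks = v.pick_peaks(lorentzian_spec, 0.1, "positive")
        neg_peaks = v.pick_peaks(neg, 0.1, "negative")
        assert len(neg_peaks) == len(pos_peaks) == 1
        assert neg_peaks[0].f2_index_lowres == pos_peaks[0].f2_index_lowres
        assert neg_peaks[0].sign == -1
        assert v.pick_peaks(neg, 0.1, "positive") == []

    def test_threshold_must_be_positive(self, lorentzian_spec):
        with pytest.raises(ValueError):
            v.pick_peaks(lorentzian_spec, 0.0)

    def test_three_isolated_ch_systems_give_three_per_sign(self):
        systems = [v.SpinSystemSpec(delta_h=h, delta_c=c, j_ch=j)
                   for h, c, j in [(2.5, 30.0, 140.0), (4.5, 45.0, 150.0),
                                   (6.5, 60.0, 160.0)]]
        f2 = v.FrequencyAxis(12.0172, 700.13, 9.5, 4096)
        raw = v.simulate_hsqc(systems, v.AcquisitionParams(f2, F1_SMALL, "clap"))
        low = v.reduce_resolution(raw, 1024, 2.0, 4096, taper="qsine")
        thr = 0.05 * np.abs(low.data).max()
        assert len(v.pick_peaks(low, thr, "positive")) == 3
        assert len(v.pick_peaks(low, thr, "negative")) == 3


class TestClusterAndPair:
    def test_simple_pair_center_and_j(self):
        peaks = [peak_at_hz(0.0, 1, 5.0), peak_at_hz(150.2, -1, -5.0)]
        rep = v.cluster_and_pair(peaks, AX1HZ)
        assert len(rep.pairs) == 1
        p = rep.pairs[0]
        assert p.j_hz == pytest.approx(150.2, abs=1e-6)
        assert p.center_hz == pytest.approx(75.1, abs=1e-6)
        assert p.downfield.sign == -1    # +150.2 Hz is the downfield side

    def test_same_sign_cluster_is_ambiguous(self):
        peaks = [peak_at_hz(0.0, 1, 5.0), peak_at_hz(150.0, 1, 5.0)]
        rep = v.cluster_and_pair(peaks, AX1HZ)
        assert rep.pairs == []
        assert len(rep.ambiguous_clusters) == 1
        assert rep.ambiguous_clusters[0]["reason"] == "no opposite-sign partner"

    def test_j_below_range_rejected(self):
        peaks = [peak_at_hz(0.0, 1, 5.0), peak_at_hz(60.0, -1, -5.0)]
        rep = v.cluster_and_pair(peaks, AX1HZ)
        assert rep.pairs == []
        assert len(rep.rejected) == 1
        assert "below j_min" in rep.rejected[0]["reason"]

    def test_matching_enumeration_minimizes_intensity_mismatch(self):
        """Both perfect matchings of this 4-peak cluster are J-valid; the
        one with equal component magnitudes (cost 0 vs 8) must win."""
        peaks = [
            peak_at_hz(0.0, 1, 5.0), peak_at_hz(20.0, 1, 1.0),
            peak_at_hz(145.0, -1, -5.0), peak_at_hz(165.0, -1, -1.0),
        ]
        rep = v.cluster_and_pair(peaks, AX1HZ)
        assert len(rep.pairs) == 2
        js = sorted(round(p.j_hz, 6) for p in rep.pairs)
        assert js == [145.0, 145.0]
        for p in rep.pairs:
            assert abs(p.upfield.intensity) == pytest.approx(
                abs(p.downfield.intensity))

    def test_unequal_counts_ambiguous(self):
        peaks = [peak_at_hz(0.0, 1, 5.0), peak_at_hz(10.0, 1, 4.0),
                 peak_at_hz(150.0, -1, -5.0)]
        rep = v.cluster_and_pair(peaks, AX1HZ)
        assert rep.pairs == []
        assert "unequal" in rep.ambiguous_clusters[0]["reason"]

    def test_row_tolerance_merges_adjacent_rows(self):
        peaks = [peak_at_hz(0.0, 1, 5.0, row=10), peak_at_hz(150.0, -1, -5.0, row=11)]
        strict = v.cluster_and_pair(peaks, AX1HZ, v.VdConfig(row_tolerance=0))
        assert strict.pairs == []
        loose = v.cluster_and_pair(peaks, AX1HZ, v.VdConfig(row_tolerance=1))
        assert len(loose.pairs) == 1

    def test_manual_pairing_overrides(self, tmp_path):
        peaks = [peak_at_hz(0.0, 1, 5.0), peak_at_hz(10.0, 1, 4.0),
                 peak_at_hz(150.0, -1, -5.0)]
        pairs_file = tmp_path / "pairs.json"
        pairs_file.write_text(json.dumps({"pairs": [[0, 2]], "ignore": [1]}))
        rep = v.cluster_and_pair(peaks, AX1HZ,
                                 v.VdConfig(manual_pairs_file=str(pairs_file)))
        assert len(rep.pairs) == 1
        assert rep.pairs[0].j_hz == pytest.approx(150.0, abs=1e-6)
        assert len(rep.rejected) == 1

    def test_malformed_manual_file_lists_entries(self, tmp_path):
        peaks = [peak_at_hz(0.0, 1, 5.0), peak_at_hz(150.0, -1, -5.0)]
        pairs_file = tmp_path / "pairs.json"
        pairs_file.write_text(json.dumps({"pairs": [[0, 99], "junk"]}))
        with pytest.raises(ValueError, match="malformed"):
            v.cluster_and_pair(peaks, AX1HZ,
                               v.VdConfig(manual_pairs_file=str(pairs_file)))


@settings(max_examples=50, deadline=None)
@given(st.lists(
    st.tuples(st.integers(0, 5),                      # row
              st.floats(-400, 400),                   # hz
              st.sampled_from([1, -1]),               # sign
              st.floats(0.5, 10)),                    # magnitude
    max_size=10))
def test_every_peak_is_accounted_for(entries):
    """pairs + ambiguous + rejected always partition the peak list."""
    peaks = [peak_at_hz(hz, s, s * mag, row=r) for r, hz, s, mag in entries]
    peaks.sort(key=lambda p: (p.f1_index, p.f2_index_lowres))
    rep = v.cluster_and_pair(peaks, AX1HZ)
    assert rep.n_accounted() == len(peaks)


class TestBackshift:
    @staticmethod
    def make_clip(col_up, width=3.0, n=1024):
        f2 = v.FrequencyAxis(10.24, 100.0, 5.0, n)   # 1 Hz per point
        f1 = v.FrequencyAxis(60.0, 176.05, 80.0, 4)
        cols = np.arange(n)
        data = np.zeros((4, n))
        data[2] = np.exp(-0.5 * ((cols - col_up) / width) ** 2)
        return v.Spectrum2D(data, f1, f2)

    @staticmethod
    def make_pair(spec, col_up, j_hz):
        axis = spec.f2_axis
        up_ppm = float(axis.index_to_ppm(col_up))
        down_ppm = float(axis.hz_to_ppm(float(axis.ppm_to_hz(up_ppm)) + j_hz))
        up = v.Peak(2, float(col_up), up_ppm, -1, -1.0)
        down = v.Peak(2, float(axis.ppm_to_index(down_ppm)), down_ppm, 1, 1.0)
        hz_up = float(axis.ppm_to_hz(up_ppm))
        return v.DoubletPair(2, up, down, hz_up + j_hz / 2.0, j_hz)

    def test_grid_aligned_shift_lands_on_center(self):
        spec = self.make_clip(600.0)
        pair = self.make_pair(spec, 600, 140.0)   # 140 Hz = 140 points, even
        seg, (start, stop), warns = v.backshift(spec, pair)
        assert warns == []
        vd_row = np.zeros(1024)
        vd_row[start:stop] = seg
        assert np.argmax(vd_row) == 600 - 70

    def test_zero_shift_is_identity(self):
        spec = self.make_clip(600.0)
        pair = self.make_pair(spec, 600, 140.0)
        object.__setattr__(pair, "j_hz", 0.0)     # validation off for the check
        cfg = v.VdConfig(window_halfwidth_hz=50.0)
        seg, (start, stop), _ = v.backshift(spec, pair, cfg)
        np.testing.assert_allclose(seg, spec.data[2, start:stop], atol=1e-12)

    @pytest.mark.parametrize("subpoint", [True, False])
    def test_window_integral_conserved(self, subpoint):
        spec = self.make_clip(600.0)
        j_hz = 141.3                              # non-integer half-shift
        pair = self.make_pair(spec, 600, j_hz)
        cfg = v.VdConfig(subpoint_shift=subpoint)
        seg, _, _ = v.backshift(spec, pair, cfg)
        # original (unshifted) window around the upfield component
        half_pts = j_hz / 2.0 / spec.f2_axis.hz_per_point
        lo, hi = round(600 - half_pts), round(600 + half_pts) + 1
        orig = spec.data[2, lo:hi]
        assert seg.sum() == pytest.approx(orig.sum(), rel=1e-6)

    def test_subpoint_mode_hits_fractional_center(self):
        spec = self.make_clip(600.0)
        pair = self.make_pair(spec, 600, 141.0)   # half-shift 70.5 points
        seg, (start, stop), _ = v.backshift(spec, pair,
                                            v.VdConfig(subpoint_shift=True))
        vd_row = np.zeros(1024)
        vd_row[start:stop] = seg
        imax = int(np.argmax(vd_row))
        refined = v.parabolic_refine(vd_row, imax)
        assert abs(refined - (600 - 70.5)) <= 0.05

    def test_window_truncation_warns(self):
        # upfield component near the upfield (right) edge: the extraction
        # window would run past the axis and must be clipped with a warning
        spec = self.make_clip(990.0)
        pair = self.make_pair(spec, 990, 140.0)
        seg, (start, stop), warns = v.backshift(spec, pair)
        assert any("truncated" in w for w in warns)
        assert stop <= spec.f2_axis.n_points and start >= 0


@pytest.fixture(scope="module")
def clip_clap():
    f2 = v.FrequencyAxis(12.0172, 700.13, 9.5, 4096)
    ch = v.SpinSystemSpec(delta_h=3.25, delta_c=43.3, j_ch=145.0)
    clip = v.process_2d(v.simulate_hsqc([ch], v.AcquisitionParams(f2, F1_SMALL, "clip")))
    clap = v.process_2d(v.simulate_hsqc([ch], v.AcquisitionParams(f2, F1_SMALL, "clap")))
    return clip, clap


class TestIpapCombine:

    def test_alpha_plus_beta_is_clip(self, clip_clap):
        clip, clap = clip_clap
        alpha, beta = v.ipap_combine(clip, clap)
        assert np.max(np.abs(alpha.data + beta.data - clip.data)) < 1e-12

    def test_each_subspectrum_has_one_component(self, clip_clap):
        clip, clap = clip_clap
        alpha, beta = v.ipap_combine(clip, clap)
        ia = np.unravel_index(np.argmax(alpha.data), alpha.data.shape)
        ib = np.unravel_index(np.argmax(beta.data), beta.data.shape)
        sep_hz = abs(float(alpha.f2_axis.index_to_hz(ia[1]))
                     - float(beta.f2_axis.index_to_hz(ib[1])))
        assert sep_hz == pytest.approx(145.0, abs=alpha.f2_axis.hz_per_point)
        # the opposite component is (near) absent in each subspectrum
        assert alpha.data[ib] < 0.05 * alpha.data[ia]
        assert beta.data[ia] < 0.05 * beta.data[ib]

    def test_scale_zero_halves_clip(self, clip_clap):
        clip, clap = clip_clap
        alpha, beta = v.ipap_combine(clip, clap, scale=0.0)
        np.testing.assert_array_equal(alpha.data, clip.data / 2)
        np.testing.assert_array_equal(beta.data, clip.data / 2)

    def test_axis_mismatch_rejected(self, clip_clap):
        clip, _ = clip_clap
        other = v.Spectrum2D(np.zeros((16, 128)),
                             v.FrequencyAxis(60.0, 176.05, 80.0, 16),
                             v.FrequencyAxis(10.0, 100.0, 5.0, 128))
        with pytest.raises(ValueError, match="axes"):
            v.ipap_combine(clip, other)


class TestVirtualDecouple:
    def test_pure_noise_yields_empty_vd(self):
        rng = np.random.default_rng(12)
        f1 = v.FrequencyAxis(60.0, 176.05, 79.98, 8)
        f2 = v.FrequencyAxis(12.0172, 700.13, 9.5, 2048)
        mk = lambda: v.RawFID2D(
            rng.normal(0, 1.0, (16, 2048)) + 1j * rng.normal(0, 1.0, (16, 2048)),
            f1, f2)
        res = v.virtual_decouple(mk(), mk())
        assert res.report.pairs == []
        assert np.all(res.vd.data == 0.0)
        assert res.report.parameters   # report carries the configuration

    def test_j_recovery_over_random_systems(self):
        """Estimated 1JCH within 2*(sw/1024) of truth for 20 systems with J
        drawn in [115, 180] Hz; centroid refinement keeps the mean error
        below half that bound."""
        rng = np.random.default_rng(20)
        f2 = v.FrequencyAxis(12.0172, 700.13, 9.5, 4096)
        f1 = v.FrequencyAxis(60.0, 176.05, 79.98, 32)
        j_true = rng.uniform(115, 180, 20)
        dh = np.linspace(1.2, 8.8, 20)
        dc = np.linspace(25, 75, 20)
        systems = [v.SpinSystemSpec(delta_h=float(h), delta_c=float(c), j_ch=float(j))
                   for h, c, j in zip(dh, dc, j_true)]
        acq = lambda m: v.AcquisitionParams(f2, f1, m)
        clip = v.simulate_hsqc(systems, acq("clip"))
        clap = v.simulate_hsqc(systems, acq("clap"))
        res = v.virtual_decouple(clip, clap)
        assert len(res.report.pairs) == 20
        pairs = sorted(res.report.pairs, key=lambda p: p.center_ppm)
        err = np.abs([p.j_hz - jt for p, jt in zip(pairs, j_true)])
        bound = 2 * f2.sw_hz / 1024
        assert err.max() <= bound
        assert err.mean() <= bound / 2

    @pytest.mark.parametrize("subpoint,tol_points", [(True, 0.2), (False, 1.0)])
    def test_chemical_shift_restoration(self, subpoint, tol_points):
        """The vd peak of an isolated system lands on the true proton shift
        to within a fraction of a full-resolution point."""
        f2 = v.FrequencyAxis(12.0172, 700.13, 9.5, 16384)
        ch = v.SpinSystemSpec(delta_h=3.25, delta_c=43.3, j_ch=147.3)
        clip = v.simulate_hsqc([ch], v.AcquisitionParams(f2, F1_SMALL, "clip"))
        clap = v.simulate_hsqc([ch], v.AcquisitionParams(f2, F1_SMALL, "clap"))
        res = v.virtual_decouple(clip, clap, v.VdConfig(subpoint_shift=subpoint))
        [pair] = res.report.pairs
        row = res.vd.data[pair.f1_index]
        refined = v.parabolic_refine(row, int(np.argmax(row)))
        assert abs(refined - float(f2.ppm_to_index(3.25))) <= tol_points

    def test_lineshape_preserved_vs_ideal_decoupling(self):
        """The vd trace of an isolated multiplet correlates >= 0.99 with an
        idealized infinite-acquisition decoupled simulation processed the
        same way."""
        f2 = v.FrequencyAxis(12.0172, 700.13, 9.5, 8192)
        ch = v.SpinSystemSpec(delta_h=3.25, delta_c=43.3, j_ch=145.0,
                              passive_couplings=((6.8, 2),))
        mk = lambda m: v.simulate_hsqc([ch], v.AcquisitionParams(
            f2, F1_SMALL, m, aq_override_s=np.inf))
        cfg = v.VdConfig()
        res = v.virtual_decouple(mk("clip"), mk("clap"), cfg)
        ideal = v.process_2d(mk("decoupled"), cfg.effective_clip_proc())
        tr_vd = v.extract_row(res.vd, 43.3)
        tr_ideal = v.extract_row(ideal, 43.3)
        r = v.trace_similarity(tr_vd, tr_ideal, (3.15, 3.35))
        assert r >= 0.99

    def test_bit_identical_determinism(self):
        f2 = v.FrequencyAxis(12.0172, 700.13, 9.5, 4096)
        ch = v.SpinSystemSpec(delta_h=3.25, delta_c=43.3, j_ch=145.0)
        clip = v.simulate_hsqc([ch], v.AcquisitionParams(f2, F1_SMALL, "clip"),
                               noise_sigma=0.01, seed=9)
        clap = v.simulate_hsqc([ch], v.AcquisitionParams(f2, F1_SMALL, "clap"),
                               noise_sigma=0.01, seed=10)
        r1 = v.virtual_decouple(clip, clap)
        r2 = v.virtual_decouple(clip, clap)
        assert np.array_equal(r1.vd.data, r2.vd.data)
        assert r1.report.to_dict() == r2.report.to_dict()

    def test_report_json_serializable(self, zebra_result):
        doc = zebra_result.report.to_dict(zebra_result.vd.f1_axis)
        text = json.dumps(doc)
        assert "pairs" in json.loads(text)
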