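import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from datbridge import phantom, quantify
from datbridge.volume_io import Volume


def _vol(data):
    return Volume(data=np.asarray(data, dtype=float), affine=np.eye(4))


def _masks(shape, n_roi, n_bg, seed=0):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(int(np.prod(shape)))
    roi = np.zeros(shape, dtype=bool).ravel()
    bg = np.zeros(shape, dtype=bool).ravel()
    roi[idx[:n_roi]] = True
    bg[idx[n_roi:n_roi + n_bg]] = True
    return roi.reshape(shape), bg.reshape(shape)


class TestBindingRatio:
    def test_hand_fixture(self):
        data = np.zeros((3, 1, 1))
        data[0] = 6.0   # ROI voxel
        data[1] = 2.0   # background voxels
        data[2] = 2.0
        roi = np.array([True, False, False])[:, None, None]
        bg = np.array([False, True, True])[:, None, None]
        assert quantify.binding_ratio(_vol(data), roi, bg) == pytest.approx(2.0)

    def test_null_contrast(self, rng):
        data = np.full((4, 4, 4), 3.3)
        roi, bg = _masks((4, 4, 4), 10, 20)
        assert quantify.binding_ratio(_vol(data), roi, bg) == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(7)
        data = rng.random((4, 4, 4)) + 0.5
        roi, bg = _masks((4, 4, 4), 8, 16, seed=1)
        base = quantify.binding_ratio(_vol(data), roi, bg)
        scaled = quantify.binding_ratio(_vol(c * data), roi, bg)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_matches_bruteforce_loop_oracle(self):
        rng = np.random.default_rng(11)
        for trial in range(100):
            data = rng.random((4, 4, 4)) + 0.1
            roi, bg = _masks((4, 4, 4), int(rng.integers(1, 20)),
                             int(rng.integers(1, 20)), seed=trial)
            r_sum = b_sum = 0.0
            r_n = b_n = 0
            for i in range(4):
                for j in range(4):
                    for k in range(4):
                        if roi[i, j, k]:
                            r_sum += data[i, j, k]
                            r_n += 1
                        if bg[i, j, k]:
                            b_sum += data[i, j, k]
                            b_n += 1
            brute = (r_sum / r_n - b_sum / b_n) / (b_sum / b_n)
            assert quantify.binding_ratio(_vol(data), roi, bg) == pytest.approx(
                brute, abs=1e-9)

    def test_empty_sets_and_bad_background(self):
        data = np.ones((3, 3, 3))
        roi, bg = _masks((3, 3, 3), 3, 3)
        with pytest.raises(ValueError, match="ROI"):
            quantify.binding_ratio(_vol(data), np.zeros((3, 3, 3), bool), bg)
        with pytest.raises(ValueError, match="background"):
            quantify.binding_ratio(_vol(data), roi, np.zeros((3, 3, 3), bool))
        with pytest.raises(ValueError, match="positive"):
            quantify.binding_ratio(_vol(np.zeros((3, 3, 3))), roi, bg)


class TestCNR:
    def test_hand_fixture(self):
        # striatum mean 8, background mean 2 with population SD 3
        data = np.zeros((5, 1, 1))
        data[0] = 8.0
        data[1:5, 0, 0] = [2 - 3, 2 + 3, 2 - 3, 2 + 3]
        stri = np.array([True] + [False] * 4)[:, None, None]
        bg = ~stri
        assert quantify.cnr(_vol(data), stri, bg) == pytest.approx(2.0)

    def test_null_contrast_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        data = rng.random((4, 4, 4)) + 1.0
        stri, bg = _masks((4, 4, 4), 8, 20, seed=2)
        data[stri] = data[bg].mean()
        assert quantify.cnr(_vol(data), stri, bg) == pytest.approx(0.0, abs=1e-12)
        base_data = rng.random((4, 4, 4)) + 1.0
        base = quantify.cnr(_vol(base_data), stri, bg)
        assert quantify.cnr(_vol(3.7 * base_data), stri, bg) == pytest.approx(base, rel=1e-9)

    def test_population_sd_convention(self, rng):
        data = rng.random((4, 4, 4)) + 1.0
        stri, bg = _masks((4, 4, 4), 6, 12, seed=3)
        expected = (data[stri].mean() - data[bg].mean()) / data[bg].std(ddof=0)
        assert quantify.cnr(_vol(data), stri, bg) == pytest.approx(expected, abs=1e-12)

    def test_zero_background_sd_rejected(self):
        data = np.ones((3, 3, 3))
        stri, bg = _masks((3, 3, 3), 3, 6)
        with pytest.raises(ValueError, match="SD"):
            quantify.cnr(_vol(data), stri, bg)


class TestReport:
    @pytest.fixture
    def pd_phantom(self):
        from dataclasses import replace

        spec = replace(phantom.default_spec("PD", "SPECT_like"),
                       psf_fwhm_mm=0.0, noise_sd=0.0)
        return spec, *phantom.generate_phantom(spec)

    def test_region_recovery(self, pd_phantom):
        spec, vol, atlas = pd_phantom
        rep = quantify.report(vol, atlas)
        assert rep.CBR == pytest.approx(
            (spec.target_sbr["caudate_left"] + spec.target_sbr["caudate_right"]) / 2, abs=1e-9)
        assert rep.PBR == pytest.approx(
            (spec.target_sbr["putamen_left"] + spec.target_sbr["putamen_right"]) / 2, abs=1e-9)

    def test_sbr_between_cbr_and_pbr(self, pd_phantom):
        _, vol, atlas = pd_phantom
        rep = quantify.report(vol, atlas)
        assert min(rep.CBR, rep.PBR) <= rep.SBR <= max(rep.CBR, rep.PBR)

    def test_hemisphere_mean_flag(self, pd_phantom):
        _, vol, atlas = pd_phantom
        pooled = quantify.report(vol, atlas)
        hemi = quantify.report(vol, atlas, hemisphere_mean=True)
        expected = 0.5 * (pooled.SBR_L + pooled.SBR_R)
        assert hemi.SBR == pytest.approx(expected, abs=1e-12)

    def test_grid_mismatch_rejected(self, pd_phantom, rng):
        _, vol, atlas = pd_phantom
        small = Volume(data=rng.random((8, 8, 8)), affine=np.eye(4))
        with pytest.raises(ValueError, match="grid mismatch"):
            quantify.report(small, atlas)


class TestCohortTable:
    def _rep(self, value, cohort="NC", sid="s"):
        return quantify.BindingReport(subject_id=sid, cohort=cohort, SBR=value,
                                      CBR=value, PBR=value, SBR_L=value, SBR_R=value,
                                      asymmetry=0.0, CNR=1.0)

    def test_single_report_sd_zero(self):
        table = quantify.cohort_table([self._rep(1.5)])
        row = table.iloc[0]
        assert row["SBR_mean"] == 1.5
        assert row["SBR_sd"] == 0.0

    def test_two_reports_mean(self):
        table = quantify.cohort_table([self._rep(1.0, sid="a"), self._rep(3.0, sid="b")])
        assert table.iloc[0]["SBR_mean"] == pytest.approx(2.0)

    def test_matches_spreadsheet_style_recomputation(self, rng):
        reports = [self._rep(float(v), cohort="NC" if i % 2 else "PD", sid=str(i))
                   for i, v in enumerate(rng.random(10) + 1.0)]
        table = quantify.cohort_table(reports).set_index("cohort")
        for cohort in ("NC", "PD"):
            vals = [r.SBR for r in reports if r.cohort == cohort]
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert table.loc[cohort, "SBR_mean"] == pytest.approx(mean, abs=1e-12)
            assert table.loc[cohort, "SBR_sd"] == pytest.approx(sd, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quantify.cohort_table([])


class TestScaleInvarianceOfAllMeasures:
    def test_max_normalization_never_changes_ratios(self):
        vol, atlas = phantom.generate_phantom(phantom.default_spec("NC", "SPECT_like", seed=4))
        rep = quantify.report(vol, atlas)
        scaled = quantify.report(vol.with_data(vol.data / vol.data.max()), atlas)
        for field in ("SBR", "CBR", "PBR", "SBR_L", "SBR_R", "asymmetry", "CNR"):
            assert getattr(scaled, field) == pytest.approx(getattr(rep, field), rel=1e-9)
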