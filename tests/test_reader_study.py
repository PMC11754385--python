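import itertools

import numpy as np
import pandas as pd
import pytest

from datbridge import reader_study
from datbridge.reader_study import (
    CRITERIA,
    GroupComparison,
    ReaderSheet,
    cohen_d,
    compare_groups,
    mann_whitney,
    reader_diagnostics,
    reader_report,
    vgas,
    vgas_table,
)


def make_sheet(rng=None, n_images=10, n_obs=4, scores_real=None, scores_syn=None):
    """Complete reader sheet; 5 NC + 5 PD per source, perfect diagnoses."""
    rng = rng or np.random.default_rng(0)
    rows = []
    truth = {}
    for source in ("real", "synthetic"):
        for i in range(n_images):
            img = f"{source}_{i}"
            truth[img] = "NC" if i < n_images // 2 else "PD"
            for o in range(n_obs):
                fixed = scores_real if source == "real" else scores_syn
                s = fixed if fixed is not None else int(rng.integers(1, 4))
                rows.append({"observer": f"r{o}", "image": img, "source": source,
                             "noise": s, "artifacts": s, "synthetic_appearance": s,
                             "confidence": s, "diagnosis": truth[img]})
    return ReaderSheet(scores=pd.DataFrame(rows), ground_truth=truth)


class TestVgas:
    def test_bounds(self):
        assert vgas(np.full((2, 3), 1)) == 1.0
        assert vgas(np.full((5, 4), 3)) == 3.0

    def test_hand_arithmetic(self):
        assert vgas(np.array([[1, 2], [3, 2]])) == pytest.approx(2.0)

    def test_equals_mean_of_all_scores(self, rng):
        for _ in range(20):
            grid = rng.integers(1, 4, size=(rng.integers(2, 8), rng.integers(2, 6)))
            assert vgas(grid) == pytest.approx(grid.mean(), abs=1e-12)
            assert 1.0 <= vgas(grid) <= 3.0

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError, match="1, 2, 3"):
            vgas(np.array([[1, 4], [2, 2]]))
        with pytest.raises(ValueError, match="missing"):
            vgas(np.array([[1.0, np.nan], [2.0, 2.0]]))


class TestSheetValidation:
    def test_duplicate_observer_image_rejected(self):
        sheet = make_sheet()
        dup = pd.concat([sheet.scores, sheet.scores.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            ReaderSheet(scores=dup, ground_truth=sheet.ground_truth)

    def test_score_out_of_range_rejected(self):
        sheet = make_sheet()
        bad = sheet.scores.copy()
        bad.loc[0, "noise"] = 5
        with pytest.raises(ValueError, match="outside"):
            ReaderSheet(scores=bad, ground_truth=sheet.ground_truth)

    def test_csv_round_trip(self, tmp_path):
        sheet = make_sheet()
        df = sheet.scores.copy()
        df["truth"] = df["image"].map(sheet.ground_truth)
        path = tmp_path / "sheet.csv"
        df.to_csv(path, index=False)
        back = ReaderSheet.from_csv(path)
        assert back.ground_truth == sheet.ground_truth
        assert len(back.scores) == len(sheet.scores)


class TestVgasTable:
    def test_identical_distributions_p_one(self):
        sheet = make_sheet(scores_real=2, scores_syn=2)
        table = vgas_table(sheet)
        assert np.allclose(table["p_real_vs_synthetic"], 1.0)

    def test_extreme_separation_u_statistic_matches_enumeration(self):
        sheet = make_sheet(scores_real=3, scores_syn=1)
        table = vgas_table(sheet)
        # brute-force U: count pairs (real image, synthetic image) with
        # real per-image mean > synthetic per-image mean (+0.5 for ties)
        real, syn = [3.0] * 10, [1.0] * 10
        u_brute = sum(1.0 if r > s else (0.5 if r == s else 0.0)
                      for r, s in itertools.product(real, syn))
        assert u_brute == 100.0
        assert np.allclose(table["U"], u_brute)

    def test_shape_four_criteria_by_two_sources(self, rng):
        table = vgas_table(make_sheet(rng))
        assert len(table) == 8
        assert set(table["criterion"]) == set(CRITERIA)
        assert set(table["source"]) == {"real", "synthetic"}

    def test_single_source_rejected(self):
        sheet = make_sheet()
        real_only = sheet.scores[sheet.scores["source"] == "real"]
        rs = ReaderSheet(scores=real_only, ground_truth=sheet.ground_truth)
        with pytest.raises(ValueError, match="both image sources"):
            vgas_table(rs)


class TestReaderDiagnostics:
    def _sheet_with_confusion(self, tp, fn, tn, fp):
        """5 PD and 5 NC images; one observer with the given confusion."""
        rows = []
        truth = {}
        pd_calls = ["PD"] * tp + ["NC"] * fn
        nc_calls = ["NC"] * tn + ["PD"] * fp
        for i, call in enumerate(pd_calls + nc_calls):
            img = f"img{i}"
            truth[img] = "PD" if i < 5 else "NC"
            rows.append({"observer": "r1", "image": img, "source": "synthetic",
                         "noise": 1, "artifacts": 1, "synthetic_appearance": 1,
                         "confidence": 1, "diagnosis": call})
        return ReaderSheet(scores=pd.DataFrame(rows), ground_truth=truth)

    def test_reader_with_4of5_pd_1of5_nc_auc_half(self):
        sheet = self._sheet_with_confusion(tp=4, fn=1, tn=1, fp=4)
        out = reader_diagnostics(sheet)
        assert out.iloc[0]["auc"] == pytest.approx(0.5)

    def test_perfect_reader_auc_one(self):
        out = reader_diagnostics(self._sheet_with_confusion(tp=5, fn=0, tn=5, fp=0))
        assert out.iloc[0]["auc"] == 1.0

    def test_reader_with_2of5_pd_4of5_nc_npv(self):
        out = reader_diagnostics(self._sheet_with_confusion(tp=2, fn=3, tn=4, fp=1))
        assert out.iloc[0]["npv_pct"] == 57.1

    def test_binary_auc_identity_matches_sweep(self, rng):
        """(sens+spec)/2 equals the generic sweep AUC on a binary score."""
        from datbridge.classify import roc_auc_sweep

        for _ in range(30):
            tp, fn = rng.integers(0, 6), rng.integers(0, 6)
            tn, fp = rng.integers(0, 6), rng.integers(0, 6)
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = reader_report(int(tp), int(fp), int(tn), int(fn))
            labels = [1] * (tp + fn) + [0] * (tn + fp)
            scores = ([1.0] * tp + [0.0] * fn) + ([0.0] * tn + [1.0] * fp)
            sweep, _, _ = roc_auc_sweep(np.array(labels), np.array(scores))
            assert rep.auc == pytest.approx(sweep, abs=1e-12)


class TestCompareGroups:
    def test_identical_samples_d_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = compare_groups(x, x.copy())
        assert res.cohen_d == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_unit_shift_gives_d_one(self, rng):
        x = rng.normal(0.0, 1.0, size=200)
        x = (x - x.mean()) / x.std(ddof=1)  # sample SD exactly 1
        res = compare_groups(x + 1.0, x)
        assert res.cohen_d == pytest.approx(1.0, abs=1e-9)

    def test_normal_samples_route_to_t(self, rng):
        res = compare_groups(rng.normal(size=30), rng.normal(size=30) + 0.2)
        assert res.test_name == "student_t"
        assert res.ci95_mean_difference is not None

    def test_heavy_tailed_samples_route_to_mann_whitney(self, rng):
        x = rng.standard_cauchy(size=50)
        y = rng.standard_cauchy(size=50) + 1.0
        res = compare_groups(x, y)
        assert res.test_name == "mann_whitney_u"

    def test_symmetry_up_to_sign(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25) + 0.4
        ab = compare_groups(x, y)
        ba = compare_groups(y, x)
        assert ab.test_name == ba.test_name
        assert ab.cohen_d == pytest.approx(-ba.cohen_d, abs=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, abs=1e-9)

    def test_degenerate_sample_flags_d_undefined(self):
        res = compare_groups(np.ones(5), np.ones(5))
        assert res.cohen_d is None

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_groups(np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0]))

    def test_exact_u_for_small_tie_free_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        u, p = mann_whitney(x, y)
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-9)  # 2 * 1/C(6,3)
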