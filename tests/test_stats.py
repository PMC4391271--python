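import itertools
import math

import numpy as np
import pandas as pd
import pytest

from xylemtrace.hydraulics import HydraulicSummary
from xylemtrace.stats import (ComparisonReport, PairedSample, SegmentData,
                              coefficient_of_variation, compare_bf_ef,
                              fit_regression, paired_ttest, paired_wilcoxon,
                              percent_reduction)


def _sample(x, y):
    return PairedSample(list(range(len(x))), np.asarray(x, float),
                        np.asarray(y, float))


class TestPairedWilcoxon:
    def test_identical_samples_degenerate(self):
        with pytest.warns(UserWarning):
            _, p = paired_wilcoxon(_sample([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        assert p == 1.0

    def test_exact_against_sign_enumeration(self):
        """n=6 all-positive distinct differences: p must equal the exact
        two-sided tail from brute-force enumeration of all 2^6 sign flips."""
        x = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        d = np.array(x) - np.array(y)
        ranks = np.argsort(np.argsort(np.abs(d))) + 1
        w_obs = ranks[d > 0].sum()
        total = ranks.sum()
        count = 0
        for signs in itertools.product([1, -1], repeat=6):
            w = sum(r for r, s in zip(ranks, signs) if s > 0)
            if min(w, total - w) <= min(w_obs, total - w_obs):
                count += 1
        p_exact = count / 2 ** 6
        assert p_exact == 2 / 64
        _, p = paired_wilcoxon(_sample(x, y))
        assert p == pytest.approx(p_exact, rel=1e-12)

    def test_sign_flip_symmetry(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0]
        y = [2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0]
        _, p1 = paired_wilcoxon(_sample(x, y))
        _, p2 = paired_wilcoxon(_sample(y, x))
        assert p1 == p2

    def test_zero_differences_discarded(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 7.0]
        _, p_with_zero = paired_wilcoxon(_sample(x, y))
        _, p_without = paired_wilcoxon(_sample(x[:6], y[:6]))
        assert p_with_zero == p_without


class TestPairedTTest:
    def test_identical_samples(self):
        with pytest.warns(UserWarning):
            t, p = paired_ttest(_sample([1, 2, 3], [1, 2, 3]))
        assert (t, p) == (0.0, 1.0)

    def test_alternating_differences_cancel(self):
        t, p = paired_ttest(_sample([1, -1, 1, -1], [0, 0, 0, 0]))
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, rel=1e-12)

    def test_matches_textbook_formula(self):
        x = np.array([5.1, 4.8, 6.2, 5.5, 5.9])
        y = np.array([4.9, 4.9, 5.8, 5.0, 5.4])
        d = x - y
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        t, _ = paired_ttest(_sample(x, y))
        assert t == pytest.approx(t_expected, rel=1e-12)


class TestRegression:
    def test_exact_line(self):
        slope, intercept, r2 = fit_regression([1, 2, 3, 4], [2, 4, 6, 8])
        assert slope == pytest.approx(2.0, rel=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0, rel=1e-12)

    def test_permuted_response_uncorrelated(self):
        rng = np.random.default_rng(0)
        x = np.linspace(1, 10, 1000)
        y = rng.permutation(2 * x)
        _, _, r2 = fit_regression(x, y)
        assert r2 < 0.05

    def test_r2_scale_invariant(self):
        x = np.array([1.0, 2, 3, 5, 8])
        y = np.array([1.2, 1.9, 3.4, 4.8, 8.3])
        _, _, r2a = fit_regression(x, y)
        _, _, r2b = fit_regression(x * 1e-10, y * 42.0)
        assert r2a == pytest.approx(r2b, rel=1e-12)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            fit_regression([1, 1, 1], [1, 2, 3])


class TestCV:
    def test_constant_values(self):
        assert coefficient_of_variation([2, 2, 2]) == 0.0

    def test_known_value(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(0.5, rel=1e-12)

    def test_scale_invariance(self):
        v = [1.3, 2.1, 0.8, 4.4]
        assert coefficient_of_variation(v) == pytest.approx(
            coefficient_of_variation([3.7 * x for x in v]), rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1, 1])


class TestPercentReduction:
    @pytest.mark.parametrize("ref,new,expected", [
        (102, 66, 35), (61, 43, 30), (40, 23, 43), (10, 10, 0)])
    def test_printed_count_arithmetic(self, ref, new, expected):
        assert percent_reduction(ref, new) == expected

    def test_half_rounds_away_from_zero(self):
        assert percent_reduction(200, 115) == 43  # 42.5 -> 43
        assert percent_reduction(200, 285) == -43

    def test_bad_reference(self):
        with pytest.raises(ValueError):
            percent_reduction(0, 5)


def _segment(i, segment_type, kh, kht_bf, kht_ef, counts=None):
    summary = HydraulicSummary(
        kh=kh, kht_bf=kht_bf, kht_ef=kht_ef,
        total_lumen_area_bf=1e-8, total_lumen_area_ef=8e-9,
        mean_diameter_bf=10.0, mean_diameter_ef=10.5,
        khs_bf=kh / 1e-8 if kh else None, khs_ef=kh / 8e-9 if kh else None,
        khts_bf=kht_bf / 1e-8, khts_ef=kht_ef / 8e-9,
        ratio_bf_percent=100 * kh / kht_bf if kh else None,
        ratio_ef_percent=100 * kh / kht_ef if kh else None,
        counts=counts or {"px_bf": 60, "px_ef": 42, "mx_bf": 41, "mx_ef": 24,
                          "total_bf": 101, "total_ef": 66})
    return SegmentData(segment_id=f"s{i}", segment_type=segment_type,
                       summary=summary)


class TestCompareBfEf:
    def make_dataset(self, n=8):
        rng = np.random.default_rng(1)
        segs = []
        for i in range(n):
            kht_ef = 10 ** rng.uniform(-11.5, -10)
            kht_bf = kht_ef * rng.uniform(1.3, 2.2)
            kh = kht_ef * rng.uniform(0.15, 0.6)
            segs.append(_segment(i, "apical" if i % 2 else "basal",
                                 kh, kht_bf, kht_ef))
        return segs

    def test_ratio_cells_recomputable(self):
        segs = self.make_dataset()
        report = compare_bf_ef(segs)
        expected = np.mean([s.summary.ratio_ef_percent for s in segs])
        assert report.ratios["mean_ef"] == pytest.approx(expected, rel=1e-12)
        diff = report.ratios["mean_ef"] - report.ratios["mean_bf"]
        assert report.ratios["difference_ef_minus_bf"] == pytest.approx(
            diff, rel=1e-12)

    def test_stores_mean_of_ratios_not_ratio_of_means(self):
        segs = self.make_dataset()
        report = compare_bf_ef(segs)
        mean_of_ratios = np.mean([s.summary.ratio_ef_percent for s in segs])
        ratio_of_means = 100 * (np.mean([s.summary.kh for s in segs])
                                / np.mean([s.summary.kht_ef for s in segs]))
        assert mean_of_ratios != pytest.approx(ratio_of_means, rel=1e-6)
        assert report.ratios["mean_ef"] == pytest.approx(mean_of_ratios, rel=1e-12)

    def test_coincident_calls_give_zero_differences(self):
        segs = []
        for i in range(6):
            kht = 1e-11 * (i + 1)
            counts = {"px_bf": 50, "px_ef": 50, "mx_bf": 30, "mx_ef": 30,
                      "total_bf": 80, "total_ef": 80}
            segs.append(_segment(i, "apical", 0.3 * kht, kht, kht, counts))
        report = compare_bf_ef(segs)
        assert report.reductions == {"px": 0, "mx": 0, "total": 0}
        assert report.ratios["difference_ef_minus_bf"] == pytest.approx(0.0)

    def test_segments_without_kh_excluded_with_warning(self):
        segs = self.make_dataset()
        segs.append(_segment(99, "basal", None, 2e-10, 1e-10))
        with pytest.warns(UserWarning, match="lack K_h"):
            report = compare_bf_ef(segs)
        assert report.ratios["n_ef"] == len(segs) - 1
        assert report.regressions["ef"]["n"] == len(segs) - 1

    def test_report_deterministic(self):
        segs = self.make_dataset()
        a = compare_bf_ef(segs).to_dict()
        b = compare_bf_ef(segs).to_dict()
        assert a == b

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            compare_bf_ef(self.make_dataset(1))

    def test_markdown_render(self):
        report = compare_bf_ef(self.make_dataset())
        text = report.to_markdown()
        assert "K_h ~ K_ht regressions" in text and "R2" in text
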