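"""Dice overlap, NIRF positivity calls, contingency analysis, exact tests."""

import math

import numpy as np
import pytest
import scipy.stats

from fgsquant import concord, pipeline, synth
from fgsquant.concord import ContingencyTable
from fgsquant.exceptions import UndefinedStatisticError
from fgsquant.roiquant import MFIStats

from conftest import square_mask


def dice_oracle(a, b):
    inter = na = nb = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            na += bool(a[r, c])
            nb += bool(b[r, c])
            inter += bool(a[r, c]) and bool(b[r, c])
    return 2 * inter / (na + nb)


class TestDice:
    def test_identical_and_disjoint(self):
        a = square_mask()
        assert concord.dice(a, a) == 1.0
        b = np.zeros_like(a)
        b[0:2, 0:2] = True
        assert concord.dice(a, b) == 0.0

    def test_half_overlap_hand_case(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0:4] = True  # |A| = 4
        b[0, 2:4] = b[1, 0:2] = True  # |B| = 4, overlap 2
        assert concord.dice(a, b) == 0.5

    def test_matches_brute_force_oracle_and_symmetry(self, rng):
        for _ in range(25):
            a = rng.random((32, 32)) < 0.3
            b = rng.random((32, 32)) < 0.3
            if not (a.any() or b.any()):
                continue
            d = concord.dice(a, b)
            assert d == pytest.approx(dice_oracle(a, b))
            assert d == concord.dice(b, a)
            assert 0.0 <= d <= 1.0
            assert (d == 1.0) == np.array_equal(a, b)

    def test_error_cases(self):
        with pytest.raises(UndefinedStatisticError):
            concord.dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            concord.dice(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestNirfPositiveMask:
    BG = MFIStats(mean=40.0, minimum=30, maximum=50, sd=2.0, n_pixels=100)

    def test_background_level_image_gives_empty_mask(self):
        img = np.full((50, 50), 40, np.uint8)
        assert not concord.nirf_positive_mask(img, self.BG, k=3).any()

    def test_huge_k_gives_empty_mask(self):
        img = np.full((50, 50), 200, np.uint8)
        bg = MFIStats(mean=40.0, minimum=40, maximum=40, sd=1.0, n_pixels=100)
        assert not concord.nirf_positive_mask(img, bg, k=1e6).any()

    def test_speckles_below_min_area_removed(self):
        img = np.full((50, 50), 40, np.uint8)
        img[10, 10] = 200  # single bright pixel
        img[30:37, 30:37] = 200  # 49-px focus survives
        mask = concord.nirf_positive_mask(img, self.BG, k=3, min_area=25)
        assert not mask[10, 10]
        assert mask[33, 33]

    def test_phantom_signal_matches_tumor_with_high_dice(self):
        cfg = synth.PhantomConfig(true_tbr=3.0, noise_sd=1.0, seed=8)
        case = synth.make_phantom(cfg)
        bg = pipeline.background_stats(case)
        mask = concord.nirf_positive_mask(case.ir_image, bg, k=3)
        assert concord.dice(mask, case.tumor_mask) >= 0.95

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            concord.nirf_positive_mask(np.zeros((5, 5), np.uint8), self.BG, k=0)


class TestClassifySection:
    @pytest.mark.parametrize(
        "call,label,expected",
        [
            ("positive", "neoplastic", "TP"),
            ("positive", "non-neoplastic", "FP"),
            ("negative", "neoplastic", "FN"),
            ("negative", "non-neoplastic", "TN"),
        ],
    )
    def test_mapping(self, call, label, expected):
        assert concord.classify_section(call, label) == expected

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            concord.classify_section("bright", "neoplastic")
        with pytest.raises(ValueError):
            concord.classify_section("positive", "tumour")


class TestAccuracySummary:
    def test_reference_cohort_estimates(self):
        s = concord.accuracy_summary(ContingencyTable(tp=76, tn=56, fp=16, fn=0))
        assert s.sensitivity == 100.0
        assert s.specificity == 77.8  # prints as 78%
        assert s.accuracy == 89.2
        assert s.tp_share == 57.6 and s.tn_share == 42.4
        assert s.fp_rate == 10.8
        lo, hi = s.ci["sensitivity"]
        assert (lo, hi) == (95.3, 100.0)  # exact CI at 76/76

    def test_trivial_perfect_table(self):
        s = concord.accuracy_summary(ContingencyTable(tp=1, tn=1, fp=0, fn=0))
        assert s.sensitivity == s.specificity == s.accuracy == 100.0

    def test_three_of_four_sensitivity(self):
        s = concord.accuracy_summary(ContingencyTable(tp=3, tn=0, fp=1, fn=1))
        assert s.sensitivity == 75.0

    def test_ci_contains_estimate(self):
        s = concord.accuracy_summary(ContingencyTable(tp=40, tn=30, fp=10, fn=5))
        for name in ("sensitivity", "specificity", "accuracy"):
            lo, hi = s.ci[name]
            assert lo <= getattr(s, name) <= hi

    def test_undefined_estimates_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            concord.accuracy_summary(ContingencyTable(tp=0, tn=5, fp=1, fn=0))

    def test_exact_ci_coverage_near_nominal(self, rng):
        # Clopper-Pearson is conservative: coverage >= 95% up to MC error
        p, n, sims = 0.8, 72, 2000
        counts = rng.binomial(n, p, size=sims)
        lo = scipy.stats.beta.ppf(0.025, counts, n - counts + 1)
        hi = scipy.stats.beta.ppf(0.975, counts + 1, n - counts)
        lo = np.where(counts == 0, 0.0, lo)
        hi = np.where(counts == n, 1.0, hi)
        coverage = np.mean((lo <= p) & (p <= hi))
        assert coverage >= 0.95 - 0.015


def fisher_oracle(tp, fn, fp, tn):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    row1, row2 = tp + fn, fp + tn
    col1 = tp + fp
    n = row1 + row2

    def prob(a):
        return (
            math.comb(row1, a) * math.comb(row2, col1 - a) / math.comb(n, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = prob(tp)
    return sum(p for a in range(lo, hi + 1) if (p := prob(a)) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_balanced_table_p_is_one(self):
        assert concord.fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 9, size=4))
            if tp + tn + fp + fn == 0:
                continue
            table = ContingencyTable(tp=tp, tn=tn, fp=fp, fn=fn)
            assert concord.fisher_exact(table) == pytest.approx(
                fisher_oracle(tp, fn, fp, tn), rel=1e-9
            )

    def test_p_in_unit_interval(self):
        p = concord.fisher_exact(ContingencyTable(5, 5, 0, 0))
        assert 0 < p <= 1


class TestRoundHalfUp:
    @pytest.mark.parametrize(
        "x,expected", [(77.75, 77.8), (10.7382, 10.7), (0.05, 0.1), (89.189, 89.2)]
    )
    def test_half_up_not_bankers(self, x, expected):
        assert concord.round_half_up(x, 1) == expected
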