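"""Mask overlap arithmetic and evaluation statistics."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from contourqa.metrics import (
    UNDEFINED,
    FailureRuleConfig,
    MetricReport,
    QualityPair,
    dice,
    is_failed_prediction,
    mae,
    mape_percent,
    metric_report,
    qualitative_accuracy,
    spearman,
)


def brute_force_dice(a, b):
    """Voxel-enumeration oracle: count memberships with explicit loops."""
    na = nb = ninter = 0
    for idx in np.ndindex(a.shape):
        if a[idx]:
            na += 1
        if b[idx]:
            nb += 1
        if a[idx] and b[idx]:
            ninter += 1
    return 2 * ninter / (na + nb)


class TestDice:
    def test_known_overlap_on_explicit_grid(self):
        # |A| = 4, |B| = 6, |A∩B| = 3 on a 3×3×1 grid → 2·3/(4+6) = 0.6
        a = np.zeros((3, 3, 1), bool)
        b = np.zeros((3, 3, 1), bool)
        a[0, 0, 0] = a[0, 1, 0] = a[1, 0, 0] = a[1, 1, 0] = True
        b[0, 1, 0] = b[1, 0, 0] = b[1, 1, 0] = b[2, 0, 0] = b[2, 1, 0] = b[2, 2, 0] = True
        assert int(a.sum()) == 4 and int(b.sum()) == 6 and int((a & b).sum()) == 3
        assert dice(a, b) == brute_force_dice(a, b) == 0.6

    def test_identical_and_disjoint(self, rng):
        m = rng.random((4, 5, 3)) < 0.4
        m[0, 0, 0] = True
        assert dice(m, m) == 1.0
        other = ~m
        assert dice(m, other) == 0.0

    def test_symmetry_and_self_identity(self, rng):
        for _ in range(100):
            a = rng.random((5, 4, 3)) < rng.uniform(0.1, 0.9)
            b = rng.random((5, 4, 3)) < rng.uniform(0.1, 0.9)
            if not (a.any() or b.any()):
                continue
            assert dice(a, b) == dice(b, a)
            if a.any():
                assert dice(a, a) == 1.0

    def test_nested_masks_closed_form(self, rng):
        big = rng.random((6, 6, 4)) < 0.5
        big[0, 0, 0] = True
        small = big.copy()
        drop = np.flatnonzero(big.ravel())[:: 2]
        small.ravel()[drop] = False
        if not small.any():
            small.ravel()[np.flatnonzero(big.ravel())[0]] = True
        assert dice(small, big) == 2 * small.sum() / (small.sum() + big.sum())

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        a=hnp.arrays(bool, (4, 3, 2)),
        b=hnp.arrays(bool, (4, 3, 2)),
    )
    def test_bounds_symmetry_intersection_property(self, a, b):
        if not (a.any() or b.any()):
            return
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        assert (d == 0.0) == (not (a & b).any())

    def test_errors(self):
        a = np.zeros((2, 2, 2), bool)
        with pytest.raises(ValueError, match="empty"):
            dice(a, a)
        with pytest.raises(ValueError, match="shape"):
            dice(np.ones((2, 2, 2), bool), np.ones((3, 2, 2), bool))
        with pytest.raises(ValueError, match="binary"):
            dice(np.full((2, 2, 2), 2.0), np.ones((2, 2, 2), bool))


class TestErrorMetrics:
    def test_mae_exact_cases(self):
        assert mae([QualityPair(0.5, 0.5), QualityPair(0.9, 0.9)]) == (0.0, 0.0)
        m, _ = mae([QualityPair(0.8, 0.9), QualityPair(0.9, 0.8)])
        assert m == pytest.approx(0.1)

    def test_mae_against_summation_oracle(self, rng):
        pairs = [QualityPair(rng.uniform(), rng.uniform()) for _ in range(1000)]
        total = 0.0
        for p, t in pairs:
            total += abs(p - t)
        mean_oracle = total / len(pairs)
        sq = sum((abs(p - t) - mean_oracle) ** 2 for p, t in pairs)
        sd_oracle = math.sqrt(sq / (len(pairs) - 1))
        m, sd = mae(pairs)
        assert m == pytest.approx(mean_oracle, abs=1e-12)
        assert sd == pytest.approx(sd_oracle, abs=1e-12)

    def test_mape(self, rng):
        assert mape_percent([QualityPair(0.9, 0.9)]) == 0.0
        assert mape_percent([QualityPair(0.9, 1.0)]) == pytest.approx(10.0)
        pairs = [QualityPair(rng.uniform(), rng.uniform(0.1, 1)) for _ in range(200)]
        oracle = sum(100 * abs(p - t) / t for p, t in pairs) / len(pairs)
        assert mape_percent(pairs) == pytest.approx(oracle, abs=1e-10)
        with pytest.raises(ValueError, match="target"):
            mape_percent([QualityPair(0.5, 0.0)])

    def test_empty_inputs_raise(self):
        for fn in (mae, mape_percent, qualitative_accuracy, metric_report):
            with pytest.raises(ValueError):
                fn([])


class TestSpearman:
    def test_perfect_orders(self):
        inc = [QualityPair(i / 10, i / 10 + 0.01) for i in range(8)]
        assert spearman(inc) == 1.0
        rev = [QualityPair(i / 10, 1.0 - i / 10) for i in range(8)]
        assert spearman(rev) == -1.0

    def test_constant_side_is_undefined(self):
        pairs = [QualityPair(0.1 * i, 0.5) for i in range(5)]
        assert spearman(pairs) is UNDEFINED
        pairs = [QualityPair(0.5, 0.1 * i) for i in range(5)]
        assert spearman(pairs) is UNDEFINED

    def test_against_rank_then_pearson_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            # coarse grid → plenty of ties
            pred = rng.integers(0, 5, n) / 4.0
            target = rng.integers(0, 5, n) / 4.0
            pairs = [QualityPair(p, t) for p, t in zip(pred, target)]
            if np.all(pred == pred[0]) or np.all(target == target[0]):
                assert spearman(pairs) is UNDEFINED
                continue
            rp = stats.rankdata(pred)
            rt = stats.rankdata(target)
            oracle = np.corrcoef(rp, rt)[0, 1]
            assert spearman(pairs) == pytest.approx(oracle, abs=1e-12)


class TestFailureRule:
    @pytest.mark.parametrize(
        "pred,target,failed",
        [
            # the two printed misleading predictions from the failure study
            (0.81, 0.11, True),
            (0.82, 0.72, True),
            # quadrant corners of {0.7, 0.85}²
            (0.7, 0.7, False),
            (0.7, 0.85, True),
            (0.85, 0.7, True),
            (0.85, 0.85, False),
            # the [0.75, 0.8] gap never triggers on either axis
            (0.77, 0.95, False),
            (0.1, 0.78, False),
            (0.9, 0.9, False),
            (0.75, 0.95, False),  # boundary: strict inequality
            (0.8, 0.5, False),
        ],
    )
    def test_truth_table(self, pred, target, failed):
        assert is_failed_prediction(QualityPair(pred, target)) is failed

    def test_accuracy_fraction(self):
        good = [QualityPair(0.9, 0.9)] * 478
        bad = [QualityPair(0.9, 0.1)] * 2
        assert qualitative_accuracy(good + bad) == pytest.approx(478 / 480)
        assert qualitative_accuracy(good) == 1.0
        assert qualitative_accuracy(bad) == 0.0

    def test_custom_thresholds(self):
        cfg = FailureRuleConfig(low_pred=0.5, high_pred=0.6,
                                low_target=0.5, high_target=0.6)
        assert is_failed_prediction(QualityPair(0.45, 0.65), cfg)
        assert not is_failed_prediction(QualityPair(0.55, 0.65), cfg)
        with pytest.raises(ValueError):
            FailureRuleConfig(low_pred=0.9, high_pred=0.8)


class TestMetricReport:
    def test_composition(self, rng):
        pairs = [QualityPair(rng.uniform(), rng.uniform(0.05, 1)) for _ in range(50)]
        rep = metric_report(pairs)
        assert rep.mae == mae(pairs)[0]
        assert rep.mape_percent == mape_percent(pairs)
        assert rep.spearman == spearman(pairs)
        assert rep.qualitative_accuracy == qualitative_accuracy(pairs)
        assert rep.max_abs_error >= rep.mae
        assert rep.n == 50

    def test_identical_pairs(self):
        rep = metric_report([QualityPair(0.9, 0.9)] * 5)
        assert rep.mae == 0.0 and rep.qualitative_accuracy == 1.0
        assert rep.spearman is UNDEFINED

    def test_json_round_trip(self, rng):
        pairs = [QualityPair(rng.uniform(), rng.uniform(0.05, 1)) for _ in range(20)]
        rep = metric_report(pairs)
        back = MetricReport.from_json(rep.to_json())
        assert back == rep
        # undefined correlation serializes as null
        rep2 = metric_report([QualityPair(0.5, 0.5)] * 4)
        assert json.loads(rep2.to_json())["spearman"] is None
        assert MetricReport.from_json(rep2.to_json()).spearman is UNDEFINED
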