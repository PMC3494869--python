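"""Tests of Bland–Altman, percentage error and polar trending statistics."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from escco import (
    PairedComparison,
    bland_altman,
    compute_deltas,
    evaluate,
    percentage_error,
    polar_analysis,
    repeated_measures_sd,
)
from escco.method_comparison import CoDelta


def pairs_from(ref, test, sid="A"):
    return [
        PairedComparison(subject_id=sid, time_index=i, test_co=t, ref_co=r)
        for i, (r, t) in enumerate(zip(ref, test))
    ]


class TestBlandAltman:
    def test_hand_arithmetic(self):
        pairs = pairs_from([5.0, 6.0, 7.0], [4.0, 6.0, 8.0])
        res = bland_altman(pairs)
        assert res.bias == pytest.approx(0.0)
        assert res.sd == pytest.approx(1.0)  # sample SD of {-1, 0, 1}
        assert res.loa_lower == pytest.approx(-1.96)
        assert res.loa_upper == pytest.approx(1.96)
        assert res.percentage_error == pytest.approx(100.0 / 3.0)
        assert res.n == 3

    def test_identical_methods_degenerate(self):
        pairs = pairs_from([4.0, 5.0, 6.0], [4.0, 5.0, 6.0])
        res = bland_altman(pairs)
        assert res.bias == 0.0
        assert res.sd == 0.0
        assert res.percentage_error == 0.0
        assert res.loa_lower == res.loa_upper == 0.0
        assert res.r == pytest.approx(1.0)

    def test_limits_span_identity(self, rng):
        co = rng.uniform(2, 10, size=40)
        pairs = pairs_from(co, co + rng.normal(0.3, 0.8, size=40))
        res = bland_altman(pairs)
        assert res.loa_upper - res.loa_lower == pytest.approx(2 * 1.96 * res.sd)

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="at least 2"):
            bland_altman(pairs_from([5.0], [5.5]))


class TestPercentageError:
    def test_zero_sd(self):
        assert percentage_error(0.0, 5.0) == 0.0

    def test_arithmetic(self):
        assert percentage_error(1.0, 5.0) == pytest.approx(40.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            percentage_error(1.0, 0.0)
        with pytest.raises(ValueError):
            percentage_error(-1.0, 5.0)


class TestRepeatedMeasuresSd:
    def test_one_pair_per_subject_equals_plain_sd(self, rng):
        diffs = rng.normal(0.3, 1.2, size=15)
        pairs = [
            PairedComparison(f"S{i}", 0, test_co=5.0 + d, ref_co=5.0)
            for i, d in enumerate(diffs)
        ]
        assert repeated_measures_sd(pairs) == pytest.approx(np.std(diffs, ddof=1))

    def test_balanced_two_subject_closed_form(self):
        """2 subjects x 3 pairs, offsets ±1, no within-subject noise.

        One-way ANOVA by hand: MSW = 0, MSB = 6, n0 = 3, so the
        between-subject variance is 2 and the corrected SD is sqrt(2).
        """
        pairs = [
            PairedComparison("A", i, test_co=5.0 + 1.0, ref_co=5.0) for i in range(3)
        ] + [
            PairedComparison("B", i, test_co=5.0 - 1.0, ref_co=5.0) for i in range(3)
        ]
        assert repeated_measures_sd(pairs) == pytest.approx(math.sqrt(2.0))

    def test_single_subject_falls_back_with_warning(self):
        pairs = pairs_from([5.0, 6.0, 7.0], [4.0, 6.0, 8.0])
        with pytest.warns(UserWarning, match="single subject"):
            out = repeated_measures_sd(pairs)
        assert out == pytest.approx(1.0)

    def test_matches_brute_force_variance_components(self, rng):
        """Oracle: explicit loop-based one-way variance-component estimate."""
        for trial in range(10):
            sizes = rng.integers(1, 5, size=int(rng.integers(2, 6)))
            pairs = []
            diffs_by_subject = []
            for si, m in enumerate(sizes):
                offset = rng.normal(0, 1)
                ds = [offset + rng.normal(0, 0.5) for _ in range(m)]
                diffs_by_subject.append(ds)
                pairs += [
                    PairedComparison(f"S{si}", j, test_co=6.0 + d, ref_co=6.0)
                    for j, d in enumerate(ds)
                ]
            if len(pairs) < 2:
                continue
            expected = _brute_force_corrected_sd(diffs_by_subject)
            assert repeated_measures_sd(pairs) == pytest.approx(expected, abs=1e-9)


def _brute_force_corrected_sd(groups):
    """Independent method-of-moments computation written with plain loops."""
    all_d = [d for g in groups for d in g]
    N = len(all_d)
    k = len(groups)
    if N == k:
        return statistics.stdev(all_d)
    grand = sum(all_d) / N
    ssb = 0.0
    ssw = 0.0
    for g in groups:
        m = sum(g) / len(g)
        ssb += len(g) * (m - grand) ** 2
        for d in g:
            ssw += (d - m) ** 2
    msb = ssb / (k - 1)
    msw = ssw / (N - k)
    n0 = (N - sum(len(g) ** 2 for g in groups) / N) / (k - 1)
    vb = max(0.0, (msb - msw) / n0)
    return math.sqrt(vb + msw)


class TestComputeDeltas:
    def test_direct_subtraction(self):
        pairs = pairs_from([4.0, 5.0, 3.0], [4.2, 5.1, 3.3])
        deltas = compute_deltas(pairs)
        assert [d.d_ref for d in deltas] == [1.0, -2.0]
        assert [round(d.d_test, 10) for d in deltas] == [
            pytest.approx(0.9),
            pytest.approx(-1.8),
        ]

    def test_constant_series_zero_deltas(self):
        deltas = compute_deltas(pairs_from([5.0] * 4, [6.0] * 4))
        assert all(d.d_ref == 0 and d.d_test == 0 for d in deltas)

    def test_grouping_contract(self):
        pairs = pairs_from([4.0, 5.0, 6.0], [4.0, 5.0, 6.0], sid="A") + [
            PairedComparison("B", 0, test_co=5.0, ref_co=5.0)
        ]
        assert len(compute_deltas(pairs)) == 2  # none across subjects

    def test_unsorted_input_sorted_by_time_index(self):
        pairs = [
            PairedComparison("A", 1, test_co=6.0, ref_co=6.0),
            PairedComparison("A", 0, test_co=5.0, ref_co=5.0),
        ]
        [d] = compute_deltas(pairs)
        assert d.d_ref == 1.0


class TestPolarAnalysis:
    def test_perfect_trending(self):
        deltas = [CoDelta("A", 1.0, 1.0) for _ in range(5)]
        res, pts = polar_analysis(deltas)
        assert res.angular_bias_deg == pytest.approx(0.0)
        assert res.radial_loa_deg == pytest.approx(0.0)
        assert res.concordance_rate_30 == 100.0
        assert res.n_included == 5 and res.n_central_excluded == 0

    def test_half_circle_reflection(self):
        res, [pt] = polar_analysis([CoDelta("A", -1.0, -1.0)])
        assert (pt.d_ref, pt.d_test) == (1.0, 1.0)
        assert pt.mean_change == pytest.approx(1.0)
        assert pt.angle_deg == pytest.approx(0.0)
        assert pt.included

    def test_trigonometric_example_and_boundary(self):
        res, pts = polar_analysis([CoDelta("A", 1.0, 3.0), CoDelta("A", 1.0, 0.0)])
        assert pts[0].mean_change == pytest.approx(2.0)
        assert pts[0].angle_deg == pytest.approx(
            math.degrees(math.atan2(3.0, 1.0)) - 45.0
        )
        assert pts[0].angle_deg == pytest.approx(26.565051, abs=1e-5)
        # mean change exactly 0.5: boundary included; angle −45° is discordant
        assert pts[1].mean_change == pytest.approx(0.5)
        assert pts[1].included
        assert pts[1].angle_deg == pytest.approx(-45.0)
        assert res.concordance_rate_30 == pytest.approx(50.0)

    def test_zero_delta_pair_central_zone_excluded(self):
        res, [pt] = polar_analysis([CoDelta("A", 0.0, 0.0)])
        assert not pt.included
        assert res.undefined
        assert res.n_included == 0 and res.n_central_excluded == 1
        assert math.isnan(res.angular_bias_deg)

    def test_concordance_boundary_inclusive(self):
        # angle exactly +30°: tan(75°) ratio
        d_test = math.tan(math.radians(75.0))
        res, [pt] = polar_analysis([CoDelta("A", 1.0, d_test)])
        assert pt.angle_deg == pytest.approx(30.0, abs=1e-9)
        assert res.concordance_rate_30 == 100.0

    def test_percentile_radial_method(self, rng):
        deltas = [
            CoDelta("A", float(a), float(b))
            for a, b in rng.normal(1.5, 0.8, size=(200, 2))
        ]
        sd_res, _ = polar_analysis(deltas, radial_method="sd")
        pc_res, _ = polar_analysis(deltas, radial_method="percentile")
        angles = [p.angle_deg for p in _included(deltas)]
        lo, hi = np.percentile(angles, [2.5, 97.5])
        assert pc_res.radial_limits == (pytest.approx(lo), pytest.approx(hi))
        assert sd_res.radial_limits[0] < sd_res.angular_bias_deg < sd_res.radial_limits[1]


def _included(deltas, central_zone=0.5):
    _, pts = polar_analysis(deltas, central_zone=central_zone)
    return [p for p in pts if p.included]


def test_polar_matches_independent_trigonometric_oracle(rng):
    """Per-point oracle coded separately with plain math functions."""
    deltas = [
        CoDelta("A", float(a), float(b))
        for a, b in rng.normal(0.0, 1.2, size=(1000, 2))
    ]
    res, pts = polar_analysis(deltas)

    oracle_angles = []
    n_excluded = 0
    for d in deltas:
        x, y = d.d_ref, d.d_test
        if (x + y) / 2.0 < 0:
            x, y = -x, -y
        radius = (x + y) / 2.0
        theta = math.atan2(y, x) * 180.0 / math.pi - 45.0
        if radius >= 0.5 - 1e-12:
            oracle_angles.append(theta)
        else:
            n_excluded += 1
    assert res.n_included == len(oracle_angles)
    assert res.n_central_excluded == n_excluded
    got = sorted(p.angle_deg for p in pts if p.included)
    assert np.allclose(got, sorted(oracle_angles), atol=1e-9)
    assert res.angular_bias_deg == pytest.approx(statistics.mean(oracle_angles), abs=1e-9)
    assert res.radial_loa_deg == pytest.approx(
        1.96 * statistics.stdev(oracle_angles), abs=1e-9
    )
    conc = sum(1 for a in oracle_angles if abs(a) <= 30.0 + 1e-12) / len(oracle_angles)
    assert res.concordance_rate_30 == pytest.approx(100.0 * conc, abs=1e-9)


class TestEvaluate:
    def test_zero_noise_cohort_degenerate(self):
        pairs = pairs_from([4.0, 5.5, 7.0], [4.0, 5.5, 7.0])
        report = evaluate(pairs)
        assert report.bland_altman.percentage_error == 0.0
        assert report.polar.concordance_rate_30 == 100.0

    def test_report_internally_consistent_on_random_inputs(self, rng):
        pairs = []
        for sid in "ABCDE":
            co = np.maximum(rng.uniform(2, 9, size=6) , 0.5)
            test = np.maximum(co + rng.normal(0, 1, size=6), 0.5)
            pairs += pairs_from(co, test, sid=sid)
        report = evaluate(pairs)
        ba = report.bland_altman
        assert np.isfinite([ba.bias, ba.sd, ba.sd_corrected, ba.percentage_error]).all()
        assert ba.loa_upper - ba.loa_lower == pytest.approx(2 * 1.96 * ba.sd)
        po = report.polar
        assert po.n_included + po.n_central_excluded == len(report.delta_pairs)
        assert 0.0 <= po.concordance_rate_30 <= 100.0

    def test_subject_permutation_invariance(self, rng):
        pairs = []
        for sid in "ABC":
            co = rng.uniform(3, 8, size=5)
            pairs += pairs_from(co, co + rng.normal(0, 0.7, size=5), sid=sid)
        rep1 = evaluate(pairs)
        rep2 = evaluate(list(reversed(pairs)))
        assert rep1.bland_altman.bias == pytest.approx(rep2.bland_altman.bias)
        assert rep1.bland_altman.sd == pytest.approx(rep2.bland_altman.sd)
        assert rep1.bland_altman.sd_corrected == pytest.approx(
            rep2.bland_altman.sd_corrected
        )
        assert rep1.bland_altman.percentage_error == pytest.approx(
            rep2.bland_altman.percentage_error
        )
        assert rep1.polar.angular_bias_deg == pytest.approx(
            rep2.polar.angular_bias_deg
        )
        assert rep1.polar.concordance_rate_30 == rep2.polar.concordance_rate_30

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate([])


@given(
    st.lists(
        st.tuples(st.floats(1.0, 10.0), st.floats(1.0, 10.0)),
        min_size=4,
        max_size=20,
    )
)
def test_swap_antisymmetry(data):
    """Swapping test and reference negates bias and angular bias."""
    ref = [r for r, _ in data]
    test = [t for _, t in data]
    fwd = evaluate(pairs_from(ref, test))
    rev = evaluate(pairs_from(test, ref))
    assert rev.bland_altman.bias == pytest.approx(-fwd.bland_altman.bias, abs=1e-9)
    assert rev.bland_altman.sd == pytest.approx(fwd.bland_altman.sd, abs=1e-9)
    if fwd.polar is not None and not fwd.polar.undefined:
        assert rev.polar.angular_bias_deg == pytest.approx(
            -fwd.polar.angular_bias_deg, abs=1e-9
        )
        assert rev.polar.radial_loa_deg == pytest.approx(
            fwd.polar.radial_loa_deg, abs=1e-9
        )


@given(
    st.lists(
        st.tuples(st.floats(1.0, 10.0), st.floats(1.0, 10.0)),
        min_size=4,
        max_size=15,
    ),
    st.floats(0.2, 5.0),
)
def test_scale_invariance(data, c):
    """Scaling all CO values leaves PE and per-point polar angles unchanged."""
    ref = [r for r, _ in data]
    test = [t for _, t in data]
    base = evaluate(pairs_from(ref, test))
    scaled = evaluate(pairs_from([c * r for r in ref], [c * t for t in test]))
    assert scaled.bland_altman.percentage_error == pytest.approx(
        base.bland_altman.percentage_error, rel=1e-9
    )
    for p0, p1 in zip(base.delta_pairs, scaled.delta_pairs):
        assert p1.angle_deg == pytest.approx(p0.angle_deg, abs=1e-9)


def test_percentage_error_monte_carlo_consistency():
    """With proportional noise SD sigma on both methods and no bias, the
    percentage error converges to its analytic value ~ 2·sigma·sqrt(2)·100
    (differences test−ref have SD sigma·sqrt(2)·CO around mean CO)."""
    rng = np.random.default_rng(5)
    sigma = 0.08
    co = np.full(1000, 5.0)
    ref = co * (1 + rng.normal(0, sigma, 1000))
    test = co * (1 + rng.normal(0, sigma, 1000))
    pairs = [
        PairedComparison(f"S{i}", 0, test_co=float(t), ref_co=float(r))
        for i, (r, t) in enumerate(zip(ref, test))
    ]
    pe = bland_altman(pairs).percentage_error
    analytic = 2 * sigma * math.sqrt(2) * 100
    assert pe == pytest.approx(analytic, rel=0.12)
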