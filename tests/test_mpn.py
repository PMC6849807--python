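import itertools
import math

import numpy as np
import pytest

from sporetrace.mpn import (
    MpnDesign,
    MpnObservation,
    estimate_mpn,
    mpn_confidence_interval,
    mpn_point_estimate,
    score_tubes,
    select_reading_window,
)

THREE_TUBE = MpnDesign.tenfold(0.1, 3)  # 0.1 / 0.01 / 0.001 g


def grid_mle(obs: MpnObservation, n_points: int = 10_000) -> float:
    """Independent oracle: argmax of the likelihood on a dense log grid."""
    lams = np.logspace(-2, 8, n_points)
    masses = np.array(obs.design.masses)
    pos = np.array(obs.positives, dtype=float)
    neg = np.array(obs.design.n_tubes, dtype=float) - pos
    p = 1.0 - np.exp(-lams[:, None] * masses)
    p = np.clip(p, 1e-300, 1.0)
    q = np.clip(1.0 - p, 1e-300, 1.0)
    loglik = (pos * np.log(p) + neg * np.log(q)).sum(axis=1)
    return float(lams[np.argmax(loglik)])


class TestDesignValidation:
    def test_masses_must_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            MpnDesign(((0.01, 3), (0.1, 3)))

    def test_positives_bounded_by_tubes(self):
        with pytest.raises(ValueError):
            MpnObservation(THREE_TUBE, (4, 0, 0))


class TestScoreTubes:
    def test_clear_positive_and_negative(self):
        obs = score_tubes(
            [[5.0, 5.2, 4.8], [0.04, 0.02, 5.1], [0.0, 0.05, 0.1]],
            blank_mM=[0.0, 0.1, 0.05],
            design=THREE_TUBE,
        )
        assert obs.positives == (3, 1, 0)
        assert obs.sulfide_threshold_mM > 0

    def test_reading_at_blank_mean_is_negative(self):
        obs = score_tubes(
            [[0.05, 0.05, 0.05]], blank_mM=[0.0, 0.1], design=MpnDesign(((0.1, 3),))
        )
        assert obs.positives == (0,)

    def test_single_blank_has_zero_sd(self):
        obs = score_tubes(
            [[0.2, 0.09, 0.1]], blank_mM=[0.1], design=MpnDesign(((0.1, 3),))
        )
        assert obs.positives == (1,)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            score_tubes([[-0.1, 0, 0]], blank_mM=[0.0], design=MpnDesign(((0.1, 3),)))


class TestPointEstimate:
    def test_classic_300_pattern_reads_23_per_gram(self):
        est = estimate_mpn(MpnObservation(THREE_TUBE, (3, 0, 0)))
        assert est.rounded[0] == 23
        # closed form for this pattern: only level 1 positive, so
        # exp(-0.1 lam) / (1 - exp(-0.1 lam)) = 0.11  =>  lam = 10 ln(111/11)
        closed = 10 * math.log(111 / 11)
        assert est.mpn_per_g == pytest.approx(closed, rel=1e-9)

    def test_classic_331_pattern_reads_4600_per_gram(self):
        design = MpnDesign.tenfold(0.01, 3)
        est = estimate_mpn(MpnObservation(design, (3, 3, 1)))
        assert est.rounded[0] == 4600
        assert est.mpn_per_g == pytest.approx(grid_mle(MpnObservation(design, (3, 3, 1))), rel=3e-3)

    def test_single_level_single_positive(self):
        # 1 of 3 tubes at 0.1 g: p = 1/3 => lam = -ln(2/3)/0.1
        design = MpnDesign(((0.1, 3),))
        est = mpn_point_estimate(MpnObservation(design, (1,)))
        assert est.mpn_per_g == pytest.approx(-math.log(2 / 3) / 0.1, rel=1e-9)
        assert est.mpn_per_g == pytest.approx(grid_mle(MpnObservation(design, (1,))), rel=3e-3)

    def test_flags_for_degenerate_patterns(self):
        assert mpn_point_estimate(MpnObservation(THREE_TUBE, (0, 0, 0))).flag == "below_detection"
        assert mpn_point_estimate(MpnObservation(THREE_TUBE, (3, 3, 3))).flag == "above_range"

    def test_mle_matches_grid_oracle_for_all_64_outcomes(self):
        """The score-equation root must agree with dense-grid likelihood
        maximization for the entire 3-level/3-tube outcome space."""
        lams = np.logspace(-2, 8, 10_000)
        step = lams[1] / lams[0]
        for pattern in itertools.product(range(4), repeat=3):
            obs = MpnObservation(THREE_TUBE, pattern)
            if obs.all_negative or obs.all_positive:
                continue
            mle = mpn_point_estimate(obs).mpn_per_g
            oracle = grid_mle(obs)
            # within half a grid step on the log axis
            assert abs(math.log(mle / oracle)) <= 0.5 * math.log(step), pattern

    def test_estimate_monotone_in_positives(self):
        """More positive tubes never lowers the density estimate."""
        def value(pattern):
            obs = MpnObservation(THREE_TUBE, pattern)
            if obs.all_negative:
                return 0.0
            if obs.all_positive:
                return math.inf
            return mpn_point_estimate(obs).mpn_per_g

        for pattern in itertools.product(range(4), repeat=3):
            base = value(pattern)
            for i in range(3):
                if pattern[i] < 3:
                    bumped = list(pattern)
                    bumped[i] += 1
                    assert value(tuple(bumped)) >= base - 1e-9

    def test_scaling_invariance(self):
        scaled = MpnDesign.tenfold(1.0, 3)
        a = mpn_point_estimate(MpnObservation(THREE_TUBE, (3, 1, 0))).mpn_per_g
        b = mpn_point_estimate(MpnObservation(scaled, (3, 1, 0))).mpn_per_g
        assert a == pytest.approx(10 * b, rel=1e-9)


class TestConfidenceInterval:
    def test_exact_limits_for_300_match_classic_table(self):
        est = estimate_mpn(MpnObservation(THREE_TUBE, (3, 0, 0)))
        assert est.rounded == (23, 4.6, 94)

    def test_scaling_invariance_of_limits(self):
        small = estimate_mpn(MpnObservation(MpnDesign.tenfold(1.0, 3), (3, 0, 0)))
        big = estimate_mpn(MpnObservation(THREE_TUBE, (3, 0, 0)))
        assert big.ci_low_per_g == pytest.approx(10 * small.ci_low_per_g, rel=1e-6)
        assert big.ci_high_per_g == pytest.approx(10 * small.ci_high_per_g, rel=1e-6)

    def test_cochran_lognormal_brackets_the_estimate(self):
        obs = MpnObservation(THREE_TUBE, (3, 1, 0))
        lo, hi = mpn_confidence_interval(obs, "cochran_lognormal")
        lam = mpn_point_estimate(obs).mpn_per_g
        assert lo < lam < hi
        # symmetric on the log scale
        assert lam / lo == pytest.approx(hi / lam, rel=1e-9)
        # Cochran's factor for 3 tubes, 10-fold: 10**(1.96*0.58/sqrt(3))
        assert hi / lo == pytest.approx(10 ** (2 * 1.96 * 0.58 / math.sqrt(3)), rel=1e-9)

    def test_one_sided_intervals_for_flagged_patterns(self):
        below = estimate_mpn(MpnObservation(THREE_TUBE, (0, 0, 0)))
        assert below.flag == "below_detection"
        assert below.mpn_per_g == 0 and below.ci_low_per_g == 0
        assert 0 < below.ci_high_per_g < math.inf
        above = estimate_mpn(MpnObservation(THREE_TUBE, (3, 3, 3)))
        assert above.flag == "above_range"
        assert math.isinf(above.ci_high_per_g) and above.ci_low_per_g > 0

    def test_interval_brackets_point_estimate_for_all_informative_outcomes(self):
        for pattern in itertools.product(range(4), repeat=3):
            obs = MpnObservation(THREE_TUBE, pattern)
            if obs.all_negative or obs.all_positive:
                continue
            est = estimate_mpn(obs)
            assert est.ci_low_per_g <= est.mpn_per_g <= est.ci_high_per_g, pattern


class TestReadingWindow:
    SEVEN = MpnDesign.tenfold(0.1, 7)

    def test_window_starts_at_last_all_positive_level(self):
        obs = MpnObservation(self.SEVEN, (3, 3, 1, 0, 0, 0, 0))
        win = select_reading_window(obs)
        assert win.design.masses == pytest.approx((0.01, 0.001, 0.0001))
        assert win.positives == (3, 1, 0)

    def test_all_negative_takes_highest_mass_levels(self):
        obs = MpnObservation(self.SEVEN, (0,) * 7)
        win = select_reading_window(obs)
        assert win.design.masses == pytest.approx((0.1, 0.01, 0.001))
        assert win.positives == (0, 0, 0)

    def test_all_positive_takes_lowest_mass_levels(self):
        obs = MpnObservation(self.SEVEN, (3,) * 7)
        win = select_reading_window(obs)
        assert win.design.masses == pytest.approx((1e-5, 1e-6, 1e-7))
        assert win.positives == (3, 3, 3)

    def test_windowed_and_full_series_estimates_differ(self):
        obs = MpnObservation(self.SEVEN, (3, 3, 1, 0, 0, 0, 0))
        windowed = estimate_mpn(obs).mpn_per_g
        full = estimate_mpn(obs, window=False).mpn_per_g
        assert windowed != pytest.approx(full, rel=1e-3)
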