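"""Required information size, spending functions and sequential boundaries.

Boundary values from the density recursion are cross-checked against
multivariate-normal rectangle probabilities (an independent route through
scipy's MVN integrator) and against closed forms where they exist.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multivariate_normal, norm

from tsameta import (
    GridConfig,
    RISSpec,
    alpha_spent,
    beta_spent,
    build_z_curve,
    compute_boundaries,
    futility_boundaries,
    monitoring_boundaries,
    required_information_size,
    assess_crossings,
    cumulative_series,
)
from tsameta.tsa import ZCurve, ZPoint, BoundarySet

Z975 = 1.959964
Z80 = norm.ppf(0.8)


class TestRIS:
    def test_reference_design(self):
        """alpha .05, power .8, OR 1.5, MAF .3: the unpooled two-proportion
        formula gives 843.94 alleles before heterogeneity adjustment."""
        spec = RISSpec(control_maf=0.3, heterogeneity_adjustment=0.0)
        ris = required_information_size(spec)
        assert ris.p1 == pytest.approx(0.45 / 1.15, abs=1e-12)
        # independent recomputation of the two-proportion size
        p1, p2 = ris.p1, 0.3
        n = (Z975 + Z80) ** 2 * (p1 * (1 - p1) + p2 * (1 - p2)) / (p1 - p2) ** 2
        assert ris.unadjusted_alleles == pytest.approx(2 * n, rel=1e-12)
        assert ris.unadjusted_alleles == pytest.approx(843.94, abs=0.01)
        assert ris.adjusted_alleles == ris.unadjusted_alleles

    def test_matches_statsmodels_sample_size(self):
        """statsmodels' normal-approximation two-sample size for the same
        proportions agrees closely (its variance convention differs only in
        higher-order terms)."""
        from statsmodels.stats.power import NormalIndPower

        spec = RISSpec(control_maf=0.3, heterogeneity_adjustment=0.0)
        ris = required_information_size(spec)
        p1, p2 = ris.p1, ris.p2
        es = (p1 - p2) / math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2)
        n = NormalIndPower().solve_power(effect_size=es, alpha=0.05, power=0.8, ratio=1)
        assert ris.unadjusted_alleles == pytest.approx(2 * n, rel=1e-3)

    def test_heterogeneity_adjustment_is_multiplicative(self):
        base = required_information_size(RISSpec(control_maf=0.3, heterogeneity_adjustment=0.0))
        adj = required_information_size(RISSpec(control_maf=0.3, heterogeneity_adjustment=0.8))
        assert adj.adjusted_alleles == pytest.approx(5 * base.unadjusted_alleles, rel=1e-12)
        assert adj.unadjusted_alleles == pytest.approx(base.unadjusted_alleles, rel=1e-12)

    def test_smaller_alpha_needs_more_information(self):
        sizes = [
            required_information_size(RISSpec(control_maf=0.3, alpha=a)).adjusted_alleles
            for a in (0.05, 0.01, 0.001)
        ]
        assert sizes[0] < sizes[1] < sizes[2]

    def test_null_or_rejected(self):
        with pytest.raises(ValueError):
            RISSpec(control_maf=0.3, assumed_or=1.0)


class TestSpending:
    def test_all_alpha_spent_at_full_information(self):
        assert alpha_spent(1.0, 0.05) == pytest.approx(0.05, abs=1e-8)

    def test_half_information_value(self):
        expected = 2 * norm.sf(Z975 / math.sqrt(0.5))
        assert alpha_spent(0.5, 0.05) == pytest.approx(expected, abs=1e-12)
        assert alpha_spent(0.5, 0.05) == pytest.approx(0.00556, abs=2e-5)

    @given(t=st.floats(0.01, 0.99))
    def test_monotone_spending(self, t):
        assert alpha_spent(t) < alpha_spent(min(1.0, t + 0.01))

    @pytest.mark.parametrize("t", [0.0, -0.5, 1.001])
    def test_domain_errors(self, t):
        with pytest.raises(ValueError):
            alpha_spent(t)
        with pytest.raises(ValueError):
            beta_spent(t)

    def test_beta_spending_normalised(self):
        assert beta_spent(1.0, 0.2) == pytest.approx(0.2, abs=1e-12)
        assert beta_spent(0.3, 0.2) < 0.2


def _mvn_non_crossing(ts, u, seed=0):
    """P(|Z_j| < u_j for all j) for the canonical process, via scipy MVN."""
    ts = np.asarray(ts, float)
    cov = np.sqrt(np.minimum.outer(ts, ts) / np.maximum.outer(ts, ts))
    mv = multivariate_normal(mean=np.zeros(len(ts)), cov=cov, seed=seed)
    return float(mv.cdf(np.asarray(u), lower_limit=-np.asarray(u)))


class TestMonitoringBoundaries:
    def test_single_look_is_fixed_sample_test(self):
        u = monitoring_boundaries([1.0])
        assert u[0] == pytest.approx(1.959964, abs=1e-4)

    def test_first_look_closed_form(self):
        """At the first look the boundary is z_{1-a/2}/sqrt(t1) exactly."""
        for t1 in (0.3, 0.5, 0.8):
            u = monitoring_boundaries([t1, 1.0])
            # probability-scale solver tolerance maps to ~1e-3 in z here
            assert u[0] == pytest.approx(Z975 / math.sqrt(t1), abs=1e-3)
        assert monitoring_boundaries([0.5, 1.0])[0] == pytest.approx(2.7718, abs=5e-4)

    @pytest.mark.parametrize(
        "ts",
        [[0.5, 1.0], [0.25, 0.5, 0.75, 1.0], [0.15, 0.4, 0.9]],
    )
    def test_crossing_probability_matches_mvn_oracle(self, ts):
        u = monitoring_boundaries(ts)
        crossing = 1.0 - _mvn_non_crossing(ts, u)
        assert crossing == pytest.approx(alpha_spent(ts[-1]), abs=5e-4)

    def test_non_increasing_in_information(self):
        u = monitoring_boundaries([0.2, 0.4, 0.6, 0.8, 1.0])
        assert all(np.diff(u) < 0)

    def test_prefix_invariance(self):
        """Appending future looks never changes earlier boundaries."""
        short = monitoring_boundaries([0.3, 0.6])
        long = monitoring_boundaries([0.3, 0.6, 0.85, 1.0])
        assert long[:2] == pytest.approx(short, abs=1e-12)

    def test_bad_schedules_rejected(self):
        for ts in ([], [0.5, 0.5], [0.8, 0.4], [0.0, 1.0], [0.5, 1.2]):
            with pytest.raises(ValueError):
                monitoring_boundaries(ts)


class TestFutilityBoundaries:
    def test_single_look_closes_at_critical_value(self):
        f = futility_boundaries([1.0], alpha=0.05, beta=0.2)
        assert f[0] == pytest.approx(1.959964, abs=1e-3)

    def test_early_wedge_closed(self):
        f = futility_boundaries([0.05, 0.2, 1.0])
        assert math.isnan(f[0])

    def test_wedge_below_monitoring(self):
        ts = [0.4, 0.6, 0.8, 1.0]
        f = futility_boundaries(ts)
        u = monitoring_boundaries(ts)
        mask = ~np.isnan(f)
        assert np.all(f[mask] < u[mask])
        assert np.all(np.diff(f[mask]) > 0)  # wedge opens as information grows

    def test_first_look_closed_form_under_drift(self):
        """First-look futility bound: drift*sqrt(t1) + PHI^-1(beta*(t1))."""
        t1 = 0.5
        drift = Z975 + Z80
        f = futility_boundaries([t1, 1.0], drift=drift)
        expected = drift * math.sqrt(t1) + norm.ppf(beta_spent(t1, 0.2))
        if expected >= 0:
            assert f[0] == pytest.approx(expected, abs=2e-3)
        else:
            assert math.isnan(f[0])

    def test_nonpositive_drift_rejected(self):
        with pytest.raises(ValueError):
            futility_boundaries([1.0], drift=0.0)


class TestComputeBoundaries:
    def test_fractions_beyond_one_reuse_final_boundary(self, small_grid):
        bounds = compute_boundaries([0.4, 0.8, 1.3, 1.9], grid=small_grid)
        assert bounds.info_fractions == (0.4, 0.8, 1.0, 1.0)
        assert bounds.monitoring[2] == bounds.monitoring[3]
        assert math.isnan(bounds.futility[3])
        assert all(b > 0 for b in bounds.monitoring)

    def test_monitoring_non_increasing(self, small_grid):
        bounds = compute_boundaries([0.3, 0.5, 0.9, 1.4], grid=small_grid)
        assert list(bounds.monitoring) == sorted(bounds.monitoring, reverse=True)


class TestZCurveAndCrossings:
    def _curve(self, fractions, zs, ris):
        pts = tuple(
            ZPoint(info_fraction=f, z=z, cum_alleles=int(f * ris.adjusted_alleles), k=i + 1)
            for i, (f, z) in enumerate(zip(fractions, zs))
        )
        return ZCurve(points=pts, ris=ris)

    @pytest.fixture()
    def ris(self):
        return required_information_size(RISSpec(control_maf=0.3))

    def test_curve_from_series(self, effect_literature):
        ris = required_information_size(RISSpec(control_maf=0.3))
        series = cumulative_series(effect_literature)
        curve = build_z_curve(series, ris)
        fracs = [p.info_fraction for p in curve.points]
        assert fracs == sorted(fracs)
        assert curve.points[-1].info_fraction == pytest.approx(
            series[-1].cum_alleles / ris.adjusted_alleles
        )

    def test_no_crossing_low_information(self, ris):
        curve = self._curve([0.2], [0.1], ris)
        bounds = compute_boundaries([0.2], grid=GridConfig(nodes=801))
        rep = assess_crossings(curve, bounds)
        assert rep.first_monitoring_look is None
        assert not rep.ris_reached

    def test_monitoring_crossing_detected(self, ris):
        curve = self._curve([0.5], [3.5], ris)
        bounds = compute_boundaries([0.5], grid=GridConfig(nodes=801))
        assert bounds.monitoring[0] == pytest.approx(2.7718, abs=5e-3)
        rep = assess_crossings(curve, bounds)
        assert rep.first_monitoring_look == 1
        assert rep.monitoring_sign == 1

    def test_mismatched_lengths_rejected(self, ris):
        curve = self._curve([0.5, 0.8], [1.0, 1.0], ris)
        bounds = compute_boundaries([0.5], grid=GridConfig(nodes=801))
        with pytest.raises(ValueError):
            assess_crossings(curve, bounds)

    def test_fraction_one_reports_ris_reached(self, ris):
        curve = self._curve([0.6, 1.1], [0.3, 0.4], ris)
        bounds = compute_boundaries([0.6, 1.1], grid=GridConfig(nodes=801))
        rep = assess_crossings(curve, bounds)
        assert rep.ris_reached and rep.first_ris_look == 2
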