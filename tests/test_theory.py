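"""Closed-form supplementary-point theory: fits, identities, conditions."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

from eccfit import (TheoryScenario, classify_scenario, delta_curve, l2_error,
                    off_axis_conditions, off_axis_update, on_axis_interval,
                    on_axis_update, random_scenario, restricted_fit,
                    type3_scenario)
from eccfit.errors import DegenerateInputError


class TestRestrictedFit:
    def test_circle_samples(self):
        theta = np.linspace(0.1, np.pi / 2 - 0.1, 10)
        a1, b1 = restricted_fit(np.full(10, 2.5), theta)
        assert (a1, b1) == pytest.approx((2.5, 2.5), abs=1e-12)

    def test_decoupled_axis_samples(self):
        a1, b1 = restricted_fit([2.0, 1.0], [0.0, np.pi / 2])
        assert (a1, b1) == pytest.approx((2.0, 1.0), abs=1e-12)

    def test_matches_numeric_minimizer(self):
        sc = random_scenario(np.random.default_rng(3), n=50, spread=0.2)
        res = minimize(lambda p: sc.mse(*p), [1.0, 0.5], method="Nelder-Mead",
                       options=dict(xatol=1e-12, fatol=1e-16, maxiter=20000))
        assert np.abs(np.array(sc.fit) - res.x).max() < 1e-8

    def test_degenerate_angles_rejected(self):
        with pytest.raises(DegenerateInputError):
            restricted_fit([1.0, 2.0], [0.0, 0.0])


class TestL2Error:
    def test_zero_at_truth(self):
        assert l2_error(2.0, 1.0, 2.0, 1.0) == 0.0

    def test_unit_offset_gives_pi(self):
        assert l2_error(2.0, 1.0, 1.0, 1.0) == pytest.approx(np.pi, abs=1e-14)

    def test_matches_quadrature(self):
        a0, b0, a, b = 2.0, 1.0, 1.7, 1.2
        val, _ = quad(lambda t: (a0 - a) ** 2 * np.cos(t) ** 2
                      + (b0 - b) ** 2 * np.sin(t) ** 2, 0, 2 * np.pi)
        assert l2_error(a0, b0, a, b) == pytest.approx(val, abs=1e-10)


class TestOnAxis:
    def test_beta_one_at_r_equal_a1(self, rng):
        sc = random_scenario(rng, 20)
        a1, _ = sc.fit
        a2, b2, beta, ds = on_axis_update(sc, a1)
        assert beta == pytest.approx(1.0, abs=1e-12)
        assert ds == pytest.approx(0.0, abs=1e-12)

    def test_zero_at_interval_endpoint(self, rng):
        for _ in range(20):
            sc = random_scenario(rng, 15, spread=0.2)
            lo, hi = on_axis_interval(sc)
            for R in (lo, hi):
                if R <= 0:
                    continue
                *_, ds = on_axis_update(sc, R)
                assert abs(ds) < 1e-10

    def test_identity_with_brute_force(self, rng):
        for _ in range(1000):
            sc = random_scenario(rng, int(rng.integers(5, 40)),
                                 a0=1 + rng.uniform(0, 2),
                                 b0=0.3 + rng.uniform(0, 0.5), spread=0.2)
            a1, b1 = sc.fit
            R = rng.uniform(0.05, 3.0)
            a2, b2, beta, ds = on_axis_update(sc, R)
            brute = l2_error(sc.a0, sc.b0, a1, b1) - l2_error(sc.a0, sc.b0, a2, b2)
            assert abs(ds - brute) < 1e-10

    def test_unbiased_fit_has_empty_interval(self):
        theta = np.linspace(0.1, np.pi / 2 - 0.1, 20)
        a0, b0 = 2.0, 1.0
        r = a0 * b0 / np.sqrt((b0 * np.cos(theta)) ** 2 + (a0 * np.sin(theta)) ** 2)
        # exact samples: a1 = a0 only if residuals vanish, so force a1 = a0
        sc = TheoryScenario(a0=restricted_fit(r, theta)[0], b0=b0, r=r, theta=theta)
        lo, hi = on_axis_interval(sc)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_underestimating_fit_gives_positive_width(self, rng):
        sc = random_scenario(rng, 20)
        a1, _ = sc.fit
        shrunk = TheoryScenario(a0=a1 * 1.2, b0=min(sc.b0, a1), r=sc.r,
                                theta=sc.theta)
        lo, hi = on_axis_interval(shrunk)
        assert lo == pytest.approx(a1, abs=1e-12)
        assert hi > lo

    def test_interval_characterizes_sign(self, rng):
        """Strictly inside the interval ΔΣ > 0; strictly outside ΔΣ ≤ 0."""
        for _ in range(1000):
            sc = random_scenario(rng, int(rng.integers(5, 30)), spread=0.15)
            lo, hi = on_axis_interval(sc)
            R = rng.uniform(0.01, 3.0)
            *_, ds = on_axis_update(sc, R)
            if lo < R < hi:
                assert ds > 0
            elif R < lo or R > hi:
                assert ds <= 1e-12


class TestOffAxis:
    def test_alpha_zero_reduces_to_on_axis(self, rng):
        sc = random_scenario(rng, 20)
        a2o, b2o, betao, dso = on_axis_update(sc, 1.3)
        a2, b2, beta, delta, ds = off_axis_update(sc, 1.3, 0.0)
        assert (a2, beta, ds) == pytest.approx((a2o, betao, dso), abs=1e-12)
        assert delta == pytest.approx(1.0, abs=1e-12)

    def test_alpha_right_angle_moves_only_minor_axis(self, rng):
        sc = random_scenario(rng, 20)
        a1, b1 = sc.fit
        a2, b2, beta, delta, ds = off_axis_update(sc, 0.8, np.pi / 2)
        assert beta == pytest.approx(1.0, abs=1e-12)
        assert a2 == pytest.approx(a1, abs=1e-12)

    def test_identity_on_grid(self, rng):
        sc = random_scenario(rng, 25, spread=0.2)
        a1, b1 = sc.fit
        s1 = l2_error(sc.a0, sc.b0, a1, b1)
        for R in np.linspace(0.1, 2.5, 12):
            for alpha in np.linspace(0, np.pi / 2, 7):
                a2, b2, *_, ds = off_axis_update(sc, R, alpha)
                assert abs(ds - (s1 - l2_error(sc.a0, sc.b0, a2, b2))) < 1e-10


class TestOffAxisConditions:
    def test_alpha_zero_collapses_to_on_axis_interval(self, rng):
        sc = random_scenario(rng, 20)
        rep = off_axis_conditions(sc, 1.1, 0.0)
        assert rep.a_interval == pytest.approx(on_axis_interval(sc), abs=1e-9)

    def test_overestimating_fit_with_small_r_never_improves(self):
        """Both semi-axes slightly overestimated and R below both
        improvement intervals: no branch holds and ΔΣ ≤ 0."""
        a0, b0 = 2.0, 1.0
        # on-axis sample pair decouples the closed-form fit: a1 = r1, b1 = r2
        sc = TheoryScenario(a0=a0, b0=b0, r=[a0 + 0.02, b0 + 0.02],
                            theta=[0.0, np.pi / 2])
        a1, b1 = sc.fit
        assert a1 > a0 and b1 > b0
        R = 0.5 * b0
        rep = off_axis_conditions(sc, R, np.pi / 4)
        assert 0 < rep.a_interval[0] and 0 < rep.b_interval[0]
        assert R < rep.a_interval[0] and R < rep.b_interval[0]
        assert rep.branch == ""
        assert rep.delta_sigma <= 0

    def test_branch_satisfaction_implies_improvement(self, rng):
        satisfied = 0
        for _ in range(1000):
            sc = random_scenario(rng, int(rng.integers(5, 30)), spread=0.15)
            R = rng.uniform(0.05, 3.0)
            alpha = rng.uniform(0.0, np.pi / 2)
            rep = off_axis_conditions(sc, R, alpha)
            if rep.branch:
                satisfied += 1
                assert rep.delta_sigma > 0
        assert satisfied > 0

    def test_per_axis_terms_match_interval_membership(self, rng):
        """Each term of ΔΣ is positive exactly when R is interior to the
        corresponding axis interval."""
        for _ in range(300):
            sc = random_scenario(rng, 15, spread=0.2)
            R = rng.uniform(0.05, 3.0)
            alpha = rng.uniform(0.05, np.pi / 2 - 0.05)
            rep = off_axis_conditions(sc, R, alpha)
            assert (rep.a_term > 0) == (rep.a_interval[0] < R < rep.a_interval[1])
            assert (rep.b_term > 0) == (rep.b_interval[0] < R < rep.b_interval[1])


class TestClassifyScenario:
    def make(self, low_factor, high_factor, a0=2.0, b0=1.0):
        theta = np.linspace(0.05, np.pi / 2 - 0.05, 20)
        r_true = a0 * b0 / np.sqrt((b0 * np.cos(theta)) ** 2
                                   + (a0 * np.sin(theta)) ** 2)
        f = np.where(theta < np.pi / 4, low_factor, high_factor)
        return TheoryScenario(a0=a0, b0=b0, r=r_true * f, theta=theta)

    @pytest.mark.parametrize("low, high, expected", [
        (0.95, 0.95, 1), (1.05, 1.05, 2), (1.05, 0.95, 3), (0.95, 1.05, 4),
    ])
    def test_types(self, low, high, expected):
        assert classify_scenario(self.make(low, high)) == expected

    def test_on_ellipse_rejected(self):
        sc = self.make(1.0, 1.0)
        with pytest.raises(DegenerateInputError):
            classify_scenario(sc)


class TestDeltaCurve:
    def test_alpha_zero_column_equals_on_axis(self, rng):
        sc = random_scenario(rng, 20)
        grid = np.linspace(0.2, 2.0, 25)
        tab = delta_curve(sc, [0.0], grid)
        expect = [on_axis_update(sc, R)[3] for R in grid]
        assert np.allclose(tab["delta_sigma"].to_numpy(), expect, atol=1e-12)

    def test_sign_changes_at_reported_boundaries(self, rng):
        sc = random_scenario(rng, 20, spread=0.15)
        lo, hi = on_axis_interval(sc)
        if hi - lo > 1e-6:
            grid = np.linspace(max(lo - 0.5, 1e-3), hi + 0.5, 400)
            tab = delta_curve(sc, [0.0], grid)
            pos = tab.loc[tab.delta_sigma > 0, "R"]
            assert pos.min() >= lo - 2e-3 * (hi - lo + 1)
            assert pos.max() <= hi + 2e-3 * (hi - lo + 1)

    def test_type3_positive_range_shrinks_with_alpha(self):
        """Highly eccentric Type 3 scenario: ΔΣ > 0 over a wide radius range
        for a near-axis supplementary point, shrinking as α grows."""
        sc = type3_scenario(eccentricity=0.99)
        assert classify_scenario(sc) == 3
        grid = np.linspace(0.01, 3.0, 600)
        tab = delta_curve(sc, [0.0, 0.3, 0.8, 1.4], grid)
        widths = {}
        for alpha, g in tab.groupby("alpha"):
            pos = g[g.delta_sigma > 0]
            widths[alpha] = (pos.R.max() - pos.R.min()) if len(pos) else 0.0
        assert widths[0.0] > 0.5 * sc.a0       # wide for small α
        assert widths[0.0] >= widths[0.3] >= widths[1.4]
        assert widths[1.4] < widths[0.0]
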