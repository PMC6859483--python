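import cmath
import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from loopchar import (
    DimerParams,
    acdc_min_threshold,
    acdc_threshold,
    dimer_alpha2,
    dimer_optimal_db,
    dimer_threshold,
    dimer_threshold_three_angle,
    four_species_hopf,
    four_species_jacobian,
    hes1_period,
    optimize_subloop,
    ring_threshold,
    subloop_phi,
    subloop_threshold,
)
from loopchar.hopf import dimer_subloop_gain, stationarity_tan_phi
from loopchar.models import dimer_steady_state


def ring_jacobian(rates, gain):
    """Jacobian of an n-ring whose edge gains multiply to `gain`."""
    d = np.asarray(rates, dtype=float)
    n = len(d)
    J = np.diag(-d).astype(float)
    edge = abs(gain) ** (1.0 / n)
    for i in range(n):
        J[i, (i - 1) % n] = d[i] * edge
    if gain < 0:
        J[0, n - 1] *= -1.0
    return J


class TestRingThreshold:
    def test_three_equal_rates(self):
        res = ring_threshold([1.0, 1.0, 1.0])
        assert res.threshold == pytest.approx(8.0, abs=1e-10)
        assert res.alpha == pytest.approx(math.sqrt(3.0), abs=1e-10)
        assert all(t == pytest.approx(math.pi / 3) for t in res.thetas)

    def test_four_equal_rates(self):
        assert ring_threshold([1.0] * 4).threshold == pytest.approx(4.0, abs=1e-10)

    def test_two_species_cannot_oscillate(self):
        assert ring_threshold([1.0, 5.0]) is None
        assert ring_threshold([0.3]) is None

    @pytest.mark.parametrize("seed", range(8))
    def test_crossing_verified_by_eigenvalues(self, seed):
        rng = np.random.default_rng(seed)
        rates = rng.uniform(0.2, 5.0, size=rng.integers(3, 7))
        res = ring_threshold(rates)
        J = ring_jacobian(rates, -res.threshold)
        ev = np.linalg.eigvals(J)
        pair = ev[np.abs(ev.imag) > 1e-9]
        assert pair.size >= 2
        lead = pair[np.argmax(pair.real)]
        assert abs(lead.real) < 1e-6
        assert abs(abs(lead.imag) - res.alpha) < 1e-6 * res.alpha


class TestSubloopAngles:
    def test_zero_subloop_recovers_pure_ring(self):
        theta = math.pi / 5
        phi = subloop_phi(5, 2, 0.0, theta)
        assert (5 - 2) * phi + 2 * theta == pytest.approx(math.pi, abs=1e-12)

    def test_closed_form_tangent_n3_w2(self):
        G, theta = 0.75, math.pi / 3
        phi = subloop_phi(3, 2, G, theta)
        t = math.tan(theta)
        assert math.tan(phi) == pytest.approx(2 * t / (G - 1 + t * t), rel=1e-12)
        # argument-sum residual (crossing condition)
        z = (1 + 1j * t) ** 2 - G
        assert phi + cmath.phase(z) == pytest.approx(math.pi, abs=1e-10)

    def test_zero_frequency_limit(self):
        # a vanishing-frequency crossing exists only on the strong positive
        # branch (G > 1), where the sub-loop block -G + 1 is already negative
        for G in (1.5, 3.0):
            assert subloop_phi(3, 2, G, 1e-9) == pytest.approx(0.0, abs=1e-6)
        for G in (0.3, 0.9):
            assert subloop_phi(3, 2, G, 1e-9) is None

    def test_sine_rule_identity(self):
        # G / sin(w th + (n-w) phi) = sec^w(th) / sin((n-w) phi), as a
        # cross-multiplied residual, wherever a crossing exists
        for n, w in [(3, 2), (5, 2), (6, 3)]:
            for G in (-2.0, -0.5, 0.5, 0.9, 2.0):
                for theta in np.linspace(0.05, 1.5, 25):
                    phi = subloop_phi(n, w, G, float(theta))
                    if phi is None:
                        continue
                    lhs = G * math.sin((n - w) * phi)
                    rhs = math.sin(w * theta + (n - w) * phi) / math.cos(theta) ** w
                    assert lhs == pytest.approx(rhs, abs=1e-10 * max(1, abs(rhs)))

    def test_threshold_two_routes_agree(self):
        # the sine form and the |..| form are asserted equal inside
        F = subloop_threshold(3, 2, 0.75, math.pi / 3)
        z = (1 + 1j * math.tan(math.pi / 3)) ** 2 - 0.75
        phi = subloop_phi(3, 2, 0.75, math.pi / 3)
        assert F == pytest.approx(abs(z) / math.cos(phi), rel=1e-12)

    def test_ring_limit_threshold(self):
        n = 4
        theta = math.pi / n
        F = subloop_threshold(n, 2, 0.0, theta)
        assert F == pytest.approx(1 / math.cos(math.pi / n) ** n, rel=1e-10)


class TestAcdcOptimum:
    def test_repressilator_recovered_at_zero_gain(self):
        res = acdc_min_threshold(0.0)
        assert (res.lambda_star, res.threshold, res.attained) == (1.0, 8.0, True)

    def test_weak_positive_subloop_closed_form(self):
        res = acdc_min_threshold(0.75)
        assert res.lambda_star == pytest.approx(2.0)
        assert res.threshold == pytest.approx(6.0)
        assert res.attained

    def test_strong_positive_subloop_infimum(self):
        res = acdc_min_threshold(5.0)
        assert res.lambda_star == pytest.approx(0.5)
        assert res.threshold == pytest.approx(4.0)
        assert not res.attained
        # the infimum is approached but |F| stays strictly above it
        for lam in (0.49, 0.45, 0.3):
            assert acdc_threshold(lam, 5.0) > 4.0

    @pytest.mark.parametrize("G", [-4.0, -1.0, -0.25, 0.1, 0.6, 0.97])
    def test_closed_form_matches_numeric_minimisation(self, G):
        res = minimize_scalar(
            lambda lam: acdc_threshold(lam, G),
            bounds=(1e-3, 1e3),
            method="bounded",
            options={"xatol": 1e-10},
        )
        closed = acdc_min_threshold(G)
        assert res.x == pytest.approx(closed.lambda_star, rel=1e-6)
        assert res.fun == pytest.approx(closed.threshold, rel=1e-8)

    def test_optimal_ratio_sign_structure(self):
        # negative sub-loop: slower degradation inside; weak positive: faster
        assert acdc_min_threshold(-2.0).lambda_star < 1.0
        assert 1.0 < acdc_min_threshold(0.5).lambda_star
        assert acdc_min_threshold(2.0).lambda_star > 1.0  # 2/(G-1) > 1 for G < 3
        assert acdc_min_threshold(4.0).lambda_star < 1.0

    def test_continuity_of_branches(self):
        assert acdc_min_threshold(1e-12).threshold == pytest.approx(8.0, abs=1e-10)
        assert acdc_min_threshold(1 - 1e-12).threshold == pytest.approx(4.0, rel=1e-6)
        assert acdc_min_threshold(1 + 1e-9).lambda_star > 1e8  # diverging ratio

    def test_equal_rate_crossing_verified_by_eigenvalues(self):
        # lam = 1: threshold |F| = 8 - 2G; instantiate the 3x3 Jacobian
        for G in (-1.0, -0.3, 0.4, 1.5):
            F = -(8.0 - 2.0 * G)
            J = np.array(
                [[-1.0, G, F], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]
            )
            ev = np.linalg.eigvals(J)
            pair = ev[np.abs(ev.imag) > 1e-9]
            lead = pair[np.argmax(pair.real)]
            assert abs(lead.real) < 1e-8
            assert abs(lead.imag) == pytest.approx(math.sqrt(3.0 - G), abs=1e-8)

    def test_equal_rate_angle_sum_direction(self):
        # at equal rates a positive sub-loop lowers both the angle sum and
        # the required |F| at the crossing; a negative sub-loop raises them
        base = 3 * math.atan(math.sqrt(3.0))
        for G, cmp in [(0.5, -1), (-0.5, +1)]:
            angle_sum = 3 * math.atan(math.sqrt(3.0 - G))
            assert cmp * (angle_sum - base) > 0
            assert cmp * (acdc_threshold(1.0, G) - 8.0) > 0


class TestOptimizeSubloop:
    def test_small_gain_recovers_equal_angles(self):
        for n, w in [(3, 2), (5, 2), (6, 4)]:
            res = optimize_subloop(n, w, 1e-6)
            assert res.theta == pytest.approx(math.pi / n, abs=1e-3)
            assert res.phi == pytest.approx(math.pi / n, abs=1e-3)
            assert res.threshold == pytest.approx(
                1 / math.cos(math.pi / n) ** n, rel=1e-4
            )

    @pytest.mark.parametrize("G", [-1.0, -0.2, 0.5, 0.9])
    def test_matches_acdc_closed_form(self, G):
        res = optimize_subloop(3, 2, G)
        closed = acdc_min_threshold(G)
        assert res.threshold == pytest.approx(closed.threshold, rel=1e-7)
        lam = math.tan(res.phi) / math.tan(res.theta)
        assert lam == pytest.approx(closed.lambda_star, rel=1e-5)

    @pytest.mark.parametrize("n,w,G", [(3, 2, 0.5), (4, 2, -0.8), (5, 3, 0.6)])
    def test_stationarity_relation_holds_at_optimum(self, n, w, G):
        res = optimize_subloop(n, w, G)
        assert math.tan(res.phi) == pytest.approx(
            stationarity_tan_phi(w, G, res.theta), abs=1e-6
        )


def standard_dimer_params(d_c):
    ss = dimer_steady_state(d_c=d_c)
    return DimerParams(
        k=25.0, l=0.1, d_a=0.1, d_b=3.0, d_c=d_c,
        c_star=ss[2], f_slope=5.0, g_slope=5.0,
    )


class TestDimer:
    def test_alpha2_ring_degeneration(self):
        p = DimerParams(k=0.0, l=0.0, d_a=1.0, d_b=1.0, d_c=1.0, c_star=1.0)
        assert dimer_alpha2(p) == pytest.approx(3.0)

    def test_alpha2_optimal_limit(self):
        # l, d_a -> 0 with d_c = 4 k c*: alpha^2 -> 2 d_b d_c
        p = DimerParams(k=1.0, l=1e-9, d_a=1e-9, d_b=3.0, d_c=4.0, c_star=1.0)
        assert dimer_alpha2(p) == pytest.approx(2 * 3.0 * 4.0, rel=1e-8)

    def test_alpha2_matches_eigenvalue_at_crossing(self):
        from loopchar import locate_hopf

        for bracket in [(1.0, 2.0), (70.0, 90.0)]:
            hp = locate_hopf("dimer_autorepressor", "d_c", bracket)
            p = standard_dimer_params(hp.value)
            assert dimer_alpha2(p) == pytest.approx(hp.alpha**2, rel=1e-6)

    def test_threshold_minimised_at_eight(self):
        # l, d_a -> 0, optimal d_b, d_c = 4 k c*
        kc = 2.5
        p = DimerParams(k=kc, l=1e-10, d_a=1e-10, d_b=1.0, d_c=4 * kc, c_star=1.0)
        db = dimer_optimal_db(p)
        p_opt = DimerParams(k=kc, l=1e-10, d_a=1e-10, d_b=max(db, 1e-8),
                            d_c=4 * kc, c_star=1.0)
        assert dimer_threshold(p_opt) == pytest.approx(8.0, rel=1e-4)

    def test_threshold_curve_crosses_actual_gain_twice(self):
        # |f'g'| = 25 for the standard piecewise-linear configuration
        from scipy.optimize import brentq

        def excess(d_c):
            return dimer_threshold(standard_dimer_params(d_c)) - 25.0

        lo = brentq(excess, 1.0, 3.0, xtol=1e-10)
        hi = brentq(excess, 50.0, 100.0, xtol=1e-8)
        assert 1.0 < lo < 2.0
        assert 80.0 < hi < 90.0
        # crossing points coincide with the eigenvalue bisection
        from loopchar import locate_hopf

        assert lo == pytest.approx(locate_hopf("dimer_autorepressor", "d_c", (1.0, 2.0)).value, rel=1e-8)
        assert hi == pytest.approx(locate_hopf("dimer_autorepressor", "d_c", (70.0, 90.0)).value, rel=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_three_angle_recast_equivalence(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = DimerParams(
            k=rng.uniform(0.5, 30.0),
            l=rng.uniform(0.0, 2.0),
            d_a=rng.uniform(0.05, 3.0),
            d_b=rng.uniform(0.1, 5.0),
            d_c=rng.uniform(0.1, 20.0),
            c_star=rng.uniform(0.01, 1.0),
        )
        assert dimer_threshold_three_angle(p) == pytest.approx(
            dimer_threshold(p), rel=1e-9
        )
        assert 0 <= dimer_subloop_gain(p) < 1.0 or p.l == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_optimal_db_matches_scalar_minimisation(self, seed):
        rng = np.random.default_rng(200 + seed)
        base = dict(
            k=rng.uniform(0.5, 30.0), l=rng.uniform(0.0, 2.0),
            d_a=rng.uniform(0.05, 3.0), d_c=rng.uniform(0.1, 20.0),
            c_star=rng.uniform(0.05, 1.0),
        )
        closed = dimer_optimal_db(DimerParams(d_b=1.0, **base))
        res = minimize_scalar(
            lambda db: dimer_threshold(DimerParams(d_b=db, **base)),
            bounds=(1e-4, 1e3), method="bounded", options={"xatol": 1e-12},
        )
        assert res.x == pytest.approx(closed, rel=1e-6)

    def test_optimal_db_special_case(self):
        # d_c = 4 k c*: d_b* = sqrt((2 d_a + l) d_c)
        p = DimerParams(k=2.0, l=0.3, d_a=0.2, d_b=1.0, d_c=8.0, c_star=1.0)
        assert dimer_optimal_db(p) == pytest.approx(math.sqrt((2 * 0.2 + 0.3) * 8.0))

    def test_no_feedback_path_rejected(self):
        p = DimerParams(k=0.0, l=0.1, d_a=0.1, d_b=1.0, d_c=1.0, c_star=0.5)
        with pytest.raises(ValueError, match="feedback path"):
            dimer_threshold(p)


class TestHes1Period:
    def test_quarter_hour_rates_give_111_minutes(self):
        assert hes1_period(1 / 25, 1 / 25) == pytest.approx(111.07, abs=0.01)

    def test_equal_rate_identity(self):
        d = 0.37
        assert hes1_period(d, d) == pytest.approx((2 * math.pi / d) / math.sqrt(2))

    def test_scaling_law(self):
        assert hes1_period(0.08, 0.08) == pytest.approx(hes1_period(0.04, 0.04) / 2)


class TestFourSpecies:
    def test_unit_delta_requires_gain_four(self):
        assert four_species_hopf(1.0, 2.0).hb_gc == pytest.approx(4.0)

    def test_small_delta_limits(self):
        res = four_species_hopf(1e-8, 2.0)
        assert res.hb_gc == pytest.approx(1.0, abs=1e-6)
        assert res.alpha == pytest.approx(math.sqrt(2.0 * 1e-8), rel=1e-6)

    def test_no_crossing_when_alpha_negative(self):
        # L + L delta - delta <= 0
        assert four_species_hopf(2.0, 0.5) is None

    @pytest.mark.parametrize("delta", [0.2, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("L", [1.0, 2.0, 5.0])
    def test_condition_verified_by_eigenvalue_oracle(self, delta, L):
        res = four_species_hopf(delta, L)
        if res is None:
            pytest.skip("no crossing on this grid point")
        J = four_species_jacobian(delta, L, res.hb_gc)
        ev = np.linalg.eigvals(J)
        pair = ev[np.abs(ev.imag) > 1e-9]
        lead = pair[np.argmax(pair.real)]
        assert abs(lead.real) < 1e-8
        assert abs(lead.imag) == pytest.approx(res.alpha, rel=1e-8)
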