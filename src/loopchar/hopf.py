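"""Closed-form and semi-closed-form Hopf-bifurcation conditions.

A Hopf bifurcation occurs when a complex-conjugate eigenvalue pair of the
Jacobian crosses the imaginary axis. Writing the crossing eigenvalue as
i*alpha and theta_j = arctan(alpha/d_j), the characteristic equation of a
single negative ring of n species reads F = prod_j (1 + i tan theta_j), so
the crossing with minimal ring gain |F| has sum_j theta_j = pi. When the
ring carries a single sub-loop W of gain G, two angles suffice (theta inside
W, phi outside) and the crossing satisfies

    pi = (n-|W|) phi + Arg(-G + (1 + i tan theta)^|W|),
    |F| = sec^{n-|W|} phi * |-G + (1 + i tan theta)^|W||.

This module implements those relations, the minimisation of |F| over the
degradation-rate ratio lambda = d_in/d_out (with the full closed form for
the three-species ring + two-species sub-loop, the ACDC geometry), the
dimeric auto-repressor conditions, and the symmetric four-species
(linked-repressilator) condition.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "RingHopf",
    "AcdcOptimum",
    "SubloopOptimum",
    "DimerParams",
    "FourSpeciesHopf",
    "ring_threshold",
    "subloop_phi",
    "subloop_threshold",
    "acdc_threshold",
    "acdc_min_threshold",
    "optimize_subloop",
    "stationarity_tan_phi",
    "dimer_alpha2",
    "dimer_threshold",
    "dimer_threshold_three_angle",
    "dimer_subloop_gain",
    "dimer_optimal_db",
    "hes1_period",
    "four_species_hopf",
    "four_species_jacobian",
]


# ---------------------------------------------------------------------------
# single negative ring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingHopf:
    """Imaginary-axis crossing of a single negative ring."""

    alpha: float       #: angular frequency at the crossing (rad/time)
    threshold: float   #: ring-gain magnitude |F| required for the crossing
    thetas: tuple[float, ...]


def ring_threshold(rates) -> Optional[RingHopf]:
    """Minimal-|F| Hopf crossing of a negative ring with the given rates.

    Solves sum_j arctan(alpha/d_j) = pi for alpha > 0; the required gain is
    |F| = prod_j sec(theta_j). Returns ``None`` when no crossing exists —
    with one or two species each angle stays below pi/2, so the angle sum
    cannot reach pi and no oscillation is possible.
    """
    d = np.asarray(rates, dtype=float)
    n = len(d)
    if np.any(d <= 0):
        raise ValueError("rates must be positive")
    if n <= 2:
        return None

    def angle_sum(alpha):
        return float(np.sum(np.arctan(alpha / d))) - math.pi

    hi = 10.0 * np.max(d)
    while angle_sum(hi) < 0:
        hi *= 10.0
        if hi > 1e12 * np.max(d):  # pragma: no cover - n>=3 always reaches pi
            return None
    alpha = brentq(angle_sum, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    thetas = np.arctan(alpha / d)
    threshold = float(np.prod(1.0 / np.cos(thetas)))
    return RingHopf(alpha=float(alpha), threshold=threshold, thetas=tuple(thetas))


# ---------------------------------------------------------------------------
# ring with one sub-loop: two-angle relations
# ---------------------------------------------------------------------------


def _inner_factor(w: int, G: float, theta: float) -> complex:
    """-G + (1 + i tan theta)^w, the sub-loop block of the characteristic eq."""
    return -G + (1.0 + 1j * math.tan(theta)) ** w


def subloop_phi(n: int, w: int, G: float, theta: float) -> Optional[float]:
    """Outside angle phi at the crossing, given the inside angle theta.

    Solves pi = (n-w) phi + Arg(-G + (1+i tan theta)^w) for phi in [0, pi/2);
    equivalently tan((n-w) phi) = sin(w theta) / (G cos^w theta - cos(w theta)).
    Returns ``None`` when no admissible phi exists at this theta.
    """
    if not (0 < w < n):
        raise ValueError("need n > w >= 1")
    if not (0.0 <= theta < math.pi / 2):
        raise ValueError("theta must lie in [0, pi/2)")
    z = _inner_factor(w, G, theta)
    if z == 0:
        return None
    phi = (math.pi - cmath.phase(z)) / (n - w)
    if not (0.0 <= phi < math.pi / 2):
        return None
    # consistency with the tangent form of the same relation
    den = G * math.cos(theta) ** w - math.cos(w * theta)
    num = math.sin(w * theta)
    if abs(den) > 1e-12:
        resid = math.tan((n - w) * phi) - num / den
        assert abs(resid) < 1e-8 * max(1.0, abs(num / den)), resid
    return phi


def subloop_threshold(
    n: int, w: int, G: float, theta: float, phi: Optional[float] = None
) -> Optional[float]:
    """Ring-gain magnitude |F| at the crossing for inside angle theta.

    Evaluates |F| = sec^{n-w} phi * |-G + (1+i tan theta)^w| and, where the
    sine form sec^{n-w}phi sin(w theta) sec^w theta / sin((n-w) phi) is
    defined, asserts the two routes agree. ``None`` when no crossing exists.
    """
    if phi is None:
        phi = subloop_phi(n, w, G, theta)
    if phi is None:
        return None
    sec_out = 1.0 / math.cos(phi) ** (n - w)
    F = sec_out * abs(_inner_factor(w, G, theta))
    s_out = math.sin((n - w) * phi)
    if s_out > 1e-9 and theta > 0:
        F_sine = sec_out * math.sin(w * theta) / (math.cos(theta) ** w * s_out)
        assert abs(F - F_sine) < 1e-10 * max(1.0, F), (F, F_sine)
    return F


def stationarity_tan_phi(w: int, G: float, theta: float) -> float:
    """tan(phi) at a stationary point of |F|(theta).

    Differentiating ln|F| along the crossing constraint gives
    tan phi = Re(z'/z) / Im(z'/z) with z = -G + (1 + i tan theta)^w and
    z' = i w sec^{w+1}(theta) e^{i (w-1) theta}, which reduces to

    tan phi = (sin theta + G cos^w theta sin((w-1) theta))
              / (cos theta - G cos^w theta cos((w-1) theta)).
    """
    cw = math.cos(theta) ** w
    num = math.sin(theta) + G * cw * math.sin((w - 1) * theta)
    den = math.cos(theta) - G * cw * math.cos((w - 1) * theta)
    return num / den


# ---------------------------------------------------------------------------
# three-species ring + two-species sub-loop (ACDC geometry): closed forms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcdcOptimum:
    """Optimal degradation-rate ratio for the 3-ring with a 2-sub-loop.

    ``lambda_star`` is the ratio d_in/d_out minimising the Hopf threshold
    |F|; ``threshold`` the corresponding minimal (or infimum) |F|;
    ``attained`` is False on the strong-positive-feedback branch (G > 1)
    where the infimum is approached as the crossing frequency tends to zero.
    """

    G: float
    lambda_star: float
    threshold: float
    attained: bool


def acdc_threshold(lam: float, G: float) -> float:
    """Hopf threshold |F| = 4 + 2/lambda + 2 lambda (1-G) for the 3-ring
    with a 2-species sub-loop of gain G, at rate ratio lambda = d_in/d_out.

    Valid where the crossing exists, i.e. tan^2 theta = 1 - G + 2/lambda > 0.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if 1.0 - G + 2.0 / lam <= 0:
        raise ValueError("no imaginary-axis crossing at this (lambda, G)")
    return 4.0 + 2.0 / lam + 2.0 * lam * (1.0 - G)


def acdc_min_threshold(G: float) -> AcdcOptimum:
    """Minimise the crossing threshold |F| over the rate ratio lambda.

    - G < 1: attained minimum 4 (1 + sqrt(1-G)) at lambda* = 1/sqrt(1-G).
      G = 0 recovers the plain repressilator (lambda* = 1, |F| = 8).
    - G = 1: |F| = 4 + 2/lambda decreases to the unattained infimum 4 as
      lambda grows without bound.
    - G > 1: |F| decreases on the admissible interval lambda < 2/(G-1) and
      approaches the unattained infimum G - 1 as lambda -> 2/(G-1), where
      the crossing frequency tends to zero.
    """
    if G < 1.0:
        s = math.sqrt(1.0 - G)
        return AcdcOptimum(
            G=G, lambda_star=1.0 / s, threshold=4.0 * (1.0 + s), attained=True
        )
    if G == 1.0:
        return AcdcOptimum(G=G, lambda_star=math.inf, threshold=4.0, attained=False)
    return AcdcOptimum(
        G=G, lambda_star=2.0 / (G - 1.0), threshold=G - 1.0, attained=False
    )


@dataclass(frozen=True)
class SubloopOptimum:
    theta: float
    phi: float
    threshold: float


def optimize_subloop(n: int, w: int, G: float, n_starts: int = 20) -> SubloopOptimum:
    """Numerically minimise the crossing threshold |F| over theta for a
    negative n-ring with one w-species sub-loop of gain G.

    Multi-start bounded scalar minimisation over theta in (0, pi/2) guards
    against the multiple stationary points that appear for large |G|. The
    returned optimum satisfies the analytic stationarity relation
    (:func:`stationarity_tan_phi`) where the threshold surface is smooth.
    """
    if not (n > w >= 2):
        raise ValueError("need n > w >= 2")

    _NO_CROSSING = 1e100  # finite sentinel keeps the scalar minimiser stable

    def objective(theta):
        F = subloop_threshold(n, w, G, theta)
        return F if F is not None else _NO_CROSSING

    edges = np.linspace(1e-6, math.pi / 2 - 1e-6, n_starts + 1)
    best = None
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(
            objective, bounds=(a, b), method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun < _NO_CROSSING * 0.5:
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"threshold minimisation failed for n={n}, w={w}, G={G}: "
            "no admissible crossing found"
        )
    theta = float(best.x)
    phi = subloop_phi(n, w, G, theta)
    return SubloopOptimum(theta=theta, phi=float(phi), threshold=float(best.fun))


# ---------------------------------------------------------------------------
# dimeric auto-repressor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DimerParams:
    """Parameters of the dimeric auto-repressor at its steady state.

    a (dimer) <- 2c dimerisation at rate k, dissociation l, decay d_a;
    b (mRNA) produced under repression f(a), decay d_b; c (monomer)
    produced as g(b), decay d_c. ``f_slope`` is |f'| and ``g_slope`` g' at
    the steady state; ``c_star`` the steady-state monomer level.
    """

    k: float
    l: float
    d_a: float
    d_b: float
    d_c: float
    c_star: float
    f_slope: float = 0.0
    g_slope: float = 0.0

    def __post_init__(self):
        if min(self.d_a, self.d_b, self.d_c) <= 0:
            raise ValueError("degradation rates must be positive")
        if min(self.k, self.l, self.c_star) < 0:
            raise ValueError("rates and concentrations must be non-negative")

    @property
    def kc(self) -> float:
        """k c*, the rate scale of the dimerisation feedback."""
        return self.k * self.c_star


def dimer_alpha2(p: DimerParams) -> float:
    """Squared angular frequency at the dimer model's Hopf crossing:

    alpha^2 = d_a d_b + d_b d_c + d_c d_a + l (d_c + d_b) + 4 k c* (d_a + d_b)
    """
    return (
        p.d_a * p.d_b
        + p.d_b * p.d_c
        + p.d_c * p.d_a
        + p.l * (p.d_c + p.d_b)
        + 4.0 * p.kc * (p.d_a + p.d_b)
    )


def dimer_threshold(p: DimerParams) -> float:
    """|f'g'| required at the Hopf bifurcation of the dimer model.

    From the real part of the characteristic equation at lambda = i alpha:

    |f'g'| = [ (1 + 4kc*/d_c) + (d_a + l)/d_c ]
             * [ d_b + d_a + d_c + l + 4kc*
                 + (d_c d_a + l d_c + 4 kc* d_a)/d_b ] / (2 kc*)

    Oscillations (by linear analysis) require the actual |f'g'| at the
    steady state to exceed this value.
    """
    kc = p.kc
    if kc <= 0:
        raise ValueError("k c* must be positive: no dimer feedback path")
    fac1 = (1.0 + 4.0 * kc / p.d_c) + (p.d_a + p.l) / p.d_c
    fac2 = (
        p.d_b + p.d_a + p.d_c + p.l + 4.0 * kc
        + (p.d_c * p.d_a + p.l * p.d_c + 4.0 * kc * p.d_a) / p.d_b
    )
    return fac1 * fac2 / (2.0 * kc)


def dimer_subloop_gain(p: DimerParams) -> float:
    """Gain G of the reversible dimerisation 2-loop in the three-angle
    recast: G = 4 kc* l / [(d_a + l)(d_c + 4 kc*)].
    """
    return 4.0 * p.kc * p.l / ((p.d_a + p.l) * (p.d_c + 4.0 * p.kc))


def dimer_threshold_three_angle(p: DimerParams) -> float:
    """Same threshold via the three-angle recast (independent route).

    With tan th_a = alpha/(l+d_a), tan th_b = alpha/d_b,
    tan th_c = alpha/(d_c + 4kc*), the crossing satisfies
    tan th_b = sin(th_a+th_c)/(G cos th_a cos th_c - cos(th_a+th_c)) and
    |F| = (tan th_a + tan th_c)(1 + tan^2 th_b)/tan th_b with
    |F| = 2 kc* |f'g'| d_c / [(l+d_a)(d_c+4kc*)].
    """
    kc = p.kc
    if kc <= 0:
        raise ValueError("k c* must be positive: no dimer feedback path")
    da_eff = p.l + p.d_a
    dc_eff = p.d_c + 4.0 * kc
    G = dimer_subloop_gain(p)
    alpha2 = da_eff * dc_eff * (p.d_b / da_eff + p.d_b / dc_eff + 1.0 - G)
    tb2 = alpha2 / p.d_b**2
    F = (1.0 / da_eff + 1.0 / dc_eff) * p.d_b * (1.0 + tb2)
    return F * da_eff * dc_eff / (2.0 * kc * p.d_c)


def dimer_optimal_db(p: DimerParams) -> float:
    """mRNA degradation rate minimising the Hopf threshold over d_b:

    d_b* = sqrt(d_a d_c + l d_c + 4 k c* d_a).

    The threshold depends on d_b only through d_b + C/d_b with
    C = d_a d_c + l d_c + 4 kc* d_a, so the minimiser is sqrt(C). In the
    limit l, d_a -> 0 with d_c = 4 kc* the minimal threshold over all rates
    is 8, the same bound as the equal-rate repressilator.
    """
    if p.kc <= 0:
        raise ValueError("k c* must be positive: no dimer feedback path")
    return math.sqrt(p.d_a * p.d_c + p.l * p.d_c + 4.0 * p.kc * p.d_a)


def hes1_period(d_b: float, d_c: float) -> float:
    """Oscillation period at the bifurcation in the optimal dimer regime.

    In the limit of a stable, slowly dissociating dimer with d_c = 4 k c*
    (one in three monomers dimerises), the crossing frequency reduces to
    alpha = sqrt(2 d_b d_c) — sqrt 2 times the geometric mean of the mRNA
    and monomer degradation rates — giving period 2 pi / sqrt(2 d_b d_c).
    With both rates at 1/25 per minute this predicts ~111 minutes, close to
    the observed Hes1 period.
    """
    if d_b <= 0 or d_c <= 0:
        raise ValueError("rates must be positive")
    return 2.0 * math.pi / math.sqrt(2.0 * d_b * d_c)


# ---------------------------------------------------------------------------
# four species: two linked repressilators sharing a positive 2-loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourSpeciesHopf:
    """Symmetric Hopf condition for the linked-repressilator network.

    Species b, c form the positive 2-loop (rates scaled to 1); a, d sit
    outside with rate delta; the two negative 3-loops have equal strength,
    with L the ratio of negative-loop to positive-loop coefficients.
    """

    delta: float
    L: float
    hb_gc: float   #: required positive-loop gain product at the crossing
    alpha: float   #: angular frequency at the crossing (units of d_b = d_c)


def four_species_hopf(delta: float, L: float) -> Optional[FourSpeciesHopf]:
    """Symmetric crossing condition h_b g_c = (delta+1)^2 with frequency
    alpha = sqrt(delta (L + L delta - delta)).

    Returns ``None`` when alpha^2 <= 0 (no crossing at this (delta, L)).
    For small delta the required gain tends to 1 and alpha ~ sqrt(L delta).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    alpha2 = delta * (L + L * delta - delta)
    if alpha2 <= 0:
        return None
    return FourSpeciesHopf(
        delta=delta,
        L=L,
        hb_gc=(delta + 1.0) ** 2,
        alpha=math.sqrt(alpha2),
    )


def four_species_jacobian(delta: float, L: float, hb_gc: float) -> np.ndarray:
    """Concrete symmetric Jacobian realising the four-species geometry.

    Species order (a, b, c, d); d_b = d_c = 1, d_a = d_d = delta; positive
    2-loop gains h_b = g_c = -sqrt(hb_gc); negative-loop gradients chosen so
    f' h_a / h_b = j' g_d / g_c = -L. Used as the eigenvalue oracle for
    :func:`four_species_hopf`.
    """
    s = math.sqrt(hb_gc)
    h_b = g_c = -s
    f_p = j_p = -1.0
    h_a = g_d = -L * s
    return np.array(
        [
            [-delta, delta * f_p, 0.0, 0.0],
            [0.0, -1.0, g_c, g_d],
            [h_a, h_b, -1.0, 0.0],
            [0.0, 0.0, delta * j_p, -delta],
        ]
    )
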