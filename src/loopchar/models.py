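"""Built-in worked-example models and their simulation defaults.

Three fully parameterised systems:

- ``dimer_autorepressor``   — negative auto-regulation of a gene by its dimeric
  protein: dimer a, mRNA b, monomer c, with mass-action dimerisation
  (forward k, reverse l), piecewise-linear repression f(a) and linear
  translation g(b) = m b. Outside the d(f - x) form, so it is carried as a
  raw right-hand side with an analytic Jacobian.
- ``acdc``    — a repressilator (piecewise-linear repressions of slope
  -2 at the steady state, so ring gain F = -8) with one reverse link
  forming a 2-species sub-loop of gain G = -2k via the multiplicative
  modulator max(1 - k + k x, 0).
- ``linked_repressilators`` — two repressilators sharing a positive 2-loop:
  a' = d_a (f(b)-a), b' = d_b (g(c,d)-b), c' = d_c (h(a,b)-c),
  d' = d_d (j(c)-d) with Hill-type decreasing f, g, h, j.

Each entry also records the initial condition and observed species used in
the bifurcation sweeps, and the sweep parameter grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np
from scipy.optimize import brentq

from .network import RawRHS, RegulatoryNetwork
from .regulation import ProductNode, RegulationFunction

__all__ = ["ModelInstance", "MODEL_REGISTRY", "get_model", "dimer_steady_state"]


@dataclass(frozen=True)
class ModelInstance:
    """A ready-to-analyse model: network plus simulation conventions."""

    network: RegulatoryNetwork
    params: Mapping[str, float]
    init: np.ndarray
    observed: str                      #: species whose amplitude is reported
    steady_state_fn: Optional[Callable[[], np.ndarray]] = None

    def steady_state_guess(self) -> Optional[np.ndarray]:
        return self.steady_state_fn() if self.steady_state_fn else None


# ---------------------------------------------------------------------------
# dimeric auto-repressor
# ---------------------------------------------------------------------------

DIMER_DEFAULTS = dict(
    l=0.1, d_a=0.1, d_b=3.0, d_c=10.0, k=25.0, f_max=1.0, m=5.0,
    x_on=0.9, x_off=1.1,
)


def _dimer_f(a: float, f_max: float, x_on: float, x_off: float) -> float:
    if a <= x_on:
        return f_max
    if a >= x_off:
        return 0.0
    return f_max * (x_off - a) / (x_off - x_on)


def _dimer_fprime(a: float, f_max: float, x_on: float, x_off: float) -> float:
    return -f_max / (x_off - x_on) if x_on < a < x_off else 0.0


def dimer_autorepressor(**overrides) -> ModelInstance:
    p = {**DIMER_DEFAULTS, **overrides}
    l, d_a, d_b, d_c = p["l"], p["d_a"], p["d_b"], p["d_c"]
    k, f_max, m = p["k"], p["f_max"], p["m"]
    x_on, x_off = p["x_on"], p["x_off"]

    def rhs(x):
        a, b, c = x
        return np.array(
            [
                k * c * c - l * a - d_a * a,
                d_b * (_dimer_f(a, f_max, x_on, x_off) - b),
                d_c * (m * b - c) + 2.0 * l * a - 2.0 * k * c * c,
            ]
        )

    def jacobian(x):
        a, b, c = x
        fp = _dimer_fprime(a, f_max, x_on, x_off)
        return np.array(
            [
                [-l - d_a, 0.0, 2.0 * k * c],
                [d_b * fp, -d_b, 0.0],
                [2.0 * l, d_c * m, -d_c - 4.0 * k * c],
            ]
        )

    net = RegulatoryNetwork(
        species=("a", "b", "c"),
        degradation=np.array([d_a, d_b, d_c]),
        production={},
        raw=RawRHS(name="dimer_autorepressor", rhs=rhs, jacobian=jacobian),
        name="dimer_autorepressor",
    )
    return ModelInstance(
        network=net,
        params=p,
        init=np.array([1.0, 0.1, 0.1]),
        observed="c",
        steady_state_fn=lambda: dimer_steady_state(**p),
    )


def dimer_steady_state(**params) -> np.ndarray:
    """Unique steady state of the dimer model, by 1-D bracketed root solving.

    At steady state k c*^2 = (l + d_a) a* and b* = f(a*), leaving one
    equation d_c (m b* - c*) = 2 d_a a* in the monomer level c*.
    """
    p = {**DIMER_DEFAULTS, **params}
    l, d_a, d_c, k, m = p["l"], p["d_a"], p["d_c"], p["k"], p["m"]
    f_max, x_on, x_off = p["f_max"], p["x_on"], p["x_off"]

    def res(c):
        a = k * c * c / (l + d_a)
        b = _dimer_f(a, f_max, x_on, x_off)
        return d_c * (m * b - c) - 2.0 * d_a * a

    hi = m * f_max + 1.0  # c* <= sup g = m * sup f at steady state
    c = brentq(res, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
    a = k * c * c / (l + d_a)
    return np.array([a, _dimer_f(a, f_max, x_on, x_off), c])


# ---------------------------------------------------------------------------
# ACDC: repressilator with a reverse link
# ---------------------------------------------------------------------------

ACDC_DEFAULTS = dict(k_rev=-0.5, d=1.0, f_max=2.0, x_on=0.5, x_off=1.5)


def acdc(G: Optional[float] = None, **overrides) -> ModelInstance:
    """Repressilator A -| B -| C -| A plus a reverse link B -> A.

    The reverse link multiplies A's production by max(1 - k + k x_B, 0),
    which equals 1 at the ring's steady state (1,1,1), leaving that state
    unchanged while adding a 2-loop A-B of gain G = -2 k_rev. Passing ``G``
    directly sets k_rev = -G/2.
    """
    p = {**ACDC_DEFAULTS, **overrides}
    if G is not None:
        p["k_rev"] = -G / 2.0
    rep = dict(f_max=p["f_max"], x_on=p["x_on"], x_off=p["x_off"])

    def repress(src):
        return RegulationFunction("piecewise_linear_repress", (src,), rep)

    production = {
        "A": ProductNode(
            (
                repress("C"),
                RegulationFunction("product_modulator", ("B",), {"k": p["k_rev"]}),
            )
        ),
        "B": repress("A"),
        "C": repress("B"),
    }
    net = RegulatoryNetwork(
        species=("A", "B", "C"),
        degradation=np.full(3, p["d"]),
        production=production,
        name="acdc",
    )
    return ModelInstance(
        network=net,
        params={**p, "G": -2.0 * p["k_rev"]},
        init=np.array([2.0, 1.1, 1.1]),
        observed="A",
        steady_state_fn=lambda: np.ones(3),
    )


# ---------------------------------------------------------------------------
# linked repressilators (four species)
# ---------------------------------------------------------------------------

LINKED_DEFAULTS = dict(delta=1.0)


def linked_repressilators(**overrides) -> ModelInstance:
    p = {**LINKED_DEFAULTS, **overrides}
    delta = p["delta"]

    def hill(srcs, v):
        return RegulationFunction("hill_repress", tuple(srcs), {"v": v, "K": 1.0, "h": 4.0})

    production = {
        "a": hill(("b",), 3.0),
        "b": hill(("c", "d"), 10.0),
        "c": hill(("a", "b"), 10.0),
        "d": hill(("c",), 3.0),
    }
    net = RegulatoryNetwork(
        species=("a", "b", "c", "d"),
        degradation=np.array([delta, 1.0, 1.0, delta]),
        production=production,
        name="linked_repressilators",
    )
    return ModelInstance(
        network=net,
        params=p,
        init=np.array([1.4, 1.0, 1.7, 0.3]),
        observed="a",
    )


def repressilator(n: int = 3, d: float = 1.0, v: float = 2.0, h: float = 2.0) -> ModelInstance:
    """Plain n-species Hill repressilator ring (odd number of repressions)."""
    species = tuple(f"x{i+1}" for i in range(n))
    production = {
        species[i]: RegulationFunction(
            "hill_repress", (species[i - 1],), {"v": v, "K": 1.0, "h": h}
        )
        for i in range(n)
    }
    net = RegulatoryNetwork(
        species=species,
        degradation=np.full(n, d),
        production=production,
        name="repressilator",
    )
    return ModelInstance(
        network=net,
        params={"n": n, "d": d, "v": v, "h": h},
        init=np.linspace(0.5, 1.5, n),
        observed=species[0],
    )


MODEL_REGISTRY: dict[str, Callable[..., ModelInstance]] = {
    "dimer_autorepressor": dimer_autorepressor,
    "acdc": acdc,
    "linked_repressilators": linked_repressilators,
    "repressilator": repressilator,
}


def get_model(name: str, **params) -> ModelInstance:
    try:
        builder = MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        ) from None
    return builder(**params)
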