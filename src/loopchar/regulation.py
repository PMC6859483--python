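"""Parametrised regulation functions and production expression trees.

A species' production term ``f_i`` is a composition (sums and products) of
elementary regulation functions of *other* species: Hill repression and
activation, linear (mass-action-like) production, piecewise-linear
repression, a product-form modulator, and free-form symbolic expressions.
Each elementary kind knows its value, its partial derivatives, its monotone
sign, and the points where it is not differentiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "RegulationFunction",
    "SumNode",
    "ProductNode",
    "BreakpointError",
    "KINDS",
]

KINDS = (
    "hill_repress",
    "hill_activate",
    "linear",
    "constant",
    "piecewise_linear_repress",
    "product_modulator",
    "custom_expression",
)

#: tolerance for "state sits on a breakpoint" detection
_BREAK_EPS = 1e-12


class BreakpointError(ValueError):
    """Raised when a derivative is requested at a non-differentiable point."""

    def __init__(self, species: str, location: float):
        self.species = species
        self.location = location
        super().__init__(
            f"derivative undefined: species {species!r} sits at a "
            f"piecewise breakpoint x = {location:g}"
        )


@dataclass(frozen=True)
class RegulationFunction:
    """One elementary regulation term.

    Parameters
    ----------
    kind
        One of :data:`KINDS`.
    inputs
        Names of the regulating species. Hill repression accepts several
        inputs (``v / (1 + sum (x_j/K)^h)``); the other kinds take one.
    params
        Named real constants. Per kind:

        - ``hill_repress``:   ``v`` (ceiling), ``K`` (scale, default 1),
          ``h`` (Hill coefficient, default 1)
        - ``hill_activate``:  ``v``, ``K`` (default 1), ``h`` (default 1)
        - ``linear``:         ``m`` (slope)
        - ``constant``:       ``c``
        - ``piecewise_linear_repress``: ``f_max``, ``x_on``, ``x_off`` —
          value ``f_max`` below ``x_on``, linear down to 0 at ``x_off``,
          0 above; slope ``-f_max/(x_off - x_on)`` in between
        - ``product_modulator``: ``k`` — ``max(1 - k + k*x, 0)``, a
          reverse-link factor that equals 1 at ``x = 1`` and multiplies the
          other input of the target species
        - ``custom_expression``: ``expr`` (a sympy-parsable string in the
          input names) plus optional ``sign``
    """

    kind: str
    inputs: tuple[str, ...]
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown regulation kind {self.kind!r}")
        object.__setattr__(self, "inputs", tuple(self.inputs))
        n_in = len(self.inputs)
        if self.kind == "constant":
            if n_in != 0:
                raise ValueError("constant term takes no inputs")
        elif self.kind == "hill_repress":
            if n_in < 1:
                raise ValueError("hill_repress needs at least one input")
        elif self.kind == "custom_expression":
            if n_in < 1:
                raise ValueError("custom_expression needs at least one input")
        elif n_in != 1:
            raise ValueError(f"{self.kind} takes exactly one input")
        if self.kind == "custom_expression":
            object.__setattr__(self, "_lambdas", _compile_expression(self))

    # -- evaluation --------------------------------------------------------

    def value(self, x: Mapping[str, float]) -> float:
        p = self.params
        if self.kind == "constant":
            return float(p["c"])
        if self.kind == "hill_repress":
            K = p.get("K", 1.0)
            h = p.get("h", 1.0)
            s = sum((x[name] / K) ** h for name in self.inputs)
            return p["v"] / (1.0 + s)
        xi = x[self.inputs[0]] if self.inputs else 0.0
        if self.kind == "hill_activate":
            K = p.get("K", 1.0)
            h = p.get("h", 1.0)
            u = (xi / K) ** h
            return p["v"] * u / (1.0 + u)
        if self.kind == "linear":
            return p["m"] * xi
        if self.kind == "piecewise_linear_repress":
            x_on, x_off, f_max = p["x_on"], p["x_off"], p["f_max"]
            if xi <= x_on:
                return f_max
            if xi >= x_off:
                return 0.0
            return f_max * (x_off - xi) / (x_off - x_on)
        if self.kind == "product_modulator":
            return max(1.0 - p["k"] + p["k"] * xi, 0.0)
        if self.kind == "custom_expression":
            fn = self._lambdas[0]
            return float(fn(*(x[name] for name in self.inputs)))
        raise AssertionError(self.kind)

    def partial(self, wrt: str, x: Mapping[str, float]) -> float:
        """Partial derivative with respect to species ``wrt`` at state ``x``.

        Raises :class:`BreakpointError` at kinks of the piecewise kinds.
        """
        if wrt not in self.inputs:
            return 0.0
        p = self.params
        if self.kind == "hill_repress":
            K = p.get("K", 1.0)
            h = p.get("h", 1.0)
            s = sum((x[name] / K) ** h for name in self.inputs)
            xi = x[wrt]
            if xi == 0.0 and h < 1.0:
                raise BreakpointError(wrt, 0.0)
            du = (h / K) * (xi / K) ** (h - 1.0) if xi != 0.0 or h >= 1.0 else 0.0
            return -p["v"] * du / (1.0 + s) ** 2
        xi = x[wrt]
        if self.kind == "hill_activate":
            K = p.get("K", 1.0)
            h = p.get("h", 1.0)
            u = (xi / K) ** h
            du = (h / K) * (xi / K) ** (h - 1.0) if xi != 0.0 or h >= 1.0 else 0.0
            return p["v"] * du / (1.0 + u) ** 2
        if self.kind == "linear":
            return p["m"]
        if self.kind == "piecewise_linear_repress":
            x_on, x_off, f_max = p["x_on"], p["x_off"], p["f_max"]
            for b in (x_on, x_off):
                if abs(xi - b) < _BREAK_EPS:
                    raise BreakpointError(wrt, b)
            if x_on < xi < x_off:
                return -f_max / (x_off - x_on)
            return 0.0
        if self.kind == "product_modulator":
            k = p["k"]
            if k == 0.0:
                return 0.0
            b = (k - 1.0) / k
            arg = 1.0 - k + k * xi
            if abs(arg) < _BREAK_EPS * max(1.0, abs(k)):
                raise BreakpointError(wrt, b)
            return k if arg > 0.0 else 0.0
        if self.kind == "custom_expression":
            fn = self._lambdas[1][self.inputs.index(wrt)]
            return float(fn(*(x[name] for name in self.inputs)))
        return 0.0  # constant

    # -- structure ---------------------------------------------------------

    def sign(self, wrt: str) -> int:
        """Monotone sign (+1/-1/0) of this term with respect to ``wrt``."""
        if wrt not in self.inputs:
            return 0
        if self.kind in ("hill_repress", "piecewise_linear_repress"):
            return -1
        if self.kind == "hill_activate":
            return +1
        if self.kind == "linear":
            return _sgn(self.params["m"])
        if self.kind == "product_modulator":
            return _sgn(self.params["k"])
        if self.kind == "custom_expression":
            return int(self.params.get("sign", 0))
        return 0

    def breakpoints(self, wrt: str) -> tuple[float, ...]:
        """Input values at which the derivative w.r.t. ``wrt`` is undefined."""
        if wrt not in self.inputs:
            return ()
        if self.kind == "piecewise_linear_repress":
            return (self.params["x_on"], self.params["x_off"])
        if self.kind == "product_modulator":
            k = self.params["k"]
            return ((k - 1.0) / k,) if k != 0.0 else ()
        return ()

    def supremum(self) -> float:
        """Least upper bound of the term over non-negative inputs.

        ``inf`` for the unbounded kinds (linear, custom).
        """
        p = self.params
        if self.kind in ("hill_repress", "hill_activate"):
            return float(p["v"])
        if self.kind == "piecewise_linear_repress":
            return float(p["f_max"])
        if self.kind == "constant":
            return float(p["c"])
        if self.kind == "product_modulator":
            return math.inf if p["k"] > 0 else max(1.0 - p["k"], 0.0)
        return math.inf


def _sgn(v: float) -> int:
    return (v > 0) - (v < 0)


def _compile_expression(rf: RegulationFunction):
    import sympy

    syms = [sympy.Symbol(name) for name in rf.inputs]
    expr = sympy.sympify(rf.params["expr"])
    val = sympy.lambdify(syms, expr, "math")
    grads = [sympy.lambdify(syms, sympy.diff(expr, s), "math") for s in syms]
    return (val, grads)


@dataclass(frozen=True)
class SumNode:
    """Sum of production sub-trees."""

    terms: tuple

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def inputs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            for name in t.inputs:
                if name not in seen:
                    seen.append(name)
        return tuple(seen)

    def value(self, x):
        return sum(t.value(x) for t in self.terms)

    def partial(self, wrt, x):
        return sum(t.partial(wrt, x) for t in self.terms)

    def sign(self, wrt) -> int:
        signs = {t.sign(wrt) for t in self.terms if wrt in t.inputs}
        signs.discard(0)
        if len(signs) == 1:
            return signs.pop()
        return 0

    def breakpoints(self, wrt):
        out: tuple[float, ...] = ()
        for t in self.terms:
            out += t.breakpoints(wrt)
        return out

    def supremum(self):
        return sum(t.supremum() for t in self.terms)


@dataclass(frozen=True)
class ProductNode:
    """Product of production sub-trees (e.g. a Hill term times a reverse-link
    modulator). Factor values are assumed non-negative, which holds for every
    built-in kind, so the sign of a partial follows the differentiated factor.
    """

    terms: tuple

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def inputs(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.terms:
            for name in t.inputs:
                if name not in seen:
                    seen.append(name)
        return tuple(seen)

    def value(self, x):
        out = 1.0
        for t in self.terms:
            out *= t.value(x)
        return out

    def partial(self, wrt, x):
        vals = [t.value(x) for t in self.terms]
        total = 0.0
        for i, t in enumerate(self.terms):
            if wrt not in t.inputs:
                continue
            rest = 1.0
            for j, v in enumerate(vals):
                if j != i:
                    rest *= v
            total += t.partial(wrt, x) * rest
        return total

    def sign(self, wrt) -> int:
        signs = {t.sign(wrt) for t in self.terms if wrt in t.inputs}
        signs.discard(0)
        if len(signs) == 1:
            return signs.pop()
        return 0

    def breakpoints(self, wrt):
        out: tuple[float, ...] = ()
        for t in self.terms:
            out += t.breakpoints(wrt)
        return out

    def supremum(self):
        out = 1.0
        for t in self.terms:
            out *= t.supremum()
        return out
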