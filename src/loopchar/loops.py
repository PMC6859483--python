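"""Feedback-loop enumeration and the loop expansion of the characteristic
equation.

At a steady state, local stability is governed by the characteristic
polynomial of the Jacobian. For networks of the d(f - x) form with no direct
self-regulation, that polynomial — normalised by the product of degradation
rates — expands as a sum over sets S of pairwise vertex-disjoint ("mutually
exclusive") feedback loops:

    P(lam) = sum_S (-1)^{l_S} H_S  prod_{j not in S} (1 + lam/d_j),

where l_S is the number of loops in S, H_S the product of the production
gradients around every loop in S evaluated at the steady state, and the
empty set contributes H = 1. This module enumerates loops and disjoint loop
sets, evaluates their gains, assembles P(lam), and provides the direct
determinant construction as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from numpy.polynomial import Polynomial

from .network import RegulatoryNetwork, SteadyState

__all__ = [
    "Loop",
    "LoopSet",
    "CharacteristicPoly",
    "enumerate_loops",
    "enumerate_disjoint_loop_sets",
    "loop_gain",
    "characteristic_from_loops",
    "characteristic_direct",
]


@dataclass(frozen=True)
class Loop:
    """A simple directed cycle of the regulation graph.

    ``vertices`` is the cycle in canonical rotation (smallest species index
    first); edge ``vertices[k] -> vertices[k+1]`` means the first species
    regulates the second. ``sign`` is the product of structural edge signs
    (0 when any edge sign is indeterminate).
    """

    vertices: tuple[int, ...]
    sign: int

    def __len__(self):
        return len(self.vertices)

    @property
    def edges(self) -> tuple[tuple[int, int], ...]:
        v = self.vertices
        return tuple((v[k], v[(k + 1) % len(v)]) for k in range(len(v)))


@dataclass(frozen=True)
class LoopSet:
    """A set of pairwise vertex-disjoint loops with its expansion bookkeeping."""

    loops: tuple[Loop, ...]
    outside: tuple[int, ...]

    @property
    def l_S(self) -> int:
        return len(self.loops)

    @property
    def vertices(self) -> frozenset[int]:
        return frozenset(v for lp in self.loops for v in lp.vertices)

    def gain(self, network: RegulatoryNetwork, state) -> float:
        """Product gain H_S at ``state`` (1 for the empty set)."""
        out = 1.0
        for lp in self.loops:
            out *= loop_gain(network, lp, state)
        return out


@dataclass(frozen=True)
class CharacteristicPoly:
    """Degree-n polynomial in the eigenvalue variable, normalised so the
    no-loop term is prod_j (1 + lam/d_j) (i.e. det(lam I - J) / prod_j d_j).
    """

    coefficients: np.ndarray  # ascending order

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", c)
        if c[-1] == 0.0:
            raise ValueError("leading coefficient must be nonzero")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, lam):
        return Polynomial(self.coefficients)(lam)

    def roots(self) -> np.ndarray:
        return Polynomial(self.coefficients).roots()


def _canonical(cycle: Sequence[int]) -> tuple[int, ...]:
    cycle = list(cycle)
    k = cycle.index(min(cycle))
    return tuple(cycle[k:] + cycle[:k])


def enumerate_loops(network: RegulatoryNetwork) -> list[Loop]:
    """All simple directed cycles of the production-dependency graph.

    Deterministic order: by length, then lexicographically by canonical
    vertex sequence. Acyclic networks yield an empty list.
    """
    if network.is_raw:
        raise ValueError("loop enumeration needs an explicit production graph")
    g = nx.DiGraph()
    g.add_nodes_from(range(network.n))
    edge_sign = {}
    for src, tgt, sign in network.edges():
        g.add_edge(src, tgt)
        edge_sign[(src, tgt)] = sign
    loops = []
    for cyc in nx.simple_cycles(g):
        v = _canonical(cyc)
        sign = 1
        for e in Loop(v, 0).edges:
            s = edge_sign[e]
            if s == 0:
                sign = 0
                break
            sign *= s
        loops.append(Loop(vertices=v, sign=sign))
    loops.sort(key=lambda lp: (len(lp), lp.vertices))
    return loops


def enumerate_disjoint_loop_sets(
    loops: Sequence[Loop], n: Optional[int] = None
) -> list[LoopSet]:
    """Every subset of pairwise vertex-disjoint loops, empty set included.

    ``n`` (species count) fixes the ``outside`` vertex bookkeeping; it
    defaults to the highest vertex index seen plus one.
    """
    if n is None:
        n = 1 + max((v for lp in loops for v in lp.vertices), default=-1)
    all_v = set(range(n))
    sets: list[LoopSet] = []
    order = sorted(loops, key=lambda lp: (min(lp.vertices), lp.vertices))

    def backtrack(start: int, chosen: list[Loop], used: set[int]):
        sets.append(
            LoopSet(loops=tuple(chosen), outside=tuple(sorted(all_v - used)))
        )
        for i in range(start, len(order)):
            lv = set(order[i].vertices)
            if used & lv:
                continue
            chosen.append(order[i])
            backtrack(i + 1, chosen, used | lv)
            chosen.pop()

    backtrack(0, [], set())
    sets.sort(key=lambda s: (s.l_S, tuple(lp.vertices for lp in s.loops)))
    return sets


def loop_gain(network: RegulatoryNetwork, loop: Loop, state) -> float:
    """Product of production gradients df_tgt/dx_src around the cycle."""
    x = state.values if isinstance(state, SteadyState) else np.asarray(state, float)
    dP = network.production_jacobian(x)
    out = 1.0
    for src, tgt in loop.edges:
        out *= dP[tgt, src]
    return float(out)


def _one_plus_lam_over(d: float) -> Polynomial:
    return Polynomial([1.0, 1.0 / d])


def characteristic_from_loops(
    network: RegulatoryNetwork, state
) -> CharacteristicPoly:
    """Assemble the characteristic polynomial by the loop expansion."""
    if network.is_raw:
        raise ValueError(
            "loop expansion requires the d(f - x) form; use characteristic_direct"
        )
    loops = enumerate_loops(network)
    d = network.degradation
    total = Polynomial([0.0])
    for ls in enumerate_disjoint_loop_sets(loops, n=network.n):
        term = Polynomial([(-1.0) ** ls.l_S * ls.gain(network, state)])
        for j in ls.outside:
            term = term * _one_plus_lam_over(d[j])
        total = total + term
    coef = np.zeros(network.n + 1)
    coef[: len(total.coef)] = total.coef
    return CharacteristicPoly(coefficients=coef)


def characteristic_direct(network: RegulatoryNetwork, state) -> CharacteristicPoly:
    """Characteristic polynomial from the Jacobian determinant (oracle form).

    Computes det(lam I - J) via the eigenvalue-free companion expansion
    (numpy.poly) and applies the same 1/prod(d_j) normalisation as
    :func:`characteristic_from_loops`.
    """
    x = state.values if isinstance(state, SteadyState) else np.asarray(state, float)
    J = network.jacobian_at(x)
    coef_desc = np.poly(J)  # descending, monic in lam
    coef = coef_desc[::-1] / np.prod(network.degradation)
    imag = np.max(np.abs(np.imag(coef))) if np.iscomplexobj(coef) else 0.0
    assert imag < 1e-12, "characteristic coefficients must be real"
    return CharacteristicPoly(coefficients=np.real(coef))
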