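"""Regulatory-network ODE models of the form x_i' = d_i (f_i(x) - x_i).

Each species decays linearly at rate ``d_i`` and is produced at rate
``d_i f_i(x)`` where ``f_i`` is a composition of regulation functions of the
*other* species (no direct self-regulation). Models that fall outside this
form — notably the dimeric auto-repressor, whose dimerisation reaction
couples species through mass-action terms — are carried as a raw
right-hand-side override with an optional analytic Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import root as _scipy_root
from scipy.stats import qmc

from .regulation import BreakpointError, ProductNode, RegulationFunction, SumNode

__all__ = [
    "RegulatoryNetwork",
    "RawRHS",
    "SteadyState",
    "NetworkSpecError",
    "build_network",
    "load_network",
    "find_steady_states",
]

#: steady states closer than this (max-norm) are considered duplicates
DEDUP_TOL = 1e-6
#: residual tolerance for an accepted steady state, max-norm of f(x*) - x*
RESIDUAL_TOL = 1e-9


class NetworkSpecError(ValueError):
    """Malformed network specification."""


@dataclass(frozen=True)
class RawRHS:
    """Right-hand-side override for models outside the d(f - x) form."""

    name: str
    rhs: Callable[[np.ndarray], np.ndarray]
    jacobian: Optional[Callable[[np.ndarray], np.ndarray]] = None


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of the network dynamics."""

    values: np.ndarray
    residual_norm: float

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __getitem__(self, i):
        return self.values[i]

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class RegulatoryNetwork:
    """An ODE model of interacting biochemical species.

    Attributes
    ----------
    species
        Ordered species names; all vectors follow this order.
    degradation
        Strictly positive per-species linear decay rates ``d_i`` (1/time).
    production
        Per-species production tree ``f_i`` (absent entries mean ``f_i = 0``).
        A species never appears among the inputs of its own tree.
    raw
        Optional :class:`RawRHS` override; when present, ``rhs`` and
        ``jacobian_at`` delegate to it and the production trees are unused.
    """

    species: tuple[str, ...]
    degradation: np.ndarray
    production: Mapping[str, object]
    raw: Optional[RawRHS] = None
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        d = np.asarray(self.degradation, dtype=float)
        object.__setattr__(self, "degradation", d)
        if len(d) != len(self.species):
            raise NetworkSpecError("one degradation rate per species required")
        if np.any(d <= 0):
            raise NetworkSpecError("degradation rates must be strictly positive")
        for name, tree in self.production.items():
            if name not in self.species:
                raise NetworkSpecError(f"production for unknown species {name!r}")
            for ref in tree.inputs:
                if ref == name:
                    raise NetworkSpecError(
                        f"species {name!r} regulates itself through production; "
                        "direct self-regulation is not representable"
                    )
                if ref not in self.species:
                    raise NetworkSpecError(
                        f"production of {name!r} references unknown species {ref!r}"
                    )

    # -- basic structure ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def is_raw(self) -> bool:
        return self.raw is not None

    def index(self, name: str) -> int:
        return self.species.index(name)

    def edges(self) -> list[tuple[int, int, int]]:
        """Regulatory edges ``(source, target, sign)`` of the production graph."""
        out = []
        for tgt, tree in self.production.items():
            j = self.index(tgt)
            for src in tree.inputs:
                out.append((self.index(src), j, tree.sign(src)))
        out.sort()
        return out

    def _state_map(self, x: np.ndarray) -> dict[str, float]:
        return dict(zip(self.species, map(float, x)))

    # -- evaluation --------------------------------------------------------

    def production_values(self, x: np.ndarray) -> np.ndarray:
        xm = self._state_map(x)
        return np.array(
            [
                self.production[s].value(xm) if s in self.production else 0.0
                for s in self.species
            ]
        )

    def rhs(self, x: Sequence[float]) -> np.ndarray:
        """Time derivative of the state: ``d_i (f_i(x) - x_i)`` or the raw form."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(
                f"state has shape {x.shape}, expected ({self.n},) for species "
                f"{self.species}"
            )
        if self.raw is not None:
            return np.asarray(self.raw.rhs(x), dtype=float)
        return self.degradation * (self.production_values(x) - x)

    def production_jacobian(self, x: Sequence[float]) -> np.ndarray:
        """Matrix of production gradients ``df_i/dx_j`` at ``x``.

        These per-edge gradients are the factors entering loop gains; the
        dynamical Jacobian scales row ``i`` by ``d_i`` and subtracts ``d_i``
        on the diagonal.
        """
        if self.raw is not None:
            raise ValueError(
                "production gradients undefined for raw-RHS models; "
                "use jacobian_at"
            )
        x = np.asarray(x, dtype=float)
        xm = self._state_map(x)
        J = np.zeros((self.n, self.n))
        for tgt, tree in self.production.items():
            i = self.index(tgt)
            for src in tree.inputs:
                J[i, self.index(src)] = tree.partial(src, xm)
        return J

    def jacobian_at(self, x: Sequence[float]) -> np.ndarray:
        """Dynamical Jacobian ``d(rhs)/dx`` at state ``x``.

        For piecewise regulation kinds the state must lie strictly inside a
        smooth region; at a breakpoint a :class:`BreakpointError` is raised
        naming the offending species.
        """
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"state has shape {x.shape}, expected ({self.n},)")
        if self.raw is not None:
            if self.raw.jacobian is not None:
                return np.asarray(self.raw.jacobian(x), dtype=float)
            return _fd_jacobian(self.raw.rhs, x)
        dP = self.production_jacobian(x)
        return self.degradation[:, None] * (dP - np.eye(self.n))


def _fd_jacobian(f: Callable, x: np.ndarray) -> np.ndarray:
    """Central finite-difference Jacobian with step 1e-7 * (1 + |x_j|)."""
    n = len(x)
    J = np.zeros((n, n))
    for j in range(n):
        h = 1e-7 * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# specification parsing
# ---------------------------------------------------------------------------


def _parse_tree(node, context: str):
    """Parse one production node: a regulation-term mapping or sum/product."""
    if not isinstance(node, Mapping):
        raise NetworkSpecError(f"{context}: production node must be a mapping")
    if "sum" in node:
        return SumNode(tuple(_parse_tree(t, context) for t in node["sum"]))
    if "product" in node:
        return ProductNode(tuple(_parse_tree(t, context) for t in node["product"]))
    if "kind" not in node:
        raise NetworkSpecError(f"{context}: expected 'kind', 'sum' or 'product'")
    inputs = node.get("inputs", node.get("input", ()))
    if isinstance(inputs, str):
        inputs = (inputs,)
    try:
        return RegulationFunction(
            kind=node["kind"], inputs=tuple(inputs), params=dict(node.get("params", {}))
        )
    except ValueError as exc:
        raise NetworkSpecError(f"{context}: {exc}") from exc


def build_network(spec: Mapping) -> RegulatoryNetwork:
    """Build a :class:`RegulatoryNetwork` from a structured description.

    The description is a mapping with keys ``species`` (ordered list),
    ``degradation`` (name -> positive rate) and ``production``
    (name -> expression tree), or alternatively ``model`` naming a built-in
    model from the registry with optional ``params`` overrides.
    """
    if "model" in spec:
        from .models import get_model

        return get_model(spec["model"], **dict(spec.get("params", {}))).network
    try:
        species = list(spec["species"])
    except KeyError:
        raise NetworkSpecError("spec must list 'species'")
    if len(set(species)) != len(species):
        raise NetworkSpecError("duplicate species names")
    degr = spec.get("degradation", {})
    missing = [s for s in species if s not in degr]
    if missing:
        raise NetworkSpecError(f"no degradation rate for species {missing}")
    production = {
        name: _parse_tree(node, f"production[{name}]")
        for name, node in spec.get("production", {}).items()
    }
    return RegulatoryNetwork(
        species=tuple(species),
        degradation=np.array([float(degr[s]) for s in species]),
        production=production,
        name=str(spec.get("name", "")),
    )


def load_network(path) -> RegulatoryNetwork:
    """Load a network spec file (YAML; JSON is a YAML subset)."""
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, Mapping):
        raise NetworkSpecError(f"{path}: spec file must contain a mapping")
    return build_network(spec)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------


def _search_box(network: RegulatoryNetwork, default_hi: float = 10.0) -> np.ndarray:
    """Upper corner of the multi-start box: sup f_i per species when finite."""
    hi = np.full(network.n, default_hi)
    if network.raw is None:
        for i, s in enumerate(network.species):
            tree = network.production.get(s)
            if tree is not None:
                sup = tree.supremum()
                if np.isfinite(sup):
                    hi[i] = max(sup, 1e-3)
    return hi


def find_steady_states(
    network: RegulatoryNetwork,
    n_starts: int = 200,
    seed: int = 0,
    box_hi: Optional[Sequence[float]] = None,
    tol: float = 1e-12,
) -> list[SteadyState]:
    """Locate non-negative fixed points by multi-start root finding.

    Starts are a Latin-hypercube sample of ``[0, x_max]`` per species, with
    ``x_max = sup f_i`` where finite (the fixed point of the d(f - x) form
    must satisfy ``x_i* = f_i(x*) <= sup f_i``). Converged roots are
    deduplicated at max-norm tolerance 1e-6 and sorted by the first species'
    value; results are deterministic for a given seed. Roots with a
    meaningfully negative component are discarded as unphysical.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    n = network.n
    hi = np.asarray(box_hi, dtype=float) if box_hi is not None else _search_box(network)
    sampler = qmc.LatinHypercube(d=n, seed=seed)
    starts = sampler.random(n_starts) * hi

    if network.raw is None:
        def residual(x):
            return network.production_values(x) - x
    else:
        def residual(x):
            return network.raw.rhs(x)

    found: list[np.ndarray] = []
    for x0 in starts:
        sol = _scipy_root(residual, x0, method="hybr", tol=tol)
        if not sol.success:
            continue
        x = sol.x
        res = float(np.max(np.abs(residual(x))))
        if res > RESIDUAL_TOL:
            continue
        if np.min(x) < -1e-8:
            continue
        x = np.where(np.abs(x) < 1e-14, 0.0, x)
        if all(np.max(np.abs(x - y)) > DEDUP_TOL for y in found):
            found.append(x)
    if not found:
        warnings.warn(
            f"no steady state found for network {network.name or network.species} "
            f"with {n_starts} starts",
            stacklevel=2,
        )
        return []
    found.sort(key=lambda x: tuple(x))
    return [
        SteadyState(values=x, residual_norm=float(np.max(np.abs(residual(x)))))
        for x in found
    ]
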