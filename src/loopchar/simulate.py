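"""Time integration, oscillation metrics and bifurcation sweeps.

Oscillation amplitude is the max-minus-min of the observed species on a
fixed late time window (default [500, 1000]) of a trajectory started from
the model's standard initial condition; the period is the mean spacing of
upward mean-crossings in the same window. Bifurcation sweeps repeat this
per parameter value; Hopf points are located independently by bisection on
the real part of the leading complex eigenvalue pair at the tracked steady
state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .models import ModelInstance, get_model
from .network import RegulatoryNetwork, SteadyState, find_steady_states

__all__ = [
    "Trajectory",
    "HopfPoint",
    "integrate",
    "amplitude",
    "period",
    "bifurcation_sweep",
    "locate_hopf",
    "OSCILLATION_AMPLITUDE_MIN",
    "DEFAULT_WINDOW",
]

#: amplitude above which a trajectory is classified as oscillating
OSCILLATION_AMPLITUDE_MIN = 1e-3
#: standard measurement window (time units)
DEFAULT_WINDOW = (500.0, 1000.0)


@dataclass(frozen=True)
class Trajectory:
    """Uniformly resampled solution of one model integration."""

    times: np.ndarray
    states: np.ndarray            # shape (n_times, n_species)
    species: tuple[str, ...]
    model: str = ""

    def column(self, species: str) -> np.ndarray:
        return self.states[:, self.species.index(species)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df


@dataclass(frozen=True)
class HopfPoint:
    """An imaginary-axis eigenvalue crossing found numerically."""

    parameter: str
    value: float
    steady_state: np.ndarray
    alpha: float                 #: |Im| of the crossing pair (rad/time)
    real_part_residual: float
    threshold: Optional[float] = None


def integrate(
    network: RegulatoryNetwork,
    init: Sequence[float],
    t_end: float,
    dt_out: float = 0.05,
    t0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    model: str = "",
) -> Trajectory:
    """Integrate the network ODEs and resample on a uniform grid.

    A stiff-capable solver with dense output is used so the amplitude and
    period extraction work on a solver-independent uniform grid. Initial
    concentrations are clipped at zero.
    """
    if t_end <= t0:
        raise ValueError("t_end must exceed t0")
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    y0 = np.clip(np.asarray(init, dtype=float), 0.0, None)
    sol = solve_ivp(
        lambda t, y: network.rhs(y),
        (t0, t_end),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed for model {model or network.name!r}: {sol.message}"
        )
    times = np.arange(t0, t_end + 0.5 * dt_out, dt_out)
    times = times[times <= sol.t[-1] + 1e-12]
    states = sol.sol(times).T
    return Trajectory(
        times=times, states=states, species=network.species,
        model=model or network.name,
    )


def _window_slice(traj: Trajectory, window) -> slice:
    t0, t1 = window
    if t0 < traj.times[0] - 1e-9 or t1 > traj.times[-1] + 1e-9:
        raise ValueError(
            f"window {window} outside trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}]"
        )
    i0 = int(np.searchsorted(traj.times, t0 - 1e-12))
    i1 = int(np.searchsorted(traj.times, t1 + 1e-12))
    if i1 <= i0:
        raise ValueError("empty measurement window")
    return slice(i0, i1)


def amplitude(traj: Trajectory, species: str, window=DEFAULT_WINDOW) -> float:
    """Max minus min of one species over the grid points in the window."""
    x = traj.column(species)[_window_slice(traj, window)]
    return float(x.max() - x.min())


def period(traj: Trajectory, species: str, window=DEFAULT_WINDOW) -> Optional[float]:
    """Mean spacing between upward mean-crossings in the window.

    A crossing timepoint is one at which the concentration is below its
    window mean but is not at the next timepoint. With k such timepoints the
    period is (t_last - t_first)/(k - 1), i.e. the elapsed time divided by
    the number of whole cycles between the first and last crossing. Returns
    ``None`` with fewer than two crossings.
    """
    sl = _window_slice(traj, window)
    t = traj.times[sl]
    x = traj.column(species)[sl]
    mean = x.mean()
    below = x < mean
    crossing = below[:-1] & ~below[1:]
    t_cross = t[:-1][crossing]
    if len(t_cross) < 2:
        return None
    return float((t_cross[-1] - t_cross[0]) / (len(t_cross) - 1))


def bifurcation_sweep(
    model: str,
    parameter: str,
    values: Sequence[float],
    window=DEFAULT_WINDOW,
    dt_out: float = 0.05,
    init: Optional[Sequence[float]] = None,
    observed: Optional[str] = None,
    amplitude_min: float = OSCILLATION_AMPLITUDE_MIN,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    **fixed_params,
) -> pd.DataFrame:
    """One integration per parameter value; amplitude/period/oscillating rows.

    Uses the registry model's standard initial condition and observed
    species unless overridden. Per-value integration failures are recorded
    (NaN amplitude) and the sweep continues.
    """
    rows = []
    t_end = window[1]
    t_mid = 0.5 * (window[0] + window[1])
    for v in values:
        inst = get_model(model, **{parameter: v}, **fixed_params)
        obs = observed or inst.observed
        y0 = init if init is not None else inst.init
        try:
            traj = integrate(
                inst.network, y0, t_end=t_end, dt_out=dt_out,
                rtol=rtol, atol=atol, model=model,
            )
            amp = amplitude(traj, obs, window)
            per = period(traj, obs, window)
            amp_early = amplitude(traj, obs, (window[0], t_mid))
            amp_late = amplitude(traj, obs, (t_mid, window[1]))
        except RuntimeError as exc:
            warnings.warn(f"{model} at {parameter}={v}: {exc}", stacklevel=2)
            amp, per = math.nan, None
            amp_early = amp_late = math.nan
        oscillating = bool(amp > amplitude_min) if math.isfinite(amp) else False
        # a limit cycle keeps its amplitude through the window; slowly
        # decaying transients (possible just below the bifurcation) do not
        sustained = (
            oscillating
            and math.isfinite(amp_late)
            and amp_late > amplitude_min
            and amp_late > 0.5 * amp_early
        )
        rows.append(
            {
                "parameter": parameter,
                "value": float(v),
                "amplitude": amp,
                "period": per if per is not None else math.nan,
                "oscillating": oscillating,
                "sustained": sustained,
            }
        )
    return pd.DataFrame(rows)


def _leading_pair_real(J: np.ndarray) -> tuple[float, float]:
    """(max real part, |Im|) over the complex eigenvalue pairs of J;
    falls back to the overall leading eigenvalue if all are real."""
    ev = np.linalg.eigvals(J)
    cplx = ev[np.abs(ev.imag) > 1e-12]
    if len(cplx) == 0:
        lead = ev[np.argmax(ev.real)]
        return float(lead.real), 0.0
    lead = cplx[np.argmax(cplx.real)]
    return float(lead.real), float(abs(lead.imag))


def locate_hopf(
    model: str,
    parameter: str,
    bracket: tuple[float, float],
    seed: int = 0,
    xtol: float = 1e-10,
    **fixed_params,
) -> HopfPoint:
    """Bisect on the real part of the leading complex eigenvalue pair.

    At each trial parameter value the steady state is recomputed (the
    model's own solver when it has one, multi-start search otherwise, with
    continuation from the previous value's state) and the Jacobian's
    leading complex pair is evaluated. Raises if the real part does not
    change sign across the bracket.
    """
    prev_state: dict[str, Optional[np.ndarray]] = {"x": None}

    def steady(inst: ModelInstance) -> np.ndarray:
        guess = inst.steady_state_guess()
        if guess is not None:
            return guess
        states = find_steady_states(inst.network, n_starts=40, seed=seed)
        if not states:
            raise RuntimeError(f"no steady state at {parameter} in bracket")
        if prev_state["x"] is not None:
            states.sort(
                key=lambda s: float(np.max(np.abs(s.values - prev_state["x"])))
            )
        return states[0].values

    def real_part(v: float) -> float:
        inst = get_model(model, **{parameter: v}, **fixed_params)
        x = steady(inst)
        prev_state["x"] = x
        re, _ = _leading_pair_real(inst.network.jacobian_at(x))
        return re

    lo, hi = bracket
    f_lo, f_hi = real_part(lo), real_part(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no eigenvalue-crossing sign change in bracket {bracket}: "
            f"Re = {f_lo:.3e} and {f_hi:.3e}"
        )
    v_star = brentq(real_part, lo, hi, xtol=xtol, rtol=8.9e-16)
    inst = get_model(model, **{parameter: v_star}, **fixed_params)
    x = steady(inst)
    re, im = _leading_pair_real(inst.network.jacobian_at(x))
    return HopfPoint(
        parameter=parameter,
        value=float(v_star),
        steady_state=x,
        alpha=im,
        real_part_residual=re,
    )
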