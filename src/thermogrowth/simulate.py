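"""Numerical integration of the network over the experimental timeline.

Integration starts at the prelude (``t = -24`` h) from a dark-adapted state:
no active phyB, and ELF3/COP1/PIF at their constant-drive dark steady state
at 22 °C, so genotype differences at the start of the growth phase emerge
from the prelude dynamics rather than being asserted.  The adaptive stepper
is restarted at every forcing discontinuity (lights on/off, plate transfer,
and the edges of the ELF3 dusk bump), so no step straddles a switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .environment import (
    EnvironmentRegime,
    PRELUDE_LIGHT_H,
    PRELUDE_START_H,
    light_at,
    temperature_at,
    transition_times,
)
from .model import (
    ParameterSet,
    State,
    elf3_drive,
    free_running_mean_drive,
    rhs_constant_forcing,
    steady_state_constant,
)

__all__ = [
    "Trajectory",
    "integrate",
    "final_hypocotyl",
    "thermal_elongation",
    "initial_state",
    "rhs_breakpoints",
    "elf3_periodic_profile",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass
class Trajectory:
    """Time course of the five state variables for one genotype x regime."""

    times: np.ndarray  # hours, strictly increasing
    states: np.ndarray  # shape (len(times), 5): columns B, E, C, P, H
    regime: EnvironmentRegime
    genotype: str
    parameters: ParameterSet
    g_Y: float = 1.0

    @property
    def B(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def C(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def P(self) -> np.ndarray:
        return self.states[:, 3]

    @property
    def H(self) -> np.ndarray:
        return self.states[:, 4]

    @property
    def Y(self) -> np.ndarray:
        p = self.parameters
        return self.g_Y * p.Y0 / (1.0 + self.C / p.K_C)

    def at(self, t: float) -> State:
        """State at grid time ``t`` (must be a grid point)."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9:
            raise ValueError(f"t={t} is not on the output grid")
        return State.from_array(self.states[i])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, B, E, C, P, Y, H, light, temperature_C,
        genotype, photoperiod_h."""
        return pd.DataFrame(
            {
                "time_h": self.times,
                "B": self.B,
                "E": self.E,
                "C": self.C,
                "P": self.P,
                "Y": self.Y,
                "H": self.H,
                "light": [light_at(t, self.regime) for t in self.times],
                "temperature_C": [temperature_at(t, self.regime) for t in self.times],
                "genotype": self.genotype,
                "photoperiod_h": self.regime.photoperiod_h,
            }
        )


def rhs_breakpoints(regime: EnvironmentRegime, horizon: float,
                    p: ParameterSet) -> list[float]:
    """Forcing discontinuities plus the ELF3 dusk-bump edges in
    ``(start, horizon)`` — every instant where the RHS is discontinuous."""
    events = set(transition_times(regime, horizon))
    D = regime.photoperiod_h
    if regime.sync_prelude:
        e = PRELUDE_START_H + PRELUDE_LIGHT_H + p.w_E  # prelude bump end
        if e < 0.0:
            events.add(e)
    if 0.0 < D < 24.0 and p.w_E > 0.0:
        e = (D + p.w_E) % 24.0
        k = 0
        while 24.0 * k + e < horizon:
            if 24.0 * k + e > regime.start_h:
                events.add(24.0 * k + e)
            k += 1
    return sorted(events)


def initial_state(p: ParameterSet, g) -> State:
    """Dark-adapted state at the start of the timeline: B = 0; E, C, P at
    the dark constant-drive steady state at 22 °C; H = H0."""
    s = steady_state_constant(p, g, L=0, T=22.0, drive=free_running_mean_drive(p))
    s.B = 0.0
    return s


def integrate(p: ParameterSet, g, regime: EnvironmentRegime,
              output_step: float = 0.5, rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL) -> Trajectory:
    """Integrate the model from the dark-adapted start to the end of the
    growth phase, restarting the adaptive stepper at each discontinuity.

    The output grid is the union of multiples of ``output_step`` (counted
    from the timeline start), every breakpoint, and the endpoint.
    """
    if output_step <= 0:
        raise ValueError(f"output_step must be > 0, got {output_step}")
    t0, t1 = regime.start_h, regime.end_h
    breaks = np.unique(np.round(
        [t0] + rhs_breakpoints(regime, t1, p) + [t1], 9))

    n_out = int(math.floor((t1 - t0) / output_step + 1e-9))
    out_pts = t0 + output_step * np.arange(n_out + 1)
    grid = np.unique(np.round(np.concatenate([out_pts, breaks]), 9))

    y = initial_state(p, g).to_array()
    times: list[float] = [float(breaks[0])]
    states: list[np.ndarray] = [y.copy()]
    for a, b in zip(breaks[:-1], breaks[1:]):
        # forcing is constant within the segment: freeze it at the midpoint
        # so the stepper never samples the post-switch state at b
        tm = 0.5 * (a + b)
        L = light_at(tm, regime)
        T = temperature_at(tm, regime)
        drive = elf3_drive(tm, regime, p)
        fun = lambda t, s, L=L, T=T, d=drive: rhs_constant_forcing(  # noqa: E731
            s, L, T, d, p, g)
        # every break is a grid point, so t_eval always ends exactly at b
        seg_eval = grid[(grid > a) & (grid <= b)]
        sol = solve_ivp(fun, (a, b), y, method="RK45", rtol=rtol, atol=atol,
                        t_eval=seg_eval)
        if not sol.success:
            raise RuntimeError(
                f"integration failed in segment [{a}, {b}] h: {sol.message}")
        for tt, yy in zip(sol.t, sol.y.T):
            times.append(float(tt))
            states.append(yy.copy())
        y = states[-1].copy()
    ts = np.array(times)
    ys = np.array(states)
    if not np.all(np.isfinite(ys)):
        raise RuntimeError("non-finite state encountered during integration")
    return Trajectory(times=ts, states=ys, regime=regime, genotype=g.name,
                      parameters=p, g_Y=g.g_Y)


def final_hypocotyl(p: ParameterSet, g, regime: EnvironmentRegime,
                    method: str = "adaptive", rtol: float = DEFAULT_RTOL,
                    atol: float = DEFAULT_ATOL) -> float:
    """Hypocotyl length (mm) at the end of the growth phase.

    ``method="adaptive"`` uses the scipy reference integrator;
    ``method="fast"`` the compiled fixed-step path used by the fitter.
    """
    if method == "fast":
        from ._fast import final_hypocotyl_batch

        return float(
            final_hypocotyl_batch(
                p, [g.multipliers()], [regime.photoperiod_h],
                [regime.temperature_C], duration_days=regime.duration_days,
                sync_prelude=regime.sync_prelude)[0]
        )
    traj = integrate(p, g, regime, output_step=regime.end_h - regime.start_h,
                     rtol=rtol, atol=atol)
    return float(traj.H[-1])


def thermal_elongation(p: ParameterSet, g, photoperiod_h: float,
                       temperatures: tuple[float, float] = (28.0, 22.0),
                       duration_days: float = 5.0, sync_prelude: bool = True,
                       method: str = "adaptive") -> float:
    """ΔH (mm): final length at the warm temperature minus at the cool one,
    same genotype and photoperiod."""
    warm, cool = temperatures
    h = [final_hypocotyl(
            p, g,
            EnvironmentRegime(photoperiod_h, T, duration_days, sync_prelude),
            method=method)
         for T in (warm, cool)]
    return h[0] - h[1]


def elf3_periodic_profile(p: ParameterSet, regime: EnvironmentRegime,
                          g_E: float = 1.0,
                          times: np.ndarray | None = None) -> pd.DataFrame:
    """Entrained (periodic) diel ELF3 trajectory, computed exactly.

    With the default ``d_EC = 0`` the ELF3 equation is linear with
    piecewise-constant coefficients over the growth phase, so the entrained
    cycle is the fixed point of the affine one-cycle propagation map; values
    are then piecewise exponentials.  Requires ``d_EC = 0``.

    Returns a frame with columns ``time_h`` (hours after dawn, in [0, 24))
    and ``E``.
    """
    if p.d_EC != 0.0:
        raise NotImplementedError(
            "exact periodic profile requires d_EC = 0; integrate() instead")
    if times is None:
        times = np.arange(0.0, 24.0, 1.0)
    times = np.asarray(times, dtype=float)
    if np.any((times < 0) | (times >= 24.0)):
        raise ValueError("profile times must lie in [0, 24)")
    T = regime.temperature_C
    d = p.d_E * p.q_E(T)
    if d <= 0:
        raise ValueError("ELF3 decay rate must be > 0")
    rho = min(1.0, math.exp(-p.rho_E * (T - 22.0)))
    D = regime.photoperiod_h
    if D <= 0.0 or D >= 24.0:
        E = g_E * p.a_E * rho * free_running_mean_drive(p) / d
        return pd.DataFrame({"time_h": times, "E": np.full_like(times, E)})

    # segment edges of the drive within one cycle
    edges = sorted({0.0, D % 24.0, (D + p.w_E) % 24.0, 24.0} - {24.0}) + [24.0]

    def drive_at(tau: float) -> float:
        inside = (tau - D) % 24.0 < p.w_E
        return rho * (p.b_E + (1.0 - p.b_E) * (1.0 if inside else 0.0))

    # one-cycle affine map E(24) = mult * E(0) + add
    mult, add = 1.0, 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        s = g_E * p.a_E * drive_at(0.5 * (a + b))
        f = math.exp(-d * (b - a))
        mult, add = mult * f, add * f + (s / d) * (1.0 - f)
    E0 = add / (1.0 - mult)

    out = np.empty_like(times)
    order = np.argsort(times)
    e_cur, t_cur = E0, 0.0
    idx = 0
    for a, b in zip(edges[:-1], edges[1:]):
        s = g_E * p.a_E * drive_at(0.5 * (a + b))
        while idx < len(order) and times[order[idx]] < b - 1e-12:
            tt = times[order[idx]]
            if tt >= a - 1e-12:
                f = math.exp(-d * (tt - a))
                out[order[idx]] = (s / d) + (e_cur - s / d) * f
                idx += 1
            else:  # pragma: no cover - times sorted into segments
                idx += 1
        f = math.exp(-d * (b - a))
        e_cur = (s / d) + (e_cur - s / d) * f
    return pd.DataFrame({"time_h": times, "E": out})
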