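"""Core regulatory network: five coupled ODEs for thermomorphogenic growth.

State variables (all activities dimensionless, scaled so wild type = 1-ish;
hypocotyl length in mm; time in hours):

``B``  active phyB (Pfr-like).  Photoactivated in the light, reverted by
       light-driven and thermal (dark-reversion) processes; thermal reversion
       accelerates with temperature following a Q10 law.
``E``  ELF3 / evening-complex activity.  Synthesis follows a clock-controlled
       transcriptional drive with a broad bump of width ``w_E`` starting at
       dusk; warmth damps the transcriptional drive but slows protein
       turnover (Q10_E < 1), so net protein can rise at 28 °C.
``C``  nuclear COP1 activity, relaxing toward a light/temperature-dependent
       target: saturated (``C_dark``) at night regardless of temperature,
       reduced in the day with a warmth-enhanced target capped at the night
       ceiling.
``P``  active PIF level.  Transcription Hill-repressed by ELF3; removal
       enhanced by active phyB and suppressed (stabilization) by COP1.
``H``  hypocotyl length.  Elongation is a Hill function of PIF activity with
       competitive inhibition by phyB, ELF3 and HY5 at growth-gene promoters.

HY5 is not integrated: its level is a quasi-steady function of COP1
(proteolytic degradation), ``Y = g_Y * Y0 / (1 + C / K_C)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, fields

import numpy as np

from .environment import EnvironmentRegime, light_at, temperature_at

__all__ = [
    "ParameterSet",
    "State",
    "elf3_drive",
    "hy5_qss",
    "cop1_target",
    "rhs",
    "steady_state_constant",
]

REFERENCE_TEMPERATURE_C = 22.0
#: Photoperiod used as the clock surrogate for free-running (DD/LL) ELF3 drive.
FREE_RUN_REFERENCE_PHOTOPERIOD_H = 8.0


@dataclass
class ParameterSet:
    """Kinetic constants of the five-equation network.

    All rates are per hour, lengths in mm, activities dimensionless.
    Genotype multipliers are *not* part of this set; they scale individual
    channels at evaluation time (see :mod:`thermogrowth.genotypes`).
    """

    # -- phyB ---------------------------------------------------------------
    k_pB: float  # light-driven activation rate (Pr -> Pfr)
    k_rB: float  # light-driven reversion rate
    k_dB: float  # dark thermal-reversion rate at 22 degC
    Q10_B: float  # fold-change of thermal reversion per 10 degC (>= 1)
    # -- ELF3 ---------------------------------------------------------------
    a_E: float  # synthesis scale
    d_E: float  # first-order protein decay at 22 degC
    b_E: float  # basal (trough) fraction of transcriptional drive, in [0, 1]
    w_E: float  # dusk-bump width, hours
    rho_E: float  # warm damping of the transcriptional drive, per degC
    d_EC: float = 0.0  # optional COP1-dependent ELF3 decay coefficient
    Q10_E: float = 1.0  # fold-change of ELF3 protein decay per 10 degC
    # -- COP1 ---------------------------------------------------------------
    C_dark: float = 1.0  # night target activity (ceiling)
    C_light: float = 0.2  # day target activity at 22 degC (<= C_dark)
    eps_C: float = 0.0  # temperature sensitivity of the day target, per degC
    tau_C: float = 1.0  # relaxation time, hours
    # -- PIF ----------------------------------------------------------------
    a_P: float = 1.0  # maximal production
    K_E: float = 1.0  # ELF3 repression constant
    h_E: float = 2.0  # repression Hill exponent (>= 1)
    d_P: float = 0.5  # basal decay
    beta_B: float = 0.0  # phyB-enhanced removal coefficient
    beta_C: float = 0.0  # COP1 stabilization coefficient
    # -- HY5 ----------------------------------------------------------------
    Y0: float = 1.0  # HY5 level at zero COP1
    K_C: float = 1.0  # COP1 half-repression constant
    # -- growth -------------------------------------------------------------
    v0: float = 0.01  # basal elongation rate, mm/h
    v_max: float = 0.1  # maximal PIF-driven elongation rate, mm/h
    K_G: float = 1.0  # PIF half-activation constant
    n_G: float = 2.0  # growth Hill exponent (>= 1)
    K_Bg: float = 1.0  # competitive-inhibition constant of phyB on growth
    K_Eg: float = 1.0  # competitive-inhibition constant of ELF3 on growth
    K_Yg: float = 1.0  # competitive-inhibition constant of HY5 on growth
    # -- initial condition --------------------------------------------------
    H0: float = 0.5  # hypocotyl length at start of prelude, mm

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.Q10_B < 1:
            raise ValueError(f"Q10_B must be >= 1, got {self.Q10_B}")
        if self.b_E > 1:
            raise ValueError(f"b_E must be <= 1, got {self.b_E}")
        if self.h_E < 1:
            raise ValueError(f"h_E must be >= 1, got {self.h_E}")
        if self.n_G < 1:
            raise ValueError(f"n_G must be >= 1, got {self.n_G}")
        if self.C_light > self.C_dark:
            raise ValueError(
                f"C_light ({self.C_light}) must not exceed C_dark ({self.C_dark})"
            )

    # lossless flat-JSON round trip
    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ParameterSet":
        return cls.from_dict(json.loads(text))

    def replace(self, **changes: float) -> "ParameterSet":
        d = self.to_dict()
        d.update(changes)
        return ParameterSet(**d)

    def q_B(self, T: float) -> float:
        """Thermal-reversion acceleration factor Q10_B**((T-22)/10)."""
        return self.Q10_B ** ((T - REFERENCE_TEMPERATURE_C) / 10.0)

    def q_E(self, T: float) -> float:
        """ELF3 protein-decay factor Q10_E**((T-22)/10)."""
        return self.Q10_E ** ((T - REFERENCE_TEMPERATURE_C) / 10.0)


@dataclass
class State:
    """Instantaneous system state (HY5 is derived, not integrated)."""

    B: float
    E: float
    C: float
    P: float
    H: float

    def to_array(self) -> np.ndarray:
        return np.array([self.B, self.E, self.C, self.P, self.H], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "State":
        return cls(*map(float, a))


def _drive_rho(T: float, p: ParameterSet) -> float:
    # clamp to (0, 1]: cooling below 22 degC cannot push the drive above peak
    return min(1.0, math.exp(-p.rho_E * (T - REFERENCE_TEMPERATURE_C)))


def free_running_mean_drive(p: ParameterSet) -> float:
    """24-h mean of the bump profile under the reference 8-h photoperiod,
    used as the clock surrogate in constant conditions (DD/LL)."""
    return p.b_E + (1.0 - p.b_E) * min(p.w_E, 24.0) / 24.0


def elf3_drive(t: float, regime: EnvironmentRegime, p: ParameterSet) -> float:
    """ELF3 transcriptional drive at time ``t``.

    ``rho(T) * [b_E + (1 - b_E) * Pi(t)]`` where ``Pi`` is 1 inside the
    window of width ``w_E`` opening at dusk (wrapped mod 24) and 0 outside.
    In constant-light or constant-dark growth phases the clock free-runs and
    the bump is replaced by its 24-h mean under a reference 8-h photoperiod.
    """
    T = temperature_at(t, regime)
    rho = _drive_rho(T, p)
    if t < 0.0:
        tau = t + 24.0
        dusk = 4.0  # prelude: 4-h pulse, dusk at -20 h
    else:
        D = regime.photoperiod_h
        if D <= 0.0 or D >= 24.0:
            return rho * free_running_mean_drive(p)
        tau = t % 24.0
        dusk = D
    in_window = (tau - dusk) % 24.0 < p.w_E
    return rho * (p.b_E + (1.0 - p.b_E) * (1.0 if in_window else 0.0))


def hy5_qss(C: float, p: ParameterSet, g_Y: float = 1.0) -> float:
    """Quasi-steady HY5 level under COP1-mediated degradation."""
    if C < 0 or g_Y < 0:
        raise ValueError("C and g_Y must be >= 0")
    if p.K_C == 0:
        raise ValueError("K_C = 0 is degenerate: HY5 would be undefined at C > 0")
    return g_Y * p.Y0 / (1.0 + C / p.K_C)


def cop1_target(L: int, T: float, p: ParameterSet) -> float:
    """COP1 relaxation target ``C_inf(L, T)`` before genotype scaling.

    Night target is the saturated ``C_dark`` (temperature-blind); the day
    target rises with warmth but is capped at the night ceiling.
    """
    if L == 0:
        return p.C_dark
    return min(p.C_dark, p.C_light * math.exp(p.eps_C * (T - REFERENCE_TEMPERATURE_C)))


def growth_rate(B: float, E: float, C: float, P: float, p: ParameterSet,
                g_Y: float = 1.0) -> float:
    """Elongation rate dH/dt (mm/h) at the given regulator levels."""
    Y = hy5_qss(C, p, g_Y)
    A = (P / p.K_G) / (1.0 + B / p.K_Bg + E / p.K_Eg + Y / p.K_Yg)
    An = A ** p.n_G
    return p.v0 + p.v_max * An / (1.0 + An)


def rhs_constant_forcing(s: np.ndarray, L: int, T: float, drive: float,
                         p: ParameterSet, g) -> np.ndarray:
    """RHS evaluated at explicit forcing values (L, T, ELF3 drive)."""
    B, E, C, P, _H = s
    q = p.q_B(T)
    dB = L * p.k_pB * (g.g_B - B) - (L * p.k_rB + p.k_dB * q) * B
    dE = g.g_E * p.a_E * drive - (p.d_E * p.q_E(T) + p.d_EC * C) * E
    dC = (cop1_target(L, T, p) * g.g_C - C) / p.tau_C
    dP = (g.g_P * p.a_P / (1.0 + (E / p.K_E) ** p.h_E)
          - p.d_P * (1.0 + p.beta_B * B) / (1.0 + p.beta_C * C) * P)
    dH = growth_rate(B, E, C, P, p, g.g_Y)
    return np.array([dB, dE, dC, dP, dH])


def rhs(t: float, s: np.ndarray, p: ParameterSet, g, regime: EnvironmentRegime
        ) -> np.ndarray:
    """Right-hand side of the five-equation system.

    ``s`` is ``[B, E, C, P, H]``; ``g`` carries genotype multipliers
    ``g_B, g_E, g_C, g_P, g_Y`` (wild type: all 1).
    """
    if not np.all(np.isfinite(s)):
        raise FloatingPointError(f"non-finite state at t={t}: {s}")
    L = light_at(t, regime)
    T = temperature_at(t, regime)
    drive = elf3_drive(t, regime, p)
    return rhs_constant_forcing(s, L, T, drive, p, g)


def steady_state_constant(p: ParameterSet, g, L: int, T: float, drive: float
                          ) -> State:
    """Fixed point of B, E, C, P under constant forcing (H excluded).

    Closed forms; used as the integration oracle and to build dark-adapted
    initial conditions.  Raises on zero decay rates.
    """
    q = p.q_B(T)
    denom_B = L * (p.k_pB + p.k_rB) + p.k_dB * q
    if denom_B <= 0 or p.tau_C <= 0 or p.d_P <= 0:
        raise ValueError("all decay rates must be > 0 for a steady state")
    B = L * p.k_pB * g.g_B / denom_B
    C = cop1_target(L, T, p) * g.g_C
    denom_E = p.d_E * p.q_E(T) + p.d_EC * C
    if denom_E <= 0:
        raise ValueError("ELF3 decay rate must be > 0 for a steady state")
    E = g.g_E * p.a_E * drive / denom_E
    P = (g.g_P * p.a_P / (1.0 + (E / p.K_E) ** p.h_E)) / (
        p.d_P * (1.0 + p.beta_B * B) / (1.0 + p.beta_C * C))
    return State(B=B, E=E, C=C, P=P, H=p.H0)
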