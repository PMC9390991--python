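"""Compiled fixed-step integrator used by the fitter.

The annealing cost needs thousands of evaluations of the full multi-genotype
growth surface, so this module provides a numba-compiled RK4 integrator that
is segment-aligned to every forcing discontinuity (the same breakpoints the
reference integrator restarts at) and steps each smooth segment with a fixed
substep, shrunk automatically when a proposed parameter set implies fast
kinetics.  Agreement with :func:`thermogrowth.simulate.integrate` is pinned
by tests; the adaptive scipy path remains the reference.
"""

from __future__ import annotations

import numpy as np

from .model import ParameterSet

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

#: packing order of ParameterSet fields into the theta vector
PACK_ORDER = (
    "k_pB", "k_rB", "k_dB", "Q10_B",
    "a_E", "d_E", "b_E", "w_E", "rho_E", "d_EC", "Q10_E",
    "C_dark", "C_light", "eps_C", "tau_C",
    "a_P", "K_E", "h_E", "d_P", "beta_B", "beta_C",
    "Y0", "K_C",
    "v0", "v_max", "K_G", "n_G", "K_Bg", "K_Eg", "K_Yg",
    "H0",
)

DEFAULT_SUBSTEP_H = 0.05


def pack_parameters(p: ParameterSet) -> np.ndarray:
    d = p.to_dict()
    return np.array([d[name] for name in PACK_ORDER], dtype=np.float64)


def unpack_parameters(theta: np.ndarray) -> ParameterSet:
    return ParameterSet(**{name: float(v) for name, v in zip(PACK_ORDER, theta)})


@njit(cache=False, inline="always")
def _hill_pow(x, n):
    # Hill exponents are often small integers; avoid the generic pow
    if n == 1.0:
        return x
    if n == 2.0:
        return x * x
    if n == 3.0:
        return x * x * x
    if n == 4.0:
        x2 = x * x
        return x2 * x2
    if n == 5.0:
        x2 = x * x
        return x2 * x2 * x
    if n == 6.0:
        x3 = x * x * x
        return x3 * x3
    # generic branch: exp/log avoids the slow libm pow on denormal arguments
    # and maps the (tiny) negative excursions of RK4 stage states to 0
    if x < 1e-12:
        return 0.0
    return np.exp(n * np.log(x))


@njit(cache=False, inline="always")
def _deriv(B, E, C, P,
           sB, rB, sE, rE0, d_EC, cT, inv_tau,
           sP, inv_K_E, h_E, d_P, beta_B, beta_C,
           gYY0, inv_K_C, v0, v_max, inv_K_G, n_G,
           inv_K_Bg, inv_K_Eg, inv_K_Yg):
    dB = sB - rB * B
    dE = sE - (rE0 + d_EC * C) * E
    dC = (cT - C) * inv_tau
    dP = sP / (1.0 + _hill_pow(E * inv_K_E, h_E)) \
        - d_P * (1.0 + beta_B * B) / (1.0 + beta_C * C) * P
    Y = gYY0 / (1.0 + C * inv_K_C)
    A = (P * inv_K_G) / (1.0 + B * inv_K_Bg + E * inv_K_Eg + Y * inv_K_Yg)
    An = _hill_pow(A, n_G)
    dH = v0 + v_max * An / (1.0 + An)
    return dB, dE, dC, dP, dH


@njit(cache=False)
def _simulate_batch(theta, gmat, photo, temp, duration_h, sync, h0):
    ncell = gmat.shape[0]
    out = np.empty((ncell, 5))
    k_pB = theta[0]; k_rB = theta[1]; k_dB = theta[2]; Q10_B = theta[3]
    a_E = theta[4]; d_E = theta[5]; b_E = theta[6]; w_E = theta[7]
    rho_E = theta[8]; d_EC = theta[9]; Q10_E = theta[10]
    C_dark = theta[11]; C_light = theta[12]; eps_C = theta[13]; tau_C = theta[14]
    a_P = theta[15]; K_E = theta[16]; h_E = theta[17]; d_P = theta[18]
    beta_B = theta[19]; beta_C = theta[20]
    Y0 = theta[21]; K_C = theta[22]
    v0 = theta[23]; v_max = theta[24]; K_G = theta[25]; n_G = theta[26]
    K_Bg = theta[27]; K_Eg = theta[28]; K_Yg = theta[29]
    H0 = theta[30]
    inv_tau = 1.0 / tau_C
    inv_K_E = 1.0 / K_E
    inv_K_C = 1.0 / K_C
    inv_K_G = 1.0 / K_G
    inv_K_Bg = 1.0 / K_Bg
    inv_K_Eg = 1.0 / K_Eg
    inv_K_Yg = 1.0 / K_Yg
    w_eff = w_E if w_E < 24.0 else 24.0
    mean_drive = b_E + (1.0 - b_E) * w_eff / 24.0
    for i in range(ncell):
        gB, gE, gC, gP, gY = gmat[i, 0], gmat[i, 1], gmat[i, 2], gmat[i, 3], gmat[i, 4]
        D = photo[i]
        Tg = temp[i]

        # dark-adapted initial state at 22 degC with the free-running drive
        B = 0.0
        E = gE * a_E * mean_drive / d_E
        C = C_dark * gC
        P = (gP * a_P / (1.0 + (E / K_E) ** h_E)) / (d_P / (1.0 + beta_C * C))
        H = H0

        # breakpoints: forcing and drive discontinuities
        ncyc = int(np.ceil(duration_h / 24.0))
        ev = np.empty(3 * ncyc + 8)
        ne = 0
        t_start = 0.0
        if sync:
            t_start = -24.0
            ev[ne] = -20.0
            ne += 1
            if -20.0 + w_E < 0.0:
                ev[ne] = -20.0 + w_E
                ne += 1
        ev[ne] = 0.0
        ne += 1
        if 0.0 < D < 24.0:
            e_bump = D + w_E
            while e_bump >= 24.0:
                e_bump -= 24.0
            for k in range(ncyc):
                base = 24.0 * k
                if base > 0.0 and base < duration_h:
                    ev[ne] = base
                    ne += 1
                if base + D < duration_h:
                    ev[ne] = base + D
                    ne += 1
                if 0.0 < base + e_bump < duration_h:
                    ev[ne] = base + e_bump
                    ne += 1
        ev[ne] = duration_h
        ne += 1
        events = np.sort(ev[:ne])

        a = t_start
        ok = True
        for j in range(ne):
            b = events[j]
            if b <= a + 1e-12 or b < t_start:
                continue
            tm = 0.5 * (a + b)
            # forcing at the segment midpoint (constant over the segment)
            if tm < 0.0:
                L = 1.0 if tm < -20.0 else 0.0
                T = 22.0
                tau = tm + 24.0
                dusk = 4.0
                inside = (tau - dusk) % 24.0 < w_E
                drv = b_E + (1.0 - b_E) * (1.0 if inside else 0.0)
            else:
                T = Tg
                rho = np.exp(-rho_E * (T - 22.0))
                if rho > 1.0:
                    rho = 1.0
                if D <= 0.0:
                    L = 0.0
                    drv = rho * mean_drive
                elif D >= 24.0:
                    L = 1.0
                    drv = rho * mean_drive
                else:
                    tau = tm % 24.0
                    L = 1.0 if tau < D else 0.0
                    inside = (tau - D) % 24.0 < w_E
                    drv = rho * (b_E + (1.0 - b_E) * (1.0 if inside else 0.0))

            # per-segment composite rates (forcing constant within segment)
            q = Q10_B ** ((T - 22.0) / 10.0)
            qE = Q10_E ** ((T - 22.0) / 10.0)
            sB = L * k_pB * gB
            rB = L * (k_pB + k_rB) + k_dB * q
            sE = gE * a_E * drv
            rE0 = d_E * qE
            if L > 0.0:
                c_inf = C_light * np.exp(eps_C * (T - 22.0))
                if c_inf > C_dark:
                    c_inf = C_dark
            else:
                c_inf = C_dark
            cT = c_inf * gC
            sP = gP * a_P
            gYY0 = gY * Y0

            # substep shrunk when kinetics are fast (explicit RK4 stability)
            lam = rB
            lam2 = rE0 + d_EC * C_dark * gC
            if lam2 > lam:
                lam = lam2
            if inv_tau > lam:
                lam = inv_tau
            lam2 = d_P * (1.0 + beta_B * gB)
            if lam2 > lam:
                lam = lam2
            h = h0
            if lam > 0.0 and 2.0 / lam < h:
                h = 2.0 / lam
            nsub = int(np.ceil((b - a) / h))
            h = (b - a) / nsub
            for _ in range(nsub):
                k1 = _deriv(B, E, C, P,
                            sB, rB, sE, rE0, d_EC, cT, inv_tau,
                            sP, inv_K_E, h_E, d_P, beta_B, beta_C,
                            gYY0, inv_K_C, v0, v_max, inv_K_G, n_G,
                            inv_K_Bg, inv_K_Eg, inv_K_Yg)
                k2 = _deriv(B + 0.5 * h * k1[0], E + 0.5 * h * k1[1],
                            C + 0.5 * h * k1[2], P + 0.5 * h * k1[3],
                            sB, rB, sE, rE0, d_EC, cT, inv_tau,
                            sP, inv_K_E, h_E, d_P, beta_B, beta_C,
                            gYY0, inv_K_C, v0, v_max, inv_K_G, n_G,
                            inv_K_Bg, inv_K_Eg, inv_K_Yg)
                k3 = _deriv(B + 0.5 * h * k2[0], E + 0.5 * h * k2[1],
                            C + 0.5 * h * k2[2], P + 0.5 * h * k2[3],
                            sB, rB, sE, rE0, d_EC, cT, inv_tau,
                            sP, inv_K_E, h_E, d_P, beta_B, beta_C,
                            gYY0, inv_K_C, v0, v_max, inv_K_G, n_G,
                            inv_K_Bg, inv_K_Eg, inv_K_Yg)
                k4 = _deriv(B + h * k3[0], E + h * k3[1],
                            C + h * k3[2], P + h * k3[3],
                            sB, rB, sE, rE0, d_EC, cT, inv_tau,
                            sP, inv_K_E, h_E, d_P, beta_B, beta_C,
                            gYY0, inv_K_C, v0, v_max, inv_K_G, n_G,
                            inv_K_Bg, inv_K_Eg, inv_K_Yg)
                B += h / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                E += h / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                C += h / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
                P += h / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
                H += h / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
            if not (np.isfinite(B) and np.isfinite(E) and np.isfinite(C)
                    and np.isfinite(P) and np.isfinite(H)):
                ok = False
                break
            a = b
        if ok:
            out[i, 0] = B
            out[i, 1] = E
            out[i, 2] = C
            out[i, 3] = P
            out[i, 4] = H
        else:
            for m in range(5):
                out[i, m] = np.nan
    return out


def final_state_batch(p: ParameterSet, multipliers, photoperiods, temperatures,
                      duration_days: float = 5.0, sync_prelude: bool = True,
                      substep_h: float = DEFAULT_SUBSTEP_H) -> np.ndarray:
    """Final [B, E, C, P, H] for a batch of (genotype, photoperiod, T) cells.

    ``multipliers`` is a sequence of dicts with keys g_B..g_Y (or 5-tuples).
    Cells whose dynamics blow up (pathological proposals) return NaN rows.
    """
    theta = pack_parameters(p)
    rows = []
    for m in multipliers:
        if isinstance(m, dict):
            rows.append([m["g_B"], m["g_E"], m["g_C"], m["g_P"], m["g_Y"]])
        else:
            rows.append(list(m))
    gmat = np.array(rows, dtype=np.float64)
    photo = np.asarray(photoperiods, dtype=np.float64)
    temp = np.asarray(temperatures, dtype=np.float64)
    if not (gmat.shape[0] == photo.size == temp.size):
        raise ValueError("multipliers, photoperiods and temperatures must align")
    return _simulate_batch(theta, gmat, photo, temp, 24.0 * duration_days,
                           sync_prelude, substep_h)


def final_hypocotyl_batch(p: ParameterSet, multipliers, photoperiods,
                          temperatures, duration_days: float = 5.0,
                          sync_prelude: bool = True,
                          substep_h: float = DEFAULT_SUBSTEP_H) -> np.ndarray:
    """Final hypocotyl lengths (mm) for a batch of cells."""
    return final_state_batch(p, multipliers, photoperiods, temperatures,
                             duration_days, sync_prelude, substep_h)[:, 4]
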