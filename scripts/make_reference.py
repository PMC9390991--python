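"""Construct the packaged reference parameter set.

The reference set stands in for a fitted wild-type parameterization: it is
obtained, once, by annealing a hand-derived seed against hinge losses on the
qualitative-checklist margins (plus soft anchors pinning the overall growth
scale to realistic seedling dimensions), with a fixed seed so the procedure
is reproducible.  The result is frozen into
``src/thermogrowth/data/reference_parameters.json`` and shipped with the
package; it is *constructed*, synthetic, and versioned — not a measurement.

Run from the repository root:

    python scripts/make_reference.py
"""

from __future__ import annotations

import json
import math
import pathlib

import numpy as np

from thermogrowth.fit import (DEFAULT_BOUNDS, FitConfig, anneal_vector,
                              registry_with_gains)
from thermogrowth.model import ParameterSet
from thermogrowth.predict import qualitative_checklist

SEED = 20220613
OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "thermogrowth" \
    / "data" / "reference_parameters.json"

# hand-derived seed point, pre-polished by an earlier run of this script
# (see docs/methods.md for the reasoning per channel); Hill exponents are
# held at integer values by design
SEED_PARAMS = ParameterSet(
    k_pB=4.9, k_rB=3.3, k_dB=0.35, Q10_B=4.0,
    a_E=0.26, d_E=0.53, b_E=0.10, w_E=1.5, rho_E=0.006, d_EC=0.0, Q10_E=0.45,
    C_dark=1.0, C_light=0.013, eps_C=0.75, tau_C=0.16,
    a_P=1.8, K_E=0.42, h_E=2.0, d_P=0.61, beta_B=11.2, beta_C=40.0,
    Y0=3.3, K_C=0.38,
    v0=0.005, v_max=0.057, K_G=1.65, n_G=6.0, K_Bg=0.037, K_Eg=5.8, K_Yg=0.14,
    H0=0.5)

SEED_GAINS = {
    "PHYBox:g_B": 1.5,
    "ELF3ox:g_E": 2.2,
    "cop1-4:g_C": 0.09,
    "COP1-OE:g_C": 1.5,
    "PIF4ox:g_P": 8.3,
}
# not exercised by the checklist; kept at their hand values
FIXED_GAINS = {"pif4:g_P": 0.6, "pifq:g_P": 0.15}

FREE_PARAMETERS = (
    "k_pB", "k_rB", "k_dB", "Q10_B",
    "a_E", "d_E", "b_E", "w_E", "rho_E", "Q10_E",
    "C_light", "eps_C", "tau_C",
    "a_P", "K_E", "d_P", "beta_B", "beta_C",
    "Y0", "K_C", "v0", "v_max", "K_G", "K_Bg", "K_Eg", "K_Yg",
)
GAIN_BOUNDS = {
    "PHYBox:g_B": (1.5, 10.0),
    "ELF3ox:g_E": (1.2, 10.0),
    "cop1-4:g_C": (0.01, 0.5),
    "COP1-OE:g_C": (1.5, 10.0),
    "PIF4ox:g_P": (1.5, 20.0),
}

# design anchors (mm): realistic 5-day seedling scales
ANCHOR_WT_DH8 = 2.5
ANCHOR_WT_DARK = 11.0
ANCHOR_WT_CWL = 1.5


def softplus(z: float) -> float:
    return math.log1p(math.exp(-abs(z))) + max(z, 0.0)


def margin_cost(p: ParameterSet, gains: dict[str, float]) -> float:
    reg = registry_with_gains({**gains, **FIXED_GAINS})
    try:
        rep = qualitative_checklist(p, registry=reg, with_dynamics=False)
    except (ValueError, RuntimeError, ZeroDivisionError):
        return math.inf
    tol = rep.tolerance_mm
    if not math.isfinite(tol) or tol <= 0:
        return math.inf
    cost = 0.0
    for item in rep.items:
        s = 0.5 * tol  # target: margin at least half a tolerance band
        cost += softplus((s - item.margin) / s)

    # cheap closed-form proxies for the regulator-dynamics battery
    # daytime ELF3 protein must rise with warmth: synthesis damping must be
    # outweighed by slowed turnover (quasi-steady ratio > 1)
    e_ratio = math.exp(-6.0 * p.rho_E) / (p.Q10_E ** 0.6) - 1.0
    cost += softplus((0.10 - e_ratio) / 0.10)
    # nocturnal COP1 temperature-blindness: the warm/cool gap carried into
    # the night by the finite relaxation time must stay under 5 % of C_dark
    c22 = min(p.C_dark, p.C_light)
    c28 = min(p.C_dark, p.C_light * math.exp(6.0 * p.eps_C))
    c_carry = 0.05 * p.C_dark - (c28 - c22) * p.tau_C / 16.0
    cost += softplus((0.01 - c_carry) / 0.01)
    # the day target must actually be warmth-sensitive below the ceiling
    cost += softplus((0.05 * p.C_dark - (c28 - c22)) / (0.05 * p.C_dark))

    # soft scale anchors
    wt = rep["wt_daylength_monotone"]  # noqa: F841  (tol already uses dH8)
    dh8 = tol / 0.1
    from thermogrowth.predict import _response_single

    wt_resp = _response_single(p, reg["WT"], (0.0, 24.0))
    h_dark = float(wt_resp["H22_mm"].iloc[0])
    h_cwl = float(wt_resp["H22_mm"].iloc[1])
    cost += 0.5 * ((dh8 - ANCHOR_WT_DH8) / ANCHOR_WT_DH8) ** 2
    cost += 0.3 * ((h_dark - ANCHOR_WT_DARK) / ANCHOR_WT_DARK) ** 2
    cost += 0.3 * ((h_cwl - ANCHOR_WT_CWL) / ANCHOR_WT_CWL) ** 2
    return cost


def main() -> None:
    names = list(FREE_PARAMETERS) + list(SEED_GAINS)
    cfg = FitConfig(free_parameters=FREE_PARAMETERS,
                    free_multipliers=tuple(SEED_GAINS),
                    bounds=GAIN_BOUNDS,
                    initial_accept=0.4, cooling=0.90, proposals_per_T=150,
                    min_accept_frac=0.005, max_proposals=4500,
                    step_log10=0.05, seed=SEED)
    lo = np.log10([cfg.bound_for(n)[0] for n in names])
    hi = np.log10([cfg.bound_for(n)[1] for n in names])
    seed_dict = SEED_PARAMS.to_dict()
    x0 = np.log10([seed_dict[n] if ":" not in n else SEED_GAINS[n]
                   for n in names])
    x0 = np.clip(x0, lo, hi)

    def cost_fn(xlog: np.ndarray) -> float:
        vals = 10.0 ** xlog
        changes = {n: float(v) for n, v in zip(names, vals) if ":" not in n}
        gains = {n: float(v) for n, v in zip(names, vals) if ":" in n}
        try:
            p = SEED_PARAMS.replace(**changes)
        except ValueError:
            return math.inf
        return margin_cost(p, gains)

    rng = np.random.default_rng(SEED)
    print(f"seed cost: {cost_fn(x0):.4f}")
    best_x, best_cost, trace, warns = anneal_vector(cost_fn, x0, lo, hi, cfg, rng)
    print(f"best cost: {best_cost:.4f} after {len(trace)} proposals; "
          f"warnings: {warns}")

    vals = 10.0 ** best_x
    changes = {n: float(v) for n, v in zip(names, vals) if ":" not in n}
    gains = {n: float(v) for n, v in zip(names, vals) if ":" in n}
    p = SEED_PARAMS.replace(**changes)
    reg = registry_with_gains({**gains, **FIXED_GAINS})
    rep = qualitative_checklist(p, registry=reg, with_dynamics=True)
    print(rep.to_frame().to_string())
    if not rep.all_pass:
        raise SystemExit("checklist not fully satisfied; adjust seed/schedule")

    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps({
        "description": "synthetic reference parameter set constructed by "
                       "scripts/make_reference.py (checklist-margin anneal, "
                       f"seed {SEED})",
        "parameters": p.to_dict(),
        "genotype_gains": {**gains, **FIXED_GAINS},
    }, indent=1))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
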