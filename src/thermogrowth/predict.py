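"""Prediction products: day-length response curves, held-out genotype
predictions, activity x day-length thermoelongation heatmaps, and the
qualitative-pattern checklist.

Thermal elongation ΔH is always the difference in final hypocotyl length
between growth at 28 °C and at 22 °C for the same genotype and photoperiod.
The checklist encodes the qualitative growth and regulator patterns the
model is expected to reproduce (wild-type day-length dependence and its
inversion in phyB-deficient lines, the epistasis of reduced COP1 activity,
dark-growth saturation, and the diel regulator dynamics); "≈ 0" is judged
against a band equal to 10 % of the wild-type 8-h ΔH by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fast import final_hypocotyl_batch
from .environment import EnvironmentRegime
from .genotypes import Genotype, builtin_registry, resolve
from .model import ParameterSet
from .simulate import integrate

__all__ = [
    "HeatmapGrid",
    "daylength_response",
    "predict_holdout",
    "heatmap",
    "qualitative_checklist",
    "ChecklistReport",
    "HOLDOUT_GENOTYPES",
]

HOLDOUT_GENOTYPES = ("elf3-8 phyB-9", "phyB-9 cop1-4",
                     "phyB-9 COP1-OE", "PHYBox COP1-OE")
REGULATOR_CHANNELS = {"phyB": "g_B", "ELF3": "g_E", "COP1": "g_C"}


def _lengths_batch(p: ParameterSet, genotypes: list[Genotype],
                   photoperiods, temperatures,
                   duration_days: float = 5.0) -> np.ndarray:
    mult = [g.multipliers() for g in genotypes]
    return final_hypocotyl_batch(p, mult, photoperiods, temperatures,
                                 duration_days=duration_days)


def _response_single(p: ParameterSet, g: Genotype, photoperiods,
                     duration_days: float = 5.0) -> pd.DataFrame:
    D = np.asarray(photoperiods, dtype=float)
    n = D.size
    lens = _lengths_batch(p, [g] * (2 * n), np.concatenate([D, D]),
                          np.concatenate([np.full(n, 22.0), np.full(n, 28.0)]),
                          duration_days)
    h22, h28 = lens[:n], lens[n:]
    return pd.DataFrame({"genotype": g.name, "photoperiod_h": D,
                         "H22_mm": h22, "H28_mm": h28, "dH_mm": h28 - h22})


def daylength_response(p, g: Genotype | str, photoperiods=(0, 4, 8, 12, 16, 24),
                       duration_days: float = 5.0,
                       registry: dict[str, Genotype] | None = None
                       ) -> pd.DataFrame:
    """Per photoperiod: lengths at 22 and 28 °C and their difference ΔH.

    ``p`` may be a single ParameterSet or a sequence of them (an ensemble);
    for an ensemble the table carries the member median and the central 80 %
    band of each quantity.
    """
    if isinstance(g, str):
        g = resolve(g, registry)
    if isinstance(p, ParameterSet):
        return _response_single(p, g, photoperiods, duration_days)
    frames = [_response_single(pi, g, photoperiods, duration_days) for pi in p]
    stack = pd.concat(frames)
    out = frames[0][["genotype", "photoperiod_h"]].copy()
    for col in ("H22_mm", "H28_mm", "dH_mm"):
        grp = stack.groupby("photoperiod_h")[col]
        out[col] = grp.median().to_numpy()
        out[f"{col}_lo"] = grp.quantile(0.1).to_numpy()
        out[f"{col}_hi"] = grp.quantile(0.9).to_numpy()
    return out


def predict_holdout(p, genotypes=HOLDOUT_GENOTYPES,
                    photoperiods=(0, 4, 8, 12, 16, 24),
                    registry: dict[str, Genotype] | None = None
                    ) -> pd.DataFrame:
    """ΔH and per-temperature lengths for the validation genotypes that are
    excluded from training."""
    reg = builtin_registry() if registry is None else registry
    tables = [daylength_response(p, name, photoperiods, registry=reg)
              for name in genotypes]
    return pd.concat(tables, ignore_index=True)


@dataclass
class HeatmapGrid:
    """ΔH over a (regulator activity scale) x (day length) grid.

    ``dH_mm[i, j]`` is the thermal elongation with the regulator's
    multiplier set to ``scales[i]`` times the background's own multiplier,
    at day length ``daylengths[j]``.  A scale of 1.0 reproduces the
    background itself.
    """

    background: str
    regulator: str
    scales: np.ndarray
    daylengths: np.ndarray
    dH_mm: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.scales):
            for j, d in enumerate(self.daylengths):
                rows.append((self.background, self.regulator, s, d,
                             self.dH_mm[i, j]))
        return pd.DataFrame(rows, columns=["background", "regulator",
                                           "activity_scale", "photoperiod_h",
                                           "dH_mm"])


def default_heatmap_scales(n: int = 13) -> np.ndarray:
    """Log-uniform activity scales on [0.05, 4] with 1.0 included exactly."""
    s = np.geomspace(0.05, 4.0, n)
    s[np.argmin(np.abs(s - 1.0))] = 1.0
    return np.unique(s)


def heatmap(p: ParameterSet, background: Genotype | str, regulator: str,
            scales=None, daylengths=None,
            registry: dict[str, Genotype] | None = None) -> HeatmapGrid:
    """Thermoelongation heatmap for one regulator in one background."""
    if regulator not in REGULATOR_CHANNELS:
        raise ValueError(
            f"regulator must be one of {sorted(REGULATOR_CHANNELS)}, "
            f"got {regulator!r}")
    if isinstance(background, str):
        background = resolve(background, registry)
    scales = default_heatmap_scales() if scales is None else np.asarray(
        scales, dtype=float)
    if np.any(scales < 0):
        raise ValueError("scales must be >= 0")
    daylengths = (np.arange(0.0, 25.0, 2.0) if daylengths is None
                  else np.asarray(daylengths, dtype=float))
    channel = REGULATOR_CHANNELS[regulator]
    grid = np.empty((scales.size, daylengths.size))
    for i, s in enumerate(scales):
        g = background.with_multipliers(
            **{channel: s * getattr(background, channel)})
        resp = _response_single(p, g, daylengths)
        grid[i] = resp["dH_mm"].to_numpy()
    return HeatmapGrid(background=background.name, regulator=regulator,
                       scales=scales, daylengths=daylengths, dH_mm=grid)


# ---------------------------------------------------------------------------
# qualitative checklist


@dataclass
class ChecklistItem:
    name: str
    passed: bool
    margin: float  # > 0 means inside the pass region, in the check's units
    detail: str = ""


@dataclass
class ChecklistReport:
    items: list[ChecklistItem] = field(default_factory=list)
    tolerance_mm: float = float("nan")

    @property
    def all_pass(self) -> bool:
        return all(i.passed for i in self.items)

    def __getitem__(self, name: str) -> ChecklistItem:
        for i in self.items:
            if i.name == name:
                return i
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"item": i.name, "passed": i.passed,
                              "margin": i.margin, "detail": i.detail}
                             for i in self.items])


def _mean_between(traj, lo: float, hi: float, comp: str) -> float:
    m = (traj.times >= lo) & (traj.times < hi)
    return float(getattr(traj, comp)[m].mean())


def qualitative_checklist(p: ParameterSet,
                          registry: dict[str, Genotype] | None = None,
                          tol_frac: float = 0.1,
                          with_dynamics: bool = True) -> ChecklistReport:
    """Evaluate the qualitative growth/regulator pattern battery.

    Every "≈" comparison uses a band of ``tol_frac`` times the wild-type
    8-h ΔH (both for ΔH values and for length comparisons).  Returns
    per-item booleans with margins (positive = passed, in mm except for the
    regulator-dynamics item where units are activity units).
    """
    reg = builtin_registry() if registry is None else registry
    report = ChecklistReport()
    add = report.items.append

    D_grid = (0.0, 4.0, 8.0, 12.0, 16.0, 24.0)
    resp = {name: _response_single(p, reg[name], D_grid)
            for name in ("WT", "phyB-9", "PHYBox", "elf3-8", "ELF3ox",
                         "cop1-4", "COP1-OE", "PIF4ox", "phyB-9 cop1-4",
                         "elf3-8 cop1-4")}

    def dh(name: str, D: float) -> float:
        r = resp[name]
        return float(r.loc[r["photoperiod_h"] == D, "dH_mm"].iloc[0])

    def h22(name: str, D: float) -> float:
        r = resp[name]
        return float(r.loc[r["photoperiod_h"] == D, "H22_mm"].iloc[0])

    tol = tol_frac * dh("WT", 8.0)
    report.tolerance_mm = tol

    # 1. WT: thermal response inversely related to day length; none in CWL
    m = min(dh("WT", 8) - dh("WT", 12), dh("WT", 12) - dh("WT", 16),
            tol - abs(dh("WT", 24)))
    add(ChecklistItem("wt_daylength_monotone", m > 0, m,
                      f"dH(8,12,16,24)={[round(dh('WT', d), 3) for d in (8, 12, 16, 24)]}"))

    # 2. WT: substantially reduced thermal response in continuous darkness
    m = dh("WT", 8) - dh("WT", 0) - tol
    add(ChecklistItem("wt_dark_reduced", m > 0, m,
                      f"dH(0)={dh('WT', 0):.3f} vs dH(8)={dh('WT', 8):.3f}"))

    # 3. phyB-9 and PIF4ox: thermal response grows with day length
    for name in ("phyB-9", "PIF4ox"):
        diffs = [dh(name, b) - dh(name, a)
                 for a, b in zip((8, 12, 16), (12, 16, 24))]
        m = min(diffs)
        add(ChecklistItem(f"{name.replace('-', '').lower()}_increasing",
                          m > 0, m, f"dH diffs along (8,12,16,24): {np.round(diffs, 3)}"))

    # 4. reduced COP1 activity abolishes thermal elongation at any day length
    for name in ("cop1-4", "phyB-9 cop1-4", "elf3-8 cop1-4"):
        m = min(tol - abs(dh(name, d)) for d in (0, 8, 12, 16, 24))
        add(ChecklistItem(f"{name.replace(' ', '_').replace('-', '')}_flat",
                          m > 0, m,
                          f"max |dH| = {max(abs(dh(name, d)) for d in (0, 8, 12, 16, 24)):.3f}"))

    # 5. COP1-OE: dark growth identical to WT and temperature-blind, but a
    # large CWL response, monotone in COP1 dosage
    g_oe = reg["COP1-OE"]
    dosage = []
    for scale in (0.6, 1.0, 1.6):
        g = g_oe.with_multipliers(g_C=scale * g_oe.g_C)
        r = _response_single(p, g, (24.0,))
        dosage.append(float(r["dH_mm"].iloc[0]))
    m = min(tol - abs(h22("COP1-OE", 0) - h22("WT", 0)),
            tol - abs(dh("COP1-OE", 0)),
            dh("COP1-OE", 24) - tol,
            dosage[1] - dosage[0], dosage[2] - dosage[1])
    add(ChecklistItem("cop1oe_dark_wt_cwl_response", m > 0, m,
                      f"dark |H-WT|={abs(h22('COP1-OE', 0) - h22('WT', 0)):.3f}, "
                      f"dH(0)={dh('COP1-OE', 0):.3f}, dH(24)={dh('COP1-OE', 24):.3f}, "
                      f"dosage dH(24)={np.round(dosage, 3)}"))

    # 6. PHYBox: dark growth identical to WT; thermal response partly
    # restored under 4-h light relative to 8-h
    m = min(tol - abs(h22("PHYBox", 0) - h22("WT", 0)),
            dh("PHYBox", 4) - dh("PHYBox", 8))
    add(ChecklistItem("phybox_dark_wt_4h_restoration", m > 0, m,
                      f"dark |H-WT|={abs(h22('PHYBox', 0) - h22('WT', 0)):.3f}, "
                      f"dH(4)={dh('PHYBox', 4):.3f} vs dH(8)={dh('PHYBox', 8):.3f}"))

    # 7. elf3-8: de-repressed growth at 22 degC in short days, residual dH
    m = min(h22("elf3-8", 8) - h22("WT", 8), dh("elf3-8", 8) - tol)
    add(ChecklistItem("elf3_tall22_residual_dh", m > 0, m,
                      f"H22(8): {h22('elf3-8', 8):.3f} vs WT {h22('WT', 8):.3f}; "
                      f"dH(8)={dh('elf3-8', 8):.3f}"))

    # 8. ELF3ox: impaired at 16 h, WT-like at 8 h, dark height = elf3-8 dark
    m = min(dh("WT", 16) - dh("ELF3ox", 16) - tol,
            tol - abs(dh("ELF3ox", 8) - dh("WT", 8)),
            tol - abs(h22("ELF3ox", 0) - h22("elf3-8", 0)))
    add(ChecklistItem("elf3ox_longday_impaired", m > 0, m,
                      f"dH(16)={dh('ELF3ox', 16):.3f} vs WT {dh('WT', 16):.3f}; "
                      f"dH(8)={dh('ELF3ox', 8):.3f} vs WT {dh('WT', 8):.3f}; "
                      f"dark H {h22('ELF3ox', 0):.3f} vs elf3-8 {h22('elf3-8', 0):.3f}"))

    # 9. regulator dynamics in WT short days (last diel cycle of day 5)
    if not with_dynamics:
        return report
    wt = reg["WT"]
    tr22 = integrate(p, wt, EnvironmentRegime(8.0, 22.0), output_step=0.25)
    tr28 = integrate(p, wt, EnvironmentRegime(8.0, 28.0), output_step=0.25)
    day = (96.0, 104.0)
    night = (104.0, 120.0)
    e_day = _mean_between(tr28, *day, comp="E") - _mean_between(tr22, *day, comp="E")
    p_night = _mean_between(tr22, *night, comp="P") - _mean_between(tr22, *day, comp="P")
    p_warm = _mean_between(tr28, 96.0, 120.0, "P") - _mean_between(tr22, 96.0, 120.0, "P")
    b_warm = _mean_between(tr22, 96.0, 120.0, "B") - _mean_between(tr28, 96.0, 120.0, "B")
    # dark inactivation speed: fractional B loss over the first 4 h of night
    def _b_decay(tr):
        b0 = tr.at(104.0).B
        return (b0 - tr.at(108.0).B) / b0 if b0 > 0 else 0.0
    b_fast = _b_decay(tr28) - _b_decay(tr22)
    c_night_blind = 0.05 * p.C_dark - abs(
        _mean_between(tr28, *night, comp="C") - _mean_between(tr22, *night, comp="C"))
    c_day_reduced = _mean_between(tr22, *night, comp="C") - _mean_between(tr22, *day, comp="C")
    c_day_warm = _mean_between(tr28, *day, comp="C") - _mean_between(tr22, *day, comp="C")
    m = min(e_day, p_night, p_warm, b_warm, b_fast, c_night_blind,
            c_day_reduced, c_day_warm)
    add(ChecklistItem("regulator_dynamics", m > 0, m,
                      f"E day@28-22={e_day:.4f}, P night-day={p_night:.4f}, "
                      f"P 28-22={p_warm:.4f}, B 22-28={b_warm:.4f}, "
                      f"B decay 28-22={b_fast:.4f}, C night blind margin={c_night_blind:.4f}, "
                      f"C night-day={c_day_reduced:.4f}, C day 28-22={c_day_warm:.4f}"))

    return report
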