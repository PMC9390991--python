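"""Synthetic study generator: growth datasets and ELF3 profile targets.

Emulates the design of the multi-genotype growth experiment — ~13 genetic
backgrounds grown for 5 days under {0, 8, 12, 16, 24} h light at 22 or
28 °C, with 14–112 seedlings per condition — by simulating the reference
model and adding per-seedling normal noise (CV 10 % of the mean, truncated
at zero).  Two cells are dropped by default, mirroring the missing entries
of the real design.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._fast import final_hypocotyl_batch
from .environment import EnvironmentRegime
from .fit import GrowthDataset, registry_with_gains
from .genotypes import Genotype, resolve
from .model import ParameterSet
from .simulate import elf3_periodic_profile

__all__ = [
    "StudyDesign",
    "reference_parameters",
    "generate_dataset",
    "generate_elf3_targets",
    "TRAINING_GENOTYPES",
]

#: genotypes of the training design (the validation composites are held out)
TRAINING_GENOTYPES = (
    "WT", "phyB-9", "PHYBox", "elf3-8", "ELF3ox", "pif4", "pifq", "PIF4ox",
    "cop1-4", "COP1-OE", "hy5", "elf3-8 cop1-4", "ELF3ox cop1-4",
)


@dataclass(frozen=True)
class StudyDesign:
    """Shape and noise model of a synthetic growth study."""

    genotypes: tuple[str, ...] = TRAINING_GENOTYPES
    photoperiods: tuple[float, ...] = (0.0, 8.0, 12.0, 16.0, 24.0)
    temperatures: tuple[float, ...] = (22.0, 28.0)
    n_range: tuple[int, int] = (14, 112)
    cv: float = 0.10
    sd_floor_mm: float = 0.01
    drop_cells: tuple[tuple[str, float, float], ...] = (
        ("PHYBox", 12.0, 22.0), ("ELF3ox", 16.0, 28.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            raise ValueError(f"invalid n_range {self.n_range}")


_REFERENCE_CACHE: tuple[ParameterSet, dict[str, float]] | None = None


def reference_parameters() -> tuple[ParameterSet, dict[str, float]]:
    """The packaged reference parameter set and fitted genotype gains.

    A constructed, versioned fixture (see scripts/make_reference.py) chosen
    to satisfy the full qualitative checklist; it stands in for a fitted
    wild-type parameterization.
    """
    global _REFERENCE_CACHE
    if _REFERENCE_CACHE is None:
        text = (resources.files("thermogrowth") / "data"
                / "reference_parameters.json").read_text()
        d = json.loads(text)
        _REFERENCE_CACHE = (ParameterSet.from_dict(d["parameters"]),
                            {k: float(v) for k, v in d["genotype_gains"].items()})
    return _REFERENCE_CACHE


def generate_dataset(p: ParameterSet | None = None,
                     design: StudyDesign = StudyDesign(),
                     registry: dict[str, Genotype] | None = None
                     ) -> GrowthDataset:
    """Simulate the study and report noisy per-cell summaries.

    Per cell: the model's final hypocotyl length is the true mean; ``n``
    seedlings are drawn i.i.d. normal with SD = CV x mean (truncated at 0)
    and summarized as sample mean, sample SD (``ddof=1``, floored) and n.
    Deterministic given ``design.seed``.
    """
    if p is None:
        p, gains = reference_parameters()
        registry = registry_with_gains(gains) if registry is None else registry
    cells = [(g, D, T)
             for g in design.genotypes
             for D in design.photoperiods
             for T in design.temperatures
             if (g, D, T) not in design.drop_cells]
    mult = [resolve(g, registry).multipliers() for g, _, _ in cells]
    true_means = final_hypocotyl_batch(
        p, mult, [D for _, D, _ in cells], [T for _, _, T in cells])

    rng = np.random.default_rng(design.seed)
    rows = []
    for (g, D, T), mu in zip(cells, true_means):
        n = int(rng.integers(design.n_range[0], design.n_range[1] + 1))
        if design.cv == 0.0:
            mean, sd = float(mu), 0.0
        else:
            draws = np.maximum(rng.normal(mu, design.cv * mu, size=n), 0.0)
            mean = float(draws.mean())
            sd = float(draws.std(ddof=1)) if n > 1 else 0.0
        rows.append((g, D, T, mean, max(sd, design.sd_floor_mm), n))
    return GrowthDataset(pd.DataFrame(rows, columns=[
        "genotype", "photoperiod_h", "temperature_C", "mean_mm", "sd_mm", "n"]))


def generate_elf3_targets(p: ParameterSet | None = None,
                          regime: EnvironmentRegime | None = None
                          ) -> pd.DataFrame:
    """Hourly diel ELF3 profile at steady entrainment, normalized to max 1.

    A synthetic stand-in for a measured expression waveform; columns
    ``time_h`` (hours after dawn) and ``value``.
    """
    if p is None:
        p, _ = reference_parameters()
    if regime is None:
        regime = EnvironmentRegime(8.0, 22.0)
    prof = elf3_periodic_profile(p, regime, times=np.arange(0.0, 24.0, 1.0))
    vals = prof["E"].to_numpy()
    peak = vals.max()
    if peak <= 0:
        raise ValueError("ELF3 trajectory is identically zero; cannot normalize")
    return pd.DataFrame({"time_h": prof["time_h"], "value": vals / peak})
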