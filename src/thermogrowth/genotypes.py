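"""Genetic backgrounds as multiplier templates over the wild-type parameters.

Each genotype is a set of non-negative channel multipliers: ``g_B`` scales
phyB photoactivation capacity, ``g_E`` ELF3 synthesis, ``g_C`` the COP1
target, ``g_P`` PIF production and ``g_Y`` HY5 capacity.  A value of 1.0 is
wild type; 0 a null allele; values in (0, 1) hypomorphs (e.g. the weak
*cop1-4* allele); values > 1 overexpressors.  Double mutants compose by
component-wise product, so composition is commutative and associative with
the wild type as identity.

Overexpression gains and hypomorph residual activities are free parameters of
the model fit; the registry ships the values frozen alongside the reference
parameter set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .model import ParameterSet

__all__ = ["Genotype", "WT", "builtin_registry", "compose", "apply_genotype",
           "resolve"]

MULTIPLIER_NAMES = ("g_B", "g_E", "g_C", "g_P", "g_Y")


@dataclass(frozen=True)
class Genotype:
    """Named activity multipliers mapping a genetic background onto the
    wild-type parameter set."""

    name: str
    g_B: float = 1.0
    g_E: float = 1.0
    g_C: float = 1.0
    g_P: float = 1.0
    g_Y: float = 1.0
    #: multipliers treated as free parameters during fitting
    fitted_flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for n in MULTIPLIER_NAMES:
            v = getattr(self, n)
            if v < 0:
                raise ValueError(f"{self.name}: multiplier {n} must be >= 0, got {v}")
        for n in self.fitted_flags:
            if n not in MULTIPLIER_NAMES:
                raise ValueError(f"unknown fitted flag {n!r}")

    def multipliers(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in MULTIPLIER_NAMES}

    def with_multipliers(self, **changes: float) -> "Genotype":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = {"name": self.name, **self.multipliers()}
        if self.fitted_flags:
            d["fitted_flags"] = list(self.fitted_flags)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Genotype":
        d = dict(d)
        if "fitted_flags" in d:
            d["fitted_flags"] = tuple(d["fitted_flags"])
        return cls(**d)


WT = Genotype("WT")

# Fallback fitted gains (hypomorph residual activities and overexpression
# gains) used only when the packaged reference file is absent; the shipped
# values live in data/reference_parameters.json (see scripts/make_reference.py).
_FALLBACK_GAINS = {
    "PHYBox": {"g_B": 2.5},
    "ELF3ox": {"g_E": 2.5},
    "cop1-4": {"g_C": 0.12},
    "COP1-OE": {"g_C": 3.0},
    "pif4": {"g_P": 0.6},
    "pifq": {"g_P": 0.15},
    "PIF4ox": {"g_P": 6.0},
}


def _reference_gains() -> dict[str, dict[str, float]]:
    from importlib import resources

    gains = {k: dict(v) for k, v in _FALLBACK_GAINS.items()}
    try:
        text = (resources.files("thermogrowth") / "data"
                / "reference_parameters.json").read_text()
    except (FileNotFoundError, ModuleNotFoundError):
        return gains
    for spec, value in json.loads(text).get("genotype_gains", {}).items():
        name, channel = spec.split(":", 1)
        gains.setdefault(name, {})[channel] = float(value)
    return gains


def compose(a: Genotype, b: Genotype) -> Genotype:
    """Component-wise product of multipliers (double mutants, stacked lines).

    The name concatenates the parents' names; composing with WT returns a
    genotype identical to the other parent (name included).
    """
    prod = {n: getattr(a, n) * getattr(b, n) for n in MULTIPLIER_NAMES}
    if a.name == "WT":
        name = b.name
    elif b.name == "WT":
        name = a.name
    else:
        name = f"{a.name} {b.name}"
    flags = tuple(dict.fromkeys(a.fitted_flags + b.fitted_flags))
    return Genotype(name=name, fitted_flags=flags, **prod)


def builtin_registry() -> dict[str, Genotype]:
    """Registry of the study's genetic backgrounds, keyed by name.

    Contains the training genotypes (single mutants, hypomorphs and
    overexpressors) and the held-out validation composites.
    """
    gains = _reference_gains()
    g = {
        "WT": WT,
        "phyB-9": Genotype("phyB-9", g_B=0.0),
        "PHYBox": Genotype("PHYBox", fitted_flags=("g_B",), **gains["PHYBox"]),
        "elf3-8": Genotype("elf3-8", g_E=0.0),
        "ELF3ox": Genotype("ELF3ox", fitted_flags=("g_E",), **gains["ELF3ox"]),
        "cop1-4": Genotype("cop1-4", fitted_flags=("g_C",), **gains["cop1-4"]),
        "COP1-OE": Genotype("COP1-OE", fitted_flags=("g_C",),
                            **gains["COP1-OE"]),
        "pif4": Genotype("pif4", fitted_flags=("g_P",), **gains["pif4"]),
        "pifq": Genotype("pifq", fitted_flags=("g_P",), **gains["pifq"]),
        "PIF4ox": Genotype("PIF4ox", fitted_flags=("g_P",), **gains["PIF4ox"]),
        "hy5": Genotype("hy5", g_Y=0.0),
    }
    composites = [
        ("elf3-8", "phyB-9"),
        ("phyB-9", "cop1-4"),
        ("elf3-8", "cop1-4"),
        ("ELF3ox", "cop1-4"),
        ("phyB-9", "COP1-OE"),
        ("PHYBox", "COP1-OE"),
    ]
    for a, b in composites:
        geno = compose(g[a], g[b])
        g[geno.name] = geno
    return g


def resolve(name: str, registry: dict[str, Genotype] | None = None) -> Genotype:
    """Look up a genotype by name, raising with the known names on a miss."""
    reg = builtin_registry() if registry is None else registry
    try:
        return reg[name]
    except KeyError:
        known = ", ".join(sorted(reg))
        raise KeyError(f"unknown genotype {name!r}; known genotypes: {known}") from None


def apply_genotype(p: ParameterSet, g: Genotype) -> tuple[ParameterSet, Genotype]:
    """Fold the multipliers into effective inputs for the model equations.

    Synthesis-side channels fold directly into the wild-type parameters
    (``g_E`` into ``a_E``, ``g_P`` into ``a_P``, ``g_Y`` into ``Y0``, ``g_C``
    into both COP1 targets); ``g_B`` caps the photoactivatable phyB pool and
    cannot be expressed as a rate rescaling, so it remains on the returned
    residual genotype.  Pure function: the input set is not modified, and the
    returned pair produces dynamics identical to ``(p, g)``.
    """
    p_eff = p.replace(
        a_E=p.a_E * g.g_E,
        a_P=p.a_P * g.g_P,
        Y0=p.Y0 * g.g_Y,
        C_dark=p.C_dark * g.g_C,
        C_light=p.C_light * g.g_C,
    )
    return p_eff, Genotype(name=g.name, g_B=g.g_B)


def registry_to_json(registry: dict[str, Genotype]) -> str:
    return json.dumps({k: v.to_dict() for k, v in registry.items()}, indent=1)


def registry_from_json(text: str) -> dict[str, Genotype]:
    return {k: Genotype.from_dict(v) for k, v in json.loads(text).items()}
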