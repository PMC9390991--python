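"""thermogrowth: a dynamical model of seedling thermomorphogenesis.

Simulates hypocotyl elongation of *Arabidopsis* seedlings under diel
light/temperature cycles from the coupled activities of phyB, ELF3, COP1,
PIF and HY5, fits the model to multi-genotype growth surfaces with a custom
simulated-annealing ensemble, and generates the downstream predictions
(day-length response curves, held-out genotypes, activity x day-length
thermoelongation heatmaps).
"""

from .environment import EnvironmentRegime, light_at, temperature_at, transition_times
from .model import ParameterSet, State, elf3_drive, hy5_qss, rhs, steady_state_constant
from .genotypes import Genotype, builtin_registry, compose, apply_genotype, resolve
from .simulate import Trajectory, integrate, final_hypocotyl, thermal_elongation

__version__ = "0.1.0"

__all__ = [
    "EnvironmentRegime", "light_at", "temperature_at", "transition_times",
    "ParameterSet", "State", "elf3_drive", "hy5_qss", "rhs",
    "steady_state_constant",
    "Genotype", "builtin_registry", "compose", "apply_genotype", "resolve",
    "Trajectory", "integrate", "final_hypocotyl", "thermal_elongation",
    "reference_parameters", "ThermalGrowthRegressor",
    "__version__",
]


def reference_parameters():
    """Packaged reference parameter set and fitted genotype gains
    (lazy import to keep the base import light)."""
    from .synth import reference_parameters as _rp

    return _rp()


def __getattr__(name):
    if name == "ThermalGrowthRegressor":
        from .estimator import ThermalGrowthRegressor

        return ThermalGrowthRegressor
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
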