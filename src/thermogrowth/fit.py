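"""Cost function over the multi-genotype growth surface and the custom
simulated-annealing optimizer.

The fit minimizes a chi-square residual: for every dataset cell (genotype x
photoperiod x temperature) the squared difference between the simulated and
the measured mean hypocotyl length, weighted by the reported SD, optionally
plus a penalty tying the normalized diel ELF3 trajectory to a measured
expression profile.  Proposals are single-parameter Gaussian moves in log10
space with Metropolis acceptance on a geometric temperature ladder whose
starting temperature is calibrated from an initial probe of the cost
landscape.  Repeated restarts from independent seeds give a parameter
ensemble: the data constrain a manifold rather than a point, and it is the
ensemble's *predictions* that are expected to agree, not its parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fast import DEFAULT_SUBSTEP_H, final_hypocotyl_batch
from .environment import EnvironmentRegime
from .genotypes import MULTIPLIER_NAMES, Genotype, builtin_registry, compose, resolve
from .model import ParameterSet
from .simulate import elf3_periodic_profile

__all__ = [
    "GrowthDataset",
    "FitConfig",
    "FitResult",
    "dataset_cost",
    "elf3_profile_penalty",
    "anneal",
    "ensemble_fit",
    "DEFAULT_BOUNDS",
    "registry_with_gains",
]

DATASET_COLUMNS = ["genotype", "photoperiod_h", "temperature_C",
                   "mean_mm", "sd_mm", "n"]


class GrowthDataset:
    """Mean ± SD hypocotyl lengths per genotype x photoperiod x temperature."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in DATASET_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(
                f"growth dataset missing columns {missing}; "
                f"expected header {','.join(DATASET_COLUMNS)}")
        frame = frame[DATASET_COLUMNS].copy()
        if len(frame) == 0:
            raise ValueError("growth dataset is empty")
        keys = frame[["genotype", "photoperiod_h", "temperature_C"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate dataset key {dup}")
        if (frame["sd_mm"] <= 0).any():
            raise ValueError("sd_mm must be > 0 in every row")
        if (frame["n"] < 1).any():
            raise ValueError("n must be >= 1 in every row")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.frame["genotype"].unique())

    @classmethod
    def from_csv(cls, path) -> "GrowthDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def subset(self, genotypes=None, photoperiods=None) -> "GrowthDataset":
        f = self.frame
        if genotypes is not None:
            f = f[f["genotype"].isin(genotypes)]
        if photoperiods is not None:
            f = f[f["photoperiod_h"].isin(photoperiods)]
        return GrowthDataset(f)


# log-scale box bounds per parameter (linear-space endpoints, all > 0).
# Rates span physiologic ranges (per hour); dimensionless constants three
# decades around unity; Hill exponents and Q10s stay in narrow bands.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_pB": (0.05, 20.0), "k_rB": (1e-3, 20.0), "k_dB": (1e-3, 2.0),
    "Q10_B": (1.0, 10.0),
    "a_E": (1e-3, 10.0), "d_E": (0.02, 5.0), "b_E": (1e-3, 1.0),
    "w_E": (0.5, 12.0), "rho_E": (1e-4, 0.5), "d_EC": (1e-4, 5.0),
    "Q10_E": (0.1, 10.0),
    # C_dark is the COP1 activity scale; the day target stays below the
    # night ceiling
    "C_dark": (0.1, 10.0), "C_light": (1e-4, 1.0), "eps_C": (1e-3, 1.0),
    "tau_C": (0.1, 10.0),
    "a_P": (0.01, 10.0), "K_E": (0.01, 10.0), "h_E": (1.0, 6.0),
    "d_P": (0.01, 10.0), "beta_B": (0.01, 100.0), "beta_C": (0.01, 100.0),
    "Y0": (0.01, 10.0), "K_C": (0.01, 10.0),
    "v0": (1e-4, 0.1), "v_max": (0.005, 1.0), "K_G": (0.01, 10.0),
    "n_G": (1.0, 6.0), "K_Bg": (0.005, 10.0), "K_Eg": (0.01, 10.0),
    "K_Yg": (0.01, 10.0), "H0": (0.05, 2.0),
}
#: generic bounds for fitted genotype multipliers
MULTIPLIER_BOUNDS = (1e-3, 100.0)


@dataclass
class FitConfig:
    """Annealing schedule, proposal kernel and free-parameter selection.

    ``free_parameters`` are ParameterSet field names; ``free_multipliers``
    are ``"<genotype>:<channel>"`` strings (e.g. ``"cop1-4:g_C"``) appended
    to the optimization vector, echoing that hypomorph residual activities
    and overexpression gains are fitted quantities.
    """

    free_parameters: tuple[str, ...] = ()
    free_multipliers: tuple[str, ...] = ()
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial_accept: float = 0.5
    cooling: float = 0.98
    proposals_per_T: int = 200
    min_accept_frac: float = 0.01
    max_proposals: int = 200_000
    step_log10: float = 0.1
    lambda_E: float = 1.0
    elf3_regime: EnvironmentRegime = field(
        default_factory=lambda: EnvironmentRegime(8.0, 22.0))
    seed: int = 0
    n_restarts: int = 4
    base_parameters: ParameterSet | None = None
    substep_h: float = 0.25
    #: random starting points screened per chain (best one seeds the chain)
    n_init_probe: int = 1
    #: restarts with best cost above ``convergence_factor x ensemble best``
    #: (beyond a small absolute slack) are reported as failed, not members
    convergence_factor: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError(f"cooling must be in (0,1), got {self.cooling}")
        if self.lambda_E < 0:
            raise ValueError("lambda_E must be >= 0")
        if not self.free_parameters and not self.free_multipliers:
            raise ValueError("at least one free parameter is required")
        for name in self.free_parameters:
            if name not in DEFAULT_BOUNDS:
                raise ValueError(f"unknown parameter {name!r}")
        for spec in self.free_multipliers:
            if ":" not in spec or spec.split(":", 1)[1] not in MULTIPLIER_NAMES:
                raise ValueError(
                    f"free multiplier must be '<genotype>:<g_X>', got {spec!r}")

    def bound_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if ":" in name:
            return MULTIPLIER_BOUNDS
        return DEFAULT_BOUNDS[name]


@dataclass
class FitMember:
    parameters: ParameterSet
    gains: dict[str, float]  # "<genotype>:<g_X>" -> value
    cost: float
    seed: int
    trace: np.ndarray  # best-so-far cost after each proposal

    def to_dict(self) -> dict:
        return {"parameters": self.parameters.to_dict(), "gains": self.gains,
                "cost": self.cost, "seed": self.seed}


@dataclass
class FitResult:
    """Ensemble of accepted parameter sets (the fitted manifold).

    Restarts that never reached the manifold (trapped in a poor basin) are
    kept in ``rejected`` for inspection but are not ensemble members.
    """

    members: list[FitMember]
    config: FitConfig
    warnings: list[str] = field(default_factory=list)
    rejected: list[FitMember] = field(default_factory=list)

    @property
    def best(self) -> FitMember:
        return self.members[0]

    def to_json(self) -> str:
        return json.dumps({"members": [m.to_dict() for m in self.members],
                           "warnings": self.warnings}, indent=1)

    def traces_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self.members):
            rows.append(pd.DataFrame({"member": i, "seed": m.seed,
                                      "proposal": np.arange(len(m.trace)),
                                      "best_cost": m.trace}))
        return pd.concat(rows, ignore_index=True)


def registry_with_gains(gains: dict[str, float],
                        registry: dict[str, Genotype] | None = None
                        ) -> dict[str, Genotype]:
    """Rebuild the genotype registry with fitted gains substituted.

    ``gains`` maps ``"<genotype>:<channel>"`` to values; composites are
    recomposed from their (possibly overridden) parents so e.g. a new
    *cop1-4* residual activity propagates into *phyB-9 cop1-4*.
    """
    reg = dict(builtin_registry() if registry is None else registry)
    for spec, value in gains.items():
        name, channel = spec.split(":", 1)
        if name not in reg:
            raise KeyError(f"unknown genotype {name!r} in gains")
        reg[name] = reg[name].with_multipliers(**{channel: float(value)})
    # recompose any composite whose name is "<a> <b>"
    for key in list(reg):
        if " " in key:
            a, b = key.split(" ", 1)
            if a in reg and b in reg:
                reg[key] = compose(reg[a], reg[b])
    return reg


def predict_dataset_lengths(p: ParameterSet, data: GrowthDataset,
                            registry: dict[str, Genotype],
                            substep_h: float = DEFAULT_SUBSTEP_H) -> np.ndarray:
    """Simulated final lengths for every dataset row (fast path)."""
    mult = [resolve(name, registry).multipliers()
            for name in data.frame["genotype"]]
    return final_hypocotyl_batch(
        p, mult, data.frame["photoperiod_h"].to_numpy(),
        data.frame["temperature_C"].to_numpy(), substep_h=substep_h)


def elf3_profile_penalty(p: ParameterSet, regime: EnvironmentRegime,
                         targets: pd.DataFrame | None) -> float:
    """Sum of squared differences between the entrained diel ELF3 trajectory
    (normalized to its own diel maximum) and target values.

    ``targets`` has columns ``time_h`` (hours after dawn, in [0, 24)) and
    ``value``; empty or None targets give 0.  The simulated trajectory is
    normalized to its maximum over the compared sample times, matching how
    the target profiles themselves are normalized (expression units are
    arbitrary, so only the waveform is constrained).
    """
    if targets is None or len(targets) == 0:
        return 0.0
    times = np.asarray(targets["time_h"], dtype=float)
    vals = np.asarray(targets["value"], dtype=float)
    at_targets = elf3_periodic_profile(p, regime, times=times)["E"].to_numpy()
    peak = float(at_targets.max())
    if peak <= 0:
        return float(np.sum(vals ** 2))
    return float(np.sum((at_targets / peak - vals) ** 2))


def dataset_cost(p: ParameterSet, gains: dict[str, float], data: GrowthDataset,
                 elf3_targets: pd.DataFrame | None = None,
                 lambda_E: float = 0.0,
                 elf3_regime: EnvironmentRegime | None = None,
                 registry: dict[str, Genotype] | None = None,
                 substep_h: float = DEFAULT_SUBSTEP_H) -> float:
    """Chi-square growth residual plus the weighted ELF3-profile penalty."""
    reg = registry_with_gains(gains, registry)
    model = predict_dataset_lengths(p, data, reg, substep_h=substep_h)
    if not np.all(np.isfinite(model)):
        return math.inf
    resid = (model - data.frame["mean_mm"].to_numpy()) \
        / data.frame["sd_mm"].to_numpy()
    cost = float(np.sum(resid ** 2))
    if lambda_E > 0.0 and elf3_targets is not None and len(elf3_targets):
        regime = elf3_regime or EnvironmentRegime(8.0, 22.0)
        cost += lambda_E * elf3_profile_penalty(p, regime, elf3_targets)
    return cost


# ---------------------------------------------------------------------------
# annealing core


def anneal_vector(cost_fn, x0_log: np.ndarray, lo_log: np.ndarray,
                  hi_log: np.ndarray, cfg: FitConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, float, np.ndarray, list[str]]:
    """Generic simulated annealing in log10 space (single chain).

    Single-coordinate Gaussian proposals clipped to the box; the starting
    temperature is calibrated from a probe of uphill move sizes so the
    initial acceptance fraction approximates ``cfg.initial_accept``; the
    ladder then cools geometrically.  Returns best x (log10), best cost,
    the best-so-far trace and any warnings.
    """
    x = x0_log.copy()
    ndim = x.size
    cost = cost_fn(x)
    warnings: list[str] = []
    # an infeasible start (e.g. a parameter-invariant violation) never
    # anneals out with nan cost differences: resample until feasible
    tries = 0
    while not np.isfinite(cost) and tries < 200:
        x = rng.uniform(lo_log, hi_log)
        cost = cost_fn(x)
        tries += 1
    if not np.isfinite(cost):
        raise RuntimeError("could not find a feasible starting point "
                           "within the parameter bounds")
    best_x, best_cost = x.copy(), cost

    # probe uphill step sizes to set the initial temperature
    probe_ups = []
    for _ in range(min(50, max(10, cfg.proposals_per_T // 4))):
        i = rng.integers(ndim)
        xp = x.copy()
        xp[i] = np.clip(xp[i] + rng.normal(0.0, cfg.step_log10),
                        lo_log[i], hi_log[i])
        dc = cost_fn(xp) - cost
        if np.isfinite(dc) and dc > 0:
            probe_ups.append(dc)
    if probe_ups:
        T = float(np.median(probe_ups)) / math.log(1.0 / cfg.initial_accept)
    else:
        T = 1.0
    T = max(T, 1e-12)

    trace = np.empty(cfg.max_proposals)
    n = 0
    while n < cfg.max_proposals:
        accepted = 0
        rung = min(cfg.proposals_per_T, cfg.max_proposals - n)
        for _ in range(rung):
            i = rng.integers(ndim)
            xp = x.copy()
            xp[i] = np.clip(xp[i] + rng.normal(0.0, cfg.step_log10),
                            lo_log[i], hi_log[i])
            cp = cost_fn(xp)
            if not np.isfinite(cp):
                trace[n] = best_cost
                n += 1
                continue
            dc = cp - cost
            if dc <= 0 or rng.random() < math.exp(-min(dc / T, 700.0)):
                x, cost = xp, cp
                accepted += 1
                if cost < best_cost:
                    best_x, best_cost = x.copy(), cost
            trace[n] = best_cost
            n += 1
        if accepted == 0:
            warnings.append(f"no accepted move over rung ending at proposal {n}")
        if accepted / rung < cfg.min_accept_frac:
            break
        T *= cfg.cooling
    return best_x, best_cost, trace[:n], warnings


def _vector_names(cfg: FitConfig) -> list[str]:
    return list(cfg.free_parameters) + list(cfg.free_multipliers)


def _vector_to_model(xlog: np.ndarray, cfg: FitConfig,
                     base: ParameterSet) -> tuple[ParameterSet, dict[str, float]]:
    values = 10.0 ** xlog
    names = _vector_names(cfg)
    changes = {n: float(v) for n, v in zip(names, values) if ":" not in n}
    gains = {n: float(v) for n, v in zip(names, values) if ":" in n}
    return base.replace(**changes), gains


def _initial_vector(cfg: FitConfig, cost_fn, rng: np.random.Generator,
                    lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Random log-uniform start; with ``n_init_probe > 1`` the best of a
    random screen seeds the chain (cheap basin selection)."""
    best_x, best_c = None, math.inf
    for _ in range(max(1, cfg.n_init_probe)):
        x = rng.uniform(lo, hi)
        c = cost_fn(x)
        if c < best_c:
            best_x, best_c = x, c
    return best_x if best_x is not None else rng.uniform(lo, hi)


def anneal(data: GrowthDataset, cfg: FitConfig, seed: int | None = None,
           elf3_targets: pd.DataFrame | None = None,
           registry: dict[str, Genotype] | None = None) -> FitResult:
    """Single-chain simulated-annealing fit; bit-reproducible per seed."""
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    base = cfg.base_parameters
    if base is None:
        from .synth import reference_parameters

        base, _ = reference_parameters()
    names = _vector_names(cfg)
    lo = np.log10([cfg.bound_for(n)[0] for n in names])
    hi = np.log10([cfg.bound_for(n)[1] for n in names])

    def cost_fn(xlog: np.ndarray) -> float:
        try:
            p, gains = _vector_to_model(xlog, cfg, base)
        except ValueError:  # invariant violation (e.g. C_light > C_dark)
            return math.inf
        return dataset_cost(p, gains, data, elf3_targets, cfg.lambda_E,
                            cfg.elf3_regime, registry, cfg.substep_h)

    x0 = _initial_vector(cfg, cost_fn, rng, lo, hi)
    best_x, best_cost, trace, warns = anneal_vector(cost_fn, x0, lo, hi, cfg, rng)
    p_best, gains_best = _vector_to_model(best_x, cfg, base)
    member = FitMember(parameters=p_best, gains=gains_best, cost=best_cost,
                       seed=seed, trace=trace)
    return FitResult(members=[member], config=cfg, warnings=warns)


def ensemble_fit(data: GrowthDataset, cfg: FitConfig,
                 elf3_targets: pd.DataFrame | None = None,
                 registry: dict[str, Genotype] | None = None) -> FitResult:
    """Independent annealing chains from distinct seeds, sorted by cost."""
    if cfg.n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    seeds = [int(s) % (2 ** 31) for s in
             np.random.SeedSequence(cfg.seed).generate_state(cfg.n_restarts)]
    chains: list[FitMember] = []
    warnings: list[str] = []
    for s in seeds:
        res = anneal(data, cfg, seed=s, elf3_targets=elf3_targets,
                     registry=registry)
        chains.extend(res.members)
        warnings.extend(res.warnings)
    chains.sort(key=lambda m: m.cost)
    best = chains[0].cost
    cut = cfg.convergence_factor * best + 5.0
    members = [m for m in chains if m.cost <= cut]
    rejected = [m for m in chains if m.cost > cut]
    for m in rejected:
        warnings.append(f"restart seed {m.seed} failed to converge "
                        f"(cost {m.cost:.2f} vs best {best:.2f})")
    return FitResult(members=members, config=cfg, warnings=warnings,
                     rejected=rejected)
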