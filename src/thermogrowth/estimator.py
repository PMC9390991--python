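"""scikit-learn style estimator over the growth model.

``ThermalGrowthRegressor`` treats the thermomorphogenesis model as a
regressor from experimental conditions (genotype, photoperiod, temperature)
to final hypocotyl length: ``fit`` runs the simulated-annealing ensemble on
the provided growth surface and ``predict`` simulates the fitted model for
new condition rows.  It composes with sklearn model selection and pipelines
operating on DataFrames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .fit import FitConfig, GrowthDataset, ensemble_fit, registry_with_gains
from .genotypes import resolve
from ._fast import final_hypocotyl_batch

__all__ = ["ThermalGrowthRegressor"]

_CONDITION_COLUMNS = ["genotype", "photoperiod_h", "temperature_C"]


class ThermalGrowthRegressor(RegressorMixin, BaseEstimator):
    """Fit the regulatory-network growth model to a hypocotyl-length surface.

    Parameters
    ----------
    free_parameters, free_multipliers
        Names of kinetic parameters and ``"<genotype>:<g_X>"`` gains to
        optimize; the remaining parameters are taken from
        ``base_parameters`` (default: the packaged reference set).
    n_restarts, max_proposals, cooling, proposals_per_T, step_log10
        Annealing budget and schedule (see :class:`~thermogrowth.fit.FitConfig`).
    lambda_E
        Weight of the ELF3-profile constraint when ``elf3_targets`` is
        passed to :meth:`fit`.
    random_state
        Seed for the annealing chains; fixed seed gives bit-identical fits.

    Attributes
    ----------
    result_ : FitResult
        Full ensemble (members sorted by cost).
    best_parameters_ : ParameterSet
        Kinetic parameters of the best member.
    best_gains_ : dict
        Fitted genotype gains of the best member.
    """

    def __init__(self, free_parameters=("k_dB", "Q10_B", "C_light", "eps_C",
                                        "beta_B", "beta_C", "v_max", "K_G"),
                 free_multipliers=(), n_restarts=1, max_proposals=20000,
                 cooling=0.95, proposals_per_T=200, step_log10=0.1,
                 lambda_E=0.0, base_parameters=None, substep_h=0.25,
                 random_state=0):
        self.free_parameters = free_parameters
        self.free_multipliers = free_multipliers
        self.n_restarts = n_restarts
        self.max_proposals = max_proposals
        self.cooling = cooling
        self.proposals_per_T = proposals_per_T
        self.step_log10 = step_log10
        self.lambda_E = lambda_E
        self.base_parameters = base_parameters
        self.substep_h = substep_h
        self.random_state = random_state

    @staticmethod
    def _conditions(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in _CONDITION_COLUMNS if c not in X.columns]
            if missing:
                raise ValueError(f"X is missing columns {missing}")
            return X[_CONDITION_COLUMNS].reset_index(drop=True)
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "X must be a DataFrame with columns "
                f"{_CONDITION_COLUMNS} or an (n, 3) array in that order")
        return pd.DataFrame(X, columns=_CONDITION_COLUMNS).astype(
            {"photoperiod_h": float, "temperature_C": float})

    def fit(self, X, y, sample_weight=None, elf3_targets=None):
        """Fit to condition rows ``X`` and mean lengths ``y`` (mm).

        ``sample_weight`` follows the chi-square convention ``w = 1/sd^2``;
        unweighted rows get unit SD.
        """
        cond = self._conditions(X)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(cond):
            raise ValueError("X and y length mismatch")
        if sample_weight is None:
            sd = np.ones_like(y)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if np.any(w <= 0):
                raise ValueError("sample_weight must be > 0")
            sd = 1.0 / np.sqrt(w)
        frame = cond.assign(mean_mm=y, sd_mm=sd, n=1)
        data = GrowthDataset(frame)
        cfg = FitConfig(
            free_parameters=tuple(self.free_parameters),
            free_multipliers=tuple(self.free_multipliers),
            n_restarts=self.n_restarts, max_proposals=self.max_proposals,
            cooling=self.cooling, proposals_per_T=self.proposals_per_T,
            step_log10=self.step_log10, lambda_E=self.lambda_E,
            base_parameters=self.base_parameters, substep_h=self.substep_h,
            seed=self.random_state)
        self.result_ = ensemble_fit(data, cfg, elf3_targets=elf3_targets)
        self.best_parameters_ = self.result_.best.parameters
        self.best_gains_ = self.result_.best.gains
        self.n_features_in_ = 3
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(_CONDITION_COLUMNS, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        """Simulated final hypocotyl lengths (mm) for condition rows."""
        check_is_fitted(self, "result_")
        cond = self._conditions(X)
        reg = registry_with_gains(self.best_gains_)
        mult = [resolve(g, reg).multipliers() for g in cond["genotype"]]
        return final_hypocotyl_batch(
            self.best_parameters_, mult,
            cond["photoperiod_h"].to_numpy(dtype=float),
            cond["temperature_C"].to_numpy(dtype=float),
            substep_h=self.substep_h)
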