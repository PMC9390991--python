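"""Cost function and simulated-annealing optimizer."""

import numpy as np
import pandas as pd
import pytest

from thermogrowth._fast import final_hypocotyl_batch
from thermogrowth.environment import EnvironmentRegime
from thermogrowth.fit import (DEFAULT_BOUNDS, FitConfig, GrowthDataset, anneal,
                              dataset_cost, elf3_profile_penalty, ensemble_fit,
                              registry_with_gains)
from thermogrowth.genotypes import WT
from thermogrowth.simulate import elf3_periodic_profile
from thermogrowth.synth import generate_elf3_targets


def make_rows(p, gains, conditions, mean_offset=0.0, sd=0.5):
    """Dataset rows at the model's own predictions (optionally offset)."""
    reg = registry_with_gains(gains)
    from thermogrowth.genotypes import resolve

    mult = [resolve(g, reg).multipliers() for g, _, _ in conditions]
    sims = final_hypocotyl_batch(p, mult, [c[1] for c in conditions],
                                 [c[2] for c in conditions])
    return pd.DataFrame(
        [(g, D, T, s + mean_offset, sd, 20)
         for (g, D, T), s in zip(conditions, sims)],
        columns=["genotype", "photoperiod_h", "temperature_C", "mean_mm",
                 "sd_mm", "n"])


class TestGrowthDataset:
    def test_schema_enforced(self):
        with pytest.raises(ValueError, match="mean_mm"):
            GrowthDataset(pd.DataFrame({"genotype": ["WT"]}))

    def test_duplicates_rejected(self, ref_params):
        rows = make_rows(ref_params, {}, [("WT", 8.0, 22.0)] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            GrowthDataset(rows)

    def test_zero_sd_rejected(self, ref_params):
        rows = make_rows(ref_params, {}, [("WT", 8.0, 22.0)], sd=0.0)
        with pytest.raises(ValueError, match="sd_mm"):
            GrowthDataset(rows)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GrowthDataset(pd.DataFrame(columns=["genotype", "photoperiod_h",
                                                "temperature_C", "mean_mm",
                                                "sd_mm", "n"]))

    def test_csv_roundtrip(self, ref_params, tmp_path):
        rows = make_rows(ref_params, {}, [("WT", 8.0, 22.0), ("WT", 8.0, 28.0)])
        d = GrowthDataset(rows)
        d.to_csv(tmp_path / "g.csv")
        d2 = GrowthDataset.from_csv(tmp_path / "g.csv")
        pd.testing.assert_frame_equal(d.frame, d2.frame)


class TestDatasetCost:
    def test_perfect_model_has_zero_cost(self, ref, ref_params):
        _, gains = ref
        data = GrowthDataset(make_rows(ref_params, gains,
                                       [("WT", 8.0, 22.0), ("cop1-4", 0.0, 28.0)]))
        assert dataset_cost(ref_params, gains, data,
                            substep_h=0.05) == pytest.approx(0.0, abs=1e-18)

    def test_single_row_chi_square(self, ref, ref_params):
        # model off by 1.0 mm with sd 0.5 -> (1/0.5)^2 = 4
        _, gains = ref
        data = GrowthDataset(make_rows(ref_params, gains, [("WT", 8.0, 22.0)],
                                       mean_offset=-1.0, sd=0.5))
        assert dataset_cost(ref_params, gains, data,
                            substep_h=0.05) == pytest.approx(4.0, rel=1e-9)

    def test_additive_and_row_order_invariant(self, ref, ref_params):
        _, gains = ref
        r1 = make_rows(ref_params, gains, [("WT", 8.0, 22.0)], -1.0, 0.5)
        r2 = make_rows(ref_params, gains, [("elf3-8", 16.0, 28.0)], 2.0, 1.0)
        c1 = dataset_cost(ref_params, gains, GrowthDataset(r1), substep_h=0.05)
        c2 = dataset_cost(ref_params, gains, GrowthDataset(r2), substep_h=0.05)
        both = dataset_cost(ref_params, gains,
                            GrowthDataset(pd.concat([r1, r2])), substep_h=0.05)
        flipped = dataset_cost(ref_params, gains,
                               GrowthDataset(pd.concat([r2, r1])),
                               substep_h=0.05)
        assert both == pytest.approx(c1 + c2, rel=1e-12)
        assert both == flipped

    def test_unknown_genotype_raises(self, ref_params):
        rows = pd.DataFrame([("martian", 8.0, 22.0, 3.0, 0.5, 20)],
                            columns=["genotype", "photoperiod_h",
                                     "temperature_C", "mean_mm", "sd_mm", "n"])
        with pytest.raises(KeyError, match="unknown genotype"):
            dataset_cost(ref_params, {}, GrowthDataset(rows))


class TestElf3Penalty:
    def test_empty_targets_zero(self, ref_params):
        assert elf3_profile_penalty(ref_params, EnvironmentRegime(8, 22),
                                    None) == 0.0
        empty = pd.DataFrame(columns=["time_h", "value"])
        assert elf3_profile_penalty(ref_params, EnvironmentRegime(8, 22),
                                    empty) == 0.0

    def test_self_consistency_zero(self, ref_params):
        targets = generate_elf3_targets(ref_params, EnvironmentRegime(8, 22))
        pen = elf3_profile_penalty(ref_params, EnvironmentRegime(8, 22),
                                   targets)
        assert pen == pytest.approx(0.0, abs=1e-18)

    def test_zero_targets_give_sum_of_squares(self, ref_params):
        regime = EnvironmentRegime(8.0, 22.0)
        times = np.arange(0.0, 24.0, 1.0)
        targets = pd.DataFrame({"time_h": times, "value": 0.0})
        prof = elf3_periodic_profile(ref_params, regime, times=times)["E"]
        normalized = prof / prof.max()
        assert elf3_profile_penalty(ref_params, regime, targets) == \
            pytest.approx(float((normalized ** 2).sum()))


def toy_dataset(ref, k_dB_true=0.2):
    """Noiseless single-parameter problem: only k_dB differs from base."""
    p_ref, gains = ref
    p_true = p_ref.replace(k_dB=k_dB_true)
    conds = [("WT", D, T) for D in (4.0, 8.0, 16.0) for T in (22.0, 28.0)]
    return p_ref, GrowthDataset(make_rows(p_true, gains, conds, sd=0.1))


def grid_search_kdb(base, data, n=600):
    lo, hi = DEFAULT_BOUNDS["k_dB"]
    grid = np.geomspace(lo, hi, n)
    costs = [dataset_cost(base.replace(k_dB=float(k)), {}, data,
                          substep_h=0.25) for k in grid]
    return float(grid[int(np.argmin(costs))])


class TestAnneal:
    def test_recovers_single_parameter_vs_grid_oracle(self, ref):
        base, data = toy_dataset(ref)
        cfg = FitConfig(free_parameters=("k_dB",), base_parameters=base,
                        max_proposals=1500, cooling=0.9, proposals_per_T=100,
                        lambda_E=0.0, seed=3)
        res = anneal(data, cfg)
        k_hat = res.best.parameters.k_dB
        k_grid = grid_search_kdb(base, data)
        assert k_hat == pytest.approx(0.2, rel=0.05)
        assert k_grid == pytest.approx(0.2, rel=0.05)  # oracle agrees

    def test_bit_reproducible_for_fixed_seed(self, ref):
        base, data = toy_dataset(ref)
        cfg = FitConfig(free_parameters=("k_dB", "v_max"),
                        base_parameters=base, max_proposals=400,
                        cooling=0.9, proposals_per_T=50, lambda_E=0.0, seed=11)
        r1 = anneal(data, cfg)
        r2 = anneal(data, cfg)
        assert r1.best.cost == r2.best.cost
        assert r1.best.parameters.to_dict() == r2.best.parameters.to_dict()
        assert np.array_equal(r1.best.trace, r2.best.trace)

    def test_trace_non_increasing(self, ref):
        base, data = toy_dataset(ref)
        cfg = FitConfig(free_parameters=("k_dB",), base_parameters=base,
                        max_proposals=600, cooling=0.9, proposals_per_T=50,
                        lambda_E=0.0, seed=5)
        trace = anneal(data, cfg).best.trace
        assert np.all(np.diff(trace) <= 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="cooling"):
            FitConfig(free_parameters=("k_dB",), cooling=1.5)
        with pytest.raises(ValueError, match="free parameter"):
            FitConfig()
        with pytest.raises(ValueError, match="unknown parameter"):
            FitConfig(free_parameters=("bogus",))

    def test_ensemble_single_restart_matches_anneal(self, ref):
        base, data = toy_dataset(ref)
        cfg = FitConfig(free_parameters=("k_dB",), base_parameters=base,
                        max_proposals=300, cooling=0.9, proposals_per_T=50,
                        lambda_E=0.0, seed=7, n_restarts=1)
        ens = ensemble_fit(data, cfg)
        assert len(ens.members) == 1
        chain_seed = ens.members[0].seed
        solo = anneal(data, cfg, seed=chain_seed)
        assert solo.best.cost == ens.members[0].cost

    def test_ensemble_sorted_by_cost(self, ref):
        base, data = toy_dataset(ref)
        cfg = FitConfig(free_parameters=("k_dB",), base_parameters=base,
                        max_proposals=300, cooling=0.9, proposals_per_T=50,
                        lambda_E=0.0, seed=1, n_restarts=3)
        ens = ensemble_fit(data, cfg)
        costs = [m.cost for m in ens.members]
        assert costs == sorted(costs)


def test_dropping_elf3_constraint_never_hurts_growth_residual(ref):
    """On a 1-D grid, the growth-residual part of the constrained optimum is
    never below the unconstrained optimum's growth residual."""
    base, data = toy_dataset(ref)
    targets = generate_elf3_targets(base, EnvironmentRegime(8, 22))
    lo, hi = DEFAULT_BOUNDS["k_dB"]
    grid = np.geomspace(lo, hi, 120)
    growth = np.array([dataset_cost(base.replace(k_dB=float(k)), {}, data,
                                    substep_h=0.25) for k in grid])
    penal = np.array([elf3_profile_penalty(base.replace(k_dB=float(k)),
                                           EnvironmentRegime(8, 22), targets)
                      for k in grid])
    for lam in (0.5, 5.0, 50.0):
        k_con = int(np.argmin(growth + lam * penal))
        assert growth[int(np.argmin(growth))] <= growth[k_con] + 1e-12
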