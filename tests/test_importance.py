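import numpy as np
import pandas as pd
import pytest

import protgrad as pg
from protgrad.errors import ConfigError, DegenerateDataError


def _toy_cells(n=200, seed=0, p_noise=2):
    """Cells with one real driver 'a' and pure-noise companions."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({f"x{i}": rng.standard_normal(n) for i in range(p_noise)})
    df["a"] = rng.standard_normal(n)
    df["protected_fraction"] = 1 / (1 + np.exp(-(2.0 * df["a"] + 0.3 * rng.standard_normal(n))))
    return df


class TestKendallMatrix:
    def test_perfect_and_reversed_association(self):
        cells = pd.DataFrame({"u": np.arange(12.0)})
        cells["same"] = cells["u"] * 3 + 1
        cells["rev"] = -cells["u"]
        tau = pg.kendall_matrix(cells, ["u", "same", "rev"])
        assert tau.loc["u", "same"] == pytest.approx(1.0)
        assert tau.loc["u", "rev"] == pytest.approx(-1.0)
        assert np.allclose(tau, tau.T)

    def test_brute_force_pair_counting(self):
        p = list(range(1, 13))
        q = [1, 3, 2] + list(range(4, 13))          # one adjacent swap
        concordant = discordant = 0
        for i in range(len(p)):
            for j in range(i + 1, len(p)):
                s = (p[i] - p[j]) * (q[i] - q[j])
                concordant += s > 0
                discordant += s < 0
        expected = (concordant - discordant) / (concordant + discordant)
        tau = pg.kendall_matrix(pd.DataFrame({"p": p, "q": q}), ["p", "q"])
        assert tau.loc["p", "q"] == pytest.approx(expected, abs=1e-12)

    def test_constant_variable_reported_missing(self):
        cells = pd.DataFrame({"u": np.arange(12.0), "flat": 1.0})
        tau = pg.kendall_matrix(cells, ["u", "flat"])
        assert np.isnan(tau.loc["u", "flat"])
        assert tau.loc["u", "u"] == 1.0


class TestTuneMtry:
    def test_result_within_candidate_range_and_deterministic(self):
        cells = _toy_cells(n=150, seed=1)
        cfg = pg.RFConfig(ntree=100, seed=7)
        m1 = pg.tune_mtry(cells, predictors=("a", "x0"), config=cfg)
        m2 = pg.tune_mtry(cells, predictors=("a", "x0"), config=pg.RFConfig(ntree=100, seed=7))
        assert m1 in (1, 2)
        assert m1 == m2

    def test_too_few_cells_raises(self):
        cells = _toy_cells(n=30)
        with pytest.raises(DegenerateDataError):
            pg.tune_mtry(cells, predictors=("a", "x0"), config=pg.RFConfig(ntree=100))

    def test_invalid_config_rejected(self):
        cells = _toy_cells(n=100)
        with pytest.raises(ConfigError):
            pg.tune_mtry(cells, predictors=("a", "x0"), config=pg.RFConfig(ntree=50))
        with pytest.raises(ConfigError):
            pg.permutation_importance(cells, predictors=("a", "x0"),
                                      config=pg.RFConfig(ntree=100, mtry=5))


class TestPermutationImportance:
    def test_percent_sums_to_100_and_driver_beats_noise(self):
        cells = _toy_cells(n=400, seed=2, p_noise=3)
        cfg = pg.RFConfig(ntree=150, mtry=2, seed=0)
        table = pg.permutation_importance(
            cells, predictors=("a", "x0", "x1", "x2"), config=cfg)
        assert sum(table.percent_importance.values()) == pytest.approx(100.0, abs=1e-6)
        driver = table.percent_importance["a"]
        assert all(driver > table.percent_importance[f"x{i}"] for i in range(3))

    def test_deterministic_per_seed(self, opportunistic_world):
        cfg = pg.RFConfig(ntree=100, mtry=3, seed=5)
        t1 = pg.permutation_importance(opportunistic_world, config=cfg)
        t2 = pg.permutation_importance(opportunistic_world, config=cfg)
        assert t1.percent_importance == t2.percent_importance
        assert t1.oob_mse == t2.oob_mse

    def test_planted_driver_ranks_first(self, opportunistic_world):
        cfg = pg.RFConfig(ntree=150, mtry=3, seed=1)
        table = pg.permutation_importance(opportunistic_world, config=cfg)
        ranked = sorted(table.percent_importance, key=table.percent_importance.get,
                        reverse=True)
        assert ranked[0] == "isolation"

    def test_duplicated_predictor_does_not_displace_driver(self, opportunistic_world):
        cells = opportunistic_world.copy()
        cells["population_dup"] = cells["population"]
        predictors = list(pg.RF_PREDICTORS) + ["population_dup"]
        cfg = pg.RFConfig(ntree=150, mtry=3, seed=1)
        table = pg.permutation_importance(cells, predictors=predictors, config=cfg)
        ranked = sorted(table.percent_importance, key=table.percent_importance.get,
                        reverse=True)
        assert ranked[0] == "isolation"


class TestGroupAverages:
    def test_animal_plant_preaveraging(self):
        imp = {"tourism": 10.0, "frontiers": 2.0, "biomass": 6.0,
               "animal_richness": 8.0, "plant_richness": 4.0,
               "population": 1.0, "isolation": 1.0, "coasts": 1.0,
               "cropland_suitability": 1.0}
        out = pg.group_averages(imp)
        assert out["preferential"] == pytest.approx(6.0)
        assert out["opportunistic"] == pytest.approx(1.0)

    def test_all_equal_values_pass_through(self):
        imp = {v: 5.0 for v in pg.RF_PREDICTORS}
        out = pg.group_averages(imp)
        assert out["preferential"] == pytest.approx(5.0)
        assert out["opportunistic"] == pytest.approx(5.0)

    def test_unknown_variable_in_grouping_raises(self):
        with pytest.raises(ConfigError):
            pg.group_averages({"tourism": 1.0}, grouping={"g": ("tourism", "mystery")})
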