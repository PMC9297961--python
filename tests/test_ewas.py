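import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiclock import (BetaMatrix, SimConfig, ewas_age, ewas_interaction,
                      ewas_sex_adjusted, select_top_cpgs, simulate_dataset,
                      stratified_age_ewas)

from conftest import rng_beta_frame


def _ages(values, ids=None):
    ids = ids or [f"S{i+1}" for i in range(len(values))]
    return pd.Series(values, index=ids, dtype=float)


def _sex(values, ids=None):
    ids = ids or [f"S{i+1}" for i in range(len(values))]
    return pd.Series(values, index=ids)


class TestEwasAge:
    def test_matches_two_step_definitional_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = np.array([0.2, 0.4, 0.5, 0.4, 0.9])
        beta = BetaMatrix(pd.DataFrame({"cg1": m}, index=[f"S{i+1}" for i in range(5)]))
        tbl = ewas_age(beta, _ages(x))
        # oracle: r by definition, then the t transform
        r = (((x - x.mean()) * (m - m.mean())).sum()
             / np.sqrt(((x - x.mean()) ** 2).sum() * ((m - m.mean()) ** 2).sum()))
        t = r * np.sqrt(3) / np.sqrt(1 - r ** 2)
        p = 2 * stats.t.sf(abs(t), 3)
        assert tbl.loc["cg1", "z"] == pytest.approx(t, abs=1e-10)
        assert tbl.loc["cg1", "r"] == pytest.approx(r, abs=1e-10)
        assert tbl.loc["cg1", "p"] == pytest.approx(p, abs=1e-10)

    def test_agrees_with_regression_t_for_every_cpg(self):
        """Internal cross-check: the correlation-t and the OLS slope/SE t
        are two routes to the same statistic (agreement to 1e-8)."""
        rng = np.random.default_rng(50)
        frame = rng_beta_frame(rng, 30, 80)
        ages = _ages(rng.uniform(0.67, 13.5, 30))
        tbl = ewas_age(BetaMatrix(frame), ages)
        X = np.column_stack([np.ones(30), ages.to_numpy()])
        xtx_inv = np.linalg.inv(X.T @ X)
        for cpg in frame.columns:
            y = frame[cpg].to_numpy()
            b = xtx_inv @ X.T @ y
            resid = y - X @ b
            sigma2 = (resid @ resid) / (30 - 2)
            t_reg = b[1] / np.sqrt(sigma2 * xtx_inv[1, 1])
            assert tbl.loc[cpg, "z"] == pytest.approx(t_reg, abs=1e-8)

    def test_perfect_correlation_sentinels(self):
        ages = np.linspace(1, 10, 10)
        beta = BetaMatrix(pd.DataFrame({"cg1": ages / 20.0},
                                       index=[f"S{i+1}" for i in range(10)]))
        tbl = ewas_age(beta, _ages(ages))
        row = tbl.loc["cg1"]
        assert row["flag"] == "perfect"
        assert np.isposinf(row["z"]) and row["p"] == 0.0 and row["direction"] == 1

    def test_constant_cpg_flagged_not_silently_zero(self):
        frame = pd.DataFrame({"cg1": [0.5] * 8, "cg2": np.linspace(0.2, 0.7, 8)},
                             index=[f"S{i+1}" for i in range(8)])
        tbl = ewas_age(BetaMatrix(frame), _ages(np.arange(1.0, 9.0)))
        assert tbl.loc["cg1", "flag"] == "zero variance"
        assert np.isnan(tbl.loc["cg1", "z"])
        sel = select_top_cpgs(tbl, p_threshold=1.0)
        assert "cg1" not in sel.all_ids

    def test_pairwise_missing_removal(self):
        rng = np.random.default_rng(51)
        frame = rng_beta_frame(rng, 12, 3)
        frame.iloc[[0, 3], 0] = np.nan
        ages = _ages(rng.uniform(1, 12, 12))
        tbl = ewas_age(BetaMatrix(frame), ages)
        assert tbl.loc["cg1", "n_used"] == 10
        keep = ~frame["cg1"].isna()
        sub = BetaMatrix(frame.loc[keep, ["cg1"]])
        manual = ewas_age(sub, ages[keep])
        assert tbl.loc["cg1", "z"] == pytest.approx(manual.loc["cg1", "z"], abs=1e-12)


class TestSexAdjustedEwas:
    def test_duplicated_groups_give_null_sex_effect(self):
        rng = np.random.default_rng(52)
        half = rng_beta_frame(rng, 6, 5)
        frame = pd.concat([half, half.set_index(pd.Index([f"T{i}" for i in range(6)]))])
        ages = _ages(list(range(1, 7)) * 2, ids=list(frame.index))
        sex = _sex(["female"] * 6 + ["male"] * 6, ids=list(frame.index))
        tbl = ewas_sex_adjusted(BetaMatrix(frame), ages, sex)
        np.testing.assert_allclose(tbl["coefficient"], 0.0, atol=1e-12)
        assert (tbl["p"] > 0.99).all()

    def test_six_sample_fixture_matches_normal_equations(self):
        rng = np.random.default_rng(53)
        frame = rng_beta_frame(rng, 6, 4)
        ages = _ages([1, 3, 5, 2, 4, 6])
        sex = _sex(["female", "female", "female", "male", "male", "male"])
        tbl = ewas_sex_adjusted(BetaMatrix(frame), ages, sex)
        X = np.column_stack([np.ones(6), ages.to_numpy(),
                             (sex == "male").to_numpy().astype(float)])
        xtx_inv = np.linalg.inv(X.T @ X)
        for cpg in frame.columns:
            b = xtx_inv @ X.T @ frame[cpg].to_numpy()
            assert tbl.loc[cpg, "coefficient"] == pytest.approx(b[2], abs=1e-10)

    def test_single_sex_rejected(self):
        rng = np.random.default_rng(54)
        frame = rng_beta_frame(rng, 6, 3)
        with pytest.raises(ValueError, match="both sexes"):
            ewas_sex_adjusted(BetaMatrix(frame), _ages(range(1, 7)),
                              _sex(["female"] * 6))

    def test_planted_sex_offset_recovered_on_beta_scale(self):
        cfg = SimConfig(seed=30, n_animals=100, repeat_fraction=0.0, n_cpgs=400,
                        n_age_cpgs=0, n_sex_basal_cpgs=60, n_interaction_cpgs=0,
                        noise_sd_logit=0.3)
        beta, samples, _, truth = simulate_dataset(cfg)
        ages = samples.ages(beta.sample_ids)
        sex = samples.frame["sex"]
        tbl = ewas_sex_adjusted(beta, ages, sex)
        hits = 0
        for cpg in truth.cpg_ids_of_class("sex_basal"):
            mu = truth.cpgs.loc[cpg, "mu"]
            off = truth.cpgs.loc[cpg, "sex_offset"]
            implied = 1 / (1 + np.exp(-(mu + off))) - 1 / (1 + np.exp(-mu))
            est = tbl.loc[cpg, "coefficient"]
            se = abs(est / tbl.loc[cpg, "z"])
            hits += (est - 1.96 * se) <= implied <= (est + 1.96 * se)
        # logit-to-beta conversion is exact only at the baseline point, so
        # expect roughly nominal coverage, not certainty
        assert hits / 60 >= 0.80


class TestInteractionEwas:
    def test_identical_trends_give_null_interaction(self):
        ages = np.tile(np.arange(1.0, 7.0), 2)
        ids = [f"S{i+1}" for i in range(12)]
        trend = np.tile(0.1 + 0.05 * np.arange(1.0, 7.0), 2)
        frame = pd.DataFrame({"cg1": trend}, index=ids)
        tbl = ewas_interaction(BetaMatrix(frame), _ages(ages, ids),
                               _sex(["female"] * 6 + ["male"] * 6, ids))
        assert abs(tbl.loc["cg1", "coefficient"]) < 1e-12

    def test_eight_sample_fixture_matches_normal_equations(self):
        rng = np.random.default_rng(55)
        frame = rng_beta_frame(rng, 8, 5)
        ages = _ages([1, 4, 7, 10, 2, 5, 8, 11])
        sex = _sex(["female"] * 4 + ["male"] * 4)
        tbl = ewas_interaction(BetaMatrix(frame), ages, sex)
        male = (sex == "male").to_numpy().astype(float)
        a = ages.to_numpy()
        X = np.column_stack([np.ones(8), a, male, a * male])
        xtx_inv = np.linalg.inv(X.T @ X)
        for cpg in frame.columns:
            b = xtx_inv @ X.T @ frame[cpg].to_numpy()
            assert tbl.loc[cpg, "coefficient"] == pytest.approx(b[3], abs=1e-10)
            resid = frame[cpg].to_numpy() - X @ b
            sigma2 = (resid @ resid) / 4
            t = b[3] / np.sqrt(sigma2 * xtx_inv[3, 3])
            assert tbl.loc[cpg, "z"] == pytest.approx(t, abs=1e-10)

    def test_requires_three_per_sex(self):
        rng = np.random.default_rng(56)
        frame = rng_beta_frame(rng, 5, 3)
        with pytest.raises(ValueError, match="at least 3"):
            ewas_interaction(BetaMatrix(frame), _ages(range(1, 6)),
                             _sex(["female"] * 3 + ["male"] * 2))


class TestStratifiedEwas:
    def test_duplicated_data_relabelled_by_sex_gives_unit_correlation(self):
        rng = np.random.default_rng(57)
        half = rng_beta_frame(rng, 10, 40)
        frame = pd.concat([half, half.set_index(pd.Index([f"T{i}" for i in range(10)]))])
        ages = _ages(list(np.linspace(1, 13, 10)) * 2, ids=list(frame.index))
        sex = _sex(["female"] * 10 + ["male"] * 10, ids=list(frame.index))
        _, _, r = stratified_age_ewas(BetaMatrix(frame), ages, sex)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_sexes_correlation_near_zero(self):
        cfg = SimConfig(seed=31, n_animals=100, repeat_fraction=0.0, n_cpgs=2000,
                        n_age_cpgs=0, n_sex_basal_cpgs=0, n_interaction_cpgs=0,
                        noise_sd_logit=0.3)
        beta, samples, _, _ = simulate_dataset(cfg)
        _, _, r = stratified_age_ewas(beta, samples.ages(beta.sample_ids),
                                      samples.frame["sex"])
        assert abs(r) < 3.5 / np.sqrt(cfg.n_cpgs)

    def test_correlation_decreases_with_interaction_share(self):
        def run(n_int):
            cfg = SimConfig(seed=32, n_animals=100, repeat_fraction=0.0, n_cpgs=1000,
                            n_age_cpgs=200, n_sex_basal_cpgs=0,
                            n_interaction_cpgs=n_int, interaction_slope_logit=0.3,
                            noise_sd_logit=0.3)
            beta, samples, _, _ = simulate_dataset(cfg)
            _, _, r = stratified_age_ewas(beta, samples.ages(beta.sample_ids),
                                          samples.frame["sex"])
            return r
        r_shared, r_mixed = run(0), run(200)
        assert 0 < r_mixed < r_shared < 1


class TestSelectTopCpgs:
    @staticmethod
    def _table(z):
        n = len(z)
        z = np.asarray(z, dtype=float)
        p = 2 * stats.t.sf(np.abs(z), 50)
        return pd.DataFrame({
            "n_used": 52, "r": np.nan, "z": z, "p": p,
            "direction": np.sign(z), "flag": "ok", "screen": "age",
        }, index=pd.Index([f"cg{i:05d}" for i in range(n)], name="cpg_id"))

    def test_caps_at_500_per_direction(self):
        z = np.concatenate([np.linspace(8, 20, 700), -np.linspace(8, 20, 600),
                            np.zeros(200)])
        sel = select_top_cpgs(self._table(z))
        assert len(sel.hyper) == 500 and len(sel.hypo) == 500
        assert len(sel.all_ids) == 1000

    def test_under_cap_keeps_everything_significant(self):
        z = np.concatenate([np.full(6, 15.0), np.full(4, -15.0), np.zeros(100)])
        sel = select_top_cpgs(self._table(z))
        assert len(sel.hyper) == 6 and len(sel.hypo) == 4

    def test_tie_break_deterministic_by_id(self):
        z = np.full(12, 15.0)
        sel = select_top_cpgs(self._table(z), cap_per_direction=5)
        assert sel.hyper == [f"cg{i:05d}" for i in range(5)]

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(58)
        z = rng.normal(0, 8, 300)
        tbl = self._table(z)
        shuffled = tbl.sample(frac=1, random_state=4)
        a = select_top_cpgs(tbl, p_threshold=1e-4, cap_per_direction=30)
        b = select_top_cpgs(shuffled, p_threshold=1e-4, cap_per_direction=30)
        assert a.hyper == b.hyper and a.hypo == b.hypo
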