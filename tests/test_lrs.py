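import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from carekit._glmm import RandomTerm
from carekit.core_io import GroupMembership, Individual, ValidationError
from carekit.lrs_pipeline import (
    build_lrs_records,
    co_residence_days,
    compute_lrs,
    dispersion_parameter,
    fit_lrs_glmm,
    lrt_full_vs_null,
    stability_check,
    transform_covariates,
    vif,
)
from oracles import day_by_day_co_residence


def _kid(id_, birth, death, parent="P"):
    return Individual(id_, "male", birth, death_day=death, sire_id=parent)


class TestComputeLrs:
    def test_threshold_count(self):
        subject = Individual("P", "male", -5000)
        offspring = [
            _kid("a", 0, 400),
            _kid("b", 0, 200),
            _kid("c", 0, 366),
        ]
        assert compute_lrs(subject, offspring) == 2

    def test_no_offspring(self):
        assert compute_lrs(Individual("P", "male", -5000), []) == 0

    def test_censored_alive_all_count(self):
        subject = Individual("P", "female", -5000)
        offspring = [
            Individual(f"o{k}", "male", k, mother_id="P") for k in range(4)
        ]
        assert compute_lrs(subject, offspring) == 4

    def test_unrelated_ignored(self):
        subject = Individual("P", "male", -5000)
        assert compute_lrs(subject, [_kid("a", 0, None, parent="OTHER")]) == 0


class TestCoResidence:
    def test_father_emigrates_after_500(self):
        off = Individual("o", "male", 0)
        dad = Individual("d", "male", -4000)
        mem = [
            GroupMembership("o", "R", 0, 2000),
            GroupMembership("d", "R", -4000, 500),
        ]
        assert co_residence_days(off, dad, mem) == 500

    def test_mother_present_throughout_caps(self):
        off = Individual("o", "male", 0)
        mom = Individual("m", "female", -4000)
        mem = [
            GroupMembership("o", "R", 0, 5000),
            GroupMembership("m", "R", -4000, 5000),
        ]
        assert co_residence_days(off, mom, mem) == 1461

    def test_father_dies_on_birth_day(self):
        off = Individual("o", "male", 100)
        dad = Individual("d", "male", -4000, death_day=100)
        mem = [
            GroupMembership("o", "R", 100, 2000),
            GroupMembership("d", "R", -4000, 2000),
        ]
        assert co_residence_days(off, dad, mem) == 0

    def test_missing_membership_warns_zero(self):
        off = Individual("o", "male", 0)
        dad = Individual("d", "male", -4000)
        with pytest.warns(UserWarning):
            assert co_residence_days(off, dad, [GroupMembership("o", "R", 0, 10)]) == 0

    def test_brute_force_oracle_random_demographies(self):
        rng = np.random.default_rng(21)
        groups = ["A", "B", "C"]
        for _ in range(100):
            birth = int(rng.integers(0, 200))
            off = Individual(
                "o", "male", birth,
                death_day=int(rng.integers(birth + 1, birth + 2500)),
            )
            parent = Individual(
                "p", "female", -3000,
                death_day=int(rng.integers(birth - 50, birth + 2500))
                if rng.random() < 0.5 else None,
            )
            mem = []
            for pid in ("o", "p"):
                day = int(rng.integers(-100, 100)) if pid == "p" else birth
                for _ in range(rng.integers(1, 4)):
                    length = int(rng.integers(1, 900))
                    mem.append(
                        GroupMembership(pid, groups[rng.integers(3)], day, day + length)
                    )
                    day += length
            cap = int(rng.integers(100, 1600))
            assert co_residence_days(off, parent, mem, cap) == \
                day_by_day_co_residence(off, parent, mem, cap)


class TestTransforms:
    def _records(self, father, mother, sex=None):
        n = len(father)
        return pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(n)],
                "sex": sex or ["male"] * n,
                "father_cores_days": father,
                "mother_cores_days": mother,
            }
        )

    def test_unit_spacing(self):
        out = transform_covariates(self._records([1, 2, 3], [500, 600, 700]))
        assert out["father_cores_z"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        out = transform_covariates(
            self._records(rng.integers(0, 1461, 50).tolist(),
                          rng.integers(459, 1461, 50).tolist())
        )
        for col in ("father_cores_z", "mother_cores_logz"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_mother_error_lists_ids(self):
        with pytest.raises(ValidationError, match="i1"):
            transform_covariates(self._records([1, 2, 3], [500, 0, 700]))

    def test_log_then_z_differs_from_z_then_log(self):
        mother = [459, 500, 600, 1461]
        out = transform_covariates(self._records([0, 1, 2, 3], mother))
        v = np.array(mother, dtype=float)
        z_then_log_ok = (v - v.mean()) / v.std(ddof=1)  # z first leaves negatives
        logz = np.log(v)
        expected = (logz - logz.mean()) / logz.std(ddof=1)
        assert out["mother_cores_logz"].to_numpy() == pytest.approx(expected, abs=1e-12)
        assert not np.allclose(out["mother_cores_logz"], z_then_log_ok)


class TestVif:
    def test_orthogonal(self):
        design = pd.DataFrame({"a": [1, 1, -1, -1], "b": [1, -1, 1, -1.0]})
        out = vif(design)
        assert out["a"] == pytest.approx(1.0) and out["b"] == pytest.approx(1.0)

    def test_duplicated_infinite(self):
        x = np.random.default_rng(0).normal(size=20)
        out = vif(pd.DataFrame({"a": x, "b": x, "c": np.arange(20.0)}))
        assert out["a"] == np.inf and out["b"] == np.inf

    def test_brute_force_r2(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        df["a"] += 0.5 * df["b"]
        out = vif(df)
        X = np.column_stack([np.ones(40), df[["b", "c"]].to_numpy()])
        r2 = sm.OLS(df["a"].to_numpy(), X).fit().rsquared
        assert out["a"] == pytest.approx(1.0 / (1.0 - r2), abs=1e-10)


class TestDispersion:
    def test_exact_fit_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert dispersion_parameter(y, y, n_fixed=1) == 0.0

    def test_equidispersed_near_one(self):
        rng = np.random.default_rng(2)
        mu = np.full(2000, 3.0)
        y = rng.poisson(mu)
        assert dispersion_parameter(mu, y, n_fixed=1) == pytest.approx(1.0, abs=0.1)

    def test_overdispersed_above_one(self):
        rng = np.random.default_rng(3)
        mu = np.full(2000, 3.0)
        y = rng.negative_binomial(n=2, p=2 / (2 + 3.0), size=2000)  # mean 3, var 7.5
        assert dispersion_parameter(mu, y, n_fixed=1) > 1.2

    def test_zero_mu_rejected(self):
        with pytest.raises(ValidationError):
            dispersion_parameter(np.array([0.0, 1.0]), np.array([0.0, 1.0]), 1)


def _sim_lrs_records(seed=0, n=200, beta=(1.0, -0.25, -0.05, 0.37), re_sd=0.0):
    rng = np.random.default_rng(seed)
    father = rng.integers(0, 1462, n)
    mother = rng.integers(459, 1462, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    records = pd.DataFrame(
        {
            "id": [f"i{k}" for k in range(n)],
            "sex": sex,
            "father_cores_days": father,
            "mother_cores_days": mother,
            "mother_id": [f"D{k % 20}" for k in range(n)],
            "sire_id": [f"S{k % 20}" for k in range(n)],
            "cohort": [f"K{k % 8}" for k in range(n)],
            "birth_group": [f"G{k % 4}" for k in range(n)],
        }
    )
    design = transform_covariates(records)
    lp = (
        beta[0]
        + beta[1] * design["sex_male"].to_numpy()
        + beta[2] * design["father_cores_z"].to_numpy()
        + beta[3] * design["mother_cores_logz"].to_numpy()
    )
    if re_sd > 0:
        for col in ("mother_id", "sire_id", "cohort", "birth_group"):
            levels = {l: rng.normal(0, re_sd) for l in records[col].unique()}
            lp = lp + records[col].map(levels).to_numpy()
    records["lrs"] = rng.poisson(np.exp(lp))
    return records


class TestGlmm:
    def test_zero_variance_limit_matches_glm(self):
        records = _sim_lrs_records(seed=5)
        fit = fit_lrs_glmm(records)
        design = transform_covariates(records)
        X = np.column_stack(
            [np.ones(len(records)), design["sex_male"],
             design["father_cores_z"], design["mother_cores_logz"]]
        )
        glm = sm.GLM(records["lrs"].to_numpy(float), X,
                     family=sm.families.Poisson()).fit()
        assert np.abs(fit.beta - glm.params).max() < 1e-3

    def test_null_nested_in_full(self):
        records = _sim_lrs_records(seed=6, re_sd=0.15)
        full = fit_lrs_glmm(records)
        null = fit_lrs_glmm(records, include_fixed=False)
        assert null.loglik <= full.loglik + 1e-6

    def test_lrt_df_and_identity(self):
        records = _sim_lrs_records(seed=7)
        full = fit_lrs_glmm(records)
        null = fit_lrs_glmm(records, include_fixed=False)
        stat, df, p = lrt_full_vs_null(full, null)
        assert df == 3
        s0, _, p0 = lrt_full_vs_null(full, full)
        assert s0 == 0.0 and p0 == 1.0

    def test_mother_coefficient_recovery(self):
        ests = []
        for seed in range(10):
            records = _sim_lrs_records(seed=100 + seed, n=400, re_sd=0.1)
            fit = fit_lrs_glmm(records)
            ests.append(fit.beta[fit.fixed_names.index("mother_cores_logz")])
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.37) < 3 * mc_se + 0.02

    def test_random_term_design(self):
        term = RandomTerm.from_labels("f", ["a", "b", "a"], np.array([2.0, 3.0, 4.0]))
        Z = term.design()
        assert Z.shape == (3, 2)
        assert Z[0, 0] == 2.0 and Z[1, 1] == 3.0 and Z[2, 0] == 4.0

    def test_positive_random_variance_detected(self):
        records = _sim_lrs_records(seed=8, n=400, re_sd=0.4)
        fit = fit_lrs_glmm(records, random_slopes=False)
        assert fit.theta.max() > 0.15


class TestStability:
    def test_refit_count_structural(self):
        records = _sim_lrs_records(seed=9, n=120)
        out = stability_check(records, random_slopes=False,
                              factors=("cohort", "birth_group"))
        refits = out[(out["factor"] != "(all data)") & ~out["failed"]]
        levels = records["cohort"].nunique() + records["birth_group"].nunique()
        assert refits.groupby(["factor", "level"]).ngroups == levels

    def test_balanced_data_small_ranges(self):
        records = _sim_lrs_records(seed=10, n=240)
        out = stability_check(records, random_slopes=False, factors=("birth_group",))
        sub = out[(out["factor"] == "birth_group") & (out["effect"] == "mother_cores_logz")]
        assert sub["estimate"].max() - sub["estimate"].min() < 0.5

    def test_influential_level_shifts_intercept(self):
        records = _sim_lrs_records(seed=11, n=120)
        records.loc[records["birth_group"] == "G0", "lrs"] += 30
        out = stability_check(records, random_slopes=False, factors=("birth_group",))
        sub = out[(out["factor"] == "birth_group") & (out["effect"] == "intercept")]
        dropped_g0 = sub[sub["level"] == "G0"]["estimate"].item()
        others = sub[sub["level"] != "G0"]["estimate"]
        assert (others - dropped_g0).abs().min() > 0.1


class TestBuildRecords:
    def test_pipeline_matches_generator_truth(self, default_sim):
        records = build_lrs_records(default_sim.lrs_individuals,
                                    default_sim.lrs_memberships)
        truth = default_sim.lrs_truth.set_index("id")
        merged = records.set_index("id")
        assert len(records) == len(truth)
        assert (merged["father_cores_days"] == truth["f_days"]).all()
        assert (merged["mother_cores_days"] == truth["m_days"]).all()
        assert (merged["lrs"] == truth["lrs"]).all()

    def test_bateman_variance(self, default_sim):
        records = build_lrs_records(default_sim.lrs_individuals,
                                    default_sim.lrs_memberships)
        male_var = records.loc[records["sex"] == "male", "lrs"].var()
        female_var = records.loc[records["sex"] == "female", "lrs"].var()
        assert male_var > female_var
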