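import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from ffrcea.patient_level import (
    bootstrap_icer,
    cox_fit,
    group_cea,
    km_cumulative_incidence,
    patient_cost,
    patient_qaly,
    subgroup_cea,
)
from ffrcea.synthetic import default_config, generate_cohort


def make_records(**columns):
    n = max(len(v) for v in columns.values())
    base = {
        "arm": ["angio"] * n,
        "time_death": [np.nan] * n,
        "time_mi": [np.nan] * n,
        "time_revasc": [np.nan] * n,
        "time_censor": [4.0] * n,
    }
    base.update(columns)
    return pd.DataFrame(base)


class TestPatientQaly:
    def test_event_free_four_years(self, korea_utilities):
        rec = make_records(time_censor=[4.0])
        assert patient_qaly(rec, korea_utilities, 4.0)[0] == pytest.approx(0.79 * 4)

    def test_death_at_entry(self, korea_utilities):
        rec = make_records(time_death=[0.0])
        assert patient_qaly(rec, korea_utilities, 4.0)[0] == 0.0

    def test_mi_then_survival(self, korea_utilities):
        rec = make_records(time_mi=[1.0])
        expected = 0.79 * 1 + 0.67 * 3
        assert patient_qaly(rec, korea_utilities, 4.0)[0] == pytest.approx(expected)

    def test_mi_after_death_is_data_error(self, korea_utilities):
        rec = make_records(time_death=[1.0], time_mi=[2.0])
        with pytest.raises(ValueError, match="MI recorded after death"):
            patient_qaly(rec, korea_utilities, 4.0)

    def test_bounded_by_full_health_horizon(self, korea_utilities, small_cohort):
        q = patient_qaly(small_cohort, korea_utilities, 4.0)
        assert np.all(q >= 0)
        assert np.all(q <= korea_utilities.u_angina * 4.0 + 1e-12)


class TestPatientCost:
    def test_no_cost_columns_gives_zero(self):
        rec = make_records(time_censor=[4.0])
        assert patient_cost(rec, 4.0)[0] == 0.0

    def test_constant_stream_full_horizon(self):
        rec = make_records(
            cost_year_0=[0.0], cost_year_1=[1483.0], cost_year_2=[2966.0],
            cost_year_3=[4449.0], cost_year_4=[5932.0],
        )
        assert patient_cost(rec, 4.0)[0] == pytest.approx(5932.0)

    def test_truncation_at_death(self):
        rec = make_records(
            time_death=[2.0],
            cost_year_0=[0.0], cost_year_1=[100.0], cost_year_2=[200.0],
            cost_year_3=[999.0], cost_year_4=[999.0],
        )
        assert patient_cost(rec, 4.0)[0] == pytest.approx(200.0)

    def test_linear_interpolation_within_year(self):
        rec = make_records(
            time_censor=[1.5],
            cost_year_0=[0.0], cost_year_1=[100.0], cost_year_2=[300.0],
        )
        assert patient_cost(rec, 4.0)[0] == pytest.approx(200.0)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_fraction(self):
        deaths = [0.5, 1.5] + [np.nan] * 8
        rec = make_records(time_death=deaths, time_censor=[10.0] * 10)
        assert km_cumulative_incidence(rec, "death", 4.0) == pytest.approx(0.20)

    def test_hand_product_limit(self):
        # events at 1 and 3; censored at 2, 4, 5 -> S(3) = 4/5 * 2/3
        rec = make_records(
            time_death=[1.0, 3.0, np.nan, np.nan, np.nan],
            time_censor=[9.0, 9.0, 2.0, 4.0, 5.0],
        )
        assert km_cumulative_incidence(rec, "death", 3.5) == pytest.approx(1 - 0.8 * 2 / 3)

    def test_zero_censoring_matches_ecdf_everywhere(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(3.0, 200)
        rec = make_records(time_death=list(t), time_censor=[1e9] * 200)
        for q in (0.5, 1.0, 2.0, 5.0):
            assert km_cumulative_incidence(rec, "death", q) == pytest.approx(
                (t <= q).mean(), abs=1e-12
            )

    def test_evaluation_beyond_followup_warns(self):
        rec = make_records(time_death=[1.0, np.nan], time_censor=[5.0, 2.0])
        with pytest.warns(UserWarning, match="longest follow-up"):
            km_cumulative_incidence(rec, "death", 50.0)

    def test_death_censors_nonfatal_events(self):
        # the MI at t=3 is never observed: the patient died at t=2
        rec = make_records(
            time_death=[2.0, np.nan], time_mi=[np.nan, 1.0], time_censor=[6.0, 6.0]
        )
        assert km_cumulative_incidence(rec, "mi", 2.0) == pytest.approx(0.5)


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        """Four-subject worked example against direct likelihood maximization."""
        rec = make_records(
            time_death=[1.0, 2.0, np.nan, 4.0],
            time_censor=[10.0, 10.0, 3.0, 10.0],
            x=[1.0, 0.0, 1.0, 0.0],
        )
        fit = cox_fit(rec, ["x"], "death")

        def neg_log_pl(beta):
            # risk sets at event times 1, 2, 4 with covariates as above
            ll = beta * 1 - np.log(2 * np.exp(beta) + 2)  # t=1, x=1
            ll += 0.0 - np.log(np.exp(beta) + 2)          # t=2, x=0 (subjects 2,3,4)
            ll += 0.0 - np.log(1.0)                       # t=4, x=0 (subject 4)
            return -ll

        brute = minimize_scalar(neg_log_pl, bounds=(-5, 5), method="bounded")
        assert fit.coefficients["x"] == pytest.approx(brute.x, abs=1e-6)
        assert fit.log_partial_likelihood == pytest.approx(-brute.fun, abs=1e-6)

    def test_null_effect_ci_coverage(self):
        """With no true arm effect the 95% CI covers HR=1 at ~nominal rate."""
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            n = 120
            arm = rng.random(n) < 0.5
            t = rng.exponential(2.0, n)
            rec = make_records(
                arm=np.where(arm, "ffr", "angio"),
                time_death=list(t),
                time_censor=[4.0] * n,
            )
            fit = cox_fit(rec, ["arm"], "death")
            _, lo, hi = fit.hr("arm")
            hits += lo <= 1.0 <= hi
        assert hits / n_rep >= 0.93

    def test_recovers_generator_arm_effect(self):
        cohort = generate_cohort(default_config(n_patients=40_000, p_ffr=0.5, seed=17))
        fit = cox_fit(cohort, ["arm"], "death")
        beta = fit.coefficients["arm"]
        se = fit.standard_errors["arm"]
        assert abs(beta - np.log(0.798)) < 2 * se

    def test_constant_covariate_rejected(self, small_cohort):
        df = small_cohort.copy()
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["flat"], "death")


class TestGroupCea:
    def _mirrored_cohort(self):
        cfg = default_config(n_patients=1500, p_ffr=0.0, seed=5)
        a = generate_cohort(cfg)
        b = a.copy()
        b["arm"] = "ffr"
        return pd.concat([a, b], ignore_index=True)

    def test_identical_arms_give_null_increments(self, korea_utilities):
        both = self._mirrored_cohort()
        res = group_cea(both, korea_utilities, 4.0)
        assert res.delta_cost == 0.0
        assert res.delta_qaly == 0.0
        assert res.icer is None

    def test_single_arm_rejected(self, korea_utilities):
        cohort = generate_cohort(default_config(n_patients=100, p_ffr=0.0, seed=1))
        with pytest.raises(ValueError, match="both arms"):
            group_cea(cohort, korea_utilities, 4.0)

    def test_ffr_gains_qalys_in_default_cohort(self, korea_utilities, small_cohort):
        res = group_cea(small_cohort, korea_utilities, 4.0)
        assert res.delta_qaly > 0

    def test_bootstrap_single_replicate_interval(self, korea_utilities, small_cohort):
        res = bootstrap_icer(small_cohort, korea_utilities, 4.0, n_boot=1, seed=0)
        assert res.ci_delta_qaly[0] == pytest.approx(res.boot_delta_qaly[0])
        assert res.ci_delta_qaly[1] == pytest.approx(res.boot_delta_qaly[0])

    def test_bootstrap_identical_arms_interval_contains_zero(self, korea_utilities):
        both = self._mirrored_cohort()
        res = bootstrap_icer(both, korea_utilities, 4.0, n_boot=1000, seed=3)
        lo, hi = res.ci_delta_qaly
        assert lo <= 0.0 <= hi
        lo, hi = res.ci_delta_cost
        assert lo <= 0.0 <= hi

    def test_bootstrap_interval_brackets_point_estimate(self, korea_utilities, small_cohort):
        res = bootstrap_icer(small_cohort, korea_utilities, 4.0, n_boot=1000, seed=9)
        assert res.ci_delta_qaly[0] <= res.delta_qaly <= res.ci_delta_qaly[1]


class TestSubgroups:
    def test_all_predicate_equals_group_cea(self, korea_utilities, small_cohort):
        full = group_cea(small_cohort, korea_utilities, 4.0)
        sub = subgroup_cea(
            small_cohort, lambda df: np.ones(len(df), bool), korea_utilities, 4.0
        )
        assert sub == full

    def test_complementary_subgroups_partition_cohort(self, korea_utilities, small_cohort):
        with_dm = subgroup_cea(
            small_cohort, lambda df: df["diabetes"] == 1, korea_utilities, 4.0
        )
        without = subgroup_cea(
            small_cohort, lambda df: df["diabetes"] == 0, korea_utilities, 4.0
        )
        total = with_dm.n_angio + with_dm.n_ffr + without.n_angio + without.n_ffr
        assert total == len(small_cohort)

    def test_result_schema_mirrors_main_table(self, korea_utilities, small_cohort):
        sub = subgroup_cea(
            small_cohort, lambda df: df["diabetes"] == 1, korea_utilities, 4.0
        )
        d = sub.to_dict()
        for key in (
            "mean_cost_angio", "mean_cost_ffr", "mean_qaly_angio",
            "mean_qaly_ffr", "delta_cost", "delta_qaly", "icer",
        ):
            assert key in d

    def test_empty_subgroup_names_predicate(self, korea_utilities, small_cohort):
        with pytest.raises(ValueError, match="nobody"):
            subgroup_cea(
                small_cohort, lambda df: np.zeros(len(df), bool),
                korea_utilities, 4.0, name="nobody",
            )
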