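"""Risk-model evaluation, time-updating, conversion, and the sim engine."""

import math

import numpy as np
import pytest

import wtclung as w
from wtclung.microsim import (MonthlySchedule, RiskModelCoefficients,
                              RiskModelTerm, RiskProfile, analytic_expected,
                              build_schedules, draw_event_months,
                              load_bundled_model)

from conftest import make_participants


def profile(**kw):
    base = dict(age=55.0, education_ord=3.0, bmi=27.0, copd=False,
                prior_cancer=False, family_history=False, race="nl_white",
                smoking_status="never", intensity=0.0, duration=0.0,
                quit_years=0.0)
    base.update(kw)
    return RiskProfile(**base)


def model(intercept=0.0, terms=()):
    return RiskModelCoefficients(intercept=intercept, terms=tuple(terms))


class TestSixYearProb:
    def test_all_zero_gives_half(self):
        assert w.six_year_prob(profile(), model()) == pytest.approx(0.5)

    def test_hand_computed_linear_predictor(self):
        m = model(-5.0, [RiskModelTerm("age", 0.05, "age")])
        p = w.six_year_prob(profile(age=60), m)
        assert p == pytest.approx(1 / (1 + math.exp(2)), rel=1e-12)  # 0.1192

    def test_monotone_in_age(self):
        m = model(-5.0, [RiskModelTerm("age", 0.05, "age")])
        assert w.six_year_prob(profile(age=70), m) > \
            w.six_year_prob(profile(age=50), m)

    def test_missing_covariate_named(self):
        m = model(0.0, [RiskModelTerm("bmi", 0.1, "bmi")])
        with pytest.raises(w.ValidationError, match="bmi"):
            w.six_year_prob(profile(bmi=float("nan")), m)

    def test_never_smoker_reference_for_smoker_terms(self):
        m = model(-3.0, [RiskModelTerm("intensity", -1.8, "cigs_per_day",
                                       transform="inverse_div10",
                                       center=0.4, smoker_only=True)])
        # never smoker: the (cpd/10)^-1 term would blow up at cpd=0 but is
        # skipped at reference level
        p = w.six_year_prob(profile(), m)
        assert p == pytest.approx(1 / (1 + math.exp(3)))


class TestUpdateProfile:
    def test_current_smoker_keeps_smoking(self):
        p = w.update_profile(profile(smoking_status="current", age=50,
                                     duration=30, intensity=15))
        assert (p.age, p.duration, p.intensity) == (56, 36, 15)

    def test_former_smoker_continues_cessation(self):
        p = w.update_profile(profile(smoking_status="former", duration=10,
                                     intensity=10, quit_years=4))
        assert p.quit_years == 10 and p.duration == 10

    def test_never_smoker_only_ages(self):
        before = profile()
        after = w.update_profile(before)
        assert after.age == before.age + 6
        assert (after.duration, after.intensity, after.quit_years) == (0, 0, 0)


class TestMonthlyProb:
    @pytest.mark.parametrize("p6,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_endpoints(self, p6, expected):
        assert w.monthly_prob(p6) == expected

    def test_direct_evaluation(self):
        p = w.monthly_prob(0.06)
        assert p == pytest.approx(1 - 0.94 ** (1 / 72), rel=1e-12)
        assert p == pytest.approx(8.5901e-4, abs=1e-7)
        assert (1 - p) ** 72 == pytest.approx(0.94, rel=1e-12)

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(w.ValidationError):
                w.monthly_prob(bad)

    def test_roundtrip_identity_on_grid(self):
        for p6 in np.linspace(0.0, 0.999, 241):
            p = w.monthly_prob(p6)
            assert abs((1 - p) ** 72 - (1 - p6)) < 1e-12


class TestBuildSchedule:
    def _row(self, person_years, **kw):
        df = make_participants([kw])
        row = df.iloc[0].copy()
        row["person_years"] = person_years
        return row

    def test_single_window(self, toy_model):
        s = w.build_schedule(self._row(5.0), toy_model)
        assert s.n_months == 60
        assert np.allclose(s.monthly_probs, s.monthly_probs[0])

    def test_second_window_starts_at_month_73(self, toy_model):
        s = w.build_schedule(self._row(7.0, smoking_status="current",
                                       cigarettes_per_day=20,
                                       smoking_duration=20, pack_years=20),
                             toy_model)
        assert s.n_months == 84
        assert np.allclose(s.monthly_probs[:72], s.monthly_probs[0])
        assert np.allclose(s.monthly_probs[72:], s.monthly_probs[72])
        assert s.monthly_probs[72] != s.monthly_probs[0]
        # risk grows with the time-update for a continuing smoker
        assert s.window_probs[0] < s.window_probs[1] < s.window_probs[2]

    def test_long_followup_reuses_last_window(self, toy_model):
        long_row = self._row(20.0)  # 240 months > 3 windows
        s = w.build_schedule(long_row, toy_model)
        assert s.n_months == 240
        assert np.allclose(s.monthly_probs[216:], s.monthly_probs[215])

    def test_zero_person_years_empty_schedule(self, toy_model):
        s = w.build_schedule(self._row(0.0), toy_model)
        assert s.n_months == 0


def sched(pid, probs):
    return MonthlySchedule(pid, np.asarray(probs, dtype=float), (0, 0, 0))


class TestSimulateAndOracle:
    def test_zero_probability_zero_cases(self):
        rng = np.random.default_rng(0)
        assert w.simulate_replicate([sched("a", [0] * 12)] * 5, rng) == 0

    def test_certain_first_month_all_cases(self):
        rng = np.random.default_rng(0)
        schedules = [sched(str(i), [1.0] + [0.0] * 5) for i in range(7)]
        assert w.simulate_replicate(schedules, rng) == 7

    def test_binomial_closed_form(self):
        n, p, months = 10000, 0.001, 36
        q = 1 - (1 - p) ** months
        schedules = [sched(str(i), [p] * months) for i in range(n)]
        cases = w.simulate_replicate(schedules, np.random.default_rng(1))
        assert abs(cases - n * q) < 3 * math.sqrt(n * q * (1 - q))

    def test_analytic_expected_enumeration(self):
        # 2 people x 2 months at p=0.5: per person 1-(0.5)^2 = 0.75
        schedules = [sched("a", [0.5, 0.5]), sched("b", [0.5, 0.5])]
        assert analytic_expected(schedules) == pytest.approx(1.5)
        assert analytic_expected([]) == 0.0
        assert analytic_expected([sched("c", [0.3])]) == pytest.approx(0.3)

    def test_monotonicity_in_schedule_probs(self, analytic_cohort, toy_model):
        schedules = build_schedules(analytic_cohort, toy_model)[:200]
        bumped = [sched(s.person_id, np.minimum(s.monthly_probs * 1.5, 0.99))
                  for s in schedules if s.n_months]
        kept = [s for s in schedules if s.n_months]
        assert analytic_expected(bumped) >= analytic_expected(kept)

    def test_expected_invariant_to_ordering(self, analytic_cohort, toy_model):
        schedules = build_schedules(analytic_cohort, toy_model)
        rng = np.random.default_rng(3)
        perm = list(rng.permutation(len(schedules)))
        assert analytic_expected([schedules[i] for i in perm]) == \
            pytest.approx(analytic_expected(schedules), rel=1e-12)

    def test_draw_event_months_within_own_schedule(self):
        schedules = [sched("a", [0.2] * 6), sched("b", [0.9] * 60)]
        months = draw_event_months(schedules, np.random.default_rng(4))
        assert months[0] <= 6 and months[1] <= 60


class TestRunMicrosim:
    def test_deterministic_given_seed(self, analytic_cohort, toy_model):
        a = w.run_microsim(analytic_cohort, toy_model, n_reps=5, seed=9)
        b = w.run_microsim(analytic_cohort, toy_model, n_reps=5, seed=9)
        assert np.array_equal(a.replicate_counts, b.replicate_counts)
        assert a.expected_rate == b.expected_rate

    def test_zero_risk_zero_rate(self):
        df = make_participants([{}] * 10)
        cohort = w.apply_eligibility(df)
        null = RiskModelCoefficients(intercept=-60.0, terms=())
        out = w.run_microsim(cohort, null, n_reps=3, seed=1)
        assert out.expected_rate == pytest.approx(0.0, abs=1e-6)

    def test_nreps_validation(self, analytic_cohort, toy_model):
        with pytest.raises(w.ConfigError):
            w.run_microsim(analytic_cohort, toy_model, n_reps=0, seed=1)

    def test_mean_matches_analytic_expectation(self, analytic_cohort, toy_model):
        sim = w.run_microsim(analytic_cohort, toy_model, n_reps=30, seed=10)
        expected = analytic_expected(build_schedules(analytic_cohort, toy_model))
        se = sim.replicate_counts.std(ddof=1) / math.sqrt(sim.n_reps)
        assert abs(sim.mean_cases - expected) < 3 * se
        assert sim.expected_rate == pytest.approx(
            sim.mean_cases / analytic_cohort.total_person_years * 1e5)


class TestCoefficientFiles:
    def test_bundled_models_load(self):
        for name in ("plco2012", "toy"):
            m = load_bundled_model(name)
            assert math.isfinite(m.intercept) and len(m.terms) > 0

    def test_checksum_guard(self, tmp_path):
        import yaml
        path = tmp_path / "bad.yaml"
        doc = {"name": "bad", "intercept": -1.0, "sha256": "0" * 64,
               "terms": [{"name": "age", "coef": 0.1, "var": "age"}]}
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(w.ConfigError, match="checksum"):
            RiskModelCoefficients.from_yaml(path)

    def test_unknown_covariate_rejected(self):
        with pytest.raises(w.ConfigError, match="unknown"):
            model(0.0, [RiskModelTerm("x", 1.0, "not_a_var")])

    def test_plco_scores_plausible_sixty_year_old_smoker(self):
        m = load_bundled_model("plco2012")
        p = w.six_year_prob(profile(age=62, education_ord=4, bmi=27,
                                    smoking_status="current", intensity=20,
                                    duration=40, quit_years=0), m)
        # heavy current smoker at the centering age: percent-scale risk
        assert 0.01 < p < 0.10
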