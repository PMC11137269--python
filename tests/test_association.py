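"""Adjusted odds-ratio models: closed forms, oracle fits, invariances."""

import numpy as np
import pytest
from scipy import optimize

import multipattern as mp
from multipattern.association import Z_95
from multipattern.errors import InconsistencyError, SeparationError

def _patient(pid, pattern, dead=False, sex="F", age=40, acute=()):
    conds = frozenset({"A", "B"})
    status = "dead" if dead else "included"
    return mp.PatientRecord(
        patient_id=pid, sex=sex, age_at_baseline=age,
        status_per_wave={"2015": status, "2019": status},
        chronic_conditions_per_wave={"2011": conds, "2015": conds, "2019": conds},
        acute_diagnoses=list(acute),
    )


def _two_by_two(a, b, c, d):
    """a exposed-dead, b exposed-alive, c unexposed-dead, d unexposed-alive."""
    patients, labels = [], {}
    pid = 0
    for pattern, dead, count in ((1, True, a), (1, False, b), (0, True, c), (0, False, d)):
        for _ in range(count):
            patients.append(_patient(f"p{pid}", pattern, dead=dead))
            labels[f"p{pid}"] = pattern
            pid += 1
    return patients, labels


def test_unadjusted_or_matches_two_by_two_closed_form():
    patients, labels = _two_by_two(10, 90, 30, 70)
    res = mp.fit_logistic_mortality(
        patients, labels, horizon_wave="2015", covariates=(), reference=0
    )
    assert res.by_level("1").odds_ratio == pytest.approx((10 * 70) / (90 * 30), rel=1e-6)
    ref = res.by_level("0")
    assert ref.is_reference and ref.odds_ratio == 1.0


def test_reference_is_lowest_crude_mortality_pattern():
    patients, labels = _two_by_two(10, 90, 30, 70)   # pattern 1 has lower rate
    res = mp.fit_logistic_mortality(patients, labels, horizon_wave="2015", covariates=())
    assert res.reference == "1"
    assert res.by_level("0").odds_ratio == pytest.approx((30 * 90) / (70 * 10), rel=1e-6)


def test_wald_ci_is_exp_of_coef_pm_z_se():
    patients, labels = _two_by_two(10, 90, 30, 70)
    res = mp.fit_logistic_mortality(patients, labels, horizon_wave="2015", covariates=())
    e = res.by_level("0")
    assert e.ci_low == pytest.approx(np.exp(e.coef - Z_95 * e.se))
    assert e.ci_high == pytest.approx(np.exp(e.coef + Z_95 * e.se))
    assert e.ci_low <= e.odds_ratio <= e.ci_high


def _simulate(seed, n=400, beta_pattern=0.8):
    rng = np.random.default_rng(seed)
    age = rng.integers(18, 66, size=n)
    female = rng.random(n) < 0.55
    pattern = rng.integers(0, 2, size=n)
    lp = -4.0 + 0.05 * age - 0.3 * female + beta_pattern * pattern
    dead = rng.random(n) < 1 / (1 + np.exp(-lp))
    patients, labels = [], {}
    for i in range(n):
        patients.append(
            _patient(
                f"p{i}", pattern[i], dead=bool(dead[i]),
                sex="F" if female[i] else "M", age=int(age[i]),
            )
        )
        labels[f"p{i}"] = int(pattern[i])
    return patients, labels


def test_coefficients_match_generic_optimiser_oracle():
    """Newton fit equals direct maximisation of the same Bernoulli
    log-likelihood by an independent optimiser."""
    patients, labels = _simulate(3)
    res = mp.fit_logistic_mortality(patients, labels, horizon_wave="2015", reference=0)
    y = np.array([1 if p.status("2015") == "dead" else 0 for p in patients])
    X = np.column_stack(
        [
            np.ones(len(patients)),
            [p.age_at_baseline for p in patients],
            [1.0 if p.is_female else 0.0 for p in patients],
            [labels[p.patient_id] for p in patients],
        ]
    )

    def nll(beta):
        lp = X @ beta
        return -(y * lp - np.log1p(np.exp(lp))).sum()

    def grad(beta):
        mu = 1 / (1 + np.exp(-(X @ beta)))
        return X.T @ (mu - y)

    opt = optimize.minimize(
        nll, np.zeros(4), jac=grad, method="BFGS", options={"gtol": 1e-10}
    )
    fitted = np.array(
        [
            res.covariate_effects["const"].coef,
            res.covariate_effects["age"].coef,
            res.covariate_effects["female"].coef,
            res.by_level("1").coef,
        ]
    )
    np.testing.assert_allclose(fitted, opt.x, atol=1e-6)


def test_age_shift_changes_only_the_intercept():
    patients, labels = _simulate(5)
    res1 = mp.fit_logistic_mortality(patients, labels, horizon_wave="2015", reference=0)
    shifted = [
        mp.PatientRecord(
            patient_id=p.patient_id, sex=p.sex,
            age_at_baseline=p.age_at_baseline + 10,
            status_per_wave=p.status_per_wave,
            chronic_conditions_per_wave=p.chronic_conditions_per_wave,
            acute_diagnoses=p.acute_diagnoses, dispensations=p.dispensations,
        )
        for p in patients
    ]
    res2 = mp.fit_logistic_mortality(shifted, labels, horizon_wave="2015", reference=0)
    assert res2.by_level("1").coef == pytest.approx(res1.by_level("1").coef, abs=1e-6)
    assert res2.covariate_effects["age"].coef == pytest.approx(
        res1.covariate_effects["age"].coef, abs=1e-6
    )
    assert res2.covariate_effects["const"].coef != pytest.approx(
        res1.covariate_effects["const"].coef, abs=1e-3
    )


def test_perfect_separation_raises():
    patients, labels = _two_by_two(50, 0, 0, 50)
    with pytest.raises(SeparationError):
        mp.fit_logistic_mortality(
            patients, labels, horizon_wave="2015", covariates=()
        )


def test_lost_patients_are_excluded_from_mortality_denominator():
    patients, labels = _two_by_two(10, 90, 30, 70)
    lost = _patient("lost0", 0)
    lost.status_per_wave = {"2015": "lost", "2019": "lost"}
    labels["lost0"] = 0
    res = mp.fit_logistic_mortality(
        patients + [lost], labels, horizon_wave="2015", covariates=()
    )
    assert res.n == 200
    res2 = mp.fit_logistic_mortality(
        patients + [lost], labels, horizon_wave="2015", covariates=(),
        include_lost_as_alive=True,
    )
    assert res2.n == 201


# -------------------------------------------------------------- multinomial

def _acute_cohort(seed, n=2000, p_acute=(0.3, 0.3), n_patterns=2):
    rng = np.random.default_rng(seed)
    patients, labels = [], {}
    for i in range(n):
        pat = int(rng.integers(0, n_patterns))
        acute = [("ACU00", 1)] if rng.random() < p_acute[pat] else []
        patients.append(
            _patient(
                f"p{i}", pat, sex="F" if rng.random() < 0.5 else "M",
                age=int(rng.integers(18, 66)), acute=acute,
            )
        )
        labels[f"p{i}"] = pat
    return patients, labels


def test_two_category_multinomial_equals_binary_logistic():
    patients, labels = _acute_cohort(11, n=800, p_acute=(0.2, 0.5))
    res = mp.fit_multinomial_acute(patients, labels, "ACU00", 1, reference=0)
    # oracle: binary logit of pattern membership on (const, age, female, acute)
    import statsmodels.api as sm

    y = np.array([labels[p.patient_id] for p in patients])
    X = np.column_stack(
        [
            np.ones(len(patients)),
            [p.age_at_baseline for p in patients],
            [1.0 if p.is_female else 0.0 for p in patients],
            [1.0 if ("ACU00", 1) in p.acute_diagnoses else 0.0 for p in patients],
        ]
    )
    fit = sm.Logit(y, X).fit(disp=0)
    assert res.by_level("1").coef == pytest.approx(fit.params[3], abs=1e-6)
    assert res.by_level("1").se == pytest.approx(fit.bse[3], abs=1e-6)


def test_planted_acute_enrichment_is_detected():
    patients, labels = _acute_cohort(13, n=20000, p_acute=(0.3, 0.3, 0.6), n_patterns=3)
    res = mp.fit_multinomial_acute(patients, labels, "ACU00", 1)
    enriched = res.by_level("2")
    assert enriched.ci_low > 1.0
    null = res.by_level("1") if res.reference == "0" else res.by_level("0")
    assert null.ci_low < 1.0 < null.ci_high


def test_reference_is_smallest_pattern():
    rng = np.random.default_rng(17)
    patients, labels = [], {}
    sizes = {0: 50, 1: 20, 2: 100}
    pid = 0
    for pat, size in sizes.items():
        for _ in range(size):
            acute = [("ACU00", 1)] if rng.random() < 0.4 else []
            patients.append(_patient(f"p{pid}", pat, acute=acute, age=int(rng.integers(18, 66))))
            labels[f"p{pid}"] = pat
            pid += 1
    res = mp.fit_multinomial_acute(patients, labels, "ACU00", 1, covariates=())
    assert res.reference == "1"


def test_constant_acute_indicator_is_an_error():
    patients, labels = _acute_cohort(19, n=50, p_acute=(0.0, 0.0))
    with pytest.raises(InconsistencyError):
        mp.fit_multinomial_acute(patients, labels, "ACU00", 1)
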