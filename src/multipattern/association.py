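"""Age- and sex-adjusted associations between patterns and outcomes.

Two model families:

* binary logistic regression of death-by-horizon on pattern membership
  (dummy-coded against the pattern with the lowest crude mortality rate),
  adjusting for age in years and sex;
* multinomial logistic regression with pattern membership as the outcome
  (baseline category = the smallest pattern, i.e. lowest wave prevalence)
  and an acute-disease exposure indicator plus age and sex as covariates.

Effects are reported as odds ratios with Wald 95% confidence intervals,
OR = exp(beta), CI = exp(beta ± 1.96·SE).  Patients lost to follow-up
before the mortality horizon are excluded (their vital status is unknown);
a flag re-includes them as alive for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .cohort import DEAD, LOST, WAVES, PatientRecord
from .errors import ConvergenceError, InconsistencyError, SeparationError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class EffectEstimate:
    """One exposure level's effect on the log-odds scale and as an OR."""

    level: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    is_reference: bool = False


@dataclass
class AssociationResult:
    outcome: str
    reference: str
    reference_rule: str
    effects: list[EffectEstimate]
    covariate_effects: dict[str, EffectEstimate]
    covariates: tuple[str, ...]
    n: int
    converged: bool
    n_iter: int
    log_likelihood: float

    def by_level(self, level: str) -> EffectEstimate:
        for e in self.effects:
            if e.level == level:
                return e
        raise KeyError(level)


def _effect(level: str, coef: float, se: float) -> EffectEstimate:
    return EffectEstimate(
        level=level,
        coef=float(coef),
        se=float(se),
        odds_ratio=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z_95 * se)),
        ci_high=float(np.exp(coef + Z_95 * se)),
    )


def _records(
    patients: Sequence[PatientRecord] | Mapping[str, PatientRecord],
) -> dict[str, PatientRecord]:
    if isinstance(patients, Mapping):
        return dict(patients)
    return {p.patient_id: p for p in patients}


def _fit_logit(y: np.ndarray, X: pd.DataFrame, model_cls=sm.Logit):
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = model_cls(y, X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=0
            )
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"Newton iterations did not converge: {fit.mle_retvals}"
        )
    return fit


def fit_logistic_mortality(
    patients: Sequence[PatientRecord] | Mapping[str, PatientRecord],
    labels: Mapping[str, int],
    horizon_wave: str = WAVES[-1],
    covariates: tuple[str, ...] = ("age", "sex"),
    include_lost_as_alive: bool = False,
    reference: int | None = None,
) -> AssociationResult:
    """Adjusted odds of death by `horizon_wave` per pattern.

    `labels` maps patient id to the pattern index of the wave at which
    patterns were assigned.  The reference pattern is the one with the
    lowest crude mortality rate unless given explicitly.
    """
    by_id = _records(patients)
    if horizon_wave not in WAVES[1:]:
        raise InconsistencyError(f"unknown horizon wave {horizon_wave!r}")
    rows = []
    for pid, lab in labels.items():
        rec = by_id[pid]
        st = rec.status(horizon_wave)
        if st == LOST and not include_lost_as_alive:
            continue
        rows.append(
            {
                "pattern": int(lab),
                "dead": 1 if st == DEAD else 0,
                "age": rec.age_at_baseline,
                "female": 1 if rec.is_female else 0,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["dead"].nunique() < 2:
        raise InconsistencyError("need both outcome classes present")
    pats = sorted(df["pattern"].unique())
    if len(pats) < 2:
        raise InconsistencyError("need at least two patterns")
    if reference is None:
        rates = df.groupby("pattern")["dead"].mean()
        reference = int(rates.idxmin())
        rule = "lowest crude mortality rate"
    else:
        rule = "user supplied"

    X = pd.DataFrame({"const": 1.0}, index=df.index)
    if "age" in covariates:
        X["age"] = df["age"].astype(float)
    if "sex" in covariates:
        X["female"] = df["female"].astype(float)
    dummy_cols = {}
    for p in pats:
        if p == reference:
            continue
        col = f"pattern_{p}"
        X[col] = (df["pattern"] == p).astype(float)
        dummy_cols[p] = col

    fit = _fit_logit(df["dead"].to_numpy(), X)
    effects = []
    for p in pats:
        if p == reference:
            effects.append(
                EffectEstimate(
                    level=str(p), coef=0.0, se=0.0, odds_ratio=1.0,
                    ci_low=1.0, ci_high=1.0, is_reference=True,
                )
            )
        else:
            col = dummy_cols[p]
            effects.append(_effect(str(p), fit.params[col], fit.bse[col]))
    cov_effects = {
        name: _effect(name, fit.params[name], fit.bse[name])
        for name in X.columns
        if name.startswith(("age", "female", "const"))
    }
    return AssociationResult(
        outcome=f"death by {horizon_wave}",
        reference=str(reference),
        reference_rule=rule,
        effects=effects,
        covariate_effects=cov_effects,
        covariates=covariates,
        n=len(df),
        converged=True,
        n_iter=int(fit.mle_retvals.get("iterations", -1)),
        log_likelihood=float(fit.llf),
    )


def fit_multinomial_acute(
    patients: Sequence[PatientRecord] | Mapping[str, PatientRecord],
    labels: Mapping[str, int],
    acute_label: str,
    period: int,
    covariates: tuple[str, ...] = ("age", "sex"),
    reference: int | None = None,
) -> AssociationResult:
    """Adjusted association between an acute-disease exposure in a follow-up
    period and pattern membership (multinomial outcome).

    The baseline category is the pattern with the lowest prevalence (the
    smallest size share) unless given.  Reported effects are the acute
    indicator's ORs per non-reference pattern.
    """
    by_id = _records(patients)
    rows = []
    for pid, lab in labels.items():
        rec = by_id[pid]
        had = any(l == acute_label and p == period for l, p in rec.acute_diagnoses)
        rows.append(
            {
                "pattern": int(lab),
                "acute": 1 if had else 0,
                "age": rec.age_at_baseline,
                "female": 1 if rec.is_female else 0,
            }
        )
    df = pd.DataFrame(rows)
    if df["acute"].nunique() < 2:
        raise InconsistencyError(
            f"acute indicator for {acute_label!r} has a single value"
        )
    sizes = df["pattern"].value_counts()
    pats = sorted(sizes.index)
    if len(pats) < 2:
        raise InconsistencyError("need at least two pattern categories")
    if reference is None:
        smallest = sizes.min()
        reference = int(min(p for p in pats if sizes[p] == smallest))
        rule = "lowest wave prevalence (smallest pattern)"
    else:
        rule = "user supplied"
    # map categories so the reference is code 0 (MNLogit's baseline)
    order = [reference] + [p for p in pats if p != reference]
    code = {p: i for i, p in enumerate(order)}
    y = df["pattern"].map(code).to_numpy()

    X = pd.DataFrame({"const": 1.0}, index=df.index)
    if "age" in covariates:
        X["age"] = df["age"].astype(float)
    if "sex" in covariates:
        X["female"] = df["female"].astype(float)
    X["acute"] = df["acute"].astype(float)

    fit = _fit_logit(y, X, model_cls=sm.MNLogit)
    params = np.asarray(fit.params)      # (n_exog, k-1)
    bse = np.asarray(fit.bse)
    acute_row = list(X.columns).index("acute")
    effects = [
        EffectEstimate(
            level=str(reference), coef=0.0, se=0.0, odds_ratio=1.0,
            ci_low=1.0, ci_high=1.0, is_reference=True,
        )
    ]
    for j, p in enumerate(order[1:]):
        effects.append(_effect(str(p), params[acute_row, j], bse[acute_row, j]))
    effects.sort(key=lambda e: int(e.level))
    return AssociationResult(
        outcome=f"pattern membership vs acute {acute_label!r} (period {period})",
        reference=str(reference),
        reference_rule=rule,
        effects=effects,
        covariate_effects={},
        covariates=covariates,
        n=len(df),
        converged=True,
        n_iter=int(fit.mle_retvals.get("iterations", -1)),
        log_likelihood=float(fit.llf),
    )
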