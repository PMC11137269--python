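"""Clinical characterisation of multimorbidity patterns.

Each cluster ("pattern") is profiled by comparing, per condition, its
observed prevalence OP (share of the pattern's members carrying it) with
the expected prevalence EP (the condition's prevalence in the whole wave
population): the prevalence ratio PR = OP/EP measures over-representation.
A condition is *essential* to a pattern when it is both clearly
over-represented and common enough inside the pattern:

    (i)  PR >= 2.0 and OP >= 10%,  or
    (ii) OP >= 20% and PR >= 1.5,

with all comparisons inclusive.  A partition is clinically valid only when
every pattern carries at least one essential condition.  Candidate pattern
names are produced mechanically from the top essential conditions by PR;
real naming is a clinician-consensus step outside this package's scope.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    DEAD,
    WAVES,
    PatientRecord,
    count_distinct_acute,
    count_distinct_drugs,
    percentage,
)
from .errors import InconsistencyError, UndefinedPrevalenceRatioError

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import ClusteringResult
    from .cohort import CohortWave


@dataclass(frozen=True)
class EssentialRule:
    """Thresholds of the essential-condition rule (inclusive comparisons)."""

    pr_primary: float = 2.0    # clause (i): PR >= 2.0 ...
    op_primary: float = 0.10   # ... and OP >= 10%
    op_secondary: float = 0.20  # clause (ii): OP >= 20% ...
    pr_secondary: float = 1.5   # ... and PR >= 1.5


def prevalence_ratio(op_value: float, ep_value: float) -> float:
    """PR = OP / EP; undefined when the population prevalence is zero."""
    if ep_value <= 0:
        raise UndefinedPrevalenceRatioError(
            f"expected prevalence must be positive, got {ep_value}"
        )
    return op_value / ep_value


def is_essential(pr: float, op_value: float, rule: EssentialRule | None = None) -> bool:
    """Essential-condition rule; see the module docstring."""
    r = rule or EssentialRule()
    return (pr >= r.pr_primary and op_value >= r.op_primary) or (
        op_value >= r.op_secondary and pr >= r.pr_secondary
    )


def essential_conditions(
    op: np.ndarray, ep: np.ndarray, rule: EssentialRule | None = None
) -> list[int]:
    """Indices of essential conditions given pattern OPs and wave EPs.

    Conditions absent from the whole wave (EP = 0) cannot be essential;
    after the prevalence filter every retained condition has EP > 0.
    """
    op = np.asarray(op, dtype=float)
    ep = np.asarray(ep, dtype=float)
    out = []
    for j in range(op.size):
        if ep[j] <= 0:
            continue
        if is_essential(op[j] / ep[j], op[j], rule):
            out.append(j)
    return out


@dataclass
class PatternProfile:
    """Descriptive profile of one pattern in one wave."""

    wave_label: str
    pattern_index: int
    size: int
    share_pct: float                       # of the wave population
    member_ids: list[str]
    op: np.ndarray                         # observed prevalence per condition
    ep: np.ndarray                         # wave prevalence per condition
    pr: np.ndarray                         # OP/EP (nan where EP = 0)
    condition_labels: list[str]
    essential_set: list[str]
    candidate_name: str
    women_count: int
    women_distribution_pct: float          # share of the wave's women here
    mean_age: float
    sd_age: float
    mean_conditions: float
    sd_conditions: float
    mortality: dict[str, tuple[int, float]]   # horizon wave -> (events, %)
    mean_drugs: float | None = None        # distinct ATC-4 in following period
    sd_drugs: float | None = None
    mean_acute: float | None = None
    sd_acute: float | None = None


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan"), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def candidate_name(
    essential: Sequence[str], pr_by_label: Mapping[str, float], top: int = 2
) -> str:
    """Mechanical pattern name: top essential conditions by PR (descending),
    ties broken alphabetically; empty essential set names the pattern
    'unspecific'."""
    if not essential:
        return "unspecific"
    ranked = sorted(essential, key=lambda c: (-pr_by_label[c], c))
    return " & ".join(ranked[:top])


def profile_patterns(
    wave: "CohortWave",
    result: "ClusteringResult",
    patients: Sequence[PatientRecord] | Mapping[str, PatientRecord],
    rule: EssentialRule | None = None,
) -> list[PatternProfile]:
    """Build every pattern's descriptive profile for one wave.

    EP is the condition prevalence in the wave population; OP is computed
    within each pattern.  Mortality percentages use the pattern size as
    denominator, one entry per later wave.  Drug and acute counts cover the
    follow-up period that starts at this wave (none after the last wave).
    """
    if isinstance(patients, Mapping):
        by_id = dict(patients)
    else:
        by_id = {p.patient_id: p for p in patients}
    labels = np.asarray(result.labels)
    if labels.size != wave.n:
        raise InconsistencyError(
            f"labels length {labels.size} != wave size {wave.n}"
        )
    rule = rule or EssentialRule()
    X = wave.matrix.astype(float)
    ep = X.mean(axis=0)
    wave_idx = WAVES.index(wave.wave_label)
    later_waves = WAVES[wave_idx + 1 :]
    period = wave_idx + 1 if wave_idx + 1 in (1, 2) else None
    total_women = sum(
        1 for pid in wave.included_ids if by_id[pid].is_female
    )

    profiles = []
    for c in range(result.k):
        members = labels == c
        if not members.any():
            raise InconsistencyError(f"pattern {c} is empty")
        ids = [pid for pid, m in zip(wave.included_ids, members) if m]
        recs = [by_id[pid] for pid in ids]
        op = X[members].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.where(ep > 0, op / ep, np.nan)
        ess_idx = essential_conditions(op, ep, rule)
        ess = [wave.condition_labels[j] for j in ess_idx]
        pr_by_label = {wave.condition_labels[j]: float(pr[j]) for j in ess_idx}
        mean_age, sd_age = _mean_sd([r.age_at(wave.wave_label) for r in recs])
        mean_cond, sd_cond = _mean_sd(
            [len(r.conditions(wave.wave_label)) for r in recs]
        )
        mortality = {}
        for hw in later_waves:
            events = sum(1 for r in recs if r.status(hw) == DEAD)
            mortality[hw] = (events, percentage(events, len(recs)))
        drugs = acute = (None, None)
        if period is not None:
            drugs = _mean_sd([count_distinct_drugs(r, period) for r in recs])
            acute = _mean_sd([count_distinct_acute(r, period) for r in recs])
        women = sum(1 for r in recs if r.is_female)
        profiles.append(
            PatternProfile(
                wave_label=wave.wave_label,
                pattern_index=c,
                size=len(ids),
                share_pct=percentage(len(ids), wave.n),
                member_ids=ids,
                op=op,
                ep=ep,
                pr=pr,
                condition_labels=list(wave.condition_labels),
                essential_set=ess,
                candidate_name=candidate_name(ess, pr_by_label),
                women_count=women,
                women_distribution_pct=(
                    percentage(women, total_women) if total_women else float("nan")
                ),
                mean_age=mean_age,
                sd_age=sd_age,
                mean_conditions=mean_cond,
                sd_conditions=sd_cond,
                mortality=mortality,
                mean_drugs=drugs[0],
                sd_drugs=drugs[1],
                mean_acute=acute[0],
                sd_acute=acute[1],
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Between-pattern descriptive comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Chi-squared / ANOVA comparison of patterns with Bonferroni-adjusted
    pairwise tests."""

    sex_chi2: float
    sex_p: float
    anova: dict[str, tuple[float, float]]          # variable -> (F, p)
    pairwise: dict[str, list[tuple[int, int, float, float, bool]]]
    # variable -> [(pattern_a, pattern_b, t, p, significant at 0.05/m)]
    bonferroni_m: int
    adjusted_alpha: float
    skipped: list[str] = field(default_factory=list)


def compare_groups(
    profiles: Sequence[PatternProfile],
    patients: Sequence[PatientRecord] | Mapping[str, PatientRecord],
) -> GroupComparison:
    """Pearson chi-squared for sex x pattern; one-way ANOVA (with pairwise
    Bonferroni-corrected t-tests) for age and chronic-disease counts."""
    if len(profiles) < 2:
        raise InconsistencyError("need at least two patterns to compare")
    if isinstance(patients, Mapping):
        by_id = dict(patients)
    else:
        by_id = {p.patient_id: p for p in patients}
    wave = profiles[0].wave_label
    groups: dict[str, list[list[float]]] = {"age": [], "conditions": []}
    table = []
    for prof in profiles:
        recs = [by_id[pid] for pid in prof.member_ids]
        table.append(
            [sum(r.is_female for r in recs), sum(not r.is_female for r in recs)]
        )
        groups["age"].append([r.age_at(wave) for r in recs])
        groups["conditions"].append([len(r.conditions(wave)) for r in recs])

    obs = np.asarray(table)
    if (obs.sum(axis=0) == 0).any():
        chi2_stat, chi2_p = float("nan"), float("nan")
    else:
        chi2_stat, chi2_p, _, _ = stats.chi2_contingency(obs, correction=False)

    g = len(profiles)
    m = g * (g - 1) // 2
    alpha = 0.05 / m
    anova: dict[str, tuple[float, float]] = {}
    pairwise: dict[str, list] = {}
    skipped: list[str] = []
    for var, data in groups.items():
        arrays = [np.asarray(x, dtype=float) for x in data]
        if any(a.size > 1 and a.std(ddof=1) == 0 for a in arrays) or any(
            a.size < 2 for a in arrays
        ):
            skipped.append(var)
            continue
        f, p = stats.f_oneway(*arrays)
        anova[var] = (float(f), float(p))
        pairs = []
        for i in range(g):
            for j in range(i + 1, g):
                t, pt = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
                pairs.append((i, j, float(t), float(pt), bool(pt < alpha)))
        pairwise[var] = pairs
    return GroupComparison(
        sex_chi2=float(chi2_stat),
        sex_p=float(chi2_p),
        anova=anova,
        pairwise=pairwise,
        bonferroni_m=m,
        adjusted_alpha=alpha,
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def profiles_to_json(profiles: Sequence[PatternProfile], path: str | Path) -> Path:
    """Full per-condition OP/EP/PR profiles as JSON."""
    payload = []
    for p in profiles:
        d = asdict(p)
        for key in ("op", "ep", "pr"):
            d[key] = [float(v) for v in d[key]]
        d["mortality"] = {k: [int(v[0]), float(v[1])] for k, v in p.mortality.items()}
        payload.append(d)
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, allow_nan=True))
    return path


def profiles_to_table(profiles: Sequence[PatternProfile]) -> pd.DataFrame:
    """Descriptive table (one column per pattern), percentages/means at 2 dp."""
    cols = {}
    for p in profiles:
        col = {
            "Size, n": p.size,
            "Size, %": round(p.share_pct, 2),
            "Women, n": p.women_count,
            "Women, % distribution": round(p.women_distribution_pct, 2),
            "Mean age": round(p.mean_age, 2),
            "SD age": round(p.sd_age, 2),
            "Chronic diseases, mean": round(p.mean_conditions, 2),
            "Chronic diseases, SD": round(p.sd_conditions, 2),
        }
        if p.mean_drugs is not None:
            col["Drugs, mean"] = round(p.mean_drugs, 2)
            col["Drugs, SD"] = round(p.sd_drugs, 2)
            col["Acute diseases, mean"] = round(p.mean_acute, 2)
            col["Acute diseases, SD"] = round(p.sd_acute, 2)
        for hw, (events, pct) in p.mortality.items():
            col[f"Mortality by {hw}, n"] = events
            col[f"Mortality by {hw}, %"] = round(pct, 2)
        cols[f"{p.pattern_index}: {p.candidate_name}"] = col
    return pd.DataFrame(cols)
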