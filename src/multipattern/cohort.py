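"""Cohort construction: per-wave analysis datasets for a closed
multimorbidity cohort.

The cohort design is a closed longitudinal cohort: membership is fixed at
baseline (every member has >=2 chronic conditions there) and individuals can
only leave, through death or loss to follow-up (inactive registration).
Each wave is analysed cross-sectionally on the patients still included,
using a binary patients x conditions matrix restricted to conditions whose
wave prevalence is at or above a threshold (default 1.0%).

Chronic condition sets are cumulative: once a condition is recorded with
active status it remains part of the patient's clinical profile in every
later wave.  Drug dispensations are deduplicated at the fourth ATC level
(chemical subgroup, the first five characters of the code) within each
follow-up period, and repeated diagnoses of the same acute condition within
a period are counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AtcFormatError,
    CohortFormatError,
    EmptyWaveError,
    InconsistencyError,
)

#: Chronological wave tags.  Baseline is always the first.
WAVES: tuple[str, ...] = ("2011", "2015", "2019")

#: Follow-up periods between consecutive waves (1 = 2012-2015, 2 = 2016-2019).
PERIODS: tuple[int, ...] = (1, 2)

INCLUDED, DEAD, LOST = "included", "dead", "lost"
_STATUS_CODES = frozenset({INCLUDED, DEAD, LOST})
_SEX_CODES = frozenset({"F", "M"})


@dataclass
class PatientRecord:
    """One person: demographics, per-wave status, per-wave chronic-condition
    sets, acute diagnoses and drug dispensations with period tags."""

    patient_id: str
    sex: str                                   # 'F' or 'M'
    age_at_baseline: int
    status_per_wave: dict[str, str]            # wave tag -> included|dead|lost
    chronic_conditions_per_wave: dict[str, frozenset[str]]
    acute_diagnoses: list[tuple[str, int]] = field(default_factory=list)
    dispensations: list[tuple[str, int]] = field(default_factory=list)

    def status(self, wave: str) -> str:
        if wave == WAVES[0]:
            return INCLUDED
        return self.status_per_wave[wave]

    def conditions(self, wave: str) -> frozenset[str]:
        return self.chronic_conditions_per_wave[wave]

    @property
    def is_female(self) -> bool:
        return self.sex == "F"

    def age_at(self, wave: str) -> int:
        """Age at a wave; waves are four years apart."""
        return self.age_at_baseline + 4 * WAVES.index(wave)


@dataclass
class CohortWave:
    """One cross-section: the included patients and their binary disease
    matrix over the conditions surviving the prevalence filter."""

    wave_label: str
    included_ids: list[str]
    matrix: np.ndarray                 # shape (n_included, n_conditions), int8
    condition_labels: list[str]
    prevalence_threshold: float

    @property
    def n(self) -> int:
        return len(self.included_ids)

    def prevalences(self) -> np.ndarray:
        """Per-condition prevalence among the included patients."""
        return self.matrix.mean(axis=0)


# ---------------------------------------------------------------------------
# I/O (long-format CSVs: patients.csv, diagnoses.csv, dispensations.csv)
# ---------------------------------------------------------------------------

_PATIENT_COLS = ["patient_id", "sex", "age_at_baseline", "status_2015", "status_2019"]
_DIAG_COLS = ["patient_id", "condition_label", "kind", "wave_or_period"]
_DISP_COLS = ["patient_id", "atc_code", "period"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing required column(s) {missing}")


def load_cohort(
    patients_path: str | Path,
    diagnoses_path: str | Path,
    dispensations_path: str | Path,
) -> list[PatientRecord]:
    """Read the three long-format CSV files into patient records.

    Chronic diagnosis rows carry the wave of first appearance; the loader
    accumulates them so that per-wave condition sets are non-decreasing.
    Malformed rows raise :class:`CohortFormatError` with their row number
    (1-based, excluding the header).
    """
    pat = pd.read_csv(patients_path, dtype=str)
    _require_columns(pat, _PATIENT_COLS, str(patients_path))
    if pat["patient_id"].duplicated().any():
        dupes = pat.loc[pat["patient_id"].duplicated(), "patient_id"].tolist()
        raise CohortFormatError(f"duplicate patient_id(s): {dupes[:5]}")

    records: dict[str, PatientRecord] = {}
    for row_no, row in enumerate(pat.itertuples(index=False), start=1):
        if row.sex not in _SEX_CODES:
            raise CohortFormatError(
                f"{patients_path} row {row_no}: unknown sex code {row.sex!r}"
            )
        statuses = {"2015": row.status_2015, "2019": row.status_2019}
        for wave, st in statuses.items():
            if st not in _STATUS_CODES:
                raise CohortFormatError(
                    f"{patients_path} row {row_no}: bad status_{wave} {st!r}"
                )
        if statuses["2015"] in (DEAD, LOST) and statuses["2019"] != statuses["2015"]:
            raise CohortFormatError(
                f"{patients_path} row {row_no}: status must be absorbing "
                f"({statuses['2015']} at 2015 but {statuses['2019']} at 2019)"
            )
        try:
            age = int(row.age_at_baseline)
        except (TypeError, ValueError):
            raise CohortFormatError(
                f"{patients_path} row {row_no}: non-integer age "
                f"{row.age_at_baseline!r}"
            ) from None
        records[row.patient_id] = PatientRecord(
            patient_id=row.patient_id,
            sex=row.sex,
            age_at_baseline=age,
            status_per_wave=statuses,
            chronic_conditions_per_wave={},
        )

    # first-appearance sets per wave, accumulated below
    first_seen: dict[str, dict[str, set[str]]] = {
        pid: {w: set() for w in WAVES} for pid in records
    }
    diag = pd.read_csv(diagnoses_path, dtype=str)
    _require_columns(diag, _DIAG_COLS, str(diagnoses_path))
    for row_no, row in enumerate(diag.itertuples(index=False), start=1):
        rec = records.get(row.patient_id)
        if rec is None:
            raise CohortFormatError(
                f"{diagnoses_path} row {row_no}: diagnosis for unknown "
                f"patient_id {row.patient_id!r}"
            )
        if row.kind == "chronic":
            if row.wave_or_period not in WAVES:
                raise CohortFormatError(
                    f"{diagnoses_path} row {row_no}: bad wave tag "
                    f"{row.wave_or_period!r}"
                )
            first_seen[row.patient_id][row.wave_or_period].add(row.condition_label)
        elif row.kind == "acute":
            if row.wave_or_period not in {"1", "2"}:
                raise CohortFormatError(
                    f"{diagnoses_path} row {row_no}: bad period "
                    f"{row.wave_or_period!r}"
                )
            rec.acute_diagnoses.append((row.condition_label, int(row.wave_or_period)))
        else:
            raise CohortFormatError(
                f"{diagnoses_path} row {row_no}: kind must be chronic|acute, "
                f"got {row.kind!r}"
            )

    for pid, rec in records.items():
        acc: set[str] = set()
        for w in WAVES:
            acc |= first_seen[pid][w]
            rec.chronic_conditions_per_wave[w] = frozenset(acc)

    disp = pd.read_csv(dispensations_path, dtype=str)
    _require_columns(disp, _DISP_COLS, str(dispensations_path))
    for row_no, row in enumerate(disp.itertuples(index=False), start=1):
        rec = records.get(row.patient_id)
        if rec is None:
            raise CohortFormatError(
                f"{dispensations_path} row {row_no}: dispensation for unknown "
                f"patient_id {row.patient_id!r}"
            )
        if row.period not in {"1", "2"}:
            raise CohortFormatError(
                f"{dispensations_path} row {row_no}: bad period {row.period!r}"
            )
        rec.dispensations.append((row.atc_code, int(row.period)))

    return list(records.values())


def write_cohort(patients: Iterable[PatientRecord], outdir: str | Path) -> dict[str, Path]:
    """Write patients.csv, diagnoses.csv and dispensations.csv.

    Chronic conditions are written at their wave of first appearance so the
    cumulative (monotone) sets round-trip exactly through :func:`load_cohort`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prow, drow, srow = [], [], []
    for rec in patients:
        prow.append(
            {
                "patient_id": rec.patient_id,
                "sex": rec.sex,
                "age_at_baseline": rec.age_at_baseline,
                "status_2015": rec.status("2015"),
                "status_2019": rec.status("2019"),
            }
        )
        seen: frozenset[str] = frozenset()
        for w in WAVES:
            for cond in sorted(rec.conditions(w) - seen):
                drow.append(
                    {
                        "patient_id": rec.patient_id,
                        "condition_label": cond,
                        "kind": "chronic",
                        "wave_or_period": w,
                    }
                )
            seen = rec.conditions(w)
        for label, period in rec.acute_diagnoses:
            drow.append(
                {
                    "patient_id": rec.patient_id,
                    "condition_label": label,
                    "kind": "acute",
                    "wave_or_period": str(period),
                }
            )
        for code, period in rec.dispensations:
            srow.append({"patient_id": rec.patient_id, "atc_code": code, "period": period})

    paths = {
        "patients": outdir / "patients.csv",
        "diagnoses": outdir / "diagnoses.csv",
        "dispensations": outdir / "dispensations.csv",
    }
    pd.DataFrame(prow, columns=_PATIENT_COLS).to_csv(paths["patients"], index=False)
    pd.DataFrame(drow, columns=_DIAG_COLS).to_csv(paths["diagnoses"], index=False)
    pd.DataFrame(srow, columns=_DISP_COLS).to_csv(paths["dispensations"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Filters and wave construction
# ---------------------------------------------------------------------------

def apply_multimorbidity_filter(
    patients: Sequence[PatientRecord], wave: str = WAVES[0]
) -> list[PatientRecord]:
    """Keep patients with >=2 chronic conditions in `wave` (multimorbidity).

    The retained set defines the closed cohort analysed at every wave.
    """
    return [p for p in patients if len(p.conditions(wave)) >= 2]


def build_wave(
    patients: Sequence[PatientRecord],
    wave_label: str,
    prevalence_threshold: float = 0.01,
) -> CohortWave:
    """Cross-sectional dataset for one wave.

    Included patients are cohort members neither dead nor lost by the wave;
    a condition is retained when its prevalence among them (carriers / n) is
    at or above the threshold (inclusive, so an exactly-1.0% condition stays).
    """
    included = [p for p in patients if p.status(wave_label) == INCLUDED]
    if not included:
        raise EmptyWaveError(f"wave {wave_label}: no included patients")
    all_conditions = sorted(set().union(*(p.conditions(wave_label) for p in included)))
    index = {c: j for j, c in enumerate(all_conditions)}
    mat = np.zeros((len(included), len(all_conditions)), dtype=np.int8)
    for i, p in enumerate(included):
        for c in p.conditions(wave_label):
            mat[i, index[c]] = 1
    prevalence = mat.mean(axis=0)
    keep = prevalence >= prevalence_threshold
    return CohortWave(
        wave_label=wave_label,
        included_ids=[p.patient_id for p in included],
        matrix=mat[:, keep],
        condition_labels=[c for c, k in zip(all_conditions, keep) if k],
        prevalence_threshold=prevalence_threshold,
    )


# ---------------------------------------------------------------------------
# Cohort accounting
# ---------------------------------------------------------------------------

@dataclass
class AccountingTable:
    """Closed-cohort attrition bookkeeping across waves.

    Cumulative death/loss percentages use the baseline n as denominator.
    """

    baseline_n: int
    included: list[int]                # per wave, starting at baseline
    cumulative_deaths: list[int]       # per post-baseline wave
    cumulative_lost: list[int]

    def cumulative_death_pct(self, wave_index: int = -1, dp: int | None = None) -> float:
        return percentage(self.cumulative_deaths[wave_index], self.baseline_n, dp)

    def cumulative_lost_pct(self, wave_index: int = -1, dp: int | None = None) -> float:
        return percentage(self.cumulative_lost[wave_index], self.baseline_n, dp)


def cohort_accounting(
    baseline_n: int,
    deaths_per_period: Sequence[int],
    lost_per_period: Sequence[int],
) -> AccountingTable:
    """Propagate a closed cohort through follow-up periods.

    included(w+1) = included(w) - deaths(w) - lost(w); any negative
    intermediate count raises :class:`InconsistencyError`.
    """
    if len(deaths_per_period) != len(lost_per_period):
        raise InconsistencyError("deaths and lost sequences differ in length")
    if baseline_n < 0 or any(d < 0 for d in deaths_per_period) or any(
        l < 0 for l in lost_per_period
    ):
        raise InconsistencyError("counts must be nonnegative")
    included = [int(baseline_n)]
    cum_d, cum_l = [], []
    td = tl = 0
    for d, l in zip(deaths_per_period, lost_per_period):
        nxt = included[-1] - d - l
        if nxt < 0:
            raise InconsistencyError(
                f"attrition ({d} deaths + {l} lost) exceeds included count "
                f"{included[-1]}"
            )
        td += int(d)
        tl += int(l)
        included.append(nxt)
        cum_d.append(td)
        cum_l.append(tl)
    return AccountingTable(
        baseline_n=int(baseline_n),
        included=included,
        cumulative_deaths=cum_d,
        cumulative_lost=cum_l,
    )


def accounting_from_patients(patients: Sequence[PatientRecord]) -> AccountingTable:
    """Derive the attrition table from per-patient statuses."""
    deaths, lost = [], []
    prev_dead = prev_lost = 0
    for wave in WAVES[1:]:
        d = sum(1 for p in patients if p.status(wave) == DEAD)
        l = sum(1 for p in patients if p.status(wave) == LOST)
        deaths.append(d - prev_dead)
        lost.append(l - prev_lost)
        prev_dead, prev_lost = d, l
    return cohort_accounting(len(patients), deaths, lost)


# ---------------------------------------------------------------------------
# Deduplicated utilisation counts
# ---------------------------------------------------------------------------

def percentage(numerator: float, denominator: float, dp: int | None = None) -> float:
    """Share as a percentage, optionally rounded to `dp` decimals (the
    tables print 2 dp)."""
    if denominator == 0:
        raise InconsistencyError("percentage with zero denominator")
    value = 100.0 * numerator / denominator
    return value if dp is None else round(value, dp)


def atc4(code: str) -> str:
    """Level-4 (chemical subgroup) prefix: the first five characters."""
    if len(code) < 5:
        raise AtcFormatError(f"ATC code {code!r} shorter than 5 characters")
    return code[:5]


def count_distinct_drugs(patient: PatientRecord, period: int) -> int:
    """Distinct fourth-level ATC groups dispensed in a follow-up period.

    Repeated dispensations within the same chemical subgroup count once.
    """
    return len({atc4(code) for code, p in patient.dispensations if p == period})


def count_distinct_acute(patient: PatientRecord, period: int) -> int:
    """Distinct acute diagnoses in a period (repeats counted once)."""
    return len({label for label, p in patient.acute_diagnoses if p == period})
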