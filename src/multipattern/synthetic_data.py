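"""Synthetic closed-cohort generator.

Emulates the structure of a regional chronic-disease EHR cohort: multimorbid
adults aged 18-65 followed over two four-year periods (three waves), with a
catalog of ~130 grouped chronic conditions, cluster-structured disease
prevalences (a Bernoulli-mixture model), logistic per-period mortality,
losses to follow-up, incident chronic conditions during follow-up, repeated
acute diagnoses, and ATC-coded drug dispensations.

The generative model, per patient:

1. a latent cluster ``z`` drawn from ``cluster_weights``;
2. baseline conditions ``x_j ~ Bernoulli(prevalence_matrix[z, j])``,
   redrawn (rejection sampling) until >=2 are present when
   ``multimorbid_only`` is set;
3. per four-year period, death with probability
   ``expit(b0 + b_age * age + b_female * female + b_cluster[z])``, then loss
   to follow-up with probability ``lost_rate`` among survivors (death and
   loss are mutually exclusive within a period; both are absorbing);
4. incident conditions ``~ Bernoulli(incidence_matrix[z, j])`` among active
   survivors, added on top of the existing set (condition sets only grow);
5. per period, a Poisson number of acute-diagnosis events with labels drawn
   with replacement (so duplicates occur) and a Poisson number of
   dispensations whose codes share fourth-level ATC prefixes (so the
   deduplication rules downstream are exercised).

Identical configurations (including the seed) produce identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .cohort import DEAD, INCLUDED, LOST, PERIODS, WAVES, PatientRecord, write_cohort
from .errors import ConfigurationError

#: A small catalog of real fourth-level ATC codes (chemical subgroups) used
#: as the default dispensation universe.
DEFAULT_ATC4_CATALOG: tuple[str, ...] = (
    "A02BC", "A10BA", "A10BB", "A10BD", "A12AX", "B01AC", "C03CA", "C07AB",
    "C08CA", "C09AA", "C09CA", "C09DA", "C10AA", "H03AA", "J01CA", "J01CR",
    "M01AE", "N02BE", "N02CC", "N05BA", "N05CD", "N06AB", "N06AX", "R03AK",
    "R03BB", "R06AE", "A06AD", "G03AA", "S01AA", "D07AC",
)


class MortalityCoefs(BaseModel):
    """Log-odds of death per four-year period: intercept + linear age and
    female terms + one offset per latent cluster."""

    model_config = ConfigDict(frozen=True)

    intercept: float = -9.5
    age: float = 0.09
    female: float = -0.35
    cluster: tuple[float, ...] = ()


class GeneratorConfig(BaseModel):
    """Full specification of a synthetic cohort draw."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    n_patients: int = Field(gt=0)
    n_conditions: int = Field(default=130, gt=0)
    n_clusters: int = Field(gt=0)
    cluster_weights: tuple[float, ...]
    prevalence_matrix: tuple[tuple[float, ...], ...]
    age_range: tuple[int, int] = (18, 65)
    female_fraction: float = Field(default=0.578, ge=0.0, le=1.0)
    mortality_coefs: MortalityCoefs = MortalityCoefs()
    lost_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    incidence_matrix: tuple[tuple[float, ...], ...] | None = None
    acute_rate_per_period: float = Field(default=5.0, ge=0.0)
    n_acute_labels: int = Field(default=20, gt=0)
    atc4_catalog: tuple[str, ...] = DEFAULT_ATC4_CATALOG
    dispensation_rate: float = Field(default=11.0, ge=0.0)
    seed: int
    multimorbid_only: bool = True

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if len(self.cluster_weights) != self.n_clusters:
            raise ConfigurationError(
                "cluster_weights: length must equal n_clusters"
            )
        if any(w < 0 for w in self.cluster_weights):
            raise ConfigurationError("cluster_weights: negative weight")
        if abs(sum(self.cluster_weights) - 1.0) > 1e-9:
            raise ConfigurationError("cluster_weights: must sum to 1 ± 1e-9")
        for name, mat in (
            ("prevalence_matrix", self.prevalence_matrix),
            ("incidence_matrix", self.incidence_matrix),
        ):
            if mat is None:
                continue
            if len(mat) != self.n_clusters or any(
                len(row) != self.n_conditions for row in mat
            ):
                raise ConfigurationError(
                    f"{name}: shape must be (n_clusters, n_conditions)"
                )
            if any(not (0.0 <= p <= 1.0) for row in mat for p in row):
                raise ConfigurationError(f"{name}: probabilities must lie in [0, 1]")
        if self.n_clusters > 1:
            rows = {tuple(r) for r in self.prevalence_matrix}
            if len(rows) != self.n_clusters:
                raise ConfigurationError(
                    "prevalence_matrix: rows must differ when n_clusters > 1"
                )
        if not self.atc4_catalog:
            raise ConfigurationError("atc4_catalog: must not be empty")
        if any(len(c) < 5 for c in self.atc4_catalog):
            raise ConfigurationError("atc4_catalog: codes need >= 5 characters")
        if self.age_range[0] > self.age_range[1]:
            raise ConfigurationError("age_range: lower bound exceeds upper bound")
        if self.mortality_coefs.cluster and len(
            self.mortality_coefs.cluster
        ) != self.n_clusters:
            raise ConfigurationError(
                "mortality_coefs.cluster: length must equal n_clusters"
            )
        if self.multimorbid_only:
            for i, row in enumerate(self.prevalence_matrix):
                if sum(1 for p in row if p > 0) < 2:
                    raise ConfigurationError(
                        f"prevalence_matrix: cluster {i} has fewer than two "
                        "conditions with positive prevalence, so multimorbidity "
                        "can never be satisfied"
                    )
        return self


@dataclass
class SyntheticCohort:
    """A generated cohort plus the planted per-patient cluster labels."""

    patients: list[PatientRecord]
    truth_labels: np.ndarray
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        paths = write_cohort(self.patients, outdir)
        cfg_path = Path(outdir) / "generator_config.json"
        cfg_path.write_text(self.config.model_dump_json(indent=2))
        paths["config"] = cfg_path
        return paths


def condition_label(j: int) -> str:
    return f"C{j:03d}"


def acute_label(j: int) -> str:
    return f"ACU{j:02d}"


_MAX_REJECTION_ROUNDS = 1000


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Draw one cohort from the configured Bernoulli-mixture model."""
    rng = np.random.default_rng(config.seed)
    n, d, k = config.n_patients, config.n_conditions, config.n_clusters
    prev = np.asarray(config.prevalence_matrix, dtype=float)
    inc = (
        np.zeros((k, d))
        if config.incidence_matrix is None
        else np.asarray(config.incidence_matrix, dtype=float)
    )
    clusters = rng.choice(k, size=n, p=np.asarray(config.cluster_weights))
    conds = rng.random((n, d)) < prev[clusters]
    if config.multimorbid_only:
        for _ in range(_MAX_REJECTION_ROUNDS):
            bad = conds.sum(axis=1) < 2
            if not bad.any():
                break
            conds[bad] = rng.random((int(bad.sum()), d)) < prev[clusters[bad]]
        else:
            raise ConfigurationError(
                "prevalence_matrix: rejection sampling failed to reach "
                "multimorbidity; prevalences are too small"
            )

    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    female = rng.random(n) < config.female_fraction
    mc = config.mortality_coefs
    b_cluster = (
        np.asarray(mc.cluster, dtype=float) if mc.cluster else np.zeros(k)
    )

    active = np.ones(n, dtype=bool)
    status = {w: np.full(n, INCLUDED, dtype=object) for w in WAVES[1:]}
    wave_conds = {WAVES[0]: conds.copy()}
    for pidx, wave in zip(PERIODS, WAVES[1:]):
        age_now = ages + 4 * (pidx - 1)
        p_die = expit(mc.intercept + mc.age * age_now + mc.female * female + b_cluster[clusters])
        die = (rng.random(n) < p_die) & active
        lost = (rng.random(n) < config.lost_rate) & active & ~die
        active &= ~(die | lost)
        for later in WAVES[WAVES.index(wave):]:
            if later == WAVES[0]:
                continue
            status[later][die] = DEAD
            status[later][lost] = LOST
        gains = (rng.random((n, d)) < inc[clusters]) & active[:, None] & ~conds
        conds |= gains
        wave_conds[wave] = conds.copy()

    # acute events and dispensations, per period, for patients included at
    # the period start; duplicate labels/codes arise from replacement draws
    at_start = {1: np.ones(n, dtype=bool), 2: status["2015"] == INCLUDED}
    acute_events: list[list[tuple[str, int]]] = [[] for _ in range(n)]
    dispensations: list[list[tuple[str, int]]] = [[] for _ in range(n)]
    n_atc = len(config.atc4_catalog)
    for pidx in PERIODS:
        counts_a = rng.poisson(config.acute_rate_per_period, size=n)
        counts_d = rng.poisson(config.dispensation_rate, size=n)
        for i in range(n):
            if not at_start[pidx][i]:
                continue
            if counts_a[i]:
                labels = rng.integers(0, config.n_acute_labels, size=counts_a[i])
                acute_events[i].extend((acute_label(j), pidx) for j in labels)
            if counts_d[i]:
                codes = rng.integers(0, n_atc, size=counts_d[i])
                suffixes = rng.integers(1, 4, size=counts_d[i])
                dispensations[i].extend(
                    (f"{config.atc4_catalog[c]}{s:02d}", pidx)
                    for c, s in zip(codes, suffixes)
                )

    label_cache = [condition_label(j) for j in range(d)]
    patients = []
    for i in range(n):
        patients.append(
            PatientRecord(
                patient_id=f"P{i:06d}",
                sex="F" if female[i] else "M",
                age_at_baseline=int(ages[i]),
                status_per_wave={w: str(status[w][i]) for w in WAVES[1:]},
                chronic_conditions_per_wave={
                    w: frozenset(
                        label_cache[j] for j in np.flatnonzero(wave_conds[w][i])
                    )
                    for w in WAVES
                },
                acute_diagnoses=acute_events[i],
                dispensations=dispensations[i],
            )
        )
    return SyntheticCohort(patients=patients, truth_labels=clusters, config=config)


# ---------------------------------------------------------------------------
# Convenience configurations
# ---------------------------------------------------------------------------

def block_prevalence_matrix(
    n_clusters: int,
    n_conditions: int,
    high: float = 0.9,
    low: float = 0.05,
    block_size: int | None = None,
) -> tuple[tuple[float, ...], ...]:
    """Disjoint-block mixture: cluster c has prevalence `high` on its own
    block of conditions and `low` elsewhere — a well-separated planted
    structure used throughout the tests."""
    if block_size is None:
        block_size = n_conditions // n_clusters
    mat = np.full((n_clusters, n_conditions), low)
    for c in range(n_clusters):
        mat[c, c * block_size : (c + 1) * block_size] = high
    return tuple(tuple(row) for row in mat)


def block_config(
    n_patients: int,
    seed: int,
    n_clusters: int = 3,
    n_conditions: int = 30,
    high: float = 0.9,
    low: float = 0.05,
    **overrides,
) -> GeneratorConfig:
    """A well-separated planted-block configuration with equal weights."""
    weights = tuple([1.0 / n_clusters] * n_clusters)
    # tiny float slack: renormalise exactly
    weights = tuple(w / sum(weights) for w in weights)
    return GeneratorConfig(
        n_patients=n_patients,
        n_conditions=n_conditions,
        n_clusters=n_clusters,
        cluster_weights=weights,
        prevalence_matrix=block_prevalence_matrix(
            n_clusters, n_conditions, high=high, low=low
        ),
        seed=seed,
        **overrides,
    )


def demo_config(n_patients: int = 5000, seed: int = 0) -> GeneratorConfig:
    """Default demonstration cohort: 130-condition catalog, three planted
    patterns with overlapping prevalence profiles, realistic attrition and
    utilisation rates."""
    n_conditions = 130
    rng = np.random.default_rng(12345)  # fixed catalog structure, not the draw
    base = rng.uniform(0.0, 0.03, size=n_conditions)
    prev = np.tile(base, (3, 1))
    prev[0, 0:12] += 0.65      # metabolic-style block
    prev[1, 12:22] += 0.70     # hypertensive-style block
    prev[2, 22:34] += 0.55     # mental-health / unspecific block
    prev = np.clip(prev, 0.0, 1.0)
    inc = np.clip(prev * 0.08, 0.0, 1.0)
    return GeneratorConfig(
        n_patients=n_patients,
        n_conditions=n_conditions,
        n_clusters=3,
        cluster_weights=(0.38, 0.25, 0.37),
        prevalence_matrix=tuple(tuple(r) for r in prev),
        incidence_matrix=tuple(tuple(r) for r in inc),
        mortality_coefs=MortalityCoefs(
            intercept=-9.5, age=0.09, female=-0.35, cluster=(0.0, 0.35, -0.4)
        ),
        lost_rate=0.02,
        seed=seed,
    )
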