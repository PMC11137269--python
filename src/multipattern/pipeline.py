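"""End-to-end orchestration: generate/load -> cohort -> cluster -> profile
-> trajectories -> associations, with deterministic seed fan-out and a run
manifest."""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .association import fit_logistic_mortality, fit_multinomial_acute
from .clustering import cluster_wave
from .cohort import (
    WAVES,
    PatientRecord,
    apply_multimorbidity_filter,
    accounting_from_patients,
    build_wave,
    load_cohort,
)
from .errors import MultipatternError
from .patterns import (
    EssentialRule,
    compare_groups,
    profile_patterns,
    profiles_to_json,
    profiles_to_table,
)
from .synthetic_data import GeneratorConfig, demo_config, generate_cohort
from .trajectories import export_alluvial, link_waves


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: the stage name is hashed into a spawn
    key so adding stages never shifts another stage's stream."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(zlib.crc32(stage.encode()),)
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class RunConfig(BaseModel):
    """Validated configuration for a full pipeline run."""

    outdir: Path
    seed: int
    generator: GeneratorConfig | None = None
    input_dir: Path | None = None
    waves: tuple[str, ...] = WAVES
    prevalence_threshold: float = Field(default=0.01, ge=0.0, le=1.0)
    k_candidates: tuple[int, ...] = (2, 3, 4, 5)
    n_init: int = Field(default=10, gt=0)
    max_iter: int = Field(default=100, gt=0)
    tol: float = Field(default=1e-6, gt=0)
    ch_tolerance: float = Field(default=0.10, ge=0.0, le=1.0)
    essential_rule: EssentialRule = EssentialRule()
    mortality_horizons: tuple[str, ...] = ("2015", "2019")
    acute_labels: tuple[str, ...] = ()   # empty: the most common label per period
    include_plot: bool = True

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under config.outdir.

    Returns the manifest (also written as manifest.json).  Re-running with
    an identical config reproduces identical labels.csv and tables.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "multipattern",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "inputs": {},
    }
    current_stage = "setup"

    def stage(name):
        nonlocal current_stage
        current_stage = name
        t0 = time.perf_counter()

        def done(**extra):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "seed": stage_seed(config.seed, name),
                **extra,
            }

        return done

    try:
        # ----- input: generate or load ---------------------------------
        done = stage("cohort")
        if config.generator is not None:
            gen_cfg = config.generator.model_copy(
                update={"seed": stage_seed(config.seed, "generate")}
            )
            cohort = generate_cohort(gen_cfg)
            patients = cohort.patients
            paths = cohort.write(out / "cohort")
            manifest["inputs"] = {k: str(v) for k, v in paths.items()}
        elif config.input_dir is not None:
            indir = Path(config.input_dir)
            files = {
                "patients": indir / "patients.csv",
                "diagnoses": indir / "diagnoses.csv",
                "dispensations": indir / "dispensations.csv",
            }
            patients = load_cohort(
                files["patients"], files["diagnoses"], files["dispensations"]
            )
            manifest["inputs"] = {k: _sha256(v) for k, v in files.items()}
        else:
            raise MultipatternError("config needs a generator or an input_dir")
        patients = apply_multimorbidity_filter(patients)
        accounting = accounting_from_patients(patients)
        done(n_patients=len(patients), included=accounting.included)

        # ----- per-wave clustering --------------------------------------
        results = {}
        profiles_by_wave = {}
        label_rows = []
        for wave_label in config.waves:
            done = stage(f"cluster_{wave_label}")
            wave = build_wave(patients, wave_label, config.prevalence_threshold)
            report = cluster_wave(
                wave,
                config.k_candidates,
                seed=stage_seed(config.seed, f"cluster_{wave_label}"),
                essential_rule=config.essential_rule,
                ch_tolerance=config.ch_tolerance,
                n_init=config.n_init,
                max_iter=config.max_iter,
                tol=config.tol,
            )
            res = report.results[report.chosen_k]
            results[wave_label] = res
            (out / f"kselection_{wave_label}.json").write_text(
                json.dumps(
                    {
                        "wave": wave_label,
                        "candidates": report.candidates,
                        "ch_scores": {str(k): v for k, v in report.ch_scores.items()},
                        "validity": {str(k): v for k, v in report.validity.items()},
                        "chosen_k": report.chosen_k,
                        "rationale": report.rationale,
                    },
                    indent=2,
                    default=_jsonable,
                )
            )
            for pid, lab in zip(wave.included_ids, res.labels):
                label_rows.append(
                    {"patient_id": pid, "wave": wave_label, "pattern_index": int(lab)}
                )
            profs = profile_patterns(wave, res, patients, rule=config.essential_rule)
            profiles_by_wave[wave_label] = profs
            profiles_to_json(profs, out / f"patterns_{wave_label}.json")
            profiles_to_table(profs).to_csv(out / f"table_{wave_label}.csv")
            comparison = compare_groups(profs, patients)
            done(
                chosen_k=report.chosen_k,
                ch_scores={str(k): v for k, v in report.ch_scores.items()},
                sex_chi2_p=comparison.sex_p,
            )
        labels_df = pd.DataFrame(label_rows, columns=["patient_id", "wave", "pattern_index"])
        labels_df.to_csv(out / "labels.csv", index=False)

        # ----- trajectories ---------------------------------------------
        done = stage("trajectories")
        consecutive = link_waves(results, patients, waves=config.waves)
        traj_paths = export_alluvial(consecutive, out / "trajectories")
        if len(config.waves) > 2:
            endpoints = link_waves(
                results, patients, waves=(config.waves[0], config.waves[-1])
            )
            traj_paths.update(
                {
                    f"endpoint_{k}": v
                    for k, v in export_alluvial(
                        endpoints, out / "trajectories_endpoint"
                    ).items()
                }
            )
        done(flows=len(consecutive.flows))

        # ----- associations ---------------------------------------------
        done = stage("associations")
        assoc_out = {}
        for wave_label in config.waves[:-1]:
            labels = results[wave_label].labels_by_id()
            for horizon in config.mortality_horizons:
                if WAVES.index(horizon) <= WAVES.index(wave_label):
                    continue
                res = fit_logistic_mortality(patients, labels, horizon_wave=horizon)
                assoc_out[f"mortality_{wave_label}_to_{horizon}"] = {
                    "outcome": res.outcome,
                    "reference": res.reference,
                    "n": res.n,
                    "effects": [asdict(e) for e in res.effects],
                }
        for wave_label, period in (("2015", 1), ("2019", 2)):
            if wave_label not in results:
                continue
            labels = results[wave_label].labels_by_id()
            acute_labels = config.acute_labels or _top_acute_labels(
                patients, period, n=1
            )
            for al in acute_labels:
                try:
                    res = fit_multinomial_acute(patients, labels, al, period)
                except MultipatternError as exc:
                    assoc_out[f"acute_{al}_period{period}"] = {"error": str(exc)}
                    continue
                assoc_out[f"acute_{al}_period{period}"] = {
                    "outcome": res.outcome,
                    "reference": res.reference,
                    "n": res.n,
                    "effects": [asdict(e) for e in res.effects],
                }
        (out / "associations.json").write_text(
            json.dumps(assoc_out, indent=2, default=_jsonable)
        )
        done(models=len(assoc_out))
    except MultipatternError as exc:
        raise MultipatternError(
            f"pipeline aborted at stage {current_stage!r}: {exc}"
        ) from exc

    manifest["accounting"] = {
        "baseline_n": accounting.baseline_n,
        "included": accounting.included,
        "cumulative_deaths": accounting.cumulative_deaths,
        "cumulative_lost": accounting.cumulative_lost,
    }
    manifest["outputs"] = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return manifest


def _top_acute_labels(
    patients: Sequence[PatientRecord], period: int, n: int = 1
) -> list[str]:
    counts: dict[str, int] = {}
    for p in patients:
        for label in {l for l, pr in p.acute_diagnoses if pr == period}:
            counts[label] = counts.get(label, 0) + 1
    return [l for l, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]]


def demo_run_config(outdir: str | Path, seed: int = 0, n_patients: int = 5000) -> RunConfig:
    """Generator-backed demonstration configuration."""
    return RunConfig(
        outdir=Path(outdir),
        seed=seed,
        generator=demo_config(n_patients=n_patients, seed=seed),
    )
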