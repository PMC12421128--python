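"""Readers, writers, configuration and the end-to-end pipeline.

All tabular interchange is plain CSV with documented schemas; nested reports
are JSON and configuration is YAML.  The trial-level schema (one row per
trial) is::

    subject_id, group, sex, age, visit, trial_index, trial_type,
    high_cue_side, start_position, chosen_position, outcome_valence,
    outcome_points, rt

`run_pipeline` wires the stages together: simulate a cohort, fit every
subject-visit, derive behavioral measures, and optionally run the recovery
report, the diagnostic classifier and the LME power simulation, writing a
manifest with seeds, package versions and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agent import AgentParams
from .classify import build_feature_table, stacked_classify
from .cohort import (
    Cohort,
    GroupSpec,
    SubjectDataset,
    default_group_specs,
    fit_cohort,
    recovery_experiment,
    sample_cohort,
)
from .inference import PriorSpec
from .measures import entropy_rt_correlation, summarize_choices
from .power import PowerSimSpec, estimate_power
from .task import CUE_SIDES, START_POSITIONS, TRIAL_TYPES

logger = logging.getLogger("aacmodel")

TRIAL_COLUMNS = [
    "subject_id", "group", "sex", "age", "visit", "trial_index", "trial_type",
    "high_cue_side", "start_position", "chosen_position", "outcome_valence",
    "outcome_points", "rt",
]


def write_trials(cohort: Cohort, path) -> None:
    cohort.to_trials_frame()[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path) -> list[SubjectDataset]:
    """Load trial-level CSV into per-subject-visit datasets.

    Missing columns raise a schema error naming the column; rows with an
    out-of-range chosen position or unknown trial type are rejected with a
    logged count.
    """
    frame = pd.read_csv(path)
    if len(frame) == 0:
        raise ValueError(f"{path}: empty trials file")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    ok = (
        frame["chosen_position"].isin(range(1, 10))
        & frame["trial_type"].isin(TRIAL_TYPES)
        & frame["high_cue_side"].isin(CUE_SIDES)
        & frame["start_position"].isin(START_POSITIONS)
    )
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning("rejected %d malformed trial rows", n_rejected)
    frame = frame[ok]
    datasets = []
    for (sid, visit), sub in frame.groupby(["subject_id", "visit"], sort=False):
        first = sub.iloc[0]
        trial_cols = [c for c in TRIAL_COLUMNS
                      if c not in ("subject_id", "group", "sex", "age", "visit")]
        datasets.append(
            SubjectDataset(
                subject_id=str(sid),
                group=str(first["group"]),
                sex=str(first["sex"]),
                age=float(first["age"]),
                visit=str(visit),
                trials=sub[trial_cols].reset_index(drop=True),
            )
        )
    return datasets


def policy_table(
    subject: SubjectDataset, params: AgentParams, form: str = "risk"
) -> pd.DataFrame:
    """Per-trial policy rows and entropies for export.

    Columns: subject_id, trial_index, position_1..position_9, entropy.
    """
    from .agent import ChoicePolicy, choice_entropy, choice_policy
    from .task import TRIAL_TYPES, TrialSpec

    pols = {t: choice_policy(params, TrialSpec(t), form=form)
            for t in TRIAL_TYPES}
    rows = []
    for rec in subject.trials.itertuples():
        pol = pols[rec.trial_type]
        row = {"subject_id": subject.subject_id, "trial_index": rec.trial_index}
        row.update(
            {f"position_{k + 1}": p for k, p in enumerate(pol.as_array())}
        )
        row["entropy"] = choice_entropy(pol)
        rows.append(row)
    return pd.DataFrame(rows)


def measures_table(cohort: Cohort, fits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide per-subject-visit model-free measures, plus the entropy-RT r.

    Columns follow ``{condition}_{measure}`` (e.g. ``CONF4_mean_position``,
    ``all_mean_rt``).  The entropy-RT correlation is computed under each
    subject-visit's fitted parameters when a fits table is supplied.
    """
    fit_lookup = {}
    if fits is not None:
        usable = fits[~fits.get("fit_failed", False).astype(bool)]
        for row in usable.itertuples():
            fit_lookup[(row.subject_id, row.visit)] = AgentParams(
                du=row.du_hat, ec=row.ec_hat
            )
    rows = []
    for s in cohort.subjects:
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "sex": s.sex,
            "age": s.age,
            "visit": s.visit,
        }
        summary = summarize_choices(s)
        for rec in summary.itertuples():
            for m in ("mean_position", "position_sd", "mean_rt"):
                row[f"{rec.condition}_{m}"] = getattr(rec, m)
        params = fit_lookup.get((s.subject_id, s.visit))
        if params is not None:
            row["entropy_rt_r"] = entropy_rt_correlation(s, params).r
        rows.append(row)
    return pd.DataFrame(rows)


def classifier_features(
    fits: pd.DataFrame,
    measures: pd.DataFrame | None = None,
    groups: tuple[str, str] = ("DEP_ANX", "SUD"),
) -> pd.DataFrame:
    """Per-subject wide feature frame for the diagnostic classifier.

    Uses log-scale parameter estimates at each visit (``ec_baseline``,
    ``ec_followup``, ``du_baseline``, ``du_followup``), the baseline
    entropy-RT r, age and sex, restricted to the two requested groups;
    the second group is the positive label.
    """
    fits = fits[fits["group"].isin(groups) & ~fits["fit_failed"].astype(bool)]
    wide = fits.pivot_table(
        index="subject_id", columns="visit", values=["log_ec", "log_du"],
        aggfunc="first",
    )
    out = pd.DataFrame(
        {
            "ec_baseline": wide.get(("log_ec", "baseline")),
            "ec_followup": wide.get(("log_ec", "followup")),
            "du_baseline": wide.get(("log_du", "baseline")),
            "du_followup": wide.get(("log_du", "followup")),
        }
    )
    demo = fits.drop_duplicates("subject_id").set_index("subject_id")
    out["age"] = demo["age"]
    out["sex"] = demo["sex"]
    out["label"] = (demo["group"] == groups[1]).astype(int)
    if measures is not None and "entropy_rt_r" in measures.columns:
        base = measures[measures["visit"] == "baseline"].set_index("subject_id")
        out["entropy_rt_r"] = base["entropy_rt_r"]
    return out.reset_index()


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; round-trips through YAML."""

    seed: int = 0
    n_hc: int = 97
    n_dep_anx: int = 208
    n_sud: int = 175
    n_per_type: int = 12
    value_form: str = "risk"
    prior_mean: tuple[float, float] = (0.0, 0.0)
    prior_variance: tuple[float, float] = (4.0, 4.0)
    run_recovery: bool = False
    run_classify: bool = False
    classify_groups: tuple[str, str] = ("DEP_ANX", "SUD")
    predictor_set: int = 5
    classifier_folds: int = 5
    classifier_repeats: int = 1
    classifier_hyper_starts: int = 3
    classifier_bags: int = 2
    run_power: bool = False
    power: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("prior_mean", "prior_variance", "classify_groups"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def group_specs(self) -> list[GroupSpec]:
        return default_group_specs(self.n_hc, self.n_dep_anx, self.n_sud)

    def prior(self) -> PriorSpec:
        return PriorSpec(tuple(self.prior_mean), tuple(self.prior_variance))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Simulate -> fit -> measures (-> recover / classify / power).

    Writes trials.csv, truth.csv, fits.csv, measures.csv and any optional
    stage outputs plus manifest.json into ``out_dir``; returns the directory.
    A single global seed determines every stochastic output.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name: str, fn):
        t0 = time.time()
        logger.info("stage %s: start", name)
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        logger.info("stage %s: done in %.1fs", name,
                    manifest["stages"][name]["seconds"])
        return result

    cohort = stage("simulate", lambda: sample_cohort(
        config.group_specs(), seed=config.seed, n_per_type=config.n_per_type,
        value_form=config.value_form,
    ))
    write_trials(cohort, out / "trials.csv")
    cohort.truth().to_csv(out / "truth.csv", index=False)

    fits = stage("fit", lambda: fit_cohort(
        cohort, prior=config.prior(), value_form=config.value_form,
    ))
    fits.to_csv(out / "fits.csv", index=False)

    measures = stage("measures", lambda: measures_table(cohort, fits))
    measures.to_csv(out / "measures.csv", index=False)

    if config.run_recovery:
        recovery = stage("recover", lambda: recovery_experiment(
            config.group_specs(), prior=config.prior(), seed=config.seed,
            n_per_type=config.n_per_type, value_form=config.value_form,
        ))
        (out / "recovery.json").write_text(json.dumps(recovery, indent=2))

    if config.run_classify:
        def _classify():
            feats = classifier_features(fits, measures, config.classify_groups)
            table = build_feature_table(feats, config.predictor_set)
            return stacked_classify(
                table,
                seed=config.seed,
                folds=config.classifier_folds,
                repeats=config.classifier_repeats,
                n_hyper_starts=config.classifier_hyper_starts,
                n_bags=config.classifier_bags,
            )
        report = stage("classify", _classify)
        (out / "stack_report.json").write_text(report.to_json())
        report.fold_metrics.to_csv(out / "stack_folds.csv", index=False)

    if config.run_power:
        spec = PowerSimSpec(**config.power)
        result = stage("power", lambda: estimate_power(spec, seed=config.seed))
        payload = {"spec": dataclasses.asdict(spec), **result}
        (out / "power.json").write_text(json.dumps(payload, indent=2))

    import aacmodel

    manifest["versions"] = {
        "aacmodel": aacmodel.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    manifest["seed"] = config.seed
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
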