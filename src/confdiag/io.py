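"""Trial-table file formats, run configuration, and the end-to-end pipeline.

CSV is the sole trial interchange format (columns ``subject_id, block,
trial_index, condition, coherence, choice, confidence``) with a JSON sidecar
holding generator parameters and the seed; all derived results are JSON.
``run_pipeline`` composes the full workflow: simulate (or load) → fit →
analyze → diagnose → report, deterministically for a given config + seed.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import stats as infstats
from .observer import (
    TRIAL_COLUMNS,
    Manipulation,
    design_preset,
    sample_observers,
    simulate_cohort,
    simulate_serial_observer,
)
from .pipeline import cohort_aftereffects, diagnose

__all__ = ["read_trials", "write_trials", "RunConfig", "load_config", "run_pipeline"]

_CHOICES = {"left", "right"}
_CONFIDENCE = {"low", "high"}


class TrialValidationError(ValueError):
    """Raised when a trial file violates the schema; message names the line."""


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Malformed rows are reported with their 1-based file line number (header
    is line 1).  Duplicate ``(subject_id, block, trial_index)`` keys and
    unknown choice/confidence tokens are errors.
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"subject_id": str, "condition": str})
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise TrialValidationError(f"{path}: missing column(s) {missing}")
    table = table[list(TRIAL_COLUMNS)]

    def lines(mask) -> list[int]:
        return [int(i) + 2 for i in table.index[mask]]

    bad = ~table["choice"].isin(_CHOICES)
    if bad.any():
        raise TrialValidationError(
            f"{path}: unknown choice token {table.loc[bad, 'choice'].iloc[0]!r} at line(s) {lines(bad)}"
        )
    bad = ~table["confidence"].isin(_CONFIDENCE)
    if bad.any():
        raise TrialValidationError(
            f"{path}: unknown confidence token {table.loc[bad, 'confidence'].iloc[0]!r} "
            f"at line(s) {lines(bad)}"
        )
    coh = pd.to_numeric(table["coherence"], errors="coerce")
    if coh.isna().any():
        raise TrialValidationError(f"{path}: non-numeric coherence at line(s) {lines(coh.isna())}")
    table["coherence"] = coh.astype(float)
    dup = table.duplicated(subset=["subject_id", "block", "trial_index"], keep=False)
    if dup.any():
        raise TrialValidationError(
            f"{path}: duplicate (subject_id, block, trial_index) at line(s) {lines(dup)}"
        )
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        table.attrs["metadata"] = json.loads(sidecar.read_text())
    return table


def write_trials(table: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    """Write a trial table to CSV plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, columns=list(TRIAL_COLUMNS))
    if metadata is not None:
        path.with_suffix(".json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return path


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulated-cohort analysis run."""

    design: str = "exp1"  # exp1 | exp2 | exp3
    mechanism: str = "sensory_shift"  # sensory_shift | decision_bias | serial
    n_subjects: int = 15
    seed: int = 1
    shift: float = 10.0  # coherence %, per adaptation direction
    compliance: float = 0.8  # gamma of the default rule
    congruence: str = "incongruent"  # default with or against the cue
    delta_1back: float = 3.0  # coherence %, serial 1-back shift
    gamma_2back: float = 0.3  # serial 2-back compliance
    outdir: str | None = None

    def __post_init__(self):
        if self.mechanism not in ("sensory_shift", "decision_bias", "serial"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.congruence not in ("congruent", "incongruent"):
            raise ValueError("congruence must be 'congruent' or 'incongruent'")
        design_preset(self.design)  # validates the name


def load_config(path, overrides: list[str] | None = None) -> RunConfig:
    """Load a YAML run configuration, applying ``key=value`` overrides."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for item in overrides or []:
        key, _, value = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} is not of the form key=value")
        raw[key.strip()] = yaml.safe_load(value)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _manipulations(config: RunConfig, design) -> dict[str, Manipulation]:
    left_label, right_label = design.condition_labels
    if config.mechanism == "sensory_shift":
        # contrastive adaptation: adapting rightward raises the PSE
        return {
            left_label: Manipulation(mode="sensory_shift", shift=-config.shift),
            right_label: Manipulation(mode="sensory_shift", shift=+config.shift),
        }
    flip = config.congruence == "incongruent"
    left_default, right_default = ("right", "left") if flip else ("left", "right")
    return {
        left_label: Manipulation(
            mode="decision_bias", bias_direction=left_default, compliance=config.compliance
        ),
        right_label: Manipulation(
            mode="decision_bias", bias_direction=right_default, compliance=config.compliance
        ),
    }


def simulate_from_config(config: RunConfig) -> pd.DataFrame:
    """Simulate the cohort a RunConfig describes."""
    design = design_preset(config.design)
    observers = sample_observers(config.n_subjects, seed=config.seed)
    if config.mechanism == "serial":
        children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
        tables = [
            simulate_serial_observer(
                design,
                obs,
                config.delta_1back,
                config.gamma_2back,
                seed=int(ss.generate_state(1)[0] % (2**31)),
                subject_id=f"s{i + 1:02d}",
            )
            for i, (obs, ss) in enumerate(zip(observers, children))
        ]
        table = pd.concat(tables, ignore_index=True)
        table.attrs["design"] = design.name
        return table
    return simulate_cohort(design, observers, _manipulations(config, design), seed=config.seed)


def _group_block(estimates) -> dict:
    dp = np.array([e.delta_pse for e in estimates])
    dc = np.array([e.delta_conf for e in estimates])
    n = len(estimates)

    def summary(v):
        t = infstats.t_from_sample(v)
        d = infstats.cohens_d(t.t, n)
        bf = infstats.bf10_jzs(t.t, n)
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
            "mean_abs": float(np.mean(np.abs(v))),
            "t": t.t,
            "df": t.df,
            "p": t.p,
            "d": d.d,
            "d_ci95": [d.ci_low, d.ci_high],
            "bf10": bf.bf10,
        }

    out = {
        "n_subjects": n,
        "per_subject": [e.to_dict() for e in estimates],
        "delta_pse": summary(dp),
        "delta_conf": summary(dc),
        "delta_difference": summary(dp - dc),
        "condition_means": {
            "l_pse": float(np.mean([e.l_pse for e in estimates])),
            "r_pse": float(np.mean([e.r_pse for e in estimates])),
            "l_conf": float(np.mean([e.l_conf for e in estimates])),
            "r_conf": float(np.mean([e.r_conf for e in estimates])),
        },
    }
    diag = diagnose(estimates)
    out["diagnosis"] = {
        "label": diag.label,
        "bf_decision": diag.bf_decision,
        "bf_confidence": diag.bf_confidence,
        "bf_difference": diag.bf_difference,
        "narrative": diag.narrative,
    }
    return out


def analyze_table(table: pd.DataFrame, design_name: str, mechanism: str) -> dict:
    """Fit, estimate and diagnose a (multi-subject) trial table.

    For condition designs this is one condition-split analysis; for serial
    data it is one analysis per lag (1-back and 2-back).
    """
    design = design_preset(design_name)
    analyses = {}
    if mechanism == "serial":
        specs = [("1back", {"nback": 1}), ("2back", {"nback": 2})]
    else:
        left_label, right_label = design.condition_labels
        specs = [("condition", {"left_label": left_label, "right_label": right_label})]
    for name, kwargs in specs:
        estimates, excluded = cohort_aftereffects(table, design, **kwargs)
        if len(estimates) < 5:
            raise RuntimeError(
                f"analysis {name!r}: only {len(estimates)} subjects survived the adequacy screen"
            )
        block = _group_block(estimates)
        block["excluded"] = [{"subject_id": s, "reason": r} for s, r in excluded]
        analyses[name] = block
    return analyses


def run_pipeline(config: RunConfig) -> dict:
    """Simulate → fit → analyze → diagnose; return (and optionally write) a report.

    The report is a plain JSON-serializable dict; identical config + seed
    gives an identical report except for the ``timestamp`` field.
    """
    table = simulate_from_config(config)
    analyses = analyze_table(table, config.design, config.mechanism)
    report = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "package_version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "n_trials": int(len(table)),
        "analyses": analyses,
        "conventions": {
            "delta": "right-context PSE minus left-context PSE; contrastive aftereffects positive",
            "zero_baseline_sign": "exact-zero baseline estimates join the positive group",
            "bf_prior_width": infstats.DEFAULT_PRIOR_WIDTH,
            "diagnosis_thresholds": {"evidence": 3.0, "null": 1.0},
        },
    }
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trials(table, outdir / "trials.csv", metadata=dataclasses.asdict(config))
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        rows = [
            {"analysis": name, **est}
            for name, block in analyses.items()
            for est in block["per_subject"]
        ]
        pd.DataFrame(rows).to_csv(outdir / "aftereffects.csv", index=False)
    return report
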