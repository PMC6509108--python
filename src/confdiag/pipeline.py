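"""Aftereffect estimation and the perceptual-vs-decisional diagnosis.

The analysis logic: split each subject's trials into two opposing contexts
(left vs right adaptation/cue condition, or by the direction of the stimulus
k trials back), fit the decision and confidence functions to each half, and
take the context difference of each PSE estimate:

    ΔPSE  = PSE(right context)  − PSE(left context)      (from decisions)
    ΔCONF = peak(right context) − peak(left context)     (from confidence)

Under this sign convention the classic contrastive motion aftereffect is
positive and an assimilative (congruent-cue or choice-repetition) effect is
negative.  A sensory mechanism moves both estimates together; a decision bias
moves ΔPSE while leaving ΔCONF at zero, and the group-level Bayes-factor rule
in :func:`diagnose` turns that pattern into a label.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import stats as infstats
from .fits import ConfidenceFit, PsychometricFit, adequacy, fit_confidence, fit_decision, tabulate
from .observer import ExperimentDesign

__all__ = [
    "AftereffectEstimate",
    "DiagnosisResult",
    "split_by_condition",
    "split_by_nback",
    "estimate_aftereffect",
    "subject_aftereffect_by_condition",
    "subject_aftereffect_by_nback",
    "cohort_aftereffects",
    "baseline_sign_split",
    "diagnose",
]


@dataclass(frozen=True)
class AftereffectEstimate:
    """Per-subject aftereffect from both response measures."""

    subject_id: str
    l_pse: float
    r_pse: float
    l_conf: float
    r_conf: float

    @property
    def delta_pse(self) -> float:
        return self.r_pse - self.l_pse

    @property
    def delta_conf(self) -> float:
        return self.r_conf - self.l_conf

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delta_pse"] = self.delta_pse
        d["delta_conf"] = self.delta_conf
        return d


@dataclass(frozen=True)
class DiagnosisResult:
    """Mechanism label plus the three Bayes factors that determined it."""

    label: str  # perceptual | decisional | mixed | indeterminate
    bf_decision: float
    bf_confidence: float
    bf_difference: float
    narrative: str


def split_by_condition(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a trial table by condition label (trials conserved)."""
    labels = table["condition"].unique().tolist()
    if len(labels) < 2:
        raise ValueError("need at least 2 condition labels to split")
    return {lab: table[table["condition"] == lab].copy() for lab in labels}


def split_by_nback(table: pd.DataFrame, k: int) -> dict[str, pd.DataFrame]:
    """Split trials by the direction of the stimulus ``k`` trials back.

    History never crosses block boundaries; the first ``k`` trials of each
    block are dropped.  Requires a design without 0% coherence (a zero
    antecedent has no direction).
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    parts: dict[str, list] = {"prev_left": [], "prev_right": []}
    for (_, _), block in table.groupby(["subject_id", "block"], sort=False):
        block = block.sort_values("trial_index")
        coh = block["coherence"].to_numpy()
        prev = coh[:-k] if k else coh
        if np.any(prev == 0):
            raise ValueError("zero-coherence antecedent has no direction; exclude 0% from the design")
        rest = block.iloc[k:]
        parts["prev_left"].append(rest[prev < 0])
        parts["prev_right"].append(rest[prev > 0])
    return {key: pd.concat(frames, ignore_index=True) for key, frames in parts.items()}


def estimate_aftereffect(
    l_dec: PsychometricFit,
    r_dec: PsychometricFit,
    l_conf: ConfidenceFit,
    r_conf: ConfidenceFit,
    design: ExperimentDesign,
    subject_id: str = "s01",
) -> AftereffectEstimate:
    """Right-minus-left PSE differences from decision and confidence fits.

    Raises if any of the four fits fails the adequacy screen, carrying the
    failing criterion in the message.
    """
    for side, dec, conf in (("left", l_dec, l_conf), ("right", r_dec, r_conf)):
        ok, reason = adequacy(dec, conf, design)
        if not ok:
            raise ValueError(f"{subject_id}: inadequate {side}-context fit ({reason})")
    return AftereffectEstimate(
        subject_id=subject_id,
        l_pse=l_dec.mu,
        r_pse=r_dec.mu,
        l_conf=l_conf.mu_c,
        r_conf=r_conf.mu_c,
    )


def _fit_pair(counts_left, counts_right):
    return (
        fit_decision(counts_left),
        fit_decision(counts_right),
        fit_confidence(counts_left),
        fit_confidence(counts_right),
    )


def subject_aftereffect_by_condition(
    table: pd.DataFrame,
    design: ExperimentDesign,
    left_label: str,
    right_label: str,
) -> AftereffectEstimate:
    """Condition-split aftereffect for one subject's trial table."""
    parts = split_by_condition(table)
    for lab in (left_label, right_label):
        if lab not in parts:
            raise ValueError(f"condition {lab!r} not present in table")
    cl, cr = tabulate(parts[left_label]), tabulate(parts[right_label])
    ld, rd, lc, rc = _fit_pair(cl, cr)
    return estimate_aftereffect(ld, rd, lc, rc, design, subject_id=str(table["subject_id"].iloc[0]))


def subject_aftereffect_by_nback(
    table: pd.DataFrame, design: ExperimentDesign, k: int
) -> AftereffectEstimate:
    """k-back-split aftereffect for one subject's trial table."""
    parts = split_by_nback(table, k)
    cl, cr = tabulate(parts["prev_left"]), tabulate(parts["prev_right"])
    ld, rd, lc, rc = _fit_pair(cl, cr)
    return estimate_aftereffect(ld, rd, lc, rc, design, subject_id=str(table["subject_id"].iloc[0]))


def cohort_aftereffects(
    table: pd.DataFrame,
    design: ExperimentDesign,
    *,
    left_label: str | None = None,
    right_label: str | None = None,
    nback: int | None = None,
) -> tuple[list[AftereffectEstimate], list[tuple[str, str]]]:
    """Per-subject aftereffects over a multi-subject table.

    Exactly one of condition labels or ``nback`` must be given.  Subjects
    whose fits fail the adequacy screen are excluded, echoing how unfittable
    participants are dropped; returns (estimates, exclusions) where each
    exclusion is ``(subject_id, reason)``.
    """
    if (nback is None) == (left_label is None or right_label is None):
        raise ValueError("give either left_label/right_label or nback")
    estimates, excluded = [], []
    for sid, sub in table.groupby("subject_id", sort=True):
        try:
            if nback is None:
                est = subject_aftereffect_by_condition(sub, design, left_label, right_label)
            else:
                est = subject_aftereffect_by_nback(sub, design, nback)
            estimates.append(est)
        except ValueError as e:
            excluded.append((str(sid), str(e)))
    return estimates, excluded


def baseline_sign_split(
    baseline: pd.DataFrame, on: str = "pse"
) -> dict[str, pd.DataFrame]:
    """Split subjects by the sign of a baseline estimate.

    ``baseline`` needs columns ``subject_id, pse, peak``; ``on`` selects which
    estimate defines the groups.  Exact zeros join the positive group (a
    measure-zero event on continuous fits; fixed for determinism).  Both
    resulting groups carry both columns, so decision-defined groups can be
    compared on confidence and vice versa.
    """
    if on not in ("pse", "peak"):
        raise ValueError("on must be 'pse' or 'peak'")
    neg = baseline[baseline[on] < 0]
    pos = baseline[baseline[on] >= 0]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("degenerate sign split: need >= 2 subjects of each sign")
    return {"negative": neg.copy(), "positive": pos.copy()}


def _bf_one_sample(values: np.ndarray, prior_width: float) -> float:
    """One-sample JZS BF10 of a delta vector against 0, robust to zero spread."""
    mean, sd, n = values.mean(), values.std(ddof=1), len(values)
    if sd == 0:
        return 0.0 if mean == 0 else float("inf")
    t = infstats.t_one_sample(float(mean), float(sd), n).t
    return infstats.bf10_jzs(t, n, prior_width=prior_width).bf10


def diagnose(
    estimates: list[AftereffectEstimate],
    *,
    evidence_threshold: float = 3.0,
    null_threshold: float = 1.0,
    prior_width: float = infstats.DEFAULT_PRIOR_WIDTH,
) -> DiagnosisResult:
    """Classify an aftereffect as perceptual or decisional from group BFs.

    Three one-sample JZS Bayes factors are computed: on ΔPSE, on ΔCONF, and
    on the per-subject difference ΔPSE − ΔCONF.  Labels:

    * ``perceptual``: decision and confidence both shifted, no detectable
      difference between them (BF_dec > 3, BF_conf > 3, BF_diff < 1);
    * ``decisional``: decisions shifted, confidence flat, measures dissociate
      (BF_dec > 3, BF_conf < 1, BF_diff > 3);
    * ``indeterminate``: no compelling decision shift (BF_dec < 3);
    * ``mixed``: anything else.

    Thresholds follow conventional evidence categories and are configurable.
    """
    if len(estimates) < 5:
        raise ValueError("need >= 5 subjects to diagnose")
    dp = np.array([e.delta_pse for e in estimates])
    dc = np.array([e.delta_conf for e in estimates])
    bf_dec = _bf_one_sample(dp, prior_width)
    bf_conf = _bf_one_sample(dc, prior_width)
    bf_diff = _bf_one_sample(dp - dc, prior_width)
    if bf_dec < evidence_threshold:
        label = "indeterminate"
        narrative = "no compelling evidence that decisions shifted at all"
    elif bf_conf > evidence_threshold and bf_diff < null_threshold:
        label = "perceptual"
        narrative = (
            "decisions and confidence shifted together: consistent with changed sensory evidence"
        )
    elif bf_conf < null_threshold and bf_diff > evidence_threshold:
        label = "decisional"
        narrative = (
            "decisions shifted while confidence stayed put: consistent with a bias in resolving "
            "uncertain trials, not a change in perception"
        )
    else:
        label = "mixed"
        narrative = "evidence pattern fits neither a pure sensory nor a pure decisional account"
    return DiagnosisResult(
        label=label,
        bf_decision=float(bf_dec),
        bf_confidence=float(bf_conf),
        bf_difference=float(bf_diff),
        narrative=narrative,
    )
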