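"""Generative observer model for binary direction decisions and confidence.

A simulated observer categorises a signed motion-coherence value ``x`` (in
percent; negative = leftward, positive = rightward) as "left" or "right" and
reports binary confidence ("low"/"high").  Two latent functions define the
observer:

* a cumulative-Gaussian *decision function* ``p(x) = Φ((x − μ)/σ)`` giving the
  probability of a "right" response, whose 50% point μ is the point of
  subjective equality (PSE);
* a *raised-Gaussian uncertainty function*
  ``q(x) = floor + amplitude·exp(−(x − μ_c)²/(2σ_c²))`` giving the probability
  of a "low confidence" report, whose peak μ_c is a second PSE estimate.

Aftereffect mechanisms enter through a :class:`Manipulation`:

* ``sensory_shift`` translates *both* functions laterally by ``shift`` —
  changed sensory evidence moves decisions and confidence in tandem;
* ``decision_bias`` resolves a fraction ``compliance`` (γ) of uncertain trials
  by a default rule, mixing the unbiased decision function with the default
  direction in proportion to the normalized uncertainty bell
  ``u(x) = exp(−(x − μ_c)²/(2σ_c²))`` while leaving confidence untouched:
  ``p'(x) = (1 − γ·u(x))·p(x) + γ·u(x)·b``.

The dissociation between these two mechanisms — a sensory shift moves the
confidence distribution with the decisions, a decision bias does not — is the
diagnostic signature the rest of the package estimates and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

__all__ = [
    "ObserverParams",
    "Manipulation",
    "ExperimentDesign",
    "EXP1_DESIGN",
    "EXP2_DESIGN",
    "EXP3_DESIGN",
    "design_preset",
    "decision_probability",
    "low_confidence_probability",
    "simulate_experiment",
    "simulate_cohort",
    "simulate_serial_observer",
    "sample_observers",
    "TRIAL_COLUMNS",
]

#: canonical column order of a trial table
TRIAL_COLUMNS = (
    "subject_id",
    "block",
    "trial_index",
    "condition",
    "coherence",
    "choice",
    "confidence",
)

MODES = ("none", "sensory_shift", "decision_bias")


@dataclass(frozen=True)
class ObserverParams:
    """Latent decision and confidence functions of one observer.

    All location/scale parameters are in signed coherence percent.

    Parameters
    ----------
    pse_mu : decision-function midpoint (the PSE).
    sigma : decision-function standard deviation, > 0.
    conf_mu : location of peak uncertainty.
    conf_sigma : width of the uncertainty bell, > 0.
    conf_amplitude : peak low-confidence rate above the floor, in (0, 1].
    conf_floor : asymptotic low-confidence rate, in [0, 1).
    lapse : stimulus-independent error rate in [0, 0.1] (default 0).
    """

    pse_mu: float = 0.0
    sigma: float = 6.0
    conf_mu: float = 0.0
    conf_sigma: float = 5.0
    conf_amplitude: float = 0.8
    conf_floor: float = 0.05
    lapse: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not self.conf_sigma > 0:
            raise ValueError(f"conf_sigma must be > 0, got {self.conf_sigma}")
        if not 0 < self.conf_amplitude <= 1:
            raise ValueError("conf_amplitude must be in (0, 1]")
        if not 0 <= self.conf_floor < 1:
            raise ValueError("conf_floor must be in [0, 1)")
        if self.conf_floor + self.conf_amplitude > 1 + 1e-12:
            raise ValueError("conf_floor + conf_amplitude must be <= 1")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")


@dataclass(frozen=True)
class Manipulation:
    """Which aftereffect mechanism is active, and its magnitude.

    ``shift`` (δ, signed coherence %) is used only when ``mode ==
    "sensory_shift"``; ``bias_direction`` (b) and ``compliance`` (γ, the
    fraction of uncertain trials resolved by the default rule) only when
    ``mode == "decision_bias"``.
    """

    mode: str = "none"
    shift: float = 0.0
    bias_direction: str = "right"
    compliance: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.bias_direction not in ("left", "right"):
            raise ValueError("bias_direction must be 'left' or 'right'")
        if not 0 <= self.compliance <= 1:
            raise ValueError("compliance must be in [0, 1]")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")


NONE_MANIP = Manipulation()


@dataclass(frozen=True)
class ExperimentDesign:
    """Stimulus levels, repeats and condition blocking of one session.

    Conditions run in half-blocks: the first half of each block uses
    ``condition_labels[0]``, the second half the other label (the in-block
    reversal used in the adaptation and cue experiments).  Trial order within
    each half-block is a uniform random permutation of the levels × repeats.
    """

    coherence_levels: tuple[float, ...]
    repeats_per_level: int
    condition_labels: tuple[str, ...] = ("test",)
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.repeats_per_level < 1:
            raise ValueError("repeats_per_level must be >= 1")
        if len(set(self.coherence_levels)) != len(self.coherence_levels):
            raise ValueError("coherence levels must be distinct")
        if not 1 <= len(self.condition_labels) <= 2:
            raise ValueError("designs support 1 or 2 condition labels per block")

    @property
    def n_trials(self) -> int:
        return len(self.coherence_levels) * self.repeats_per_level * len(self.condition_labels)


#: 11 coherence levels × 10 repeats × 2 adaptation directions = 220 trials
EXP1_DESIGN = ExperimentDesign(
    coherence_levels=(-30, -20, -10, -6, -3, 0, 3, 6, 10, 20, 30),
    repeats_per_level=10,
    condition_labels=("adapt_left", "adapt_right"),
    name="exp1",
)

#: same grid, cue conditions instead of adaptation = 220 trials
EXP2_DESIGN = ExperimentDesign(
    coherence_levels=(-30, -20, -10, -6, -3, 0, 3, 6, 10, 20, 30),
    repeats_per_level=10,
    condition_labels=("cue_left", "cue_right"),
    name="exp2",
)

#: 8 levels (0% excluded) × 55 repeats = 440 trials, single condition
EXP3_DESIGN = ExperimentDesign(
    coherence_levels=(-30, -15, -5, -1, 1, 5, 15, 30),
    repeats_per_level=55,
    condition_labels=("test",),
    name="exp3",
)

_PRESETS = {"exp1": EXP1_DESIGN, "exp2": EXP2_DESIGN, "exp3": EXP3_DESIGN}


def design_preset(name: str) -> ExperimentDesign:
    """Return one of the built-in designs (``exp1``, ``exp2``, ``exp3``)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown design preset {name!r}; expected one of {sorted(_PRESETS)}") from None


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("coherence values must be finite")
    return x


def _uncertainty_bell(x, params: ObserverParams):
    # normalized to peak 1 so bias magnitude is controlled solely by gamma
    return np.exp(-((x - params.conf_mu) ** 2) / (2.0 * params.conf_sigma**2))


def decision_probability(x, params: ObserverParams, manip: Manipulation = NONE_MANIP):
    """Probability of a "right" response at coherence ``x``.

    Scalar in, scalar out; array in, array out.  Under ``sensory_shift`` the
    whole function translates by ``manip.shift``; under ``decision_bias`` the
    unbiased function is mixed with the default direction in proportion to
    the (unchanged) uncertainty bell.
    """
    x = _check_x(x)
    scalar = x.ndim == 0
    mu = params.pse_mu + (manip.shift if manip.mode == "sensory_shift" else 0.0)
    p = params.lapse / 2.0 + (1.0 - params.lapse) * ndtr((x - mu) / params.sigma)
    if manip.mode == "decision_bias":
        b = 1.0 if manip.bias_direction == "right" else 0.0
        gu = manip.compliance * _uncertainty_bell(x, params)
        p = (1.0 - gu) * p + gu * b
    p = np.clip(p, 0.0, 1.0)
    return float(p) if scalar else p


def low_confidence_probability(x, params: ObserverParams, manip: Manipulation = NONE_MANIP):
    """Probability of a "low confidence" report at coherence ``x``.

    A sensory shift translates the bell with the decision function; a
    decision bias leaves it exactly unchanged — confidence tracks the
    sensory evidence, not the decision rule.
    """
    x = _check_x(x)
    scalar = x.ndim == 0
    m = params.conf_mu + (manip.shift if manip.mode == "sensory_shift" else 0.0)
    q = params.conf_floor + params.conf_amplitude * np.exp(
        -((x - m) ** 2) / (2.0 * params.conf_sigma**2)
    )
    q = np.clip(q, 0.0, 1.0)
    return float(q) if scalar else q


def _ordered_stimuli(design: ExperimentDesign, rng: np.random.Generator):
    """Yield (condition, coherence) per trial: half-blocks, shuffled within."""
    out = []
    for label in design.condition_labels:
        half = np.repeat(np.asarray(design.coherence_levels, float), design.repeats_per_level)
        rng.shuffle(half)
        out.extend((label, c) for c in half)
    return out


def _draw_responses(p_right, p_low, rng: np.random.Generator):
    choice = np.where(rng.random(len(p_right)) < p_right, "right", "left")
    confidence = np.where(rng.random(len(p_low)) < p_low, "low", "high")
    return choice, confidence


def simulate_experiment(
    design: ExperimentDesign,
    params: ObserverParams,
    manip_by_condition: Mapping[str, Manipulation],
    seed: int,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Simulate one subject's session as a tidy trial table.

    Each condition's half-block presents every coherence level
    ``repeats_per_level`` times in random order; choices are Bernoulli draws
    from :func:`decision_probability` and confidence from
    :func:`low_confidence_probability`.  Identical seed → identical table.
    """
    missing = [c for c in design.condition_labels if c not in manip_by_condition]
    if missing:
        raise ValueError(f"no manipulation supplied for condition(s): {missing}")
    rng = np.random.default_rng(seed)
    stimuli = _ordered_stimuli(design, rng)
    cond = np.array([s[0] for s in stimuli])
    coh = np.array([s[1] for s in stimuli], dtype=float)
    p_right = np.empty(len(coh))
    p_low = np.empty(len(coh))
    for label in design.condition_labels:
        m = manip_by_condition[label]
        sel = cond == label
        p_right[sel] = decision_probability(coh[sel], params, m)
        p_low[sel] = low_confidence_probability(coh[sel], params, m)
    choice, confidence = _draw_responses(p_right, p_low, rng)
    table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "block": 1,
            "trial_index": np.arange(len(coh)),
            "condition": cond,
            "coherence": coh,
            "choice": choice,
            "confidence": confidence,
        }
    )
    table.attrs["design"] = design.name
    return table


def simulate_serial_observer(
    design: ExperimentDesign,
    params: ObserverParams,
    delta_1back: float,
    gamma_2back: float,
    seed: int,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Simulate a session with trial-history mechanisms instead of conditions.

    Two independent lagged influences act on every trial:

    * 1-back rapid adaptation: the previous stimulus contrastively shifts both
      latent functions; a rightward antecedent raises the PSE (makes ambiguous
      tests look leftward) by ``delta_1back`` coherence %, a leftward one
      lowers it.
    * 2-back choice repetition: uncertain trials default toward the direction
      of the stimulus two back, with compliance ``gamma_2back``, affecting
      decisions only.

    The first one/two trials of the block lack the corresponding antecedent
    and run that component in its neutral state.
    """
    if design.n_trials < 3:
        raise ValueError("serial simulation needs a design with at least 3 trials")
    if not 0 <= gamma_2back <= 1:
        raise ValueError("gamma_2back must be in [0, 1]")
    rng = np.random.default_rng(seed)
    stimuli = _ordered_stimuli(design, rng)
    coh = np.array([s[1] for s in stimuli], dtype=float)
    cond = np.array([s[0] for s in stimuli])
    n = len(coh)
    choice = np.empty(n, dtype=object)
    confidence = np.empty(n, dtype=object)
    u_right = rng.random(n)
    u_conf = rng.random(n)
    for t in range(n):
        shift = np.sign(coh[t - 1]) * delta_1back if t >= 1 else 0.0
        shifted = Manipulation(mode="sensory_shift", shift=float(shift))
        p = decision_probability(coh[t], params, shifted)
        q = low_confidence_probability(coh[t], params, shifted)
        if t >= 2 and gamma_2back > 0 and coh[t - 2] != 0:
            b = 1.0 if coh[t - 2] > 0 else 0.0
            # bias gate uses the *shifted* uncertainty bell: the default rule
            # operates on whatever currently counts as ambiguous
            gu = gamma_2back * np.exp(
                -((coh[t] - (params.conf_mu + shift)) ** 2) / (2.0 * params.conf_sigma**2)
            )
            p = (1.0 - gu) * p + gu * b
        choice[t] = "right" if u_right[t] < p else "left"
        confidence[t] = "low" if u_conf[t] < q else "high"
    table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "block": 1,
            "trial_index": np.arange(n),
            "condition": cond,
            "coherence": coh,
            "choice": choice.astype(str),
            "confidence": confidence.astype(str),
        }
    )
    table.attrs["design"] = design.name
    return table


@dataclass(frozen=True)
class CohortDistributions:
    """Sampling distributions for a cohort of observers.

    Defaults follow the baseline group statistics of the motion-direction
    task this package models: decision PSE ≈ N(−0.43, 1.60), decision SD
    ≈ N(6.32, 4.31) truncated below at 2, peak uncertainty ≈ N(−0.51, 1.03),
    uncertainty width ≈ N(5.37, 1.90) truncated below at 1.5.
    """

    pse_mu: tuple[float, float] = (-0.43, 1.60)
    sigma: tuple[float, float] = (6.32, 4.31)
    conf_mu: tuple[float, float] = (-0.51, 1.03)
    conf_sigma: tuple[float, float] = (5.37, 1.90)
    conf_amplitude: tuple[float, float] = (0.80, 0.05)
    conf_floor: tuple[float, float] = (0.05, 0.02)
    sigma_min: float = 2.0
    conf_sigma_min: float = 1.5


def sample_observers(
    n: int, seed: int, dists: CohortDistributions | None = None
) -> list[ObserverParams]:
    """Draw ``n`` observers from the cohort distributions (truncated normals)."""
    d = dists or CohortDistributions()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        floor = float(np.clip(rng.normal(*d.conf_floor), 0.0, 0.2))
        out.append(
            ObserverParams(
                pse_mu=float(rng.normal(*d.pse_mu)),
                sigma=float(max(rng.normal(*d.sigma), d.sigma_min)),
                conf_mu=float(rng.normal(*d.conf_mu)),
                conf_sigma=float(max(rng.normal(*d.conf_sigma), d.conf_sigma_min)),
                conf_amplitude=float(np.clip(rng.normal(*d.conf_amplitude), 0.3, 1.0 - floor)),
                conf_floor=floor,
            )
        )
    return out


def simulate_cohort(
    design: ExperimentDesign,
    observers: Sequence[ObserverParams],
    manip_by_condition: Mapping[str, Manipulation],
    seed: int,
) -> pd.DataFrame:
    """Simulate every observer's session and concatenate the trial tables.

    Per-subject random streams are spawned from the master seed, so each
    subject's table is individually reproducible.
    """
    children = np.random.SeedSequence(seed).spawn(len(observers))
    tables = []
    for i, (params, ss) in enumerate(zip(observers, children)):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        tables.append(
            simulate_experiment(
                design, params, manip_by_condition, sub_seed, subject_id=f"s{i + 1:02d}"
            )
        )
    out = pd.concat(tables, ignore_index=True)
    out.attrs["design"] = design.name
    return out
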