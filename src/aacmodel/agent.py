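"""POMDP agent for the AAC task: preferences, action values, choice policy.

The agent is a one-shot active-inference-style chooser over the nine terminal
runway positions.  Because the observation mapping is an identity, the
expected free energy of an action reduces to its risk term,

    V(k) = -KL[ p(o | k) || p(o | C) ]
         = sum_o p(o|k) ln p(o|C)  +  H[p(o|k)],

where p(o|k) is the position-dependent outcome lottery and p(o|C) the softmax
preference distribution over the seven observations.  An alternative valuation
that drops the outcome-entropy term (expected log-preference alone) is
available behind the ``form`` switch; the softmax normalizer of C cancels in
action selection, so both forms are shift-invariant in the utilities.

Two free parameters:

* ``ec`` (emotion conflict): the disvalue, in reward-point units, of
  observing an aversive stimulus.  Utilities are anchored at 0 for the safe
  positive/0-point outcome, so with ec = 4 an aversive outcome needs four
  reward points to reach indifference with the safe outcome.
* ``du`` (decision uncertainty): the softmax temperature.  The policy is
  softmax(V / du); larger du flattens choice toward the uniform distribution
  (and mid-runway behavior), smaller du concentrates it on the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

from .task import N_POSITIONS, OUTCOME_INDEX, OUTCOMES, TrialSpec

VALUE_FORMS = ("risk", "expected_log_preference")

#: Preference-scale constant converting the valuation into the units on which
#: the decision-uncertainty temperature is expressed.  The published raw DU
#: summaries (means near 4-5) coexist with strongly position-consistent
#: behavior (model accuracy near 0.77, average action probability near 0.64),
#: which pins the ratio of valuation range to temperature; with the risk
#: valuation's natural range of a few nats this requires a scale of this
#: order.  See docs/methods.md for the calibration.
PREFERENCE_SCALE = 100.0


@dataclass(frozen=True)
class AgentParams:
    """Decision-uncertainty temperature and emotion-conflict aversion."""

    du: float
    ec: float

    def __post_init__(self) -> None:
        if not self.du > 0:
            raise ValueError(f"du must be > 0, got {self.du}")
        if self.ec < 0:
            raise ValueError(f"ec must be >= 0, got {self.ec}")


@dataclass(frozen=True)
class ChoicePolicy:
    """Probability distribution over the nine final runway positions."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (N_POSITIONS,):
            raise ValueError("policy must have 9 entries")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("policy entries must be >= 0 and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


def outcome_utilities(ec: float) -> np.ndarray:
    """Anchored utilities of the seven observations.

    u = points for positive outcomes, points - ec for negative outcomes, and
    0 for both the safe positive/0 anchor and the starting sentinel.
    """
    if ec < 0:
        raise ValueError("ec must be >= 0")
    u = np.empty(len(OUTCOMES))
    for i, o in enumerate(OUTCOMES):
        u[i] = o.points - (ec if o.valence == "negative" else 0.0)
        if o.valence == "starting":
            u[i] = 0.0
    return u


def preference_log_probs(ec: float) -> np.ndarray:
    """ln p(o|C): log-softmax of the outcome utilities (sums to 1 in exp)."""
    return log_softmax(outcome_utilities(ec))


def _endpoint_indices(trial: TrialSpec) -> tuple[int, int]:
    return OUTCOME_INDEX[trial.high_end_outcome], OUTCOME_INDEX[trial.low_end_outcome]


def action_values(
    params: AgentParams,
    trial: TrialSpec,
    form: str = "risk",
    scale: float | None = None,
) -> np.ndarray:
    """Value of ending at each of the nine positions (length-9 vector)."""
    if scale is None:
        scale = PREFERENCE_SCALE
    if form not in VALUE_FORMS:
        raise ValueError(f"form must be one of {VALUE_FORMS}, got {form!r}")
    ln_c = preference_log_probs(params.ec)
    hi, lo = _endpoint_indices(trial)
    p_high = np.arange(1, N_POSITIONS + 1) / 10.0
    p_low = 1.0 - p_high
    expected_log_pref = p_high * ln_c[hi] + p_low * ln_c[lo]
    if form == "expected_log_preference":
        return scale * expected_log_pref
    # risk: add outcome-lottery entropy (p_high never hits 0 or 1 here)
    entropy = -(p_high * np.log(p_high) + p_low * np.log(p_low))
    return scale * (expected_log_pref + entropy)


def choice_policy(
    params: AgentParams,
    trial: TrialSpec,
    form: str = "risk",
    scale: float | None = None,
) -> ChoicePolicy:
    """Softmax action distribution: p(k) proportional to exp(V(k) / du)."""
    if params.du <= 0:
        raise ValueError("du must be > 0")
    v = action_values(params, trial, form=form, scale=scale)
    return ChoicePolicy(tuple(softmax(v / params.du)))


def choice_entropy(policy: ChoicePolicy) -> float:
    """Shannon entropy -sum p ln p of a policy, in nats (0 ln 0 := 0)."""
    p = policy.as_array()
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum())
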