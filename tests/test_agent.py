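"""Agent valuation and policy: oracles, symmetries, and limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aacmodel import (
    AgentParams,
    ChoicePolicy,
    TrialSpec,
    action_values,
    choice_entropy,
    choice_policy,
    outcome_utilities,
    preference_log_probs,
)
from aacmodel.task import OUTCOME_INDEX, OUTCOMES, TRIAL_TYPES


def brute_force_policy(du, ec, trial_type, form="risk"):
    """Independent re-derivation enumerating 2 outcomes x 9 positions."""
    from aacmodel.agent import PREFERENCE_SCALE

    trial = TrialSpec(trial_type)
    u = {}
    for o in OUTCOMES:
        u[o] = o.points - (ec if o.valence == "negative" else 0.0)
        if o.valence == "starting":
            u[o] = 0.0
    z = sum(np.exp(v) for v in u.values())
    ln_c = {o: v - np.log(z) for o, v in u.items()}
    values = []
    for k in range(1, 10):
        ph = k / 10.0
        pl = 1 - ph
        v = ph * ln_c[trial.high_end_outcome] + pl * ln_c[trial.low_end_outcome]
        if form == "risk":
            v += -(ph * np.log(ph) + pl * np.log(pl))
        values.append(PREFERENCE_SCALE * v)
    e = np.exp((np.array(values) - max(values)) / du)
    return e / e.sum()


class TestUtilitiesAndPreferences:
    @pytest.mark.parametrize(
        "ec,outcome,expected",
        [
            (4.0, ("negative", 4), 0.0),   # indifference with the safe anchor
            (0.0, ("negative", 6), 6.0),
            (0.0, ("positive", 2), 2.0),
            (2.0, ("negative", 6), 4.0),
        ],
    )
    def test_anchored_utilities(self, ec, outcome, expected):
        u = outcome_utilities(ec)
        idx = [i for i, o in enumerate(OUTCOMES)
               if (o.valence, o.points) == outcome][0]
        assert u[idx] == pytest.approx(expected)
        # safe positive anchor and starting sentinel stay at 0
        assert u[0] == 0.0 and u[1] == 0.0

    def test_negative_ec_rejected(self):
        with pytest.raises(ValueError):
            outcome_utilities(-0.5)

    def test_preference_log_probs_match_direct_softmax(self):
        ec = 1.0
        u = outcome_utilities(ec)
        expected = u - np.log(np.exp(u).sum())
        np.testing.assert_allclose(preference_log_probs(ec), expected, atol=1e-12)
        assert np.exp(preference_log_probs(ec)).sum() == pytest.approx(1.0)

    def test_ec4_equates_neg4_with_safe_anchor(self):
        lnc = preference_log_probs(4.0)
        i_neg4 = [i for i, o in enumerate(OUTCOMES)
                  if (o.valence, o.points) == ("negative", 4)][0]
        assert lnc[i_neg4] == pytest.approx(lnc[1], abs=1e-12)


class TestActionValues:
    def test_conf4_ec4_expected_log_preference_flat(self):
        v = action_values(AgentParams(du=1, ec=4), TrialSpec("CONF4"),
                          form="expected_log_preference")
        assert np.ptp(v) < 1e-12

    def test_av_values_decrease_toward_aversive_end(self):
        for form in ("risk", "expected_log_preference"):
            v = action_values(AgentParams(du=1, ec=2), TrialSpec("AV"), form=form)
            assert (np.diff(v) < 0).all()

    def test_conf4_ec4_risk_symmetric_about_midpoint(self):
        v = action_values(AgentParams(du=1, ec=4), TrialSpec("CONF4"))
        np.testing.assert_allclose(v, v[::-1], atol=1e-12)


class TestChoicePolicy:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        du=st.floats(0.05, 50),
        ec=st.floats(0, 20),
        ttype=st.sampled_from(TRIAL_TYPES),
        form=st.sampled_from(("risk", "expected_log_preference")),
    )
    def test_policy_matches_brute_force_and_normalizes(self, du, ec, ttype, form):
        p = choice_policy(AgentParams(du, ec), TrialSpec(ttype), form=form)
        arr = p.as_array()
        assert arr.sum() == pytest.approx(1.0, abs=1e-12)
        # mathematically strictly positive; float underflow may round to 0
        assert (arr >= 0).all()
        np.testing.assert_allclose(
            arr, brute_force_policy(du, ec, ttype, form), atol=1e-10
        )

    def test_high_temperature_limit_is_uniform(self):
        p = choice_policy(AgentParams(du=1e9, ec=3), TrialSpec("CONF6"))
        np.testing.assert_allclose(p.as_array(), np.full(9, 1 / 9), atol=1e-8)

    def test_low_temperature_limit_concentrates_on_argmax(self):
        v = action_values(AgentParams(du=1, ec=0), TrialSpec("APP"))
        p = choice_policy(AgentParams(du=1e-3, ec=0), TrialSpec("APP"))
        assert p.as_array()[np.argmax(v)] == pytest.approx(1.0, abs=1e-6)

    def test_conf4_ec4_policy_symmetric(self):
        p = choice_policy(AgentParams(du=1.5, ec=4), TrialSpec("CONF4")).as_array()
        np.testing.assert_allclose(p, p[::-1], atol=1e-12)

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            AgentParams(du=0.0, ec=1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(du=st.floats(0.2, 10), ec=st.floats(0, 10),
           ttype=st.sampled_from(TRIAL_TYPES))
    def test_entropy_nondecreasing_in_temperature(self, du, ec, ttype):
        trial = TrialSpec(ttype)
        h1 = choice_entropy(choice_policy(AgentParams(du, ec), trial))
        h2 = choice_entropy(choice_policy(AgentParams(du * 1.5, ec), trial))
        assert h2 >= h1 - 1e-12

    def test_approach_mass_nonincreasing_in_ec_on_conflict_trials(self):
        for ttype in ("CONF2", "CONF4", "CONF6"):
            trial = TrialSpec(ttype)
            for du in (0.5, 1.0, 3.0):
                masses = [
                    choice_policy(AgentParams(du, ec), trial).as_array()[5:].sum()
                    for ec in np.linspace(0, 10, 21)
                ]
                assert (np.diff(masses) <= 1e-12).all()


class TestChoiceEntropy:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            (np.full(9, 1 / 9), np.log(9)),
            ([1, 0, 0, 0, 0, 0, 0, 0, 0], 0.0),
            ([0.5, 0.5, 0, 0, 0, 0, 0, 0, 0], np.log(2)),
        ],
    )
    def test_known_entropies(self, probs, expected):
        assert choice_entropy(ChoicePolicy(tuple(probs))) == pytest.approx(expected)

    def test_entropy_bounded_by_log9(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(9))
            h = choice_entropy(ChoicePolicy(tuple(p / p.sum())))
            assert 0 <= h <= np.log(9) + 1e-12


def test_policy_invariant_to_constant_utility_shift():
    """The preference softmax normalizer cancels in action selection."""
    from aacmodel import agent

    params = AgentParams(du=1.3, ec=2.5)
    base = choice_policy(params, TrialSpec("CONF2")).as_array()
    orig = agent.outcome_utilities

    def shifted(ec):
        return orig(ec) + 17.0

    try:
        agent.outcome_utilities = shifted
        # preference_log_probs reads the module-level function
        shifted_policy = choice_policy(params, TrialSpec("CONF2")).as_array()
    finally:
        agent.outcome_utilities = orig
    np.testing.assert_allclose(base, shifted_policy, atol=1e-12)
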