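"""Disqualification policies: triggers, windows, prohibition bookkeeping."""

import numpy as np
import pytest

from conftest import force_table, make_world, zeroed_params
from denialsim.dynamics import run_simulation, step
from denialsim.policy import (
    PolicySpec,
    all_policies,
    check_and_apply,
    is_prohibited,
    parse_policy_token,
    qualifying_now,
    record_criterion_events,
)


class TestPolicySpec:
    def test_twelve_interventions(self):
        pols = all_policies()
        assert len(pols) == 12
        assert len({p.label for p in pols}) == 12

    def test_two_event_trigger_requires_ten_years(self):
        with pytest.raises(ValueError):
            PolicySpec("drug_arrest", "two_events_within_5yr", 5)

    def test_token_parsing(self):
        p = parse_policy_token("drug_arrest:single:5")
        assert p == PolicySpec("drug_arrest", "single_event", 5)
        p = parse_policy_token("alcohol_misdemeanor_conviction:two:10")
        assert p.trigger == "two_events_within_5yr"
        with pytest.raises(ValueError):
            parse_policy_token("drug_arrest:sometimes:5")
        with pytest.raises(ValueError):
            parse_policy_token("nonsense")


def _replay_events(event_years, policies, apply_policy=None, n=10,
                   owns_at_start=False):
    """Step a scripted drug-arrest event timeline through the bookkeeping.

    Returns (world, {policy label: {year: qualified}}).  ``apply_policy``
    (one of ``policies``) additionally has check_and_apply run each year.
    """
    from denialsim.justice import JusticeEvent

    ps = zeroed_params(n=n)
    w = make_world(ps, seed=0, ties=False)
    if owns_at_start:
        w.owns[0] = True
    quals = {p.label: {} for p in policies}
    horizon = (max(event_years) if event_years else 0) + 1
    for year in range(1, horizon + 1):
        w.year = year
        events = [JusticeEvent(year=year, agent=0, arrest_type="drug")] \
            if year in event_years else []
        hits = record_criterion_events(w, events)
        for p in policies:
            quals[p.label][year] = bool(qualifying_now(w, p, hits)[0])
        if apply_policy is not None:
            check_and_apply(w, apply_policy, hits)
    return ps, w, quals


class TestSlidingWindow:
    def test_brute_force_window_oracle(self):
        # brute-force oracle over random event timelines: at year y the
        # two-event trigger fires iff this year's event has a predecessor
        # within the 5-year window (gap <= 4, inclusive)
        rng = np.random.default_rng(7)
        pol1 = PolicySpec("drug_arrest", "single_event", 5)
        pol2 = PolicySpec("drug_arrest", "two_events_within_5yr", 10)
        for trial in range(60):
            years = sorted(rng.choice(np.arange(1, 15), size=rng.integers(0, 6),
                                      replace=False).tolist())
            _, _, quals = _replay_events(years, [pol1, pol2])
            for year in quals[pol1.label]:
                want1 = year in years
                want2 = year in years and any(
                    (year - p) <= 4 for p in years if p < year
                )
                assert quals[pol1.label][year] == want1, (years, year)
                assert quals[pol2.label][year] == want2, (years, year)

    def test_spec_example_gap_four_qualifies_gap_six_does_not(self):
        pol = PolicySpec("drug_arrest", "two_events_within_5yr", 10)
        _, _, quals = _replay_events([3, 7], [pol])
        assert quals[pol.label][7]
        _, _, quals = _replay_events([3, 9], [pol])
        assert not quals[pol.label][9]


class TestCheckAndApply:
    def test_single_event_five_year_boundaries(self):
        wrong = PolicySpec("alcohol_misdemeanor_conviction", "single_event", 5)
        _, w, _ = _replay_events([4], [wrong], apply_policy=wrong, owns_at_start=True)
        assert not is_prohibited(w, 5).any()
        assert w.owns[0]
        pol = PolicySpec("drug_arrest", "single_event", 5)
        _, w, _ = _replay_events([4], [pol], apply_policy=pol, owns_at_start=True)
        assert not w.owns[0]
        # prohibited for years t+1..t+5 (queries at t+5 true, t+6 false)
        assert is_prohibited(w, 9)[0]
        assert not is_prohibited(w, 10)[0]

    def test_carrying_untouched_by_prohibition(self):
        pol = PolicySpec("drug_arrest", "single_event", 5)
        from denialsim.justice import JusticeEvent

        ps = zeroed_params(n=5)
        w = make_world(ps, seed=0, ties=False)
        w.owns[0] = True
        w.carries[0] = True
        w.year = 2
        hits = record_criterion_events(w, [JusticeEvent(2, 0, "drug")])
        check_and_apply(w, pol, hits)
        assert w.carries[0] and not w.owns[0]

    def test_requalification_extends_window(self):
        pol = PolicySpec("drug_arrest", "single_event", 5)
        _, w, _ = _replay_events([2, 6], [pol], apply_policy=pol)
        assert w.prohibited_until[0] == 11

    def test_no_prohibition_without_events(self):
        ps = zeroed_params(n=5)
        w = make_world(ps, seed=0, ties=False)
        assert not is_prohibited(w, 100).any()

    def test_event_log_replay_oracle(self):
        # randomized event timelines: an independent replay of the log under
        # the prohibition rule must agree with the engine's state year-by-year
        rng = np.random.default_rng(3)
        for trial in range(40):
            timeline = sorted(rng.choice(np.arange(1, 12), size=rng.integers(1, 5),
                                         replace=False).tolist())
            pol = PolicySpec("drug_arrest", "single_event", int(rng.choice([5, 10])))
            _, w, _ = _replay_events(timeline, [pol], apply_policy=pol)
            prohibited_until = max(timeline) + pol.duration
            for q in range(1, 30):
                want = q <= prohibited_until
                assert bool(is_prohibited(w, q)[0]) == want, (timeline, q)


class TestNullPolicyInvariance:
    def test_null_policy_identical_to_baseline(self):
        from denialsim.params import default_parameter_set

        ps = default_parameter_set(seed=0, scale=1 / 400)
        _, a = run_simulation(ps, policy=None, years=4, burn_in=1, seed=5)
        _, b = run_simulation(ps, policy=None, years=4, burn_in=1, seed=5)
        for la, lb in zip(a, b):
            assert la.as_row() == lb.as_row()

    def test_zero_prevalence_policy_identical_to_baseline(self):
        # arrest tables zeroed for the criterion: the policy can never fire
        # and, under common random numbers, outputs match baseline exactly
        from denialsim.params import default_parameter_set

        ps = default_parameter_set(seed=0, scale=1 / 400)
        from conftest import force_table

        force_table(ps, "arrest_alcohol", 0.0)
        pol = PolicySpec("alcohol_arrest", "single_event", 10)
        _, a = run_simulation(ps, policy=None, years=4, burn_in=1, seed=5)
        _, b = run_simulation(ps, policy=pol, years=4, burn_in=1, seed=5)
        for la, lb in zip(a, b):
            assert la.as_row() == lb.as_row()

    def test_prohibited_agents_never_own_in_default_dynamics(self):
        from denialsim.params import default_parameter_set

        ps = default_parameter_set(seed=0, scale=1 / 400)
        pol = PolicySpec("drug_arrest", "single_event", 5)
        w = make_world(ps, seed=2)
        for _ in range(8):
            step(w, ps, policy=pol)
            active = w.prohibited_until >= w.year
            assert not (active & w.owns).any()
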