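import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medagg import (
    AgentProfile,
    Answer,
    AttributeConstraint,
    GeneratorConfig,
    HostPolicy,
    KeywordSet,
    ProtocolError,
    Rejection,
    State,
    StudyCondition,
    agent_arrive,
    allocate,
    collect_answers,
    evaluate_condition,
    explore_state_space,
    finalize_transfer,
    generate_gentamicin,
    query_dataset,
    start_session,
)
from medagg.negotiation import (
    Allocation,
    join_agent,
    renegotiate,
    run_negotiation,
)
from medagg.experiments import default_capability, make_profiles
from medagg.data_model import partition_dataset
from medagg.tuplespace import ANY, TupleTemplate

COND = StudyCondition(
    keywords=KeywordSet({"Gentamicin", "neonates"}),
    constraints=(
        AttributeConstraint("body_weight", 2000, 3000),
        AttributeConstraint("gestational_age", 38, 42),
        AttributeConstraint("gender"),
        AttributeConstraint("concentration"),
    ),
    n_records=6000,
)


class TestSessionLifecycle:
    def test_start_places_invitation_tuple(self):
        s = start_session("host", ["a", "b", "c"], COND)
        assert s.state is State.STARTED
        invited = s.tc.rd(TupleTemplate("invited", (ANY,)))
        assert invited.args[0] == ("a", "b", "c")

    def test_single_invitee_is_valid(self):
        assert start_session("host", ["a"], COND).state is State.STARTED

    def test_empty_invitee_list_rejected(self):
        with pytest.raises(ProtocolError):
            start_session("host", [], COND)

    def test_activation_fires_on_last_hello(self):
        s = start_session("host", ["a", "b", "c"], COND)
        agent_arrive(s, "a")
        agent_arrive(s, "b")
        assert s.state is State.STARTED
        agent_arrive(s, "c")
        assert s.state is State.ACTIVE
        # the host's terms tuple is now in the centre
        assert s.tc.rd(TupleTemplate("state", ("Active",))) is not None
        params = s.tc.rd(TupleTemplate("parameters", tuple([ANY] * 14)))
        assert params is not None and params.args[-1] == 6000

    def test_duplicate_hello_is_idempotent(self):
        s = start_session("host", ["a", "b"], COND)
        agent_arrive(s, "a")
        agent_arrive(s, "a")
        assert s.tc.count(TupleTemplate("hello", ("a",))) == 1
        assert s.state is State.STARTED

    def test_uninvited_agent_rejected_session_unchanged(self):
        s = start_session("host", ["a"], COND)
        assert not agent_arrive(s, "stranger")
        assert s.tc.count(TupleTemplate("hello", (ANY,))) == 0

    def test_failed_session_center_is_reusable(self):
        s = start_session("host", ["a"], COND, policy=HostPolicy(max_rounds=0))
        agent_arrive(s, "a")
        collect_answers(s, [], [Rejection("a", "keywords")])
        assert s.state is State.FAILURE
        assert s.tc.reusable
        fresh = start_session("host", ["b"], COND, tc=s.tc)
        assert fresh.state is State.STARTED
        assert fresh.tc.count(TupleTemplate("hello", (ANY,))) == 0

    def test_cannot_reuse_live_center(self):
        s = start_session("host", ["a"], COND)
        with pytest.raises(ProtocolError):
            start_session("host", ["b"], COND, tc=s.tc)


def _active_session(invitees=("a", "b", "c"), policy=None, condition=COND):
    s = start_session("host", list(invitees), condition, policy=policy)
    for agent in invitees:
        agent_arrive(s, agent)
    assert s.state is State.ACTIVE
    return s


class TestEvaluateCondition:
    def test_containment_accepts_with_equal_keywords(self, small_dataset):
        profile = AgentProfile("j", small_dataset, default_capability())
        verdict = evaluate_condition(profile, COND)
        assert isinstance(verdict, Answer)
        assert verdict.n_offered == len(query_dataset(small_dataset, COND))

    def test_narrow_capability_rejects_on_max_clause(self, small_dataset):
        cap = default_capability()
        cap["gestational_age"] = (38.0, 40.0)
        profile = AgentProfile("j", small_dataset, cap)
        verdict = evaluate_condition(profile, COND)
        assert verdict == Rejection("j", "max:gestational_age")

    def test_keyword_superset_still_accepts(self, small_dataset):
        ds = type(small_dataset)(
            records=small_dataset.records,
            keywords=KeywordSet({"Gentamicin", "neonates", "antibiotics"}),
        )
        profile = AgentProfile("j", ds, default_capability())
        assert isinstance(evaluate_condition(profile, COND), Answer)

    def test_missing_keyword_rejects(self, small_dataset):
        ds = type(small_dataset)(
            records=small_dataset.records, keywords=KeywordSet({"neonates"})
        )
        profile = AgentProfile("j", ds, default_capability())
        assert evaluate_condition(profile, COND) == Rejection("j", "keywords")

    def test_absent_attribute_rejects(self, small_dataset):
        cap = {"gestational_age": (24.0, 42.0)}
        profile = AgentProfile("j", small_dataset, cap)
        assert evaluate_condition(profile, COND) == Rejection("j", "attr:body_weight")

    def test_privacy_policy_gate(self, small_dataset):
        from medagg.negotiation import AgentPolicy
        from dataclasses import replace

        profile = AgentProfile(
            "j", small_dataset, default_capability(), policy=AgentPolicy(min_k=5)
        )
        assert evaluate_condition(profile, replace(COND, privacy_k=2)) == Rejection(
            "j", "privacy_k"
        )
        assert isinstance(
            evaluate_condition(profile, replace(COND, privacy_k=5)), Answer
        )

    def test_offer_matches_brute_force_count_random_pairs(self):
        """Accept/reject and offered counts agree with an independently coded
        clause-by-clause oracle over random (capability, condition) pairs."""
        ds = generate_gentamicin(GeneratorConfig(n_records=300, seed=13))
        rng = np.random.default_rng(99)
        for _ in range(200):
            cap, cond = _random_pair(rng)
            profile = AgentProfile("j", ds, cap)
            verdict = evaluate_condition(profile, cond)
            expected = _oracle_eq2(ds, cap, cond)
            if expected is None:
                assert isinstance(verdict, Rejection)
            else:
                assert isinstance(verdict, Answer) and verdict.n_offered == expected


def _random_pair(rng):
    """Random capability and condition over the clinical vocabulary."""
    cap = {
        "body_weight": tuple(sorted(rng.uniform(400, 5000, 2))),
        "gestational_age": tuple(sorted(rng.uniform(24, 42, 2))),
        "gender": [frozenset({"M"}), frozenset({"F"}), frozenset({"M", "F"})][
            int(rng.choice(3, p=[0.2, 0.2, 0.6]))
        ],
    }
    constraints = []
    if rng.random() < 0.9:
        constraints.append(
            AttributeConstraint("body_weight", *sorted(rng.uniform(400, 5000, 2)))
        )
    if rng.random() < 0.9:
        constraints.append(
            AttributeConstraint(
                "gestational_age", *sorted(rng.uniform(24, 42, 2))
            )
        )
    if rng.random() < 0.5:
        constraints.append(
            AttributeConstraint(
                "gender", categorical_values=frozenset({rng.choice(["M", "F"])})
            )
        )
    if not constraints:
        constraints.append(AttributeConstraint("body_weight"))
    keywords = (
        KeywordSet({"Gentamicin", "neonates"})
        if rng.random() < 0.8
        else KeywordSet({"Malaria"})
    )
    cond = StudyCondition(
        keywords=keywords,
        constraints=tuple(constraints),
        n_records=int(rng.integers(1, 5000)),
    )
    return cap, cond


def _oracle_eq2(ds, cap, cond):
    """Independent clause-by-clause evaluation; returns the offered count on
    acceptance, None on rejection."""
    if not set(cond.keywords) <= set(ds.keywords):
        return None
    for c in cond.constraints:
        if c.is_wildcard:
            continue
        if c.attribute not in cap:
            return None
        if c.categorical_values is not None:
            if not c.categorical_values <= cap[c.attribute]:
                return None
        else:
            lo, hi = cap[c.attribute]
            if c.min is not None and lo > c.min:
                return None
            if c.max is not None and hi < c.max:
                return None
    count = 0
    for row in ds.records.to_dict("records"):
        ok = True
        for c in cond.constraints:
            v = row[c.attribute]
            if v is None or v != v:
                ok = False
            elif c.categorical_values is not None:
                ok = ok and v in c.categorical_values
            else:
                ok = ok and (c.min is None or v >= c.min) and (
                    c.max is None or v <= c.max
                )
        count += ok
    return count


class TestCollectAnswers:
    def test_all_accept_proceeds(self):
        s = _active_session()
        collect_answers(
            s, [Answer("a", 10), Answer("b", 20), Answer("c", 30)]
        )
        assert s.state is State.ACTIVE
        assert s.answers == {"a": 10, "b": 20, "c": 30}

    def test_rejection_with_zero_rounds_fails(self):
        s = _active_session(policy=HostPolicy(max_rounds=0))
        collect_answers(
            s, [Answer("a", 10), Answer("b", 20)], [Rejection("c", "keywords")]
        )
        assert s.state is State.FAILURE

    def test_rejection_with_rounds_left_renegotiates(self):
        s = _active_session(policy=HostPolicy(max_rounds=1, relaxation=0.1))
        collect_answers(s, [Answer("a", 10)], [Rejection("b", "max:x"), Rejection("c", "min:x")])
        assert s.state is State.RENEGOTIATE
        renegotiate(s)
        assert s.state is State.ACTIVE
        assert s.invitees == ["a"]  # rejecting peers dropped

    def test_relaxation_widens_ranges(self):
        s = _active_session(policy=HostPolicy(max_rounds=1, relaxation=0.1, drop_rejecting=False))
        collect_answers(s, [Answer("a", 1), Answer("b", 1)], [Rejection("c", "min:body_weight")])
        renegotiate(s)
        bw = next(c for c in s.condition.constraints if c.attribute == "body_weight")
        assert bw.min == pytest.approx(1900) and bw.max == pytest.approx(3100)

    def test_silent_invitee_counts_as_rejection(self):
        s = _active_session(policy=HostPolicy(max_rounds=0))
        collect_answers(s, [Answer("a", 10), Answer("b", 5)])  # c is silent
        assert s.state is State.FAILURE
        assert s.rejections["c"] == "timeout"

    def test_non_invitee_answer_ignored(self):
        s = _active_session()
        collect_answers(
            s,
            [Answer("a", 1), Answer("b", 1), Answer("c", 1), Answer("zz", 99)],
        )
        assert "zz" not in s.answers

    def test_requires_active_state(self):
        s = start_session("host", ["a"], COND)
        with pytest.raises(ProtocolError):
            collect_answers(s, [])


class TestAllocate:
    def test_under_supply_takes_all(self):
        alloc = allocate(6000, [Answer("a", 4000), Answer("b", 1000)])
        assert alloc.quotas == {"a": 4000, "b": 1000}

    def test_symmetric_over_supply_splits_evenly(self):
        alloc = allocate(100, [Answer("a", 100), Answer("b", 100)])
        assert alloc.quotas == {"a": 50, "b": 50}

    def test_all_zero_offers_empty_allocation(self):
        assert allocate(10, [Answer("a", 0), Answer("b", 0)]).quotas == {}

    def test_remainder_goes_to_largest_offer_ties_lexicographic(self):
        alloc = allocate(10, [Answer("b", 7), Answer("a", 7), Answer("c", 1)])
        # floors: 4,4,0 -> remainder 2 -> 'a' then 'b' (descending offer, tie by id)
        assert alloc.quotas == {"a": 5, "b": 5, "c": 0}

    @given(
        n=st.integers(1, 10_000),
        offers=st.lists(st.integers(0, 2000), min_size=1, max_size=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_allocation_constraints_hold(self, n, offers):
        answers = [Answer(f"a{i}", o) for i, o in enumerate(offers)]
        alloc = allocate(n, answers)
        total = sum(offers)
        if total == 0:
            assert alloc.quotas == {}
            return
        assert alloc.total() == min(n, total)
        for ans in answers:
            assert 0 <= alloc.quotas[ans.agent_id] <= ans.n_offered


class TestFinalizeTransfer:
    def test_full_supply_reaches_success(self):
        s = _active_session()
        collect_answers(s, [Answer("a", 3), Answer("b", 2), Answer("c", 1)])
        from dataclasses import replace

        s.condition = replace(s.condition, n_records=6)
        alloc = allocate(6, [Answer("a", 3), Answer("b", 2), Answer("c", 1)])
        finalize_transfer(
            s, alloc, {"a": ["r"] * 3, "b": ["r"] * 2, "c": ["r"]}
        )
        assert s.state is State.SUCCESS
        assert s.finished == {"a", "b", "c"}

    def test_over_quota_transfer_rejected(self):
        s = _active_session(invitees=("a",))
        collect_answers(s, [Answer("a", 2)])
        alloc = Allocation({"a": 2})
        finalize_transfer(s, alloc, {"a": ["r"] * 5})
        assert "a" not in s.finished
        assert s.state is State.ACTIVE

    def test_shortfall_waits_then_new_agent_rejoins(self):
        s = _active_session(invitees=("a", "b"))
        collect_answers(s, [Answer("a", 3), Answer("b", 2)])
        alloc = allocate(s.condition.n_records, [Answer("a", 3), Answer("b", 2)])
        finalize_transfer(s, alloc, {"a": ["r"] * 3, "b": ["r"] * 2})
        assert s.state is State.ACTIVE  # 5 < 6000: waiting for new publishers
        join_agent(s, "d")
        assert "d" in s.invitees and s.state is State.ACTIVE


class TestStateSpace:
    ALLOWED = {
        ("Started", "Active"),
        ("Active", "Renegotiate"),
        ("Active", "Failure"),
        ("Active", "Success"),
        ("Renegotiate", "Active"),
        ("Renegotiate", "Failure"),
    }

    def test_small_sessions_stay_on_allowed_edges(self):
        transitions, violations = explore_state_space(max_agents=2, max_rounds=1)
        assert transitions <= self.ALLOWED
        assert violations == []

    def test_success_requires_universal_acceptance(self):
        transitions, violations = explore_state_space(max_agents=2, max_rounds=1)
        assert ("Started", "Active") in transitions
        assert ("Active", "Success") in transitions
        assert violations == []


class TestFullNegotiationRun:
    def test_distributed_offers_sum_to_central_count(self, medium_dataset, condition_bank):
        from dataclasses import replace

        cond = condition_bank[0]
        central = len(query_dataset(medium_dataset, cond))
        parts = partition_dataset(medium_dataset, 4, seed=2)
        profiles = make_profiles(parts)
        result = run_negotiation(
            profiles[0], profiles[1:], replace(cond, n_records=central + 1)
        )
        assert sum(result.answers.values()) == central

    def test_failure_returns_no_allocation(self, medium_dataset):
        parts = partition_dataset(medium_dataset, 2, seed=2)
        profiles = make_profiles(parts)
        bad = StudyCondition(
            keywords=KeywordSet({"oncology"}),
            constraints=(AttributeConstraint("body_weight", 0, 1),),
            n_records=5,
        )
        result = run_negotiation(
            profiles[0], profiles[1:], bad, policy=HostPolicy(max_rounds=0)
        )
        assert result.session.state is State.FAILURE
        assert result.allocation is None
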