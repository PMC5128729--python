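"""Host-driven negotiation of a research database's terms over a tuple centre.

The node that wants to build a research database (the *host*) creates a
tuple centre, writes an invitation tuple ``invited(AgentList)``, and loads
a state script.  Invited peers announce themselves with ``hello(AgentId)``;
when the last one arrives a reaction flips the session to *Active* and the
host publishes the proposed terms as a parameters tuple: keywords, m
attribute ranges, the record count N, and (optionally) the k-anonymity
parameter.  Each peer J evaluates the host I's terms clause by clause:

    KW_I ⊆ KW_J  ∧  attr_p_I = attr_p_J  ∧  min_p_J ≤ min_p_I
                 ∧  max_p_J ≥ max_p_I   (p = 1..m)  ∧  N ≥ 0

i.e. the peer's declared capability must contain every requested range.
Accepting peers answer with ``answer(AgentId, Ñ)`` where Ñ is the number
of matching records they can contribute; a rejection (or silence past the
answer window) sends the session to *Renegotiate* — where the host may
widen ranges and/or drop the rejecting peers — or to *Failure* once the
round budget is exhausted.  When everyone accepts, the host apportions N
among the offers, peers transfer their quotas, each is marked with
``finishedAgent(AgentId)``, and the session ends in *Success* once all
invitees are finished and the requested N has been obtained; with a
shortfall it stays quiescently *Active*, waiting for new publishers to
join via broker notifications.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import product
from typing import Iterable, Mapping, Sequence

from .data_model import (
    AttributeConstraint,
    Dataset,
    KeywordSet,
    SchemaMismatchError,
    StudyCondition,
    query_dataset,
)
from .tuplespace import ANY, LogicTuple, Reaction, TupleCenter, TupleTemplate

__all__ = [
    "State",
    "ProtocolError",
    "AgentPolicy",
    "AgentProfile",
    "HostPolicy",
    "Answer",
    "Rejection",
    "Allocation",
    "NegotiationSession",
    "start_session",
    "agent_arrive",
    "evaluate_condition",
    "collect_answers",
    "renegotiate",
    "allocate",
    "finalize_transfer",
    "join_agent",
    "run_negotiation",
    "explore_state_space",
    "capability_from_specs",
]

logger = logging.getLogger(__name__)

DEFAULT_TIMEOUT_TICKS = 100


class State(Enum):
    STARTED = "Started"
    ACTIVE = "Active"
    RENEGOTIATE = "Renegotiate"
    FAILURE = "Failure"
    SUCCESS = "Success"


class ProtocolError(RuntimeError):
    """An operation was attempted in a state that does not allow it."""


@dataclass(frozen=True)
class AgentPolicy:
    """Acceptance policy standing in for the human operator.

    ``min_k``: the weakest anonymity the agent tolerates; a proposed
    condition carrying ``privacy_k`` below this is rejected.
    """

    min_k: int = 1


@dataclass
class AgentProfile:
    """An invited peer: its local database, declared capability, and policy.

    ``capability`` maps attribute name to either an inclusive (min, max)
    pair or a set of categorical values; it must cover the value ranges
    actually present in the dataset.
    """

    agent_id: str
    dataset: Dataset
    capability: dict
    policy: AgentPolicy = field(default_factory=AgentPolicy)

    @property
    def keywords(self) -> KeywordSet:
        return self.dataset.keywords


@dataclass(frozen=True)
class HostPolicy:
    """How the host reacts to rejections.

    ``relaxation`` widens every bounded numeric range by that fraction of
    its width on each renegotiation round.
    """

    max_rounds: int = 3
    relaxation: float = 0.1
    drop_rejecting: bool = True


@dataclass(frozen=True)
class Answer:
    agent_id: str
    n_offered: int

    def __post_init__(self) -> None:
        if self.n_offered < 0:
            raise ValueError("n_offered must be non-negative")


@dataclass(frozen=True)
class Rejection:
    agent_id: str
    violated_clause: str


@dataclass(frozen=True)
class Allocation:
    """Per-agent contribution quotas; Σ quotas = min(N, Σ Ñ)."""

    quotas: Mapping[str, int]

    def total(self) -> int:
        return sum(self.quotas.values())


# tuple templates used by the protocol
T_STATE = TupleTemplate("state", (ANY,))
T_HELLO_ANY = TupleTemplate("hello", (ANY,))


@dataclass
class NegotiationSession:
    host_id: str
    invitees: list[str]
    condition: StudyCondition
    tc: TupleCenter
    policy: HostPolicy = field(default_factory=HostPolicy)
    timeout_ticks: int = DEFAULT_TIMEOUT_TICKS
    state: State = State.STARTED
    round: int = 0
    arrived: set[str] = field(default_factory=set)
    answers: dict[str, int] = field(default_factory=dict)
    rejections: dict[str, str] = field(default_factory=dict)
    finished: set[str] = field(default_factory=set)
    transferred: dict[str, int] = field(default_factory=dict)
    transitions: list[tuple[State, State]] = field(default_factory=list)

    def _set_state(self, new: State) -> None:
        if new is self.state:
            return
        self.transitions.append((self.state, new))
        self.tc.in_(T_STATE)
        self.tc.out(LogicTuple("state", (new.value,)))
        logger.debug("session %s: %s -> %s", self.host_id, self.state, new)
        self.state = new

    @property
    def total_transferred(self) -> int:
        return sum(self.transferred.values())


def _emit_parameters(session: NegotiationSession) -> None:
    """Write the t3 parameters tuple for the current condition."""
    cond = session.condition
    args: list = [tuple(sorted(cond.keywords))]
    for c in cond.constraints:
        if c.categorical_values is not None:
            args += [c.attribute, tuple(sorted(c.categorical_values)), None]
        else:
            args += [c.attribute, c.min, c.max]
    args.append(cond.n_records)
    session.tc.out(LogicTuple("parameters", tuple(args)))


def start_session(
    host_id: str,
    invitees: Sequence[str],
    condition: StudyCondition,
    policy: HostPolicy | None = None,
    timeout_ticks: int = DEFAULT_TIMEOUT_TICKS,
    tc: TupleCenter | None = None,
) -> NegotiationSession:
    """Create the tuple centre, write the invitation, load the state script.

    Passing a tuple centre previously marked ``reusable`` (after a failed
    session) recycles it: its tuples are cleared and a fresh session starts.
    """
    if not invitees:
        raise ProtocolError("invitee list must be non-empty")
    if tc is None:
        tc = TupleCenter()
    elif tc.reusable:
        tc.clear()
        tc.reactions.clear()
        tc.reusable = False
    else:
        raise ProtocolError("cannot start a session on a non-reusable tuple centre")

    session = NegotiationSession(
        host_id=host_id,
        invitees=list(invitees),
        condition=condition,
        tc=tc,
        policy=policy or HostPolicy(),
        timeout_ticks=timeout_ticks,
    )
    tc.out(LogicTuple("invited", (tuple(invitees),)))
    tc.out(LogicTuple("state", (State.STARTED.value,)))

    # the state script: the last hello of the invite list activates the session
    def all_arrived(center: TupleCenter, tup: LogicTuple) -> bool:
        if session.state is not State.STARTED:
            return False
        return all(
            center.count(TupleTemplate("hello", (a,))) > 0 for a in session.invitees
        )

    def activate(center: TupleCenter, tup: LogicTuple) -> None:
        session.transitions.append((State.STARTED, State.ACTIVE))
        center.in_(T_STATE)
        center.out(LogicTuple("state", (State.ACTIVE.value,)))
        session.state = State.ACTIVE
        _emit_parameters(session)

    tc.add_reaction(
        Reaction(
            event="out",
            template=T_HELLO_ANY,
            guard=all_arrived,
            effect=activate,
            name="activate-on-last-hello",
        )
    )
    return session


def agent_arrive(session: NegotiationSession, agent_id: str) -> bool:
    """An invited agent arrives and writes ``hello(AgentId)``.

    Uninvited agents are rejected (session unchanged); duplicate arrivals
    are idempotent.  Returns True iff the hello was recorded.
    """
    if agent_id not in session.invitees:
        logger.warning("uninvited agent %r rejected", agent_id)
        return False
    if agent_id in session.arrived:
        return True
    session.arrived.add(agent_id)
    session.tc.out(LogicTuple("hello", (agent_id,)))
    return True


def capability_from_specs(specs: Mapping[str, tuple | set | frozenset]) -> dict:
    """Normalize a capability declaration (ranges as tuples, categories as sets)."""
    out: dict = {}
    for attr, spec in specs.items():
        if isinstance(spec, (set, frozenset)):
            out[attr] = frozenset(spec)
        else:
            lo, hi = spec
            out[attr] = (lo, hi)
    return out


def evaluate_condition(
    profile: AgentProfile, condition: StudyCondition
) -> Answer | Rejection:
    """Clause-by-clause evaluation of the host's terms by one peer.

    Accepts iff the condition's keywords are a subset of the peer's, every
    non-wildcard constrained range is contained in the peer's declared
    capability for that attribute, the requested count is non-negative,
    and the proposed anonymity parameter meets the peer's policy.  On
    acceptance the offer Ñ is the peer's matching record count.
    """
    if not condition.keywords.issubset(profile.keywords):
        return Rejection(profile.agent_id, "keywords")
    for c in condition.constraints:
        if c.is_wildcard:
            continue  # wildcard terms are satisfied by any capability
        if c.attribute not in profile.capability:
            return Rejection(profile.agent_id, f"attr:{c.attribute}")
        cap = profile.capability[c.attribute]
        if c.categorical_values is not None:
            if not isinstance(cap, frozenset) or not c.categorical_values <= cap:
                return Rejection(profile.agent_id, f"values:{c.attribute}")
        else:
            lo, hi = cap
            if c.min is not None and lo > c.min:
                return Rejection(profile.agent_id, f"min:{c.attribute}")
            if c.max is not None and hi < c.max:
                return Rejection(profile.agent_id, f"max:{c.attribute}")
    if condition.n_records < 0:
        return Rejection(profile.agent_id, "n_records")
    if condition.privacy_k is not None and condition.privacy_k < profile.policy.min_k:
        return Rejection(profile.agent_id, "privacy_k")
    try:
        n_offered = len(query_dataset(profile.dataset, condition))
    except SchemaMismatchError:
        # capability claimed an attribute the data cannot answer
        return Rejection(profile.agent_id, "schema")
    return Answer(profile.agent_id, n_offered)


def collect_answers(
    session: NegotiationSession,
    answers: Iterable[Answer],
    rejections: Iterable[Rejection] = (),
) -> NegotiationSession:
    """Record the peers' answers once the response window has closed.

    Answers from non-invitees are ignored with a warning.  Invitees that
    neither answered nor rejected within ``timeout_ticks`` are treated as
    rejecting.  Any effective rejection moves the session to *Renegotiate*
    (rounds remaining) or *Failure*; with none, the session stays *Active*
    and proceeds toward allocation and transfer.
    """
    if session.state is not State.ACTIVE:
        raise ProtocolError(f"collect_answers requires Active, not {session.state}")
    for ans in answers:
        if ans.agent_id not in session.invitees:
            logger.warning("answer from non-invitee %r ignored", ans.agent_id)
            continue
        session.answers[ans.agent_id] = ans.n_offered
        session.tc.out(LogicTuple("answer", (ans.agent_id, ans.n_offered)))
    for rej in rejections:
        if rej.agent_id not in session.invitees:
            logger.warning("rejection from non-invitee %r ignored", rej.agent_id)
            continue
        session.rejections[rej.agent_id] = rej.violated_clause
    for agent in session.invitees:
        if agent not in session.answers and agent not in session.rejections:
            session.rejections[agent] = "timeout"
    if session.rejections:
        if session.round < session.policy.max_rounds:
            session._set_state(State.RENEGOTIATE)
        else:
            session._set_state(State.FAILURE)
            session.tc.reusable = True
    return session


def relax_condition(condition: StudyCondition, factor: float) -> StudyCondition:
    """Widen every bounded numeric range by ``factor`` of its width."""
    if factor <= 0:
        return condition
    new_constraints = []
    for c in condition.constraints:
        if c.categorical_values is not None or c.is_wildcard:
            new_constraints.append(c)
            continue
        lo, hi = c.min, c.max
        width = (hi - lo) if (lo is not None and hi is not None) else 0.0
        pad = factor * width
        new_constraints.append(
            AttributeConstraint(
                attribute=c.attribute,
                min=None if lo is None else lo - pad,
                max=None if hi is None else hi + pad,
            )
        )
    return replace(condition, constraints=tuple(new_constraints))


def renegotiate(
    session: NegotiationSession, new_condition: StudyCondition | None = None
) -> NegotiationSession:
    """Host resolves a *Renegotiate* round: adjust terms, resume or fail.

    Per policy, rejecting invitees may be dropped and bounded ranges
    widened; if nobody is left the session fails, otherwise it returns to
    *Active* with the revised terms and a fresh answer window.
    """
    if session.state is not State.RENEGOTIATE:
        raise ProtocolError(f"renegotiate requires Renegotiate, not {session.state}")
    session.round += 1
    if session.policy.drop_rejecting:
        dropped = set(session.rejections)
        session.invitees = [a for a in session.invitees if a not in dropped]
        for agent in dropped:
            session.tc.out(LogicTuple("removedAgent", (agent,)))
    if not session.invitees:
        session._set_state(State.FAILURE)
        session.tc.reusable = True
        return session
    if new_condition is not None:
        session.condition = new_condition
    elif session.policy.relaxation > 0:
        session.condition = relax_condition(
            session.condition, session.policy.relaxation
        )
    session.answers.clear()
    session.rejections.clear()
    session._set_state(State.ACTIVE)
    _emit_parameters(session)
    return session


def allocate(n_needed: int, answers: Sequence[Answer]) -> Allocation:
    """Apportion the requested N among the offers Ñ.

    Under-supply (Σ Ñ ≤ N): every agent contributes its full offer.
    Over-supply: proportional quotas floor(N·Ñ_a/ΣÑ), remainder handed out
    one-by-one in descending-Ñ order (ties broken by agent id), so
    Σ quotas = min(N, Σ Ñ) and quota_a ≤ Ñ_a always.
    """
    if not answers:
        raise ValueError("answers must be non-empty")
    if n_needed < 1:
        raise ValueError("n_needed must be positive")
    total = sum(a.n_offered for a in answers)
    if total == 0:
        return Allocation({})
    if total <= n_needed:
        return Allocation({a.agent_id: a.n_offered for a in answers})
    quotas = {
        a.agent_id: math.floor(n_needed * a.n_offered / total) for a in answers
    }
    remainder = n_needed - sum(quotas.values())
    for ans in sorted(answers, key=lambda a: (-a.n_offered, a.agent_id)):
        if remainder == 0:
            break
        if quotas[ans.agent_id] < ans.n_offered:
            quotas[ans.agent_id] += 1
            remainder -= 1
    return Allocation(quotas)


def finalize_transfer(
    session: NegotiationSession,
    allocation: Allocation,
    transfers: Mapping[str, Sequence],
) -> NegotiationSession:
    """Mark completed transfers with ``finishedAgent`` tuples.

    A transfer exceeding the agent's quota is rejected (logged; the agent
    is not marked finished).  When every invitee is finished and the
    requested N has been obtained the session ends in *Success*; all
    invitees finished with a shortfall leaves the session *Active*,
    waiting for new publishers.
    """
    if session.state is not State.ACTIVE:
        raise ProtocolError(f"finalize_transfer requires Active, not {session.state}")
    for agent, records in transfers.items():
        quota = allocation.quotas.get(agent, 0)
        n = len(records)
        if n > quota:
            logger.error(
                "agent %r transferred %d records, exceeding quota %d; rejected",
                agent,
                n,
                quota,
            )
            continue
        session.transferred[agent] = session.transferred.get(agent, 0) + n
        session.finished.add(agent)
        session.tc.out(LogicTuple("finishedAgent", (agent,)))
    if set(session.invitees) <= session.finished:
        if session.total_transferred >= session.condition.n_records:
            session._set_state(State.SUCCESS)
    return session


def join_agent(session: NegotiationSession, agent_id: str) -> NegotiationSession:
    """A new publisher (announced by the broker) joins a waiting session."""
    if session.state is not State.ACTIVE:
        raise ProtocolError("only an open (Active) session accepts new agents")
    if agent_id not in session.invitees:
        session.invitees.append(agent_id)
    agent_arrive(session, agent_id)
    return session


# --- whole-protocol driver ---------------------------------------------------


@dataclass
class NegotiationResult:
    session: NegotiationSession
    allocation: Allocation | None
    answers: dict[str, int]
    transfers: dict[str, "object"]  # agent_id -> DataFrame of transferred records


def run_negotiation(
    host: AgentProfile,
    peers: Sequence[AgentProfile],
    condition: StudyCondition,
    policy: HostPolicy | None = None,
    include_host_contribution: bool = True,
) -> NegotiationResult:
    """Drive one full negotiation from invitation to transfer.

    The host's own local database contributes through an internal answer,
    symmetric with the peers'.  Transferred records are the first `quota`
    matches of each agent's query result (input order).
    """
    profiles = {p.agent_id: p for p in peers}
    session = start_session(
        host.agent_id, [p.agent_id for p in peers], condition, policy=policy
    )
    for p in peers:
        agent_arrive(session, p.agent_id)

    while True:
        answers, rejections = [], []
        for agent_id in session.invitees:
            verdict = evaluate_condition(profiles[agent_id], session.condition)
            (answers if isinstance(verdict, Answer) else rejections).append(verdict)
        collect_answers(session, answers, rejections)
        if session.state is State.ACTIVE:
            break
        if session.state is State.RENEGOTIATE:
            renegotiate(session)
            if session.state is State.FAILURE:
                return NegotiationResult(session, None, {}, {})
            continue
        return NegotiationResult(session, None, {}, {})  # Failure

    all_answers = list(answers)
    if include_host_contribution:
        host_verdict = evaluate_condition(host, session.condition)
        if isinstance(host_verdict, Answer):
            all_answers.append(host_verdict)

    allocation = allocate(session.condition.n_records, all_answers)
    transfers: dict = {}
    for agent_id, quota in allocation.quotas.items():
        profile = host if agent_id == host.agent_id else profiles[agent_id]
        transfers[agent_id] = query_dataset(profile.dataset, session.condition).head(
            quota
        )
    finalize_transfer(session, allocation, transfers)
    return NegotiationResult(
        session, allocation, {a.agent_id: a.n_offered for a in all_answers}, transfers
    )


# --- exhaustive state-space exploration --------------------------------------

_BEHAVIORS = ("accept", "reject", "silent")


def explore_state_space(
    max_agents: int = 3, max_rounds: int = 2
) -> tuple[set[tuple[str, str]], list[str]]:
    """Enumerate every small session and record the observed transitions.

    For each invitee count up to ``max_agents``, each round budget up to
    ``max_rounds``, and every per-round assignment of behaviours
    (accept / reject / stay silent) to agents, a session is driven through
    the real protocol machinery.  Returns the set of (from, to) state
    transitions seen anywhere, plus a list of protocol violations
    (a *Success* without universal acceptance and completion, or a
    non-terminal session left in a non-waiting state).
    """
    transitions: set[tuple[str, str]] = set()
    violations: list[str] = []
    condition = StudyCondition(
        keywords=KeywordSet({"study"}),
        constraints=(AttributeConstraint("x", 0, 1),),
        n_records=1,
    )
    for n_agents in range(1, max_agents + 1):
        agents = [f"a{i}" for i in range(n_agents)]
        for rounds in range(max_rounds + 1):
            n_slots = n_agents * (rounds + 1)
            for combo in product(_BEHAVIORS, repeat=n_slots):
                behaviour = {
                    (r, agents[i]): combo[r * n_agents + i]
                    for r in range(rounds + 1)
                    for i in range(n_agents)
                }
                _drive_session(
                    agents, rounds, behaviour, condition, transitions, violations
                )
    return transitions, violations


def _drive_session(agents, rounds, behaviour, condition, transitions, violations):
    session = start_session(
        "host", agents, condition, policy=HostPolicy(max_rounds=rounds, relaxation=0)
    )
    for a in agents:
        agent_arrive(session, a)
    accepted: set[str] = set()
    for r in range(rounds + 1):
        if session.state is not State.ACTIVE:
            break
        answers, rejections = [], []
        for a in session.invitees:
            b = behaviour[(r, a)]
            if b == "accept":
                answers.append(Answer(a, 5))
            elif b == "reject":
                rejections.append(Rejection(a, "max:x"))
            # silent agents answer nothing: the timeout treats them as rejecting
        collect_answers(session, answers, rejections)
        if session.state is State.RENEGOTIATE:
            renegotiate(session)
            continue
        if session.state is State.ACTIVE:
            accepted = {ans.agent_id for ans in answers}
            allocation = allocate(condition.n_records, answers) if answers else None
            if allocation is not None and allocation.quotas:
                transfers = {
                    a: ["rec"] * q for a, q in allocation.quotas.items()
                }
                finalize_transfer(session, allocation, transfers)
            break
    for src, dst in session.transitions:
        transitions.add((src.value, dst.value))
    if session.state is State.SUCCESS:
        if set(session.invitees) - accepted or set(session.invitees) - session.finished:
            violations.append(
                f"Success without universal acceptance/completion: {session}"
            )
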