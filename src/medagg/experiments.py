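"""Evaluation suite: consistency, collection-time model, fairness.

Three questions are asked of the simulator, mirroring how one would
evaluate the real distributed system:

* **Consistency** — when a dataset is split across agents, do the records
  obtained from the distributed sources (including the initiator's own)
  always sum to what a direct query on the unsplit database returns?

* **Timing** — how much faster is distributed collection?  If one
  institution accumulates r eligible tests per month, collecting D
  measurements locally takes t_loc = D/r months, while n institutions
  together need t_dist(n) = D/(n·r) + t_run(n); with the system's run time
  t_run measured in seconds and t_loc in months, t_dist ≈ t_loc/n.

* **Fairness** — if every agent keeps initiating studies drawn from a
  shared condition bank, does the gap between what an agent provides and
  what it obtains wash out?  The per-run metric is the mean over agents of
  |obtained − provided| normalized by the number of runs R, which should
  decrease toward zero as R grows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np

from .aggregation import ResearchDatabase, ingest
from .data_model import (
    Dataset,
    KeywordSet,
    StudyCondition,
    partition_dataset,
    query_dataset,
)
from .negotiation import (
    AgentProfile,
    HostPolicy,
    NegotiationResult,
    capability_from_specs,
    run_negotiation,
)
from .privacy import (
    PrivacyParams,
    default_privacy_params,
    generalize,
    pseudonymize,
    serialize_released,
    sign_bundle,
)

__all__ = [
    "TimingModel",
    "local_time",
    "distributed_time",
    "seconds_to_months",
    "load_condition_bank",
    "default_capability",
    "make_profiles",
    "run_consistency",
    "FairnessLedger",
    "run_fairness",
    "build_rsdb",
]

logger = logging.getLogger(__name__)

SECONDS_PER_MONTH = 30.44 * 24 * 3600  # mean Gregorian month


# --- timing model -------------------------------------------------------------


@dataclass(frozen=True)
class TimingModel:
    """Collection-time model: D measurements needed, r tests/month/site,
    n contributing institutions, t_run system run time (months)."""

    D: float
    r: float
    n: int = 1
    t_run: float = 0.0

    def __post_init__(self) -> None:
        if self.D <= 0 or self.n < 1 or self.t_run < 0:
            raise ValueError("require D > 0, n >= 1, t_run >= 0")


def seconds_to_months(seconds: float) -> float:
    return seconds / SECONDS_PER_MONTH


def local_time(model: TimingModel) -> float:
    """Months to collect D measurements at a single institution: D/r."""
    if model.r == 0:
        raise ZeroDivisionError("tests-per-month rate r must be non-zero")
    return model.D / model.r


def distributed_time(model: TimingModel) -> float:
    """Months to collect D measurements from n institutions:
    D/(n·r) + t_run(n)."""
    if model.n == 0 or model.r == 0:
        raise ZeroDivisionError("n and r must be non-zero")
    return model.D / (model.n * model.r) + model.t_run


# --- condition bank -----------------------------------------------------------


def load_condition_bank() -> list[StudyCondition]:
    """The 20 predefined study conditions used by the evaluations.

    All share the keywords {"Gentamicin", "neonates"} and differ in values
    and combinations of body weight, gestational age, and gender; the
    first entry asks for 6000 records of neonates with body weight
    2000–3000 g, gestational age 38–42 weeks, any gender, any
    concentration.
    """
    text = resources.files("medagg").joinpath("data/condition_bank.json").read_text()
    bank = [StudyCondition.from_json(json.dumps(d)) for d in json.loads(text)]
    return bank


def default_capability() -> dict:
    """Capability covering everything the gentamicin generator can produce."""
    return capability_from_specs(
        {
            "body_weight": (400.0, 5000.0),
            "gestational_age": (24.0, 42.0),
            "postnatal_age": (0.0, 28.0),
            "gender": {"M", "F"},
            "concentration": (0.0, float("inf")),
        }
    )


def make_profiles(parts: Sequence[Dataset]) -> list[AgentProfile]:
    return [
        AgentProfile(
            agent_id=f"node{i}", dataset=part, capability=default_capability()
        )
        for i, part in enumerate(parts)
    ]


# --- consistency --------------------------------------------------------------


def run_consistency(
    dataset: Dataset, condition: StudyCondition, n_agents: int, seed: int
) -> tuple[int, list[int]]:
    """Compare a central query with a distributed aggregation of the same data.

    The dataset is split into ``n_agents`` balanced random parts, one part
    per agent; one agent hosts a negotiation whose requested N exceeds the
    total match count, so every agent contributes its full matching set.
    Returns (central count, per-agent distributed counts).
    """
    if n_agents < 1:
        raise ValueError("n_agents must be >= 1")
    central = len(query_dataset(dataset, condition))
    if n_agents == 1:
        return central, [central]
    parts = partition_dataset(dataset, n_agents, seed)
    profiles = make_profiles(parts)
    host, peers = profiles[0], profiles[1:]
    cond = replace(condition, n_records=central + 1)
    result = run_negotiation(host, peers, cond)
    distributed = [result.answers.get(p.agent_id, 0) for p in profiles]
    return central, distributed


# --- fairness -----------------------------------------------------------------


@dataclass
class FairnessLedger:
    """Cumulative records provided/obtained per agent across runs."""

    provided: dict[str, int] = field(default_factory=dict)
    obtained: dict[str, int] = field(default_factory=dict)
    runs: int = 0

    def agents(self) -> list[str]:
        return sorted(set(self.provided) | set(self.obtained))

    def conservation(self) -> int:
        """Σ obtained − Σ provided; exactly 0 when every transfer has one
        provider and one receiver."""
        return sum(self.obtained.values()) - sum(self.provided.values())

    def imbalance(self) -> float:
        """Normalized mean absolute imbalance m(R) = mean_a |o_a − p_a| / R."""
        if self.runs == 0:
            return 0.0
        agents = self.agents()
        if not agents:
            return 0.0
        return float(
            np.mean(
                [
                    abs(self.obtained.get(a, 0) - self.provided.get(a, 0))
                    for a in agents
                ]
            )
            / self.runs
        )


def run_fairness(
    n_agents: int = 10,
    n_runs: int = 200,
    records_per_agent: int = 892,
    bank: Sequence[StudyCondition] | None = None,
    seed: int = 0,
    policy: HostPolicy | None = None,
) -> tuple[FairnessLedger, list[float]]:
    """Simulate repeated study creation and track each agent's gain/loss.

    A pool of ``n_agents × records_per_agent`` records is generated and
    split randomly across the agents.  Each run, a uniformly chosen agent
    hosts a negotiation with a condition drawn uniformly from the bank;
    the other agents are the publishers (the host's own matches also count
    toward its database but move no data between agents).  Returns the
    final ledger and the trajectory of the normalized mean absolute
    imbalance m(R) after each run.
    """
    from .synthetic_data import GeneratorConfig, generate_gentamicin

    if n_agents < 2:
        raise ValueError("fairness needs at least 2 agents")
    bank = list(bank) if bank is not None else load_condition_bank()
    rng = np.random.default_rng(seed)
    data_seed, part_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    pool = generate_gentamicin(
        GeneratorConfig(n_records=n_agents * records_per_agent, seed=data_seed)
    )
    parts = partition_dataset(pool, n_agents, part_seed)
    profiles = make_profiles(parts)

    ledger = FairnessLedger(
        provided={p.agent_id: 0 for p in profiles},
        obtained={p.agent_id: 0 for p in profiles},
    )
    trajectory: list[float] = []
    for _ in range(n_runs):
        host_idx = int(rng.integers(n_agents))
        condition = bank[int(rng.integers(len(bank)))]
        host = profiles[host_idx]
        peers = [p for p in profiles if p.agent_id != host.agent_id]
        result = run_negotiation(host, peers, condition, policy=policy)
        gained = 0
        for agent_id, frame in result.transfers.items():
            if agent_id == host.agent_id:
                continue  # the host's own records move nowhere
            n = len(frame)
            ledger.provided[agent_id] += n
            gained += n
        ledger.obtained[host.agent_id] += gained
        ledger.runs += 1
        trajectory.append(ledger.imbalance())
    return ledger, trajectory


# --- full release pipeline ----------------------------------------------------


def build_rsdb(
    host: AgentProfile,
    peers: Sequence[AgentProfile],
    condition: StudyCondition,
    study_key: bytes | str,
    node_keys: dict[str, bytes | str],
    privacy: PrivacyParams | None = None,
    policy: HostPolicy | None = None,
) -> tuple[ResearchDatabase, NegotiationResult]:
    """Negotiate, then push every contribution through the release pipeline.

    Each transferring agent pseudonymizes its records under the shared
    study key, generalizes them to the negotiated k, signs the bundle with
    its own key, and the host verifies and ingests.  Returns the assembled
    research database and the negotiation result.
    """
    if privacy is None:
        privacy = default_privacy_params(condition.privacy_k or 2)
    result = run_negotiation(host, peers, condition, policy=policy)
    rsdb = ResearchDatabase(condition=condition, privacy=privacy)
    if result.allocation is None:
        return rsdb, result
    for agent_id, frame in result.transfers.items():
        if len(frame) == 0:
            continue
        frame = frame.copy()
        frame["pseudonym"] = frame["pseudonym"].map(
            lambda pid: pseudonymize(pid, study_key)
        )
        released = generalize(frame, privacy)
        payload = serialize_released(released)
        bundle = sign_bundle(payload, agent_id, node_keys[agent_id])
        ingest(rsdb, bundle, node_keys[agent_id], result.allocation.quotas[agent_id])
    return rsdb, result
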