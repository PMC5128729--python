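"""Release pipeline applied before any record leaves a node:
pseudonymize → generalize (k-anonymity) → sign.

Pseudonyms are keyed one-way digests (HMAC-SHA256 of the patient id under
a shared study key), so the same patient contributed by different nodes
maps to a single research-database identity without revealing who they
are.  Generalization follows binary trees: each quasi-identifier (QID)
attribute has a tree whose root spans the attribute's whole domain and
whose children split each interval in half; replacing an exact value by
one of its ancestor intervals coarsens it.  A release is k-anonymous when
every combination of generalized QID values is shared by at least k
records, bounding the re-identification probability by 1/k.

Level selection is a greedy lift from the leaves upward: all attributes
start at leaf level, and while some equivalence class is smaller than k
the attribute whose intervals are currently narrowest (deepest level;
ties broken by QID order) is lifted one level — the lift with the smallest
marginal utility cost.  Because that path through level space does not
depend on k, raising k can only move the stopping point further along it:
intervals only widen or stay equal as k grows.  Records that cannot reach
a class of size ≥ k even at the root (fewer than k records in total) are
suppressed.

Bundle signatures are HMAC-SHA256 over the serialized payload under the
signing node's key; verification succeeds iff the payload is unmodified
and the key matches.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GeneralizationTree",
    "CategoricalTree",
    "PrivacyParams",
    "ReleasedRecord",
    "SignedBundle",
    "pseudonymize",
    "generalize",
    "sign_bundle",
    "verify_bundle",
    "default_privacy_params",
]

DEFAULT_K = 2

#: default quasi-identifier set for the neonatal schema
DEFAULT_QID = ("body_weight", "gestational_age", "postnatal_age", "gender")


@dataclass(frozen=True)
class GeneralizationTree:
    """Binary interval hierarchy over a numeric attribute's domain.

    Level 0 is the root interval [lo, hi]; level L splits it into 2**L
    equal half-open cells (the last cell is closed at ``hi``); ``depth``
    is the leaf level.
    """

    attribute: str
    lo: float
    hi: float
    depth: int

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("root interval must be non-degenerate")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    def interval(self, value: float, level: int) -> tuple[float, float]:
        """The level-``level`` ancestor interval containing ``value``."""
        if not 0 <= level <= self.depth:
            raise ValueError(f"level must be in [0, {self.depth}]")
        if not self.lo <= value <= self.hi:
            raise ValueError(
                f"{self.attribute} value {value} outside domain "
                f"[{self.lo}, {self.hi}]"
            )
        cells = 2**level
        width = (self.hi - self.lo) / cells
        idx = min(int((value - self.lo) / width), cells - 1)
        return (self.lo + idx * width, self.lo + (idx + 1) * width)

    def width_at(self, level: int) -> float:
        return (self.hi - self.lo) / 2**level


@dataclass(frozen=True)
class CategoricalTree:
    """Two-level hierarchy for a categorical attribute: value or whole set."""

    attribute: str
    values: tuple = ("M", "F")
    depth: int = 1

    def interval(self, value, level: int):
        if value not in self.values:
            raise ValueError(f"{self.attribute} value {value!r} not in domain")
        return frozenset(self.values) if level == 0 else frozenset({value})

    def width_at(self, level: int) -> float:
        return 1.0 if level == 0 else 1.0 / len(self.values)


@dataclass(frozen=True)
class PrivacyParams:
    k: int = DEFAULT_K
    qid: tuple[str, ...] = DEFAULT_QID
    trees: Mapping[str, GeneralizationTree | CategoricalTree] = None  # type: ignore

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.trees is None:
            object.__setattr__(self, "trees", default_trees())
        missing = [a for a in self.qid if a not in self.trees]
        if missing:
            raise ValueError(f"no generalization tree for QID attribute(s) {missing}")


def default_trees() -> dict:
    """Default hierarchies for the neonatal schema.

    Leaf widths: 156.25 g body weight, 3 weeks gestational age, 4 days
    postnatal age; gender generalizes to {M, F}.
    """
    return {
        "body_weight": GeneralizationTree("body_weight", 0.0, 5000.0, depth=5),
        "gestational_age": GeneralizationTree("gestational_age", 20.0, 44.0, depth=3),
        "postnatal_age": GeneralizationTree("postnatal_age", 0.0, 32.0, depth=3),
        "gender": CategoricalTree("gender"),
    }


def default_privacy_params(k: int = DEFAULT_K) -> PrivacyParams:
    return PrivacyParams(k=k)


@dataclass(frozen=True)
class ReleasedRecord:
    """A record after pseudonymization and generalization.

    QID values are intervals encoded "lo..hi" (numeric) or "v1|v2"
    (categorical); non-QID values pass through untouched.
    """

    pseudonym: str
    values: Mapping[str, object]

    def qid_signature(self, qid: Sequence[str]) -> tuple:
        return tuple(self.values[a] for a in qid)


# --- pseudonymization --------------------------------------------------------


def pseudonymize(patient_id: str, secret_key: bytes | str) -> str:
    """Deterministic keyed one-way digest of a patient identifier.

    Same (id, key) always maps to the same pseudonym, so contributions
    about one patient from different nodes sharing the study key merge to
    a single research-database identity; without the key the mapping is
    infeasible to invert.
    """
    if not secret_key:
        raise ValueError("secret key must be non-empty")
    key = secret_key.encode() if isinstance(secret_key, str) else secret_key
    return hmac.new(key, str(patient_id).encode(), hashlib.sha256).hexdigest()


# --- generalization ----------------------------------------------------------


def _encode(interval) -> str:
    if isinstance(interval, frozenset):
        return "|".join(sorted(interval))
    lo, hi = interval
    return f"{lo:g}..{hi:g}"


def _lift_path(params: PrivacyParams) -> list[dict[str, int]]:
    """The k-independent sequence of uniform level assignments, deepest first.

    Step i+1 lifts (by one level) the attribute currently at the deepest
    level, ties broken by QID order; the path ends at the all-root
    assignment.
    """
    levels = {a: params.trees[a].depth for a in params.qid}
    path = [dict(levels)]
    while any(v > 0 for v in levels.values()):
        deepest = max(
            (a for a in params.qid if levels[a] > 0),
            key=lambda a: (levels[a], -params.qid.index(a)),
        )
        levels[deepest] -= 1
        path.append(dict(levels))
    return path


def _classes(df: pd.DataFrame, params: PrivacyParams, levels: Mapping[str, int]):
    labels = pd.DataFrame(
        {
            a: df[a].map(lambda v, a=a: _encode(params.trees[a].interval(v, levels[a])))
            for a in params.qid
        }
    )
    sizes = labels.assign(_one=1).groupby(list(params.qid), sort=False)["_one"].transform(
        "size"
    )
    return labels, sizes


def generalize(
    records: Sequence[Mapping] | pd.DataFrame, params: PrivacyParams
) -> list[ReleasedRecord]:
    """Generalize QID values until every equivalence class has size ≥ k.

    Records missing a QID value are rejected up front.  Records that
    cannot reach a class of size ≥ k even at the root level (i.e. fewer
    than k records in total) are suppressed.  Output order follows input
    order.
    """
    if isinstance(records, pd.DataFrame):
        df = records.reset_index(drop=True)
    else:
        df = pd.DataFrame([dict(r) for r in records])
    if df.empty:
        return []
    for attr in params.qid:
        if attr not in df.columns:
            raise ValueError(f"records lack QID attribute {attr!r}")
        bad = df[attr].isna()
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} record(s) missing QID value for {attr!r}; "
                "complete records are required for release"
            )
    if len(df) < params.k:
        return []  # even the root class is too small: suppress everything

    for levels in _lift_path(params):
        labels, class_sizes = _classes(df, params, levels)
        if (class_sizes >= params.k).all():
            break
    # the loop always terminates feasibly: at all-root levels there is a
    # single class of size len(df) >= k

    non_qid = [c for c in df.columns if c not in params.qid and c != "pseudonym"]
    out = []
    for i in range(len(df)):
        values = {a: labels.iloc[i][a] for a in params.qid}
        for c in non_qid:
            values[c] = df.iloc[i][c]
        out.append(ReleasedRecord(pseudonym=str(df.iloc[i]["pseudonym"]), values=values))
    return out


def chosen_levels(
    records: Sequence[Mapping] | pd.DataFrame, params: PrivacyParams
) -> dict[str, int]:
    """The uniform level assignment :func:`generalize` would use (for audit)."""
    if isinstance(records, pd.DataFrame):
        df = records.reset_index(drop=True)
    else:
        df = pd.DataFrame([dict(r) for r in records])
    if len(df) < params.k:
        raise ValueError("all records would be suppressed")
    for levels in _lift_path(params):
        _, class_sizes = _classes(df, params, levels)
        if (class_sizes >= params.k).all():
            return levels
    raise AssertionError("unreachable: root assignment is always feasible")


# --- signatures --------------------------------------------------------------


@dataclass(frozen=True)
class SignedBundle:
    payload: bytes
    signer_id: str
    signature: bytes

    def to_json(self) -> str:
        return json.dumps(
            {
                "signer_id": self.signer_id,
                "payload": base64.b64encode(self.payload).decode(),
                "signature": base64.b64encode(self.signature).decode(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SignedBundle":
        data = json.loads(text)
        return cls(
            payload=base64.b64decode(data["payload"]),
            signer_id=data["signer_id"],
            signature=base64.b64decode(data["signature"]),
        )


def serialize_released(records: Iterable[ReleasedRecord]) -> bytes:
    """Canonical JSON payload for a collection of released records."""

    def clean(v):
        if isinstance(v, float) and math.isnan(v):
            return None
        if hasattr(v, "item"):  # numpy scalar
            return v.item()
        return v

    return json.dumps(
        [
            {"pseudonym": r.pseudonym, "values": {k: clean(v) for k, v in r.values.items()}}
            for r in records
        ],
        sort_keys=True,
    ).encode()


def deserialize_released(payload: bytes) -> list[ReleasedRecord]:
    return [
        ReleasedRecord(pseudonym=d["pseudonym"], values=d["values"])
        for d in json.loads(payload.decode())
    ]


def sign_bundle(payload: bytes, signer_id: str, signer_key: bytes | str) -> SignedBundle:
    if not signer_key:
        raise ValueError("signing key must be non-empty")
    key = signer_key.encode() if isinstance(signer_key, str) else signer_key
    sig = hmac.new(key, payload, hashlib.sha256).digest()
    return SignedBundle(payload=payload, signer_id=signer_id, signature=sig)


def verify_bundle(bundle: SignedBundle, key: bytes | str) -> bool:
    """True iff the payload is unmodified and the key pair matches."""
    if not key:
        raise ValueError("verification key must be non-empty")
    key = key.encode() if isinstance(key, str) else key
    expected = hmac.new(key, bundle.payload, hashlib.sha256).digest()
    return hmac.compare_digest(expected, bundle.signature)
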