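"""Core domain types for distributed clinical-data aggregation.

A *local database* (LDB) is modelled as a :class:`Dataset`: a table of
patient records plus the set of keywords under which its owner advertises
it.  A *study condition* describes what a host wants to collect: keywords,
per-attribute range constraints, and a target record count N.  The
operations here — record-level matching, dataset querying, and balanced
random partitioning — are the primitives every other layer (negotiation,
privacy, experiments) is built on.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaMismatchError",
    "KeywordSet",
    "PatientRecord",
    "Dataset",
    "AttributeConstraint",
    "StudyCondition",
    "record_matches",
    "query_dataset",
    "partition_dataset",
]

#: canonical column order for neonatal TDM records
CLINICAL_COLUMNS = (
    "pseudonym",
    "body_weight",
    "gestational_age",
    "postnatal_age",
    "gender",
    "concentration",
)

GENDERS = ("M", "F")


class SchemaMismatchError(KeyError):
    """A condition references an attribute the dataset does not carry."""


def _normalize_keywords(keywords: Iterable[str]) -> frozenset[str]:
    out = set()
    for kw in keywords:
        kw = str(kw).strip()
        if not kw:
            raise ValueError("keywords must be non-empty strings")
        out.add(kw.casefold())
    if not out:
        raise ValueError("keyword set must be non-empty")
    return frozenset(out)


class KeywordSet(frozenset):
    """Case-normalized, duplicate-free set of topic keywords.

    Matching throughout the system is plain case-insensitive string
    equality — no stemming, no ontology.
    """

    def __new__(cls, keywords: Iterable[str]):
        return super().__new__(cls, _normalize_keywords(keywords))

    def issubset(self, other: Iterable[str]) -> bool:  # type: ignore[override]
        other = other if isinstance(other, KeywordSet) else KeywordSet(other)
        return frozenset.issubset(self, other)


@dataclass(frozen=True)
class PatientRecord:
    """One pseudonymized clinical observation.

    Units: body weight in grams, gestational age in weeks, postnatal age
    in days, drug concentration in mg/L.  ``concentration`` may be ``None``
    in raw input (incomplete records are discarded at query time).
    """

    pseudonym: str
    body_weight: float
    gestational_age: float
    postnatal_age: float
    gender: str
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError(f"body_weight must be > 0, got {self.body_weight}")
        if self.gestational_age <= 0:
            raise ValueError(
                f"gestational_age must be > 0, got {self.gestational_age}"
            )
        if self.postnatal_age < 0:
            raise ValueError(
                f"postnatal_age must be >= 0, got {self.postnatal_age}"
            )
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    def as_mapping(self) -> dict:
        return {
            "pseudonym": self.pseudonym,
            "body_weight": self.body_weight,
            "gestational_age": self.gestational_age,
            "postnatal_age": self.postnatal_age,
            "gender": self.gender,
            "concentration": self.concentration,
        }


@dataclass
class Dataset:
    """An LDB: an ordered record table plus its advertised keywords.

    ``records`` is a :class:`pandas.DataFrame` whose first column is the
    pseudonym; all other columns are clinical attributes.  Schemas may
    differ between datasets (e.g. decoy datasets carry only age/gender).
    """

    records: pd.DataFrame
    keywords: KeywordSet
    name: str = "dataset"

    def __post_init__(self) -> None:
        if not isinstance(self.keywords, KeywordSet):
            self.keywords = KeywordSet(self.keywords)
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def attributes(self) -> list[str]:
        return [c for c in self.records.columns if c != "pseudonym"]

    @classmethod
    def from_patient_records(
        cls,
        records: Sequence[PatientRecord],
        keywords: Iterable[str],
        name: str = "dataset",
    ) -> "Dataset":
        df = pd.DataFrame(
            [r.as_mapping() for r in records], columns=list(CLINICAL_COLUMNS)
        )
        return cls(records=df, keywords=KeywordSet(keywords), name=name)

    # --- CSV + JSON sidecar I/O -------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write records as CSV and keywords/name as a JSON sidecar."""
        path = Path(path)
        self.records.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps(
                {"name": self.name, "keywords": sorted(self.keywords)}, indent=2
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text())
        return cls(records=df, keywords=KeywordSet(meta["keywords"]), name=meta["name"])


WILDCARD = None  # an absent bound or value set means "any"


@dataclass(frozen=True)
class AttributeConstraint:
    """Inclusive range (or categorical-set) constraint on one attribute.

    ``min``/``max`` of ``None`` are wildcards; a constraint with all
    wildcards still *names* the attribute, which matters for missing-value
    handling: a record missing a value for a named attribute never matches.
    """

    attribute: str
    min: float | None = None
    max: float | None = None
    categorical_values: frozenset | None = None

    def __post_init__(self) -> None:
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(
                f"{self.attribute}: min {self.min} exceeds max {self.max}"
            )
        if self.categorical_values is not None:
            object.__setattr__(
                self, "categorical_values", frozenset(self.categorical_values)
            )

    @property
    def is_wildcard(self) -> bool:
        return self.min is None and self.max is None and self.categorical_values is None

    def accepts(self, value) -> bool:
        """True iff a non-missing value satisfies this constraint."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return False  # missing values never match a named attribute
        if self.categorical_values is not None:
            return value in self.categorical_values
        if self.min is not None and value < self.min:
            return False
        if self.max is not None and value > self.max:
            return False
        return True


@dataclass(frozen=True)
class StudyCondition:
    """The content contract a host proposes: t3 = parameters(KW, attr ranges, N).

    ``privacy_k`` is the proposed k-anonymity parameter; it is negotiable
    alongside the schema/content terms.
    """

    keywords: KeywordSet
    constraints: tuple[AttributeConstraint, ...]
    n_records: int
    privacy_k: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.keywords, KeywordSet):
            object.__setattr__(self, "keywords", KeywordSet(self.keywords))
        object.__setattr__(self, "constraints", tuple(self.constraints))
        if len(self.constraints) < 1:
            raise ValueError("a condition needs at least one attribute constraint")
        names = [c.attribute for c in self.constraints]
        if len(set(names)) != len(names):
            raise ValueError("constraint attribute names must be unique")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.privacy_k is not None and self.privacy_k < 1:
            raise ValueError("privacy_k must be >= 1")

    def to_json(self) -> str:
        """Serialize mirroring the tuple field order (KW, ranges..., N)."""
        return json.dumps(
            {
                "keywords": sorted(self.keywords),
                "constraints": [
                    {
                        "attribute": c.attribute,
                        "min": c.min,
                        "max": c.max,
                        "categorical_values": (
                            sorted(c.categorical_values)
                            if c.categorical_values is not None
                            else None
                        ),
                    }
                    for c in self.constraints
                ],
                "n_records": self.n_records,
                "privacy_k": self.privacy_k,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StudyCondition":
        data = json.loads(text)
        return cls(
            keywords=KeywordSet(data["keywords"]),
            constraints=tuple(
                AttributeConstraint(
                    attribute=c["attribute"],
                    min=c.get("min"),
                    max=c.get("max"),
                    categorical_values=(
                        frozenset(c["categorical_values"])
                        if c.get("categorical_values") is not None
                        else None
                    ),
                )
                for c in data["constraints"]
            ),
            n_records=data["n_records"],
            privacy_k=data.get("privacy_k"),
        )


# --- Operations ------------------------------------------------------------


def record_matches(
    record: PatientRecord | Mapping, condition: StudyCondition
) -> bool:
    """True iff every constraint of ``condition`` is satisfied by ``record``.

    Numeric bounds are inclusive on both ends.  Keywords are *not* checked
    here — keyword matching happens at capability level during negotiation.
    A record with a missing value for any conditioned attribute never
    matches.

    Raises
    ------
    SchemaMismatchError
        If the condition names an attribute the record does not have.
    """
    mapping = record.as_mapping() if isinstance(record, PatientRecord) else record
    for constraint in condition.constraints:
        if constraint.attribute not in mapping:
            raise SchemaMismatchError(
                f"record has no attribute {constraint.attribute!r}"
            )
        value = mapping[constraint.attribute]
        missing = value is None or (isinstance(value, float) and math.isnan(value))
        if missing:
            return False
        if constraint.is_wildcard:
            continue
        if not constraint.accepts(value):
            return False
    return True


def query_dataset(dataset: Dataset, condition: StudyCondition) -> pd.DataFrame:
    """All records of ``dataset`` matching ``condition``, in input order.

    Vectorized equivalent of a per-record :func:`record_matches` scan.
    Capping to the requested N is the negotiation layer's job, not the
    query's.
    """
    df = dataset.records
    if df.empty:
        for constraint in condition.constraints:
            if constraint.attribute not in df.columns:
                raise SchemaMismatchError(
                    f"dataset {dataset.name!r} has no attribute "
                    f"{constraint.attribute!r}"
                )
        return df
    mask = pd.Series(True, index=df.index)
    for constraint in condition.constraints:
        if constraint.attribute not in df.columns:
            raise SchemaMismatchError(
                f"dataset {dataset.name!r} has no attribute {constraint.attribute!r}"
            )
        col = df[constraint.attribute]
        mask &= col.notna()
        if constraint.categorical_values is not None:
            mask &= col.isin(constraint.categorical_values)
        else:
            if constraint.min is not None:
                mask &= col >= constraint.min
            if constraint.max is not None:
                mask &= col <= constraint.max
    return df[mask]


def partition_dataset(
    dataset: Dataset, n_parts: int, seed: int
) -> list[Dataset]:
    """Split a dataset uniformly at random into ``n_parts`` balanced parts.

    Every record lands in exactly one part; part sizes differ by at most 1;
    the split is deterministic for a fixed seed.  Parts may be empty when
    ``n_parts`` exceeds the record count.
    """
    if n_parts < 1:
        raise ValueError("n_parts must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset.records))
    chunks = np.array_split(order, n_parts)
    return [
        Dataset(
            records=dataset.records.iloc[np.sort(chunk)].reset_index(drop=True),
            keywords=dataset.keywords,
            name=f"{dataset.name}/part{i}",
        )
        for i, chunk in enumerate(chunks)
    ]
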