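"""Research database (RSDB) assembly from signed, anonymized contributions.

An RSDB is built under a negotiated study condition and accepts only
bundles of released records (pseudonymized + generalized) whose signature
verifies under the sender's key and whose size fits the sender's quota.
Contributions about the same patient — recognizable because shared-key
pseudonyms are deterministic — update the existing entry instead of
creating a duplicate row.  The RSDB's metadata (keywords, condition
summary, record count, privacy k — never record-level data) is published
at the broker so a later study with similar requirements can reuse the
database instead of re-aggregating.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .broker import Broker, Publication, Subscription
from .data_model import KeywordSet, StudyCondition
from .privacy import (
    PrivacyParams,
    ReleasedRecord,
    SignedBundle,
    deserialize_released,
    verify_bundle,
)

__all__ = ["ResearchDatabase", "IngestError", "ingest", "publish_metadata"]

logger = logging.getLogger(__name__)


class IngestError(RuntimeError):
    """A bundle failed verification or exceeded its quota."""


def _interval_overlaps(encoded: str, lo: float | None, hi: float | None) -> bool:
    try:
        a, b = (float(x) for x in encoded.split(".."))
    except (ValueError, AttributeError):
        return True  # categorical or passthrough values: no range audit
    if lo is not None and b < lo:
        return False
    if hi is not None and a > hi:
        return False
    return True


@dataclass
class ResearchDatabase:
    """The aggregated, anonymized study database and its accounting."""

    condition: StudyCondition
    privacy: PrivacyParams
    name: str = "rsdb"
    records: dict[str, ReleasedRecord] = field(default_factory=dict)  # by pseudonym
    contributions: dict[str, int] = field(default_factory=dict)
    merges: int = 0
    containment_violations: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def keywords(self) -> KeywordSet:
        return self.condition.keywords

    def metadata(self) -> dict:
        """Shareable descriptor; contains no record-level data."""
        return {
            "name": self.name,
            "keywords": sorted(self.keywords),
            "condition": json.loads(self.condition.to_json()),
            "record_count": len(self.records),
            "privacy_k": self.privacy.k,
            "contributors": sorted(self.contributions),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pseudonym": p, **r.values} for p, r in self.records.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(self.metadata(), indent=2)
        )


def ingest(
    rsdb: ResearchDatabase,
    bundle: SignedBundle,
    sender_key: bytes | str,
    quota: int,
) -> ResearchDatabase:
    """Verify and absorb one signed contribution.

    Rejects (raising :class:`IngestError`, leaving the RSDB unchanged)
    bundles that fail signature verification or exceed the sender's quota.
    Records whose pseudonym is already present update the existing entry
    field-wise (one patient, one row).  Generalized intervals that do not
    even overlap the requested range are logged as containment violations
    for audit but still ingested.
    """
    if not verify_bundle(bundle, sender_key):
        logger.error("bundle from %r failed verification; rejected", bundle.signer_id)
        raise IngestError(f"signature verification failed for {bundle.signer_id!r}")
    released = deserialize_released(bundle.payload)
    if len(released) > quota:
        logger.error(
            "bundle from %r has %d records, quota %d; rejected",
            bundle.signer_id,
            len(released),
            quota,
        )
        raise IngestError(f"quota exceeded by {bundle.signer_id!r}")
    for rec in released:
        for c in rsdb.condition.constraints:
            if c.attribute in rec.values and not c.is_wildcard:
                if c.categorical_values is None and not _interval_overlaps(
                    rec.values[c.attribute], c.min, c.max
                ):
                    rsdb.containment_violations.append(
                        f"{rec.pseudonym}:{c.attribute}"
                    )
        if rec.pseudonym in rsdb.records:
            # same patient seen again: field-wise replace, no new row
            merged = dict(rsdb.records[rec.pseudonym].values)
            merged.update(rec.values)
            rsdb.records[rec.pseudonym] = ReleasedRecord(rec.pseudonym, merged)
            rsdb.merges += 1
        else:
            rsdb.records[rec.pseudonym] = rec
    rsdb.contributions[bundle.signer_id] = (
        rsdb.contributions.get(bundle.signer_id, 0) + len(released)
    )
    return rsdb


def publish_metadata(
    rsdb: ResearchDatabase, broker: Broker, node_address: str
) -> list[Subscription]:
    """Publish the RSDB's metadata at the broker under its keywords.

    Subscribers whose keyword requirements match are notified, so a
    similar later study can reuse the database instead of aggregating
    again.  Returns the notified subscriptions.
    """
    if len(rsdb) == 0:
        raise ValueError("refusing to publish metadata for an empty RSDB")
    publication = Publication(
        node_address=node_address,
        keywords=rsdb.keywords,
        metadata=rsdb.metadata(),
    )
    return broker.publish(publication)
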