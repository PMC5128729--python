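"""Keyword publish/subscribe broker: the P2P lookup system.

Nodes register, then either publish the availability of data under a set
of keywords or subscribe with the keywords they are interested in.  A
subscription matches a publication when the subscription's keyword set is
a subset of the publication's (the subscriber names a topic; publishers
may be more specific).  Matching is case-insensitive exact string
equality.  Subscriptions are retained and matched against publications
that arrive later; symmetrically, a new subscription is immediately
answered with the addresses of all already-published matches.

The broker never stores record-level data — only addresses, keywords, and
free-form metadata descriptors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

from .data_model import KeywordSet

__all__ = ["Publication", "Subscription", "Broker", "NotRegisteredError"]

logger = logging.getLogger(__name__)


class NotRegisteredError(RuntimeError):
    """A node tried to publish or subscribe before registering."""


@dataclass(frozen=True)
class Publication:
    node_address: str
    keywords: KeywordSet
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.keywords, KeywordSet):
            object.__setattr__(self, "keywords", KeywordSet(self.keywords))


@dataclass(frozen=True)
class Subscription:
    subscriber_address: str
    keywords: KeywordSet

    def __post_init__(self) -> None:
        if not isinstance(self.keywords, KeywordSet):
            object.__setattr__(self, "keywords", KeywordSet(self.keywords))

    def matches(self, publication: Publication) -> bool:
        return self.keywords.issubset(publication.keywords)


class Broker:
    """In-process publish/subscribe broker with ordered, reliable delivery."""

    def __init__(self) -> None:
        self.registered_nodes: set[str] = set()
        self.publications: list[Publication] = []
        self.subscriptions: list[Subscription] = []

    def register_node(self, address: str) -> None:
        """Register a node address; idempotent."""
        if not address:
            raise ValueError("address must be non-empty")
        self.registered_nodes.add(address)

    def publish(self, publication: Publication) -> list[Subscription]:
        """Store a publication and return the subscriptions it notifies.

        Publishing never fails for lack of subscribers (decoupling).
        """
        if publication.node_address not in self.registered_nodes:
            raise NotRegisteredError(
                f"publisher {publication.node_address!r} is not registered"
            )
        self.publications.append(publication)
        notified = [s for s in self.subscriptions if s.matches(publication)]
        logger.debug(
            "publish %s by %s -> %d notification(s)",
            sorted(publication.keywords),
            publication.node_address,
            len(notified),
        )
        return notified

    def subscribe(self, subscription: Subscription) -> list[str]:
        """Store a subscription; return addresses of prior matching publishers.

        Addresses are returned in publication order.  Subscribing never
        fails for lack of publications.
        """
        if subscription.subscriber_address not in self.registered_nodes:
            raise NotRegisteredError(
                f"subscriber {subscription.subscriber_address!r} is not registered"
            )
        self.subscriptions.append(subscription)
        return [
            p.node_address for p in self.publications if subscription.matches(p)
        ]

    def to_json(self) -> str:
        """Snapshot of broker state (addresses, keywords, metadata only)."""
        return json.dumps(
            {
                "registered_nodes": sorted(self.registered_nodes),
                "publications": [
                    {
                        "node_address": p.node_address,
                        "keywords": sorted(p.keywords),
                        "metadata": p.metadata,
                    }
                    for p in self.publications
                ],
                "subscriptions": [
                    {
                        "subscriber_address": s.subscriber_address,
                        "keywords": sorted(s.keywords),
                    }
                    for s in self.subscriptions
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Broker":
        data = json.loads(text)
        broker = cls()
        broker.registered_nodes = set(data["registered_nodes"])
        broker.publications = [
            Publication(
                node_address=p["node_address"],
                keywords=KeywordSet(p["keywords"]),
                metadata=p.get("metadata", {}),
            )
            for p in data["publications"]
        ]
        broker.subscriptions = [
            Subscription(
                subscriber_address=s["subscriber_address"],
                keywords=KeywordSet(s["keywords"]),
            )
            for s in data["subscriptions"]
        ]
        return broker
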