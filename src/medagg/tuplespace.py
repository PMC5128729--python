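"""A minimal programmable tuple centre (Linda-style coordination).

A tuple centre is a shared multiset of logic tuples that agents manipulate
with three primitives — ``out`` (write), ``rd`` (read without removal),
``in_`` (consume) — plus *reactions*: rules that fire atomically on tuple
events and may themselves perform further tuple operations, which is what
lets the centre drive a negotiation state machine instead of being a
passive bag.

Reactions here are plain trigger/guard/effect records rather than a
first-order-logic script language; operationally they play the same role.
``rd``/``in_`` are non-blocking (the simulator is turn-based; blocking is
modelled by the caller re-polling) and tie-breaking among multiple
matching tuples is insertion order, so every run replays deterministically.
Every primitive call and reaction firing is appended to an event log that
can be dumped as JSON lines for audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "LogicTuple",
    "TupleTemplate",
    "Reaction",
    "TupleCenter",
    "ReactionDepthError",
    "ANY",
]

logger = logging.getLogger(__name__)

#: wildcard argument pattern in templates
ANY = object()

#: reactions may cascade; a chain deeper than this signals a runaway script
DEFAULT_MAX_REACTION_DEPTH = 100


class ReactionDepthError(RuntimeError):
    """Reaction chain exceeded the configured depth bound."""


@dataclass(frozen=True)
class LogicTuple:
    functor: str
    args: tuple = ()

    def __post_init__(self) -> None:
        if not self.functor:
            raise ValueError("functor must be non-empty")
        object.__setattr__(self, "args", tuple(self.args))

    @property
    def arity(self) -> int:
        return len(self.args)

    def __repr__(self) -> str:
        return f"{self.functor}({', '.join(map(repr, self.args))})"


@dataclass(frozen=True)
class TupleTemplate:
    """Pattern over tuples: fixed functor, per-argument constant or ANY."""

    functor: str
    patterns: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "patterns", tuple(self.patterns))

    def matches(self, tup: LogicTuple) -> bool:
        if tup.functor != self.functor or tup.arity != len(self.patterns):
            return False
        return all(p is ANY or p == a for p, a in zip(self.patterns, tup.args))


@dataclass
class Reaction:
    """Fires when ``event`` ("out" or "in") occurs on a tuple matching
    ``template`` and ``guard(tc, tuple)`` holds; ``effect(tc, tuple)`` then
    runs atomically with the triggering operation (its own tuple operations
    may trigger further reactions, depth-bounded).
    """

    event: str
    template: TupleTemplate
    effect: Callable[["TupleCenter", LogicTuple], None]
    guard: Callable[["TupleCenter", LogicTuple], bool] = lambda tc, t: True
    name: str = ""


class TupleCenter:
    """Multiset of logic tuples with reactions; insertion-ordered matching."""

    def __init__(self, max_reaction_depth: int = DEFAULT_MAX_REACTION_DEPTH) -> None:
        self.tuples: list[LogicTuple] = []
        self.reactions: list[Reaction] = []
        self.reusable: bool = False
        self.max_reaction_depth = max_reaction_depth
        self.event_log: list[dict] = []
        self._depth = 0

    # --- primitives --------------------------------------------------------

    def out(self, tup: LogicTuple) -> None:
        """Write a tuple; out-reactions fire atomically with the write."""
        self.tuples.append(tup)
        self._log("out", tup)
        self._fire("out", tup)

    def rd(self, template: TupleTemplate) -> LogicTuple | None:
        """Read (no removal) the earliest-inserted matching tuple, if any."""
        for tup in self.tuples:
            if template.matches(tup):
                self._log("rd", tup)
                return tup
        self._log("rd-miss", template)
        return None

    def in_(self, template: TupleTemplate) -> LogicTuple | None:
        """Consume the earliest-inserted matching tuple, if any."""
        for i, tup in enumerate(self.tuples):
            if template.matches(tup):
                del self.tuples[i]
                self._log("in", tup)
                self._fire("in", tup)
                return tup
        self._log("in-miss", template)
        return None

    def count(self, template: TupleTemplate) -> int:
        return sum(1 for t in self.tuples if template.matches(t))

    def clear(self) -> None:
        """Empty the centre (used when a reusable centre is recycled)."""
        self.tuples.clear()
        self._log("clear", None)

    def add_reaction(self, reaction: Reaction) -> None:
        self.reactions.append(reaction)

    # --- reaction machinery -------------------------------------------------

    def _fire(self, event: str, tup: LogicTuple) -> None:
        self._depth += 1
        try:
            if self._depth > self.max_reaction_depth:
                raise ReactionDepthError(
                    f"reaction chain exceeded depth {self.max_reaction_depth}"
                )
            for reaction in list(self.reactions):
                if reaction.event != event or not reaction.template.matches(tup):
                    continue
                if not reaction.guard(self, tup):
                    continue
                self._log("reaction", tup, reaction=reaction.name or "<anonymous>")
                reaction.effect(self, tup)
        finally:
            self._depth -= 1

    # --- audit log ----------------------------------------------------------

    def _log(self, kind: str, subject, **extra) -> None:
        entry = {"event": kind, "subject": repr(subject), **extra}
        self.event_log.append(entry)
        logger.debug("tuple-center %s %r", kind, subject)

    def dump_log(self) -> str:
        """Event log as JSON lines."""
        return "\n".join(json.dumps(e) for e in self.event_log)
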