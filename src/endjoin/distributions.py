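"""Outcome distributions over event classes, and their summary statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .catalog import (DeletionClass, TargetContext, collapse_redundant,
                      enumerate_deletion_classes, parse_event_id)

_SUM_TOL = 1e-9


class DistributionError(ValueError):
    pass


@dataclass
class OutcomeDistribution:
    """Probability (or frequency) vector over event-class ids.

    Keys are event ids (``D:<start_rel_cut>:<length>``, ``I:<seq>``,
    ``I:LONG``); ``total_support`` carries the UMI count for observed
    distributions and is None for predictions.
    """

    probs: dict[str, float]
    total_support: int | None = None

    def __post_init__(self) -> None:
        for eid, p in self.probs.items():
            parse_event_id(eid)  # validates the grammar
            if p < 0:
                raise DistributionError(f"negative probability for {eid}")

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "OutcomeDistribution":
        total = sum(counts.values())
        if total <= 0:
            raise DistributionError("no counts to normalize")
        return cls({eid: c / total for eid, c in counts.items() if c > 0},
                   total_support=total)

    def is_normalized(self, tol: float = _SUM_TOL) -> bool:
        return abs(sum(self.probs.values()) - 1.0) <= tol

    def _require_normalized(self) -> None:
        if not self.is_normalized():
            raise DistributionError(
                f"distribution sums to {sum(self.probs.values())!r}, not 1")

    def normalized(self) -> "OutcomeDistribution":
        total = sum(self.probs.values())
        if total <= 0:
            raise DistributionError("cannot normalize an all-zero distribution")
        return OutcomeDistribution({e: p / total for e, p in self.probs.items()},
                                   total_support=self.total_support)

    def entropy_bits(self) -> float:
        return entropy(self)

    def frameshift_ratio(self, long_is_frameshift: bool = True) -> float:
        return frameshift_ratio(self, long_is_frameshift)

    def top_outcome(self) -> str:
        return max(self.probs, key=lambda e: (self.probs[e], e))


def entropy(dist: OutcomeDistribution) -> float:
    """Shannon entropy -sum p_i log2 p_i in bits, with 0 log 0 := 0."""
    dist._require_normalized()
    return -sum(p * math.log2(p) for p in dist.probs.values() if p > 0.0)


def _is_frameshift(event_id: str, long_is_frameshift: bool) -> bool:
    ev = parse_event_id(event_id)
    if isinstance(ev, DeletionClass):
        return ev.length % 3 != 0
    if ev.is_long:
        # >=3 bp insertions pool all lengths; 2 of every 3 shift frame
        return long_is_frameshift
    return len(ev.inserted_seq) % 3 != 0


def frameshift_ratio(dist: OutcomeDistribution,
                     long_is_frameshift: bool = True) -> float:
    """Probability mass on outcomes whose net length change is not 0 mod 3."""
    dist._require_normalized()
    return sum(p for e, p in dist.probs.items()
               if _is_frameshift(e, long_is_frameshift))


def evaluate_mse(pred: OutcomeDistribution, obs: OutcomeDistribution) -> float:
    """Mean over classes of the squared frequency difference.

    Both distributions must be expressed over the same class set (missing
    classes are not imputed silently).
    """
    if set(pred.probs) != set(obs.probs):
        raise DistributionError("class sets differ between the distributions")
    n = len(pred.probs)
    return sum((pred.probs[e] - obs.probs[e]) ** 2 for e in pred.probs) / n


def collapse_distribution(target: TargetContext, dist: OutcomeDistribution,
                          classes: list[DeletionClass] | None = None
                          ) -> OutcomeDistribution:
    """Sum redundant deletion-class mass onto canonical classes for a target.

    Insertion-class mass is untouched.  ``classes`` defaults to the
    deletion classes present in ``dist``.
    """
    cut = target.cut_index
    events = {eid: parse_event_id(eid, cut) for eid in dist.probs}
    dels = [ev for ev in events.values() if isinstance(ev, DeletionClass)]
    if classes is None:
        classes = enumerate_deletion_classes(target.config)
    pool = list(dict.fromkeys(list(classes) + dels))
    canon = collapse_redundant(target, pool)
    out: dict[str, float] = {}
    for eid, p in dist.probs.items():
        ev = events[eid]
        if isinstance(ev, DeletionClass):
            eid = canon[ev].event_id(cut)
        out[eid] = out.get(eid, 0.0) + p
    return OutcomeDistribution(out, total_support=dist.total_support)


@dataclass
class DistributionSummary:
    """Per-target roll-up reported next to a distribution."""

    n_support: int | None
    entropy_bits: float
    frameshift_ratio: float
    p_insertion: float
    top_outcome: str

    @classmethod
    def from_distribution(cls, dist: OutcomeDistribution) -> "DistributionSummary":
        p_ins = sum(p for e, p in dist.probs.items() if e.startswith("I:"))
        return cls(n_support=dist.total_support,
                   entropy_bits=dist.entropy_bits(),
                   frameshift_ratio=dist.frameshift_ratio(),
                   p_insertion=p_ins,
                   top_outcome=dist.top_outcome())
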