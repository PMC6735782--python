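"""Event-class catalog for Cas9 end-joining repair outcomes.

Everything downstream (features, model, caller, simulator) is defined on a
60 nt *target context* centered on the double-strand break: the blunt cut
falls on the boundary before offset 30, the 20 bp protospacer occupies
offsets [13, 33) (so the cut sits between its 17th and 18th bases) and the
NGG PAM occupies offsets [33, 36).

Repair outcomes are discretised into *event classes*:

* deletions, identified by ``(start, length)`` in context coordinates,
  restricted to length < 30 and overlap with the -3/+2 assignment window
  around the cut (offsets 27..31 inclusive) -- 550 classes by default;
* insertions, identified by the inserted 1-mer (4) or 2-mer (16) or a
  single sentinel class for insertions of 3 bp or more -- 21 classes.

Distinct deletion classes can yield byte-identical alleles on a specific
target when the deleted tract and its flank share sequence (microhomology);
:func:`collapse_redundant` groups such classes and elects the right-aligned
member as canonical.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

DNA = "ACGT"

CONTEXT_LENGTH = 60
CUT_INDEX = 30  # boundary before this offset
PROTOSPACER_SPAN = (13, 33)
PAM_SPAN = (33, 36)

#: sentinel for insertions of 3 bp or more
LONG = "LONG"

_EVENT_ID_RE = re.compile(r"^(D:(-?\d+):(\d+)|I:([ACGT]{1,2}|LONG))$")


class CatalogError(ValueError):
    """Invalid target, event or configuration."""


@dataclass(frozen=True)
class CatalogConfig:
    """Constants that shape the deletion-class universe.

    Defaults reproduce the canonical setup: 60 nt context, deletions
    shorter than 30 bp overlapping a window of 3 nt upstream + 2 nt
    downstream of the cut.
    """

    context_length: int = CONTEXT_LENGTH
    max_deletion_length: int = 29
    window_upstream: int = 3
    window_downstream: int = 2

    @property
    def cut_index(self) -> int:
        return self.context_length // 2

    def __post_init__(self) -> None:
        if self.context_length < 2 or self.context_length % 2:
            raise CatalogError("context_length must be a positive even number")
        if self.max_deletion_length < 0:
            raise CatalogError("max_deletion_length must be >= 0")
        if self.window_upstream < 0 or self.window_downstream < 0:
            raise CatalogError("window bounds must be >= 0")

    def window_positions(self) -> range:
        """Offsets of the assignment window (inclusive of both flanks)."""
        return range(self.cut_index - self.window_upstream,
                     self.cut_index + self.window_downstream)


DEFAULT_CONFIG = CatalogConfig()


@dataclass(frozen=True)
class TargetContext:
    """A 60 nt sequence centered on the Cas9 cut site.

    ``sequence`` must be A/C/G/T over the protospacer, PAM and assignment
    window; N is tolerated only in the distal context where no feature is
    defined.
    """

    sequence: str
    target_id: str = "target"
    config: CatalogConfig = field(default=DEFAULT_CONFIG, compare=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        n = self.config.context_length
        if len(seq) != n:
            raise CatalogError(
                f"target {self.target_id!r}: sequence length {len(seq)} != {n}")
        if not set(seq) <= set(DNA + "N"):
            raise CatalogError(
                f"target {self.target_id!r}: non-ACGTN characters present")
        cut = self.config.cut_index
        core = set(range(*PROTOSPACER_SPAN)) | set(range(*PAM_SPAN)) if n == CONTEXT_LENGTH else set()
        core |= {p for p in self.config.window_positions() if 0 <= p < n}
        if any(seq[p] == "N" for p in core):
            raise CatalogError(
                f"target {self.target_id!r}: N not allowed in protospacer/window region")

    @property
    def cut_index(self) -> int:
        return self.config.cut_index

    @property
    def protospacer(self) -> str:
        return self.sequence[PROTOSPACER_SPAN[0]:PROTOSPACER_SPAN[1]]

    @property
    def pam(self) -> str:
        return self.sequence[PAM_SPAN[0]:PAM_SPAN[1]]

    def hexamer(self) -> str:
        """6 nt centered on the cut (3 upstream + 3 downstream)."""
        return self.sequence[self.cut_index - 3:self.cut_index + 3]


@dataclass(frozen=True, order=True)
class DeletionClass:
    """Deletion of ``length`` bp starting at context offset ``start``."""

    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def event_id(self, cut_index: int = CUT_INDEX) -> str:
        return f"D:{self.start - cut_index}:{self.length}"


@dataclass(frozen=True, order=True)
class InsertionClass:
    """Insertion at the cut boundary of a 1-2 nt sequence or >=3 bp (LONG)."""

    inserted_seq: str

    def __post_init__(self) -> None:
        if self.inserted_seq != LONG and not (
                1 <= len(self.inserted_seq) <= 2
                and set(self.inserted_seq) <= set(DNA)):
            raise CatalogError(f"bad insertion class {self.inserted_seq!r}")

    @property
    def is_long(self) -> bool:
        return self.inserted_seq == LONG

    def event_id(self, cut_index: int = CUT_INDEX) -> str:
        return f"I:{self.inserted_seq}"


EventClass = DeletionClass | InsertionClass


def render_event_id(ev: EventClass, cut_index: int = CUT_INDEX) -> str:
    return ev.event_id(cut_index)


def parse_event_id(event_id: str, cut_index: int = CUT_INDEX) -> EventClass:
    """Parse ``D:<start_rel_cut>:<length>``, ``I:<seq>`` or ``I:LONG``."""
    m = _EVENT_ID_RE.match(event_id)
    if not m:
        raise CatalogError(f"malformed event id {event_id!r}")
    if event_id.startswith("D:"):
        return DeletionClass(start=int(m.group(2)) + cut_index,
                             length=int(m.group(3)))
    return InsertionClass(m.group(4))


def enumerate_deletion_classes(cfg: CatalogConfig = DEFAULT_CONFIG) -> list[DeletionClass]:
    """All deletions shorter than the cap whose interval stays inside the
    context and overlaps the assignment window, ordered by (length, start).

    With the default configuration this yields exactly 550 classes.
    """
    window = cfg.window_positions()
    if len(window) == 0:
        return []
    wlo, whi = window.start, window.stop - 1  # inclusive window offsets
    out: list[DeletionClass] = []
    for length in range(1, cfg.max_deletion_length + 1):
        # overlap: start <= whi and start + length - 1 >= wlo
        lo = max(0, wlo - length + 1)
        hi = min(whi, cfg.context_length - length)
        out.extend(DeletionClass(s, length) for s in range(lo, hi + 1))
    return out


def enumerate_insertion_classes() -> list[InsertionClass]:
    """The 21 insertion classes: 4 single-nt + 16 di-nt + LONG, LONG last."""
    singles = [InsertionClass(b) for b in DNA]
    doubles = [InsertionClass(a + b) for a in DNA for b in DNA]
    return singles + doubles + [InsertionClass(LONG)]


def synthetic_observed_deletion_classes(
        cfg: CatalogConfig = DEFAULT_CONFIG) -> list[DeletionClass]:
    """A synthetic 536-member observed-class list.

    Which 14 of the 550 potential deletion classes go unobserved in a real
    screen is a property of the data (mostly large deletions).  This
    synthetic stand-in reproduces the canonical length-group sizes -- 4
    classes of length 1, 6 of length 2, 7 of length 3 and 519 of length
    >= 4 -- by dropping the 13 largest classes (by length, then start,
    descending) and the most downstream 1 bp class.
    """
    full = enumerate_deletion_classes(cfg)
    big = sorted((c for c in full if c.length >= 4),
                 key=lambda c: (c.length, c.start))[-13:]
    len1 = max(c for c in full if c.length == 1)
    drop = set(big) | {len1}
    return [c for c in full if c not in drop]


def apply_event(target: TargetContext, ev: EventClass,
                long_seq: str | None = None) -> str:
    """Materialise the allele produced by one event on ``target``.

    Deletions remove ``[start, end)``; insertions insert at the cut
    boundary.  A LONG insertion has no defined sequence, so ``long_seq``
    (>= 3 nt) must be supplied explicitly.
    """
    seq = target.sequence
    if isinstance(ev, DeletionClass):
        if ev.start < 0 or ev.end > len(seq) or ev.length < 1:
            raise CatalogError(f"deletion {ev} outside context")
        return seq[:ev.start] + seq[ev.end:]
    if ev.is_long:
        if long_seq is None or len(long_seq) < 3 or not set(long_seq) <= set(DNA):
            raise CatalogError(
                "LONG insertion has no representable allele without an "
                "explicit inserted sequence of >= 3 nt")
        ins = long_seq
    else:
        ins = ev.inserted_seq
    cut = target.cut_index
    return seq[:cut] + ins + seq[cut:]


def collapse_redundant(target: TargetContext,
                       classes: list[DeletionClass]) -> dict[DeletionClass, DeletionClass]:
    """Map each deletion class to the canonical member of its redundancy group.

    Two classes are redundant on this target iff they produce identical
    allele strings (possible only for equal lengths, through repeated
    sequence).  The canonical representative is the right-aligned member,
    i.e. the one with the largest start.
    """
    groups: dict[str, list[DeletionClass]] = {}
    for c in classes:
        groups.setdefault(apply_event(target, c), []).append(c)
    out: dict[DeletionClass, DeletionClass] = {}
    for members in groups.values():
        canon = max(members, key=lambda c: c.start)
        for c in members:
            out[c] = canon
    return out


def design_mh_target(target: TargetContext, mh_len: int) -> TargetContext:
    """Program a microhomology tract into a target.

    Copies the ``mh_len`` nt immediately upstream of the cut to the
    ``mh_len`` positions starting immediately downstream of the PAM
    (offsets 36..35+mh_len), leaving a fixed 6 bp spacer between the two
    tracts, so that the expected microhomology-mediated deletion is
    ``6 + mh_len`` bp (8, 10 or 12 for tracts of 2, 4 or 6).
    """
    if mh_len not in (0, 2, 4, 6):
        raise CatalogError(f"mh_len must be one of 0, 2, 4, 6; got {mh_len}")
    if mh_len == 0:
        return target
    cut = target.cut_index
    tract = target.sequence[cut - mh_len:cut]
    dest = PAM_SPAN[1]
    seq = (target.sequence[:dest] + tract + target.sequence[dest + mh_len:])
    return TargetContext(seq, target_id=f"{target.target_id}_mh{mh_len}",
                         config=target.config)


def expected_programmed_deletion(mh_len: int,
                                 cut_index: int = CUT_INDEX) -> DeletionClass:
    """The deletion a programmed MH tract is designed to elicit.

    Joining the upstream tract to its downstream copy removes the 6 bp
    spacer plus one copy of the tract: a ``6 + mh_len`` bp deletion
    starting at the cut (class ``D:0:<6+mh_len>``).
    """
    if mh_len not in (2, 4, 6):
        raise CatalogError("programmed designs use mh_len in {2, 4, 6}")
    return DeletionClass(cut_index, 6 + mh_len)
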