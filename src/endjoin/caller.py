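"""Calling event classes from sequenced or simulated alleles.

The pipeline mirrors a UMI-consensus amplicon workflow: reads are grouped
by exact UMI, a consensus representative is elected per UMI (most common
read), low-identity reads and under-sequenced UMIs are filtered, and each
representative allele is aligned/compared against its target to yield an
:class:`AlleleCall`.  Indels are right-aligned, and a single indel is
assigned to its event class only when it overlaps the -3/+2 window around
the cut; everything else is wild-type, out-of-window or complex.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib
from Bio import Align

from .catalog import (DeletionClass, EventClass, InsertionClass, LONG,
                      TargetContext)
from .distributions import OutcomeDistribution

logger = logging.getLogger(__name__)

WILDTYPE = "wildtype"
DELETION = "deletion"
INSERTION = "insertion"
COMPLEX = "complex"
OUT_OF_WINDOW = "out_of_window"

UMI_LENGTH = 15
MIN_UMI_READS = 10
MIN_READ_IDENTITY = 0.9


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scoring: a gap of length g costs |open| + (g-1)|extend|."""

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -13.0
    gap_extend: float = -0.5
    n_mismatch: float | None = None  # score of any pairing involving N

    def __post_init__(self) -> None:
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError("need gap_open <= gap_extend <= 0")


DEFAULT_SCORING = AlignmentScoring()
#: preset used when discovering references in an N-masked backbone
REFERENCE_DISCOVERY_SCORING = AlignmentScoring(gap_open=-20.0, n_mismatch=0.0)


@dataclass
class Alignment:
    query_aligned: str
    ref_aligned: str
    score: float

    def has_gaps(self) -> bool:
        return "-" in self.query_aligned or "-" in self.ref_aligned


def _build_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    if scoring.n_mismatch is None:
        aligner.match_score = scoring.match
        aligner.mismatch_score = scoring.mismatch
    else:
        from Bio.Align import substitution_matrices
        alphabet = "ACGTN"
        m = substitution_matrices.Array(alphabet, dims=2)
        for a in alphabet:
            for b in alphabet:
                if "N" in (a, b):
                    m[a, b] = scoring.n_mismatch
                else:
                    m[a, b] = scoring.match if a == b else scoring.mismatch
        aligner.substitution_matrix = m
    return aligner


def global_align(query: str, reference: str,
                 scoring: AlignmentScoring = DEFAULT_SCORING) -> Alignment:
    """Optimal global affine-gap alignment, gaps pushed rightmost.

    The dynamic program is delegated to Biopython's PairwiseAligner (whose
    open/extend convention matches :class:`AlignmentScoring` exactly); the
    returned alignment is then gap-right-aligned for a deterministic
    tie-break.
    """
    if not query or not reference:
        raise ValueError("alignment inputs must be non-empty")
    aligner = _build_aligner(scoring)
    result = aligner.align(query, reference)
    aln = result[0]
    return right_align(Alignment(str(aln[0]), str(aln[1]), float(result.score)))


def right_align(aln: Alignment) -> Alignment:
    """Shift every gap as far 3' as sequence identity allows.

    A gap run may move one column right when the base entering the run
    equals the base leaving it on the ungapped row, which leaves the score
    unchanged.  Idempotent.
    """
    rows = [list(aln.query_aligned), list(aln.ref_aligned)]
    length = len(rows[0])
    changed = True
    while changed:
        changed = False
        for g, other in ((0, 1), (1, 0)):
            gapped, solid = rows[g], rows[other]
            j = length - 1
            while j >= 0:
                if gapped[j] != "-":
                    j -= 1
                    continue
                i = j
                while i >= 0 and gapped[i] == "-":
                    i -= 1
                # gap run occupies columns i+1..j; moving it one column
                # right re-pairs the letter at j+1 with solid[i+1], which
                # is score-neutral iff solid[i+1] == solid[j+1]
                while (j + 1 < length and gapped[j + 1] != "-"
                       and solid[j + 1] != "-" and solid[i + 1] != "-"
                       and solid[i + 1] == solid[j + 1]):
                    gapped[i + 1] = gapped[j + 1]
                    gapped[j + 1] = "-"
                    i += 1
                    j += 1
                    changed = True
                j = i
    return Alignment("".join(rows[0]), "".join(rows[1]), aln.score)


@dataclass
class AlleleCall:
    """Classification of one (consensus) allele against its target."""

    target_id: str
    category: str
    event: EventClass | None = None
    umi: str | None = None
    umi_support: int = 1
    substituted: bool = False

    def __post_init__(self) -> None:
        has_event = self.event is not None
        if has_event != (self.category in (DELETION, INSERTION)):
            raise ValueError("event present iff category is deletion/insertion")

    def event_id(self, cut_index: int) -> str:
        return self.event.event_id(cut_index) if self.event else ""


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def classify_allele(target: TargetContext, allele: str,
                    scoring: AlignmentScoring = DEFAULT_SCORING,
                    umi: str | None = None, umi_support: int = 1) -> AlleleCall:
    """Assign an allele to wild-type, an event class, out-of-window or complex.

    Single deletions are right-aligned to the largest start that is still a
    catalog member (matching the collapse canonicals); single insertions
    are read at the cut boundary whenever consistent with it.  Alleles not
    explainable by a single indel are complex; substitution-only alleles
    count as wild-type but are flagged.
    """
    cfg = target.config
    seq = target.sequence
    n = cfg.context_length
    cut = cfg.cut_index
    window = cfg.window_positions()
    wlo, whi = window.start, window.stop - 1

    def call(category, event=None, substituted=False):
        return AlleleCall(target.target_id, category, event=event, umi=umi,
                          umi_support=umi_support, substituted=substituted)

    if len(allele) == n:
        if allele == seq:
            return call(WILDTYPE)
        aln = global_align(allele, seq, scoring)
        if aln.has_gaps():
            return call(COMPLEX)
        return call(WILDTYPE, substituted=True)

    lp = _common_prefix(seq, allele)
    ls = _common_suffix(seq, allele)

    if len(allele) < n:
        d = n - len(allele)
        # readings: allele == seq[:s] + seq[s+d:]
        s_lo, s_hi = max(0, n - d - ls), min(lp, n - d)
        if s_lo > s_hi:
            return call(COMPLEX)
        in_cat = [s for s in range(s_lo, s_hi + 1)
                  if d <= cfg.max_deletion_length and s <= whi and s + d - 1 >= wlo]
        if not in_cat:
            return call(OUT_OF_WINDOW)
        return call(DELETION, event=DeletionClass(max(in_cat), d))

    d = len(allele) - n
    # readings: allele == seq[:k] + X + seq[k:]
    k_lo, k_hi = max(0, n - ls), min(lp, n)
    if k_lo > k_hi:
        return call(COMPLEX)
    k = cut if k_lo <= cut <= k_hi else k_hi
    if not (wlo + 1 <= k <= whi + 1):
        return call(OUT_OF_WINDOW)
    inserted = allele[k:k + d]
    ev = InsertionClass(inserted) if d <= 2 else InsertionClass(LONG)
    return call(INSERTION, event=ev)


@dataclass
class UMIGroup:
    """Reads sharing one UMI, with their consensus representative."""

    umi: str
    reads: list[str]
    representative: str
    n_filtered: int = 0


def _identity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def consensus_umis(reads: list[tuple[str, str]],
                   min_reads: int = MIN_UMI_READS,
                   min_identity: float = MIN_READ_IDENTITY,
                   umi_length: int = UMI_LENGTH) -> tuple[list[UMIGroup], dict[str, int]]:
    """Group (umi, read) pairs, elect consensus, apply the UMI filters.

    The representative is the most common read sequence (ties broken
    lexicographically); reads below ``min_identity`` to it are discarded,
    and groups with fewer than ``min_reads`` retained reads are dropped.
    Returns the surviving groups and a tally of everything removed.
    """
    stats = {"malformed_umi_reads": 0, "low_identity_reads": 0,
             "dropped_small_groups": 0, "kept_groups": 0}
    by_umi: dict[str, list[str]] = defaultdict(list)
    for umi, read in reads:
        if len(umi) != umi_length or not set(umi) <= set("ACGT"):
            stats["malformed_umi_reads"] += 1
            continue
        by_umi[umi].append(read)
    groups: list[UMIGroup] = []
    for umi in sorted(by_umi):
        members = by_umi[umi]
        counts = Counter(members)
        maxc = max(counts.values())
        rep = min(s for s, c in counts.items() if c == maxc)
        kept = [r for r in members if _identity(r, rep) >= min_identity]
        n_filtered = len(members) - len(kept)
        stats["low_identity_reads"] += n_filtered
        if len(kept) < min_reads:
            stats["dropped_small_groups"] += 1
            continue
        stats["kept_groups"] += 1
        groups.append(UMIGroup(umi, kept, rep, n_filtered))
    if stats["malformed_umi_reads"] or stats["dropped_small_groups"]:
        logger.info("UMI consensus filters: %s", stats)
    return groups, stats


def call_reads(reads: list[tuple[str, str, str]],
               targets: dict[str, TargetContext],
               scoring: AlignmentScoring = DEFAULT_SCORING,
               min_reads: int = MIN_UMI_READS,
               min_identity: float = MIN_READ_IDENTITY) -> list[AlleleCall]:
    """Full pipeline: (target_id, umi, read) tuples -> per-UMI allele calls."""
    by_target: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for tid, umi, read in reads:
        if tid not in targets:
            raise KeyError(f"read references unknown target {tid!r}")
        by_target[tid].append((umi, read))
    calls: list[AlleleCall] = []
    for tid in sorted(by_target):
        groups, _ = consensus_umis(by_target[tid], min_reads, min_identity)
        for g in groups:
            calls.append(classify_allele(targets[tid], g.representative,
                                         scoring, umi=g.umi,
                                         umi_support=len(g.reads)))
    return calls


def observed_distribution(calls: list[AlleleCall],
                          cut_index: int = 30
                          ) -> tuple[OutcomeDistribution | None, dict]:
    """Frequencies over event classes among indel calls for one target.

    Wild-type, complex and out-of-window calls are excluded from the
    distribution but tallied in the summary.  Returns ``(None, summary)``
    when no usable indel calls exist.
    """
    n = len(calls)
    cat = Counter(c.category for c in calls)
    counts: Counter[str] = Counter()
    for c in calls:
        if c.category in (DELETION, INSERTION):
            counts[c.event.event_id(cut_index)] += 1
    summary = {
        "n_umis": n,
        "fraction_wildtype": cat[WILDTYPE] / n if n else 0.0,
        "fraction_deletion": cat[DELETION] / n if n else 0.0,
        "fraction_insertion": cat[INSERTION] / n if n else 0.0,
        "fraction_complex": cat[COMPLEX] / n if n else 0.0,
        "fraction_out_of_window": cat[OUT_OF_WINDOW] / n if n else 0.0,
    }
    if not counts:
        summary.update(entropy_bits=float("nan"), frameshift_ratio=float("nan"))
        return None, summary
    dist = OutcomeDistribution.from_counts(dict(counts))
    summary.update(entropy_bits=dist.entropy_bits(),
                   frameshift_ratio=dist.frameshift_ratio())
    return dist, summary


def entropy(dist: OutcomeDistribution) -> float:
    """Shannon entropy of an outcome distribution in bits."""
    from .distributions import entropy as _entropy
    return _entropy(dist)
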