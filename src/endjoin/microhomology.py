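"""Microhomology detection for deletion classes.

A deletion is microhomology (MH)-mediated when the sequence at the 3' end
of the rejoined upstream flank is identical to the 3' end of the deleted
tract.  With the deletion stored right-aligned, the MH length is the
largest ``n`` (scanned from 1 to 10) for which the ``n`` nt immediately
upstream of the deletion equal the last ``n`` nt of the deleted sequence.
"""

from __future__ import annotations

from .catalog import DeletionClass, TargetContext

#: largest tract length scanned
MAX_MH_SCAN = 10


def right_align_deletion(target: TargetContext, dc: DeletionClass) -> DeletionClass:
    """Shift a deletion as far 3' as sequence identity allows.

    Shifting by one is allele-preserving iff the base at the deletion start
    equals the base just past its end; repeated until that fails or the
    context ends.
    """
    seq = target.sequence
    start, length = dc.start, dc.length
    while start + length < len(seq) and seq[start] == seq[start + length]:
        start += 1
    return DeletionClass(start, length)


def deletion_mh_length(target: TargetContext, dc: DeletionClass,
                       max_scan: int = MAX_MH_SCAN) -> int:
    """MH tract length for one deletion class (0 if none).

    The class is right-aligned first; ``n`` is capped by the deletion
    length, by ``max_scan`` and by the available upstream flank (deletions
    touching the left context edge).
    """
    dc = right_align_deletion(target, dc)
    seq = target.sequence
    cap = min(max_scan, dc.length, dc.start)
    mh = 0
    for n in range(1, cap + 1):
        if seq[dc.start - n:dc.start] == seq[dc.end - n:dc.end]:
            mh = n
    return mh


def annotate_mh(target: TargetContext,
                classes: list[DeletionClass]) -> dict[DeletionClass, int]:
    """MH length for every class in ``classes`` (deterministic order)."""
    return {dc: deletion_mh_length(target, dc) for dc in classes}


def is_mh_mediated(ann: dict[DeletionClass, int], dc: DeletionClass) -> bool:
    """True iff the annotated MH tract is at least 1 bp."""
    if dc not in ann:
        raise KeyError(f"deletion class {dc} not annotated")
    return ann[dc] >= 1
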