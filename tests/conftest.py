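"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (double loops,
path enumeration, recursive maximisation) and share no code with the
package paths they check.
"""

from __future__ import annotations

import functools

import numpy as np
import pytest

from endjoin.catalog import CatalogConfig, DeletionClass, TargetContext
from endjoin.simulator import simulate_targets


@pytest.fixture
def random_targets():
    """Factory: n seeded random NGG targets."""
    def make(n: int, seed: int = 0) -> list[TargetContext]:
        return simulate_targets(n, seed)
    return make


# -- catalog oracle ------------------------------------------------------

def brute_force_deletion_classes(cfg: CatalogConfig) -> list[DeletionClass]:
    """Exhaustive double loop over all (start, length) pairs with an
    explicit interval-overlap predicate against the assignment window."""
    window = set(cfg.window_positions())
    out = []
    for length in range(1, cfg.max_deletion_length + 1):
        for start in range(0, cfg.context_length):
            interval = set(range(start, start + length))
            if start + length <= cfg.context_length and interval & window:
                out.append(DeletionClass(start, length))
    return sorted(out, key=lambda c: (c.length, c.start))


# -- microhomology oracle ------------------------------------------------

def brute_force_mh(target: TargetContext, dc: DeletionClass,
                   max_scan: int = 10) -> int:
    """Right-align by scanning all starts that yield the same allele, then
    compare suffixes for every n."""
    seq = target.sequence
    allele = seq[:dc.start] + seq[dc.start + dc.length:]
    starts = [s for s in range(0, len(seq) - dc.length + 1)
              if seq[:s] + seq[s + dc.length:] == allele]
    s = max(starts)
    best = 0
    for n in range(1, max_scan + 1):
        if n > dc.length or n > s:
            break
        if seq[s - n:s] == seq[s + dc.length - n:s + dc.length]:
            best = n
    return best


# -- alignment oracles ---------------------------------------------------

def enumerate_alignment_score(a: str, b: str, match: float, mismatch: float,
                              gap_open: float, gap_extend: float) -> float:
    """Maximum score over *all* global alignments by explicit path
    enumeration (exponential; use only for short strings)."""
    best = [-np.inf]

    def walk(i: int, j: int, last: str, score: float) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, "m",
                 score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            walk(i + 1, j, "a",
                 score + (gap_extend if last == "a" else gap_open))
        if j < len(b):
            walk(i, j + 1, "b",
                 score + (gap_extend if last == "b" else gap_open))

    walk(0, 0, "m", 0.0)
    return best[0]


def recursive_alignment_score(a: str, b: str, match: float, mismatch: float,
                              gap_open: float, gap_extend: float) -> float:
    """Memoised top-down maximisation over all affine-gap alignments."""

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append((match if a[i] == b[j] else mismatch)
                           + rec(i + 1, j + 1, "m"))
        if i < len(a):
            options.append((gap_extend if last == "a" else gap_open)
                           + rec(i + 1, j, "a"))
        if j < len(b):
            options.append((gap_extend if last == "b" else gap_open)
                           + rec(i, j + 1, "b"))
        return max(options)

    return rec(0, 0, "m")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
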