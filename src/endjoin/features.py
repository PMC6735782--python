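"""Binary feature encodings of a target sequence.

Three feature families feed the predictor:

* ``sequence`` -- one-hot mono- and di-nucleotide content of the 20 bp
  protospacer: 4 x 20 + 16 x 19 = 384 bits, 39 of them set;
* ``hexamer`` -- the same encoding restricted to the 6 nt centered on the
  cut: 4 x 6 + 16 x 5 = 104 bits, 11 set (drives the insertion component);
* ``mh`` -- per deletion class, a one-hot over its microhomology-tract
  length truncated at 4 (levels 0..min(4, length), i.e. 5 bits for classes
  of length >= 4, down to 2 bits for 1 bp deletions).

With the full 550-class catalog the MH block has 2716 bits (3100 total);
with a 536-class observed list grouped 519/7/6/4 by length it has 2649
(3033 total).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .catalog import CUT_INDEX, DNA, DeletionClass, TargetContext

SCHEMA_VERSION = "endjoin-features-1"  # di block: position-major, 2-mers lexicographic

MH_LEVEL_CAP = 4

_DI = [a + b for a in DNA for b in DNA]
_BASE_IDX = {b: i for i, b in enumerate(DNA)}
_DI_IDX = {d: i for i, d in enumerate(_DI)}


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSchema:
    """Named, contiguous feature blocks with stable labels.

    ``blocks`` maps block name -> (start, stop) index range; ``labels`` has
    one entry per feature.  Serializes to JSON bit-exactly.
    """

    blocks: tuple[tuple[str, int, int], ...]
    labels: tuple[str, ...]
    version: str = SCHEMA_VERSION

    def __len__(self) -> int:
        return len(self.labels)

    def block_slice(self, name: str) -> slice:
        for bname, start, stop in self.blocks:
            if bname == name:
                return slice(start, stop)
        raise KeyError(name)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def to_json(self) -> str:
        return json.dumps({"version": self.version,
                           "blocks": [list(b) for b in self.blocks],
                           "labels": list(self.labels)})

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(blocks=tuple(tuple(b) for b in d["blocks"]),
                   labels=tuple(d["labels"]), version=d["version"])


def _kmer_labels(width: int, prefix: str) -> tuple[list[str], list[str]]:
    mono = [f"{prefix}mono_{p}_{b}" for p in range(width) for b in DNA]
    di = [f"{prefix}di_{p}_{d}" for p in range(width - 1) for d in _DI]
    return mono, di


def sequence_schema() -> FeatureSchema:
    """Schema of the 384 protospacer one-hot features (80 mono + 304 di)."""
    mono, di = _kmer_labels(20, "seq_")
    return FeatureSchema(
        blocks=(("mono", 0, len(mono)), ("di", len(mono), len(mono) + len(di))),
        labels=tuple(mono + di))


def hexamer_schema() -> FeatureSchema:
    """Schema of the 104 cut-proximal hexamer features (24 mono + 80 di)."""
    mono, di = _kmer_labels(6, "hex_")
    return FeatureSchema(
        blocks=(("mono", 0, len(mono)), ("di", len(mono), len(mono) + len(di))),
        labels=tuple(mono + di))


def mh_level_count(dc: DeletionClass, cap: int = MH_LEVEL_CAP) -> int:
    """Number of one-hot MH levels for one class: 0..min(cap, length)."""
    return min(cap, dc.length) + 1


def mh_schema(classes: list[DeletionClass], cap: int = MH_LEVEL_CAP,
              cut_index: int = CUT_INDEX) -> FeatureSchema:
    labels: list[str] = []
    for dc in classes:
        eid = dc.event_id(cut_index)
        labels.extend(f"mh_{eid}_{lvl}" for lvl in range(mh_level_count(dc, cap)))
    return FeatureSchema(blocks=(("mh", 0, len(labels)),), labels=tuple(labels))


def full_schema(classes: list[DeletionClass], cap: int = MH_LEVEL_CAP) -> FeatureSchema:
    """Sequence blocks followed by the MH block (3033 bits for a 536-class
    observed list; 3100 for the full 550-class catalog)."""
    seq = sequence_schema()
    mh = mh_schema(classes, cap)
    n = len(seq)
    blocks = tuple((name, a, b) for name, a, b in seq.blocks) + \
        (("mh", n, n + len(mh)),)
    return FeatureSchema(blocks=blocks, labels=seq.labels + mh.labels)


def _encode_kmers(seq: str, width: int) -> np.ndarray:
    if len(seq) != width:
        raise FeatureError(f"expected {width} nt, got {len(seq)}")
    if not set(seq) <= set(DNA):
        raise FeatureError("sequence features are undefined on non-ACGT bases")
    v = np.zeros(width * 4 + (width - 1) * 16, dtype=np.float64)
    for p, b in enumerate(seq):
        v[p * 4 + _BASE_IDX[b]] = 1.0
    off = width * 4
    for p in range(width - 1):
        v[off + p * 16 + _DI_IDX[seq[p:p + 2]]] = 1.0
    return v


def encode_target_onehot(protospacer: str) -> np.ndarray:
    """One-hot encode a 20 nt protospacer: length-384 vector, 39 ones."""
    return _encode_kmers(protospacer, 20)


def encode_hexamer(hexamer: str) -> np.ndarray:
    """One-hot encode the cut-centered hexamer: length-104 vector, 11 ones."""
    return _encode_kmers(hexamer, 6)


def encode_mh_features(target: TargetContext, classes: list[DeletionClass],
                       ann: dict[DeletionClass, int],
                       cap: int = MH_LEVEL_CAP) -> np.ndarray:
    """Per-class one-hot of the (truncated) MH-tract length.

    Exactly one bit set per class: level ``min(mh_length, cap)``.
    """
    size = sum(mh_level_count(dc, cap) for dc in classes)
    v = np.zeros(size, dtype=np.float64)
    off = 0
    for dc in classes:
        if dc not in ann:
            raise FeatureError(f"class {dc} missing from MH annotation")
        nlev = mh_level_count(dc, cap)
        v[off + min(ann[dc], nlev - 1)] = 1.0
        off += nlev
    return v


def assemble_features(target: TargetContext, classes: list[DeletionClass],
                      ann: dict[DeletionClass, int],
                      cap: int = MH_LEVEL_CAP) -> np.ndarray:
    """Concatenate sequence blocks and MH block in schema order."""
    return np.concatenate([encode_target_onehot(target.protospacer),
                           encode_mh_features(target, classes, ann, cap)])
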