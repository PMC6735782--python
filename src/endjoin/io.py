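"""Reading and writing the tool's plain-text formats.

Targets travel as FASTA (60 nt contexts, or 23 nt protospacer+PAM records
that get embedded into a neutral backbone), outcome counts and
distributions as TSV with the event-id grammar ``D:<start_rel_cut>:<length>``
/ ``I:<seq>`` / ``I:LONG``, and reads as FASTQ with ``target=`` / ``umi=``
tags in the description (falling back to a 15 nt UMI prefix on the read).
All TSVs use '.' decimals, LF endings and a header row.
"""

from __future__ import annotations

import logging

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import CatalogConfig, DEFAULT_CONFIG, TargetContext

logger = logging.getLogger(__name__)

# fixed flanks used when only a 23 nt protospacer+PAM is supplied
NEUTRAL_LEFT = "ATGCTAGTCGACT"            # 13 nt upstream context
NEUTRAL_RIGHT = "TCGATCGTACGATCGATGCATGCA"  # 24 nt downstream context


def embed_protospacer(seq23: str, target_id: str = "target",
                      cfg: CatalogConfig = DEFAULT_CONFIG,
                      left: str = NEUTRAL_LEFT,
                      right: str = NEUTRAL_RIGHT) -> TargetContext:
    """Embed a 23 nt protospacer+PAM into the neutral 60 nt backbone."""
    if len(seq23) != 23:
        raise ValueError(f"expected 23 nt protospacer+PAM, got {len(seq23)}")
    seq = left + seq23.upper() + right
    return TargetContext(seq, target_id=target_id, config=cfg)


def read_targets_fasta(path, cfg: CatalogConfig = DEFAULT_CONFIG
                       ) -> list[TargetContext]:
    """Load targets; 23 nt records are auto-embedded with a logged warning."""
    out: list[TargetContext] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) == cfg.context_length:
            out.append(TargetContext(seq, target_id=rec.id, config=cfg))
        elif len(seq) == 23 and cfg.context_length == 60:
            logger.warning(
                "target %s is 23 nt; embedding into the neutral backbone",
                rec.id)
            out.append(embed_protospacer(seq, rec.id, cfg))
        else:
            raise ValueError(
                f"target {rec.id}: length {len(seq)} is neither "
                f"{cfg.context_length} nor 23")
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    seen: set[str] = set()
    for t in out:
        if t.target_id in seen:
            raise ValueError(f"duplicate target id {t.target_id!r}")
        seen.add(t.target_id)
    return out


def write_targets_fasta(targets: list[TargetContext], path) -> None:
    recs = [SeqRecord(Seq(t.sequence), id=t.target_id, description="")
            for t in targets]
    SeqIO.write(recs, str(path), "fasta")


def read_counts_tsv(path) -> dict[str, dict[str, int]]:
    """TSV with target_id / event_id / umi_count -> nested dict."""
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "event_id": str})
    for col in ("target_id", "event_id", "umi_count"):
        if col not in df.columns:
            raise ValueError(f"counts TSV missing column {col!r}")
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.target_id, {})[row.event_id] = int(row.umi_count)
    return out


def write_counts_tsv(counts: dict[str, dict[str, int]], path) -> None:
    rows = [(tid, eid, c) for tid in counts for eid, c in sorted(counts[tid].items())]
    pd.DataFrame(rows, columns=["target_id", "event_id", "umi_count"]) \
        .to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_distributions_tsv(dists: dict[str, dict[str, float]], path) -> None:
    rows = [(tid, eid, p) for tid in dists for eid, p in sorted(dists[tid].items())]
    pd.DataFrame(rows, columns=["target_id", "event_id", "probability"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.10g",
                lineterminator="\n")


def write_table_tsv(rows: list[dict], path, columns: list[str]) -> None:
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    """(target_id, umi, sequence) tuples -> FASTQ with tagged descriptions."""
    with open(path, "w") as fh:
        for i, (tid, umi, seq) in enumerate(reads):
            fh.write(f"@read{i} target={tid} umi={umi}\n{seq}\n+\n"
                     f"{'I' * len(seq)}\n")


def read_fastq_reads(path, umi_length: int = 15) -> list[tuple[str, str, str]]:
    """FASTQ -> (target_id, umi, sequence) tuples.

    ``target=`` must appear in each description; ``umi=`` is used when
    present, otherwise the first ``umi_length`` bases are taken as the UMI
    and stripped from the read.
    """
    out: list[tuple[str, str, str]] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        fields = dict(p.split("=", 1) for p in rec.description.split()
                      if "=" in p)
        if "target" not in fields:
            raise ValueError(f"read {rec.id}: no target= tag in description")
        seq = str(rec.seq).upper()
        if "umi" in fields:
            umi = fields["umi"]
        else:
            umi, seq = seq[:umi_length], seq[umi_length:]
        out.append((fields["target"], umi, seq))
    return out


def read_alleles_tsv(path) -> list[tuple[str, str, str]]:
    """Pre-merged allele TSV (target_id, umi, allele_sequence) -> tuples."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("target_id", "umi", "allele_sequence"):
        if col not in df.columns:
            raise ValueError(f"allele TSV missing column {col!r}")
    return [(r.target_id, r.umi, r.allele_sequence.upper())
            for r in df.itertuples(index=False)]
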