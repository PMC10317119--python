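"""Sequence I/O, read-quality filtering, and the text reports the pipeline
emits (SAM, needle-style pairwise alignment).

FASTA/FASTQ parsing is delegated to Bio.SeqIO; records are normalised to
uppercase ACGTN (anything else becomes N with a logged warning).  Mean read
quality is computed on the error-probability scale: the per-base Phred
scores are converted to error probabilities, averaged, and transformed back
-- the convention of the standard nanopore filtering tools, which penalises
a few very bad bases more than a plain mean of Q values would.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .align import Alignment

logger = logging.getLogger("plasmidval")

__all__ = [
    "SequenceRecord",
    "FilterParams",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "filter_reads",
    "mean_quality",
    "write_sam",
    "write_pairwise_report",
]

_NON_IUPAC = re.compile(r"[^ACGTN]")


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally circular, optionally with per-base
    Phred qualities (FASTQ reads)."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    circular: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FilterParams:
    """Read filter: minimum mean Phred quality and length bounds."""

    min_mean_q: float = 7.0
    min_len: int = 0
    max_len: int = 10**9

    def __post_init__(self):
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


def _sanitize(seq: str, rid: str) -> str:
    seq = seq.upper()
    n_bad = len(_NON_IUPAC.findall(seq))
    if n_bad:
        logger.warning("%s: %d non-ACGTN characters collapsed to N", rid, n_bad)
        seq = _NON_IUPAC.sub("N", seq)
    return seq


def _dedup_id(rid: str, seen: dict[str, int]) -> str:
    if rid not in seen:
        seen[rid] = 0
        return rid
    seen[rid] += 1
    new = f"{rid}.dup{seen[rid]}"
    logger.warning("duplicate record id %r renamed to %r", rid, new)
    return new


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (file order, uppercased)."""
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = _dedup_id(rec.id, seen)
        records.append(SequenceRecord(rid, _sanitize(str(rec.seq), rid)))
    if not records:
        logger.warning("%s: no records found", path)
    return records


def read_fastq(path) -> list[SequenceRecord]:
    """Read a FASTQ file (Phred+33) into SequenceRecords."""
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        rid = _dedup_id(rec.id, seen)
        quals = list(rec.letter_annotations["phred_quality"])
        records.append(SequenceRecord(rid, _sanitize(str(rec.seq), rid), qualities=quals))
    if not records:
        logger.warning("%s: no records found", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"{rec.id}: cannot write FASTQ without qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def mean_quality(qualities: Sequence[int]) -> float:
    """Phred-scale mean quality via the arithmetic mean error probability."""
    if len(qualities) == 0:
        return 0.0
    p = sum(10.0 ** (-q / 10.0) for q in qualities) / len(qualities)
    return -10.0 * math.log10(p)


def filter_reads(
    reads: Sequence[SequenceRecord], params: FilterParams
) -> tuple[list[SequenceRecord], int]:
    """Keep reads with mean quality >= threshold and length within bounds.

    Returns (kept reads, rejected count).  Reads without qualities are an
    input error: FASTA reads cannot be quality-filtered.
    """
    kept: list[SequenceRecord] = []
    rejected = 0
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"{read.id}: read has no qualities; cannot quality-filter")
        if (
            params.min_len <= len(read) <= params.max_len
            # small epsilon so reads sitting exactly on the threshold
            # (e.g. uniform Q7 against a Q>=7 filter) are kept
            and mean_quality(read.qualities) >= params.min_mean_q - 1e-9
        ):
            kept.append(read)
        else:
            rejected += 1
    return kept, rejected


# ---------------------------------------------------------------------------
# SAM output
# ---------------------------------------------------------------------------

def _cigar(ops: list[tuple[str, int]]) -> str:
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        code = {"match": "M", "mismatch": "M", "ins": "I", "del": "D"}[op]
        if merged and merged[-1][0] == code:
            merged[-1] = (code, merged[-1][1] + n)
        else:
            merged.append((code, n))
    return "".join(f"{n}{c}" for c, n in merged)


def write_sam(mapped_reads, refs: Sequence[SequenceRecord], path) -> None:
    """Write mapped reads as unsorted text SAM.

    ``mapped_reads`` are objects with attributes read_id, ref_id, seq, qual,
    orientation and alignment (as produced by consensus.map_reads); ``seq``
    is already oriented forward with respect to the reference.  Circular
    references are emitted doubled (name suffixed ``::doubled``, LN = 2L) so
    that origin-spanning alignments stay contiguous for viewers.
    """
    ref_by_id = {r.id: r for r in refs}
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    sq_names: dict[str, str] = {}
    for r in refs:
        if r.circular:
            sq_names[r.id] = f"{r.id}::doubled"
            lines.append(f"@SQ\tSN:{sq_names[r.id]}\tLN:{2 * len(r)}")
        else:
            sq_names[r.id] = r.id
            lines.append(f"@SQ\tSN:{r.id}\tLN:{len(r)}")
    for mr in mapped_reads:
        ref = ref_by_id[mr.ref_id]
        aln: Alignment = mr.alignment
        ts, te = aln.target_interval
        limit = 2 * len(ref) if ref.circular else len(ref)
        if te > limit:
            raise RuntimeError(f"{mr.read_id}: alignment exceeds reference bounds")
        flag = 16 if mr.orientation == "-" else 0
        qs, qe = aln.query_interval
        ops = list(aln.ops)
        # read overhangs beyond the reference ends become soft clips
        lead = trail = 0
        if ops and ops[0][0] == "ins":
            lead = ops[0][1]
            ops = ops[1:]
        if ops and ops[-1][0] == "ins":
            trail = ops[-1][1]
            ops = ops[:-1]
        cigar_parts = []
        if qs + lead > 0:
            cigar_parts.append(f"{qs + lead}S")
        cigar_parts.append(_cigar(ops))
        if qe < len(mr.seq) or trail:
            n_clip = len(mr.seq) - qe + trail
            if n_clip:
                cigar_parts.append(f"{n_clip}S")
        qual = "".join(chr(q + 33) for q in mr.qual) if mr.qual is not None else "*"
        lines.append(
            "\t".join(
                [
                    mr.read_id,
                    str(flag),
                    sq_names[mr.ref_id],
                    str(ts + 1),
                    "60",
                    "".join(cigar_parts),
                    "*",
                    "0",
                    "0",
                    mr.seq,
                    qual,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# needle-style pairwise text report
# ---------------------------------------------------------------------------

def write_pairwise_report(
    aln: Alignment, id_a: str, id_b: str, path, seq_a: str = None, seq_b: str = None
) -> None:
    """Write a needle-style plain-text report of a global alignment.

    ``seq_a``/``seq_b`` are the aligned sequences (query/target of ``aln``).
    Blocks are wrapped at 60 columns with a middle match line ('|' match,
    '.' substitution, space at gaps) and 1-based coordinates.
    """
    if seq_a is None or seq_b is None:
        raise ValueError("write_pairwise_report requires both sequences")
    rows_a: list[str] = []
    rows_b: list[str] = []
    mid: list[str] = []
    ia, ib = aln.query_interval[0], aln.target_interval[0]
    for op, n in aln.ops:
        for _ in range(n):
            if op == "match" or op == "mismatch":
                rows_a.append(seq_a[ia])
                rows_b.append(seq_b[ib])
                mid.append("|" if op == "match" else ".")
                ia += 1
                ib += 1
            elif op == "ins":
                rows_a.append(seq_a[ia])
                rows_b.append("-")
                mid.append(" ")
                ia += 1
            else:
                rows_a.append("-")
                rows_b.append(seq_b[ib])
                mid.append(" ")
                ib += 1
    cols = len(mid)
    matches = aln.matches
    gaps = sum(n for op, n in aln.ops if op in ("ins", "del"))
    pct = 100.0 * matches / cols if cols else 0.0
    gpct = 100.0 * gaps / cols if cols else 0.0
    out = [
        "########################################",
        "# Program: plasmidval",
        f"# Aligned_sequences: 2",
        f"# 1: {id_a}",
        f"# 2: {id_b}",
        f"# Length: {cols}",
        f"# Identity:  {matches}/{cols} ({pct:.1f}%)",
        f"# Gaps:      {gaps}/{cols} ({gpct:.1f}%)",
        f"# Score: {aln.score:.1f}",
        "########################################",
        "",
    ]
    pa = aln.query_interval[0]
    pb = aln.target_interval[0]
    width = 60
    name_a = (id_a[:13]).ljust(13)
    name_b = (id_b[:13]).ljust(13)
    for off in range(0, cols, width):
        chunk_a = "".join(rows_a[off : off + width])
        chunk_b = "".join(rows_b[off : off + width])
        chunk_m = "".join(mid[off : off + width])
        na = sum(1 for ch in chunk_a if ch != "-")
        nb = sum(1 for ch in chunk_b if ch != "-")
        start_a = pa + 1 if na else pa
        start_b = pb + 1 if nb else pb
        pa += na
        pb += nb
        out.append(f"{name_a} {start_a:>7} {chunk_a} {pa}")
        out.append(f"{'':13} {'':7} {chunk_m}")
        out.append(f"{name_b} {start_b:>7} {chunk_b} {pb}")
        out.append("")
    Path(path).write_text("\n".join(out))
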