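"""Reference-guided consensus: read mapping, pileup and plurality calling.

Reads are seeded to a diagonal by shared k-mers, banded-semiglobal aligned
in both orientations, and kept when identity passes a threshold and the
seeding locus is unique.  The per-column pileup then votes: the plurality
symbol among {A, C, G, T, deletion} is emitted (deletions emit nothing),
junction insertions carried by more than ``ins_frac`` of spanning reads are
polished and inserted, low-depth columns inside the covered interval become
N, and uncovered runs at the extremities are trimmed -- the consensus never
contains a base the reads did not cover (no reference back-fill).

Circular references are handled by mapping against the doubled sequence and
projecting pileup columns modulo the length, so origin-spanning reads stay
contiguous.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import (
    NEEDLE_SCHEME,
    Alignment,
    AlignmentBandError,
    ScoringScheme,
    global_align,
    reverse_complement,
    semiglobal_align,
)
from .io import SequenceRecord
from .seeding import best_diagonals, build_kmer_index, second_locus_votes

logger = logging.getLogger("plasmidval")

__all__ = [
    "MappedRead",
    "Pileup",
    "ConsensusResult",
    "NoConsensusError",
    "map_reads",
    "build_pileup",
    "call_consensus",
]

_BASES = "ACGT"
_SYM = {b: i for i, b in enumerate(_BASES)}
DEL = 4  # pileup symbol index for a deleted base


class NoConsensusError(RuntimeError):
    """No read coverage at all: no consensus can be produced."""


@dataclass
class MappedRead:
    """A read aligned to one reference, oriented forward w.r.t. it."""

    read_id: str
    ref_id: str
    seq: str
    qual: Optional[list[int]]
    orientation: str
    alignment: Alignment


@dataclass
class Pileup:
    ref_id: str
    counts: np.ndarray  # (ref_len, 5) counts over A,C,G,T,deletion
    insertions: dict[int, Counter]  # junction j -> Counter of inserted seqs
    junction_cov: np.ndarray  # reads spanning the junction before column j
    ref_seq: str

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ConsensusResult:
    sequence: str
    called_interval: tuple[int, int]
    low_depth_positions: list[int]
    mean_depth: float


def _band_width(read_len: int) -> int:
    return 100 + int(0.05 * read_len)


def map_reads(
    reads: Sequence[SequenceRecord],
    ref: SequenceRecord,
    scheme: ScoringScheme = NEEDLE_SCHEME,
    min_identity: float = 70.0,
    k: int = 13,
) -> tuple[list[MappedRead], dict[str, int]]:
    """Map reads to one reference by seeded banded semiglobal alignment.

    The default scoring uses the cheap gap extension of the needle
    convention so that long read indels stay contiguous instead of being
    scattered into mismatch runs -- essential for indel calling from the
    pileup.

    Circular references are doubled internally; reported target intervals
    start inside the first copy (project modulo length for column space).
    Returns (mapped reads, drop statistics).
    """
    L = len(ref.sequence)
    template = ref.sequence * 2 if ref.circular else ref.sequence
    index = build_kmer_index(template, k)
    modulus = L if ref.circular else None
    stats = {"mapped": 0, "no_seed": 0, "ambiguous_locus": 0, "low_identity": 0, "band_fail": 0}
    mapped: list[MappedRead] = []
    for read in reads:
        band = _band_width(len(read))
        fwd = read.sequence
        rev = reverse_complement(fwd)
        cands = []
        for orient, seq in (("+", fwd), ("-", rev)):
            diags = best_diagonals(seq, index, k, modulus=modulus)
            if diags:
                cands.append((diags[0][1], orient, seq, diags))
        if not cands:
            stats["no_seed"] += 1
            continue
        cands.sort(key=lambda c: -c[0])
        top_votes, orient, seq, diags = cands[0]
        if second_locus_votes(diags, band) >= top_votes:
            stats["ambiguous_locus"] += 1
            continue
        diag = diags[0][0]
        try:
            aln = semiglobal_align(seq, template, scheme, band=band, diagonal=diag)
        except AlignmentBandError:
            stats["band_fail"] += 1
            continue
        if aln.identity_pct < min_identity:
            stats["low_identity"] += 1
            continue
        aln.orientation = orient
        qual = read.qualities
        if qual is not None and orient == "-":
            qual = qual[::-1]
        mapped.append(MappedRead(read.id, ref.id, seq, qual, orient, aln))
        stats["mapped"] += 1
    return mapped, stats


def build_pileup(mapped: Sequence[MappedRead], ref: SequenceRecord) -> Pileup:
    """Tally per-column base/deletion counts and per-junction insertions."""
    L = len(ref.sequence)
    counts = np.zeros((L, 5), dtype=np.int64)
    junction_cov = np.zeros(L, dtype=np.int64)
    insertions: dict[int, Counter] = {}
    enc = lambda ch: _SYM.get(ch, -1)
    for mr in mapped:
        if mr.ref_id != ref.id:
            raise ValueError(f"{mr.read_id}: alignment is against {mr.ref_id}, not {ref.id}")
        aln = mr.alignment
        t = aln.target_interval[0]
        q = aln.query_interval[0]
        for op, n in aln.ops:
            if op in ("match", "mismatch"):
                for _ in range(n):
                    sym = enc(mr.seq[q])
                    if sym >= 0:
                        counts[t % L, sym] += 1
                    t += 1
                    q += 1
            elif op == "del":
                for _ in range(n):
                    counts[t % L, DEL] += 1
                    t += 1
            else:  # ins: record at the junction before column t
                if t != aln.target_interval[0] and t != aln.target_interval[1]:
                    j = t % L
                    insertions.setdefault(j, Counter())[mr.seq[q : q + n]] += 1
                q += n
        ts, te = aln.target_interval
        for p in range(ts + 1, te):
            junction_cov[p % L] += 1
    return Pileup(ref.id, counts, insertions, junction_cov, ref.sequence)


def _polish_insert(counter: Counter, scheme: ScoringScheme = ScoringScheme(1, -1, -1, -1)) -> str:
    """Consensus of the observed inserted sequences at one junction.

    Picks the medoid (max total alignment score against the others, sampled
    for large sets) and runs one round of per-column plurality voting of all
    observations against it.
    """
    seqs: list[str] = []
    for s, c in counter.items():
        seqs.extend([s] * c)
    uniq = sorted(counter, key=lambda s: (-counter[s], s))
    if len(uniq) == 1:
        return uniq[0]
    sample = uniq[:30]
    best_medoid = None
    best_total = None
    for cand in sample:
        total = 0.0
        for other, c in counter.items():
            if other == cand:
                total += scheme.match * len(cand) * c
                continue
            total += global_align(other, cand, scheme).score * c
        if best_total is None or total > best_total:
            best_total = total
            best_medoid = cand
    medoid = best_medoid
    m = len(medoid)
    col = np.zeros((m, 5), dtype=np.int64)
    ins_at: dict[int, Counter] = {}
    for s, c in counter.items():
        if s == medoid:
            aln_ops = [("match", m)]
        else:
            aln_ops = global_align(s, medoid, scheme).ops
        t = 0
        q = 0
        for op, n in aln_ops:
            if op in ("match", "mismatch"):
                for _ in range(n):
                    sym = _SYM.get(s[q], -1)
                    if sym >= 0:
                        col[t, sym] += c
                    t += 1
                    q += 1
            elif op == "del":
                col[t : t + n, DEL] += c
                t += n
            else:
                # boundary insertions are real content here (the medoid may
                # be missing its first or last bases), so keep every junction
                ins_at.setdefault(t, Counter())[s[q : q + n]] += c
                q += n
    total_obs = sum(counter.values())
    out = []
    for t in range(m + 1):
        if t in ins_at:
            seq, c = ins_at[t].most_common(1)[0]
            if c > total_obs / 2:
                out.append(seq)
        if t == m:
            break
        winners = np.flatnonzero(col[t] == col[t].max())
        w = winners[0]
        if w != DEL and col[t].max() > 0:
            out.append(_BASES[w])
        elif col[t].max() == 0:
            out.append(medoid[t])
    return "".join(out)


def call_consensus(
    pileup: Pileup, min_depth: int = 5, ins_frac: float = 0.5
) -> ConsensusResult:
    """Plurality-call the consensus from a pileup (no reference back-fill).

    Ties resolve toward the reference base when it is among the tied
    symbols, else to the lexicographically smallest base (deletion loses
    ties against the reference base only through the reference rule).
    """
    cov = pileup.coverage
    L = len(cov)
    covered = np.flatnonzero(cov > 0)
    if covered.size == 0:
        raise NoConsensusError(f"{pileup.ref_id}: empty pileup")
    start, end = int(covered[0]), int(covered[-1]) + 1
    low_depth: list[int] = []
    out: list[str] = []
    for j in range(start, end):
        if j > start and pileup.insertions.get(j):
            ins_total = sum(pileup.insertions[j].values())
            span = pileup.junction_cov[j]
            if span > 0 and ins_total > ins_frac * span:
                out.append(_polish_insert(pileup.insertions[j]))
        c = pileup.counts[j]
        depth = int(cov[j])
        if depth < min_depth:
            low_depth.append(j)
            out.append("N")
            continue
        mx = int(c.max())
        winners = set(int(w) for w in np.flatnonzero(c == mx))
        ref_sym = _SYM.get(pileup.ref_seq[j], -1)
        if ref_sym in winners:
            pick = ref_sym
        else:
            pick = min(winners)
        if pick != DEL:
            out.append(_BASES[pick])
    mean_depth = float(cov[start:end].mean()) if end > start else 0.0
    return ConsensusResult("".join(out), (start, end), low_depth, mean_depth)
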