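"""Two-stage barcode-free read binning against unique-region markers.

Stage one ("context score") locally aligns the read, in both orientations,
against a marker extended by 20 bp of flanking reference sequence; stage two
("fine score") re-aligns the context-stage hit against the bare marker.
Both scores are normalised to percent-of-maximum (100 = perfect full-length
match of the target; see :func:`plasmidval.align.normalized_score`).  A read
is assigned when exactly one reference passes both thresholds; reads passing
for two or more references are ambiguous and left unassigned, so chimeric
reads never contaminate a bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import (
    BIOBIN_SCHEME,
    Alignment,
    ScoringScheme,
    local_align,
    normalized_score,
    reverse_complement,
)
from .io import SequenceRecord
from .unique import UniqueRegion

logger = logging.getLogger("plasmidval")

__all__ = ["BinningParams", "BinAssignment", "context_score", "fine_score", "bin_reads"]


@dataclass(frozen=True)
class BinningParams:
    """Thresholds and scoring for two-stage binning.

    The fine threshold (>80) is the published assignment gate; the context
    threshold is published only as "tunable" and defaults to 55, loose
    enough that a context hit tolerates roughly 10% read error.
    """

    scheme: ScoringScheme = BIOBIN_SCHEME
    context_threshold: float = 55.0
    fine_threshold: float = 80.0
    flank: int = 20

    def __post_init__(self):
        for t in (self.context_threshold, self.fine_threshold):
            if not (0 <= t <= 100):
                raise ValueError("thresholds must be within [0, 100]")


@dataclass
class BinAssignment:
    read_id: str
    assigned_ref: Optional[str]
    context_scores: dict[str, float] = field(default_factory=dict)
    fine_scores: dict[str, float] = field(default_factory=dict)
    orientation: str = "+"
    status: str = "below_context"  # assigned | ambiguous | below_context | below_fine


def context_score(
    read: SequenceRecord, region: UniqueRegion, params: BinningParams = BinningParams()
) -> tuple[float, str, str]:
    """Local-align the read (both orientations) against the region context.

    Returns (normalized score, aligned read span, orientation); score 0 and
    an empty span when no positive-scoring local alignment exists.
    """
    best = (0.0, "", "+")
    for orient, seq in (("+", read.sequence), ("-", reverse_complement(read.sequence))):
        aln = local_align(seq, region.context, params.scheme)
        score = normalized_score(aln, len(region.context), params.scheme)
        if score > best[0]:
            qs, qe = aln.query_interval
            best = (score, seq[qs:qe], orient)
    return best


def fine_score(
    read_span: str, region: UniqueRegion, params: BinningParams = BinningParams()
) -> float:
    """Score the context-stage hit against the bare marker (percent of max)."""
    if not read_span:
        return 0.0
    aln = local_align(read_span, region.marker, params.scheme)
    return normalized_score(aln, len(region.marker), params.scheme)


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _hit_windows(ctx: str, kidx: dict[str, list[int]], k: int, read_len: int) -> list[tuple[int, int]]:
    """Merged read windows around exact context k-mer hits."""
    hits: list[int] = []
    for i in range(len(ctx) - k + 1):
        hits.extend(kidx.get(ctx[i : i + k], ()))
    if not hits:
        return []
    hits.sort()
    pad = len(ctx)
    windows: list[tuple[int, int]] = []
    for p in hits:
        s, e = max(0, p - pad), min(read_len, p + k + pad)
        if windows and s <= windows[-1][1]:
            windows[-1] = (windows[-1][0], e)
        else:
            windows.append((s, e))
    return windows


def _windowed_context_score(
    seq: str, windows: list[tuple[int, int]], region: UniqueRegion, params: BinningParams
) -> tuple[float, str]:
    """Best local alignment of the region context inside seeded read windows."""
    best = (0.0, "")
    for ws, we in windows:
        aln = local_align(seq[ws:we], region.context, params.scheme)
        score = normalized_score(aln, len(region.context), params.scheme)
        if score > best[0]:
            qs, qe = aln.query_interval
            best = (score, seq[ws + qs : ws + qe])
    return best


def bin_reads(
    reads: Sequence[SequenceRecord],
    refs: Sequence[SequenceRecord],
    regions: dict[str, list[UniqueRegion]],
    params: BinningParams = BinningParams(),
    prescreen_k: int = 9,
) -> tuple[dict[str, list[SequenceRecord]], list[BinAssignment]]:
    """Assign each read to at most one reference.

    For each reference the regions are tried longest-first and evaluation
    stops at the first region passing both gates.  With ``prescreen_k`` > 0
    the context alignment is seeded: it runs only inside read windows
    around exact shared k-mers with the context (per orientation), and is
    skipped entirely when there are none.  Seeding can only suppress
    candidate hits, never create them; set ``prescreen_k=0`` for exhaustive
    full-read alignment.  Returns (bins by ref_id, one BinAssignment per
    read).
    """
    candidates: dict[str, list[UniqueRegion]] = {}
    for ref in refs:
        regs = sorted(regions.get(ref.id, []), key=len, reverse=True)
        if not regs:
            logger.warning("%s: no unique regions; excluded from binning", ref.id)
            continue
        candidates[ref.id] = regs

    min_ctx = min((len(r.context) for regs in candidates.values() for r in regs), default=0)
    bins: dict[str, list[SequenceRecord]] = {rid: [] for rid in candidates}
    assignments: list[BinAssignment] = []
    for read in reads:
        if len(read) < min_ctx:
            logger.debug("%s: read shorter than the smallest context", read.id)
        fwd = read.sequence
        rev = reverse_complement(fwd)
        kidx = None
        if prescreen_k:
            kidx = {
                "+": _kmer_positions(fwd, prescreen_k),
                "-": _kmer_positions(rev, prescreen_k),
            }
        asg = BinAssignment(read.id, None)
        passers: list[tuple[str, str]] = []  # (ref_id, orientation)
        any_context = False
        for rid, regs in candidates.items():
            best_ctx = 0.0
            best_fine = 0.0
            best_orient = "+"
            for region in regs:
                if kidx is None:
                    ctx, span, orient = context_score(read, region, params)
                else:
                    ctx, span, orient = 0.0, "", "+"
                    for o, seq in (("+", fwd), ("-", rev)):
                        wins = _hit_windows(region.context, kidx[o], prescreen_k, len(fwd))
                        if not wins:
                            continue
                        sc, sp = _windowed_context_score(seq, wins, region, params)
                        if sc > ctx:
                            ctx, span, orient = sc, sp, o
                if ctx > best_ctx:
                    best_ctx = ctx
                    best_orient = orient
                if ctx < params.context_threshold:
                    continue
                any_context = True
                fs = fine_score(span, region, params)
                if fs > best_fine:
                    best_fine = fs
                    best_orient = orient
                if fs > params.fine_threshold:
                    break  # one confident marker suffices for this reference
            asg.context_scores[rid] = best_ctx
            asg.fine_scores[rid] = best_fine
            if best_ctx >= params.context_threshold and best_fine > params.fine_threshold:
                passers.append((rid, best_orient))
        if len(passers) == 1:
            rid, orient = passers[0]
            asg.assigned_ref = rid
            asg.orientation = orient
            asg.status = "assigned"
            bins[rid].append(read)
        elif len(passers) >= 2:
            asg.status = "ambiguous"
        else:
            asg.status = "below_fine" if any_context else "below_context"
        assignments.append(asg)
    return bins, assignments


def assignments_to_tsv(assignments: Sequence[BinAssignment], path) -> None:
    lines = ["read_id\tassigned_ref\tbest_context\tbest_fine\torientation\tstatus"]
    for a in assignments:
        ctx = max(a.context_scores.values(), default=0.0)
        fine = max(a.fine_scores.values(), default=0.0)
        lines.append(
            f"{a.read_id}\t{a.assigned_ref or '.'}\t{ctx:.1f}\t{fine:.1f}\t{a.orientation}\t{a.status}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
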