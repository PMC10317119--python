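"""Rotated-reference demultiplexing for clonal plasmid pools.

Clones of the same (or nearly identical) plasmid are linearised at distinct
restriction sites before pooling.  During analysis one copy of the
reference is supplied per clone, rewritten linearly to start at that
clone's cut site (a *rotated* reference).  A full-length read then aligns
end-to-end only against its own rotation; against any other rotation the
sequence is circularly shifted, forcing a large terminal gap and collapsing
the score.  Reads are assigned to the top-scoring rotation only when the
margin over the runner-up exceeds a configurable fraction of the read's
maximum possible score, so identical (non-rotated) reference copies yield
ties and no read is ever assigned by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import (
    BIOBIN_SCHEME,
    AlignmentBandError,
    ScoringScheme,
    banded_semiglobal_score,
    reverse_complement,
)
from .io import SequenceRecord
from .seeding import best_diagonals, build_kmer_index

logger = logging.getLogger("plasmidval")

__all__ = ["CutSpec", "ClonalAssignment", "rotate_reference", "assign_clonal_reads", "read_cut_manifest"]


@dataclass(frozen=True)
class CutSpec:
    """A restriction-site linearisation point on a circular reference."""

    ref_id: str
    cut_position: int
    enzyme_label: str = ""


def rotate_reference(ref: SequenceRecord, cut: CutSpec) -> SequenceRecord:
    """Rewrite a circular reference linearly with its origin at the cut site.

    The result is marked linear and its id is suffixed with the cut label
    (or position); length and base content are preserved.
    """
    if not ref.circular:
        raise ValueError(f"{ref.id}: rotate_reference requires a circular reference")
    if not (0 <= cut.cut_position < len(ref)):
        raise ValueError(f"{ref.id}: cut position {cut.cut_position} out of range")
    label = cut.enzyme_label or f"cut{cut.cut_position}"
    seq = ref.sequence[cut.cut_position :] + ref.sequence[: cut.cut_position]
    return SequenceRecord(f"{ref.id}|{label}", seq, circular=False)


@dataclass
class ClonalAssignment:
    read_id: str
    assigned_ref: Optional[str]
    scores: dict[str, float] = field(default_factory=dict)
    orientation: str = "+"


def _band_width(read_len: int) -> int:
    return 100 + int(0.05 * read_len)


def assign_clonal_reads(
    reads: Sequence[SequenceRecord],
    rotated_refs: Sequence[SequenceRecord],
    scheme: ScoringScheme = BIOBIN_SCHEME,
    margin_pct: float = 5.0,
    seed_k: int = 13,
) -> list[ClonalAssignment]:
    """Assign reads to rotated references by banded semiglobal score margin.

    Each read is aligned (seeded, banded, both orientations) to every
    rotated reference and assigned to the top scorer iff the margin over the
    second-best exceeds ``margin_pct`` percent of the read's maximum
    possible score (match * read length); otherwise it stays unassigned.
    """
    if len(rotated_refs) == 1:
        logger.warning("single rotated reference: demultiplexing is vacuous")
    indexes = {r.id: build_kmer_index(r.sequence, seed_k) for r in rotated_refs}
    out: list[ClonalAssignment] = []
    for read in reads:
        band = _band_width(len(read))
        fwd = read.sequence
        rev = reverse_complement(fwd)
        scores: dict[str, float] = {}
        orients: dict[str, str] = {}
        for ref in rotated_refs:
            best = None
            best_orient = "+"
            for orient, seq in (("+", fwd), ("-", rev)):
                diags = best_diagonals(seq, indexes[ref.id], seed_k)
                if not diags:
                    continue
                diag = diags[0][0]
                try:
                    s = banded_semiglobal_score(seq, ref.sequence, scheme, band, diag)
                except AlignmentBandError:
                    continue
                if best is None or s > best:
                    best = s
                    best_orient = orient
            if best is not None:
                scores[ref.id] = best
                orients[ref.id] = best_orient
        asg = ClonalAssignment(read.id, None, scores)
        if scores:
            ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
            top_id, top = ranked[0]
            second = ranked[1][1] if len(ranked) > 1 else float("-inf")
            margin = margin_pct / 100.0 * scheme.match * len(read)
            if len(ranked) == 1 or top - second >= margin:
                asg.assigned_ref = top_id
                asg.orientation = orients[top_id]
        out.append(asg)
    return out


def read_cut_manifest(path) -> list[CutSpec]:
    """Read a TSV cut-site manifest: ref_id, cut_position, [enzyme_label]."""
    cuts: list[CutSpec] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or (ln == 1 and "cut_position" in line):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected ref_id<TAB>cut_position")
            cuts.append(CutSpec(parts[0], int(parts[1]), parts[2] if len(parts) > 2 else ""))
    return cuts
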