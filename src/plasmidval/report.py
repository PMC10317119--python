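"""Consensus-versus-reference validation reports.

Each consensus is globally aligned to its reference under needle-convention
scoring (match 5, mismatch -4, gap open -10, extend -0.5); substitutions
and gap events/bases are tallied, and a per-plasmid quality score is
computed as the percentage of alignment columns free of any difference:

    quality = 100 * (1 - (substitutions + inserted bases + deleted bases)
                          / alignment columns)

floored at 0.  The score is 100 exactly when consensus and reference are
identical.  A summary table plus one needle-style alignment file per
plasmid form the user-facing output; plasmids are flagged (never dropped)
when the quality score falls below a threshold or any single indel reaches
a configurable size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .align import Alignment, NEEDLE_SCHEME, ScoringScheme, global_align
from .io import SequenceRecord, write_pairwise_report

logger = logging.getLogger("plasmidval")

__all__ = ["GapReport", "compare_consensus", "run_report"]


@dataclass
class GapReport:
    ref_id: str
    substitutions: int
    insertion_events: int
    insertion_bases: int
    deletion_events: int
    deletion_bases: int
    alignment_columns: int
    identity_pct: float
    quality_score: float
    # (kind, reference position, length) per indel event; kind is
    # "insertion" (extra consensus bases) or "deletion" (missing from consensus)
    indel_events: list[tuple[str, int, int]] = field(default_factory=list)
    alignment: Optional[Alignment] = None

    @property
    def gap_bases(self) -> int:
        return self.insertion_bases + self.deletion_bases

    @property
    def difference_bases(self) -> int:
        """Per-base differences: substituted + inserted + deleted bases."""
        return self.substitutions + self.gap_bases


def compare_consensus(
    consensus, ref, scheme: ScoringScheme = NEEDLE_SCHEME
) -> GapReport:
    """Globally align a consensus to its reference and tally differences.

    ``consensus``/``ref`` may be strings or SequenceRecords.  Insertions are
    consensus bases absent from the reference; deletions are reference
    bases absent from the consensus.  Each maximal gap run counts as one
    event; its reference position is where the event starts.
    """
    cons_seq = consensus.sequence if isinstance(consensus, SequenceRecord) else consensus
    ref_seq = ref.sequence if isinstance(ref, SequenceRecord) else ref
    ref_id = ref.id if isinstance(ref, SequenceRecord) else "reference"
    aln = global_align(cons_seq, ref_seq, scheme)
    subs = 0
    ins_ev = ins_b = del_ev = del_b = 0
    events: list[tuple[str, int, int]] = []
    t = 0  # reference coordinate
    for op, n in aln.ops:
        if op == "match":
            t += n
        elif op == "mismatch":
            subs += n
            t += n
        elif op == "ins":
            ins_ev += 1
            ins_b += n
            events.append(("insertion", t, n))
        else:
            del_ev += 1
            del_b += n
            events.append(("deletion", t, n))
            t += n
    cols = aln.columns
    quality = max(0.0, 100.0 * (1.0 - (subs + ins_b + del_b) / cols)) if cols else 0.0
    return GapReport(
        ref_id=ref_id,
        substitutions=subs,
        insertion_events=ins_ev,
        insertion_bases=ins_b,
        deletion_events=del_ev,
        deletion_bases=del_b,
        alignment_columns=cols,
        identity_pct=aln.identity_pct,
        quality_score=quality,
        indel_events=events,
        alignment=aln,
    )


def run_report(
    read_counts: dict[str, int],
    consensuses: dict[str, object],
    gap_reports: dict[str, GapReport],
    refs: Sequence[SequenceRecord],
    outdir,
    quality_threshold: float = 99.5,
    indel_flag_len: int = 10,
) -> tuple[pd.DataFrame, bool]:
    """Emit the per-plasmid summary TSV and one alignment file per plasmid.

    ``read_counts`` maps ref_id -> reads used; ``consensuses`` maps ref_id
    -> ConsensusResult (missing/None entries produce "no-consensus" rows).
    Returns (summary table, any_flagged).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    any_flagged = False
    for ref in refs:
        rid = ref.id
        cons = consensuses.get(rid)
        if cons is None:
            rows.append(
                dict(
                    ref_id=rid,
                    reads=read_counts.get(rid, 0),
                    mean_depth=0.0,
                    substitutions=0,
                    insertion_bases=0,
                    deletion_bases=0,
                    quality_score=float("nan"),
                    status="no-consensus",
                    flags="",
                )
            )
            any_flagged = True
            continue
        gr = gap_reports[rid]
        flags = []
        if gr.quality_score < quality_threshold:
            flags.append(f"quality<{quality_threshold}")
        big = [e for e in gr.indel_events if e[2] >= indel_flag_len]
        for kind, pos, length in big:
            flags.append(f"{kind}:{length}bp@{pos}")
        flagged = bool(flags)
        any_flagged = any_flagged or flagged
        rows.append(
            dict(
                ref_id=rid,
                reads=read_counts.get(rid, 0),
                mean_depth=round(cons.mean_depth, 1),
                substitutions=gr.substitutions,
                insertion_bases=gr.insertion_bases,
                deletion_bases=gr.deletion_bases,
                quality_score=round(gr.quality_score, 2),
                status="flagged" if flagged else "pass",
                flags=";".join(flags),
            )
        )
        write_pairwise_report(
            gr.alignment,
            f"{rid}|consensus",
            rid,
            outdir / f"{rid}.needle.txt",
            seq_a=cons.sequence,
            seq_b=ref.sequence,
        )
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    return table, any_flagged
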