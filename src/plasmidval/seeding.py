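"""k-mer seeding: estimate the alignment diagonal of a read on a reference.

Shared k-mers between read and reference vote for diagonals
(ref_pos - read_pos); votes are pooled into coarse bins so that small
indel-driven drift does not split a locus.  The top bins anchor the banded
aligner and expose whether a read has a unique best locus.
"""

from __future__ import annotations

from collections import Counter, defaultdict

__all__ = ["build_kmer_index", "best_diagonals"]

DEFAULT_K = 13
BIN_WIDTH = 32


def build_kmer_index(seq: str, k: int = DEFAULT_K) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return dict(index)


def best_diagonals(
    read: str,
    index: dict[str, list[int]],
    k: int = DEFAULT_K,
    stride: int = 3,
    modulus: int | None = None,
    max_hits_per_kmer: int = 8,
) -> list[tuple[int, int]]:
    """Vote for diagonals; returns [(diagonal, votes), ...] best first.

    With ``modulus`` set (circular reference indexed doubled), diagonals are
    canonicalised modulo the original length so the two copies of a locus
    pool their votes, and the returned diagonal places the alignment start
    inside the first copy.
    """
    votes: Counter[int] = Counter()
    raw_for_bin: dict[int, int] = {}
    for i in range(0, len(read) - k + 1, stride):
        hits = index.get(read[i : i + k])
        if not hits or len(hits) > max_hits_per_kmer:
            continue
        for p in hits:
            d = p - i
            if modulus is not None:
                d = d % modulus
            b = d // BIN_WIDTH
            votes[b] += 1
            raw_for_bin.setdefault(b, d)
    if not votes:
        return []
    # a locus straddling a bin edge pools votes with its neighbours
    pooled = {
        b: votes[b] + votes.get(b - 1, 0) + votes.get(b + 1, 0) for b in votes
    }
    out = [(raw_for_bin[b], v) for b, v in pooled.items()]
    out.sort(key=lambda dv: (-dv[1], dv[0]))
    return out


def second_locus_votes(diags: list[tuple[int, int]], band: int) -> int:
    """Votes of the best diagonal farther than ``band`` from the top one."""
    if not diags:
        return 0
    top = diags[0][0]
    for d, v in diags[1:]:
        if abs(d - top) > band:
            return v
    return 0
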