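"""Affine-gap pairwise alignment: global, local and (optionally banded)
semiglobal modes, plus score normalization to a 0-100 scale.

This is the engine behind read binning (local alignments against short
unique-region contexts), read-to-reference mapping (banded semiglobal) and
the final consensus-versus-reference comparison (global, EMBOSS-needle-style
scoring).  Scores follow the convention that a gap of length k costs
``gap_open + (k-1) * gap_extend``.  Internally all scores are doubled to
integers so that the needle default gap extension of -0.5 stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _gotoh

__all__ = [
    "ScoringScheme",
    "Alignment",
    "AlignmentBandError",
    "BIOBIN_SCHEME",
    "NEEDLE_SCHEME",
    "global_align",
    "local_align",
    "semiglobal_align",
    "normalized_score",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_ENC = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string (A=0 C=1 G=2 T=3 N=4)."""
    return np.frombuffer(seq.encode("ascii").translate(_ENC), dtype=np.uint8)


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scoring parameters.

    ``match`` must be positive, ``mismatch`` negative, and
    ``gap_open <= gap_extend <= 0``.  All values may be half-integers.
    """

    match: float = 3.0
    mismatch: float = -6.0
    gap_open: float = -10.0
    gap_extend: float = -5.0

    def __post_init__(self):
        if not (self.match > 0):
            raise ValueError("match score must be positive")
        if not (self.mismatch < 0):
            raise ValueError("mismatch score must be negative")
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        for v in (self.match, self.mismatch, self.gap_open, self.gap_extend):
            if round(v * 2) != v * 2:
                raise ValueError("scores must be multiples of 0.5")

    def scaled(self) -> tuple[int, int, int, int]:
        """Integer scores doubled (exact for half-point penalties)."""
        return (
            int(round(self.match * 2)),
            int(round(self.mismatch * 2)),
            int(round(self.gap_open * 2)),
            int(round(self.gap_extend * 2)),
        )


#: Binning scheme used for context/fine scoring of reads against markers.
BIOBIN_SCHEME = ScoringScheme(3, -6, -10, -5)
#: Needle-convention scheme for consensus-versus-reference reports.
NEEDLE_SCHEME = ScoringScheme(5, -4, -10, -0.5)


class AlignmentBandError(RuntimeError):
    """The supplied band contained no valid alignment path."""


@dataclass
class Alignment:
    """A pairwise alignment.

    ``ops`` is a run-length encoded edit script over
    {"match", "mismatch", "ins", "del"}: "ins" consumes the query only,
    "del" the target only.  Intervals are 0-based half-open; ``identity_pct``
    counts matches over all alignment columns (gap columns included).
    """

    mode: str
    score: float
    ops: list[tuple[str, int]]
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    identity_pct: float
    orientation: str = "+"

    @property
    def columns(self) -> int:
        return sum(n for _, n in self.ops)

    @property
    def matches(self) -> int:
        return sum(n for op, n in self.ops if op == "match")


_OP_NAME = {0: "match", 1: "mismatch", 2: "ins", 3: "del"}


def _traceback_full(a, b, tbM, tbX, tbY, bi, bj, bstate):
    raw = []  # reversed op codes
    i, j, s = bi, bj, bstate
    while True:
        if s == 0:
            if i == 0:
                break  # semiglobal row-0 start marker
            prev = tbM[i, j]
            raw.append(0 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else 1)
            i -= 1
            j -= 1
            if prev == 3:
                break
            s = prev
        elif s == 1:
            prev = tbX[i, j]
            raw.append(2)
            i -= 1
            s = prev
        else:
            prev = tbY[i, j]
            raw.append(3)
            j -= 1
            s = prev
        if i == 0 and j == 0 and s == 0:
            break
    raw.reverse()
    ops = []
    for code in raw:
        name = _OP_NAME[code]
        if ops and ops[-1][0] == name:
            ops[-1] = (name, ops[-1][1] + 1)
        else:
            ops.append((name, 1))
    return ops, (i, bi), (j, bj)


def _identity(ops) -> float:
    cols = sum(n for _, n in ops)
    if cols == 0:
        return 0.0
    return 100.0 * sum(n for op, n in ops if op == "match") / cols


def _check_inputs(a: str, b: str):
    if not a or not b:
        raise ValueError("empty sequence passed to aligner")


def _run_full(a: str, b: str, scheme: ScoringScheme, mode_code: int, mode_name: str) -> Alignment:
    _check_inputs(a, b)
    sm, sx, go, ge = scheme.scaled()
    ea, eb = encode(a), encode(b)
    best, bi, bj, bstate, tbM, tbX, tbY = _gotoh.fill_full(ea, eb, sm, sx, go, ge, mode_code)
    if mode_code == _gotoh.MODE_LOCAL and (bstate == 3 or best <= 0):
        return Alignment(mode_name, 0.0, [], (0, 0), (0, 0), 0.0)
    ops, qi, ti = _traceback_full(ea, eb, tbM, tbX, tbY, bi, bj, int(bstate))
    return Alignment(mode_name, best / 2.0, ops, qi, ti, _identity(ops))


def global_align(a: str, b: str, scheme: ScoringScheme = BIOBIN_SCHEME) -> Alignment:
    """Optimal global (Needleman-Wunsch/Gotoh) alignment of ``a`` vs ``b``."""
    return _run_full(a, b, scheme, _gotoh.MODE_GLOBAL, "global")


def local_align(a: str, b: str, scheme: ScoringScheme = BIOBIN_SCHEME) -> Alignment:
    """Optimal local (Smith-Waterman) alignment; score >= 0, may be empty."""
    return _run_full(a, b, scheme, _gotoh.MODE_LOCAL, "local")


def semiglobal_align(
    read: str,
    ref: str,
    scheme: ScoringScheme = BIOBIN_SCHEME,
    band: Optional[int] = None,
    diagonal: Optional[int] = None,
) -> Alignment:
    """Fitting alignment: the read is fully aligned, reference end-gaps are
    free.  With ``band`` set, only cells with
    ``|target_pos - (read_pos + diagonal)| <= band`` are filled; the caller
    supplies ``diagonal`` from seeding (default 0).  Raises
    :class:`AlignmentBandError` when no path fits in the band.
    """
    _check_inputs(read, ref)
    if band is None:
        return _run_full(read, ref, scheme, _gotoh.MODE_SEMIGLOBAL, "semiglobal")
    sm, sx, go, ge = scheme.scaled()
    ea, eb = encode(read), encode(ref)
    d = 0 if diagonal is None else int(diagonal)
    ok, best, bi, bc, bstate, tbM, tbX, tbY = _gotoh.fill_banded(
        ea, eb, sm, sx, go, ge, d, int(band)
    )
    if not ok:
        raise AlignmentBandError(f"no alignment path inside band (diag={d}, width={band})")
    ops, qi, ti = _traceback_banded(ea, eb, tbM, tbX, tbY, int(bi), int(bc), int(bstate), d, int(band))
    return Alignment("semiglobal", best / 2.0, ops, qi, ti, _identity(ops))


def banded_semiglobal_score(
    read: str,
    ref: str,
    scheme: ScoringScheme,
    band: int,
    diagonal: int = 0,
) -> float:
    """Score-only banded fitting alignment (no traceback objects built)."""
    _check_inputs(read, ref)
    sm, sx, go, ge = scheme.scaled()
    ok, best, *_ = _gotoh.fill_banded(
        encode(read), encode(ref), sm, sx, go, ge, int(diagonal), int(band)
    )
    if not ok:
        raise AlignmentBandError(f"no alignment path inside band (diag={diagonal}, width={band})")
    return best / 2.0


def _traceback_banded(a, b, tbM, tbX, tbY, bi, bc, bstate, diag, width):
    raw = []
    i, c, s = bi, bc, bstate
    while True:
        if s == 0:
            if i == 0:
                break  # row-0 M cells mark the alignment start
            j = i + diag - width + c
            prev = tbM[i, c]
            raw.append(0 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else 1)
            i -= 1  # a diagonal move keeps the band column
            if prev == 3:
                break
            s = prev
        elif s == 1:
            prev = tbX[i, c]
            raw.append(2)
            i -= 1
            c += 1
            s = prev
        else:
            prev = tbY[i, c]
            raw.append(3)
            c -= 1
            s = prev
    raw.reverse()
    end_j = bi + diag - width + bc
    start_j = i + diag - width + c
    ops = []
    for code in raw:
        name = _OP_NAME[code]
        if ops and ops[-1][0] == name:
            ops[-1] = (name, ops[-1][1] + 1)
        else:
            ops.append((name, 1))
    return ops, (i, bi), (start_j, end_j)


def normalized_score(aln: Alignment, target_len: int, scheme: ScoringScheme) -> float:
    """Percent-of-maximum score: 100 * score / (match * target_len), clamped
    at 0.  A perfect full-length match of the target scores 100.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    return max(0.0, 100.0 * aln.score / (scheme.match * target_len))
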