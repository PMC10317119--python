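"""Aligner unit and property tests against an independent DP oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasmidval.align import (
    BIOBIN_SCHEME,
    NEEDLE_SCHEME,
    Alignment,
    AlignmentBandError,
    ScoringScheme,
    global_align,
    local_align,
    normalized_score,
    reverse_complement,
    semiglobal_align,
)

from .oracle import oracle_score

BIOBIN_TUPLE = (3, -6, -10, -5)

dna = st.text(alphabet="ACGT", min_size=1, max_size=20)


def test_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(match=-1)
    with pytest.raises(ValueError):
        ScoringScheme(mismatch=1)
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=-1, gap_extend=-5)  # open must be <= extend
    assert NEEDLE_SCHEME.scaled() == (10, -8, -20, -1)


@pytest.mark.parametrize(
    "a,b,score,identity",
    [
        ("ACGT", "ACGT", 12.0, 100.0),  # 4 matches x 3
        ("ACGT", "AGT", -1.0, None),  # 3 matches + a 1-bp gap: 9 - 10
        ("AAAA", "TTTT", -24.0, 0.0),  # all-mismatch beats the double-gap path
    ],
)
def test_global_examples(a, b, score, identity):
    aln = global_align(a, b, BIOBIN_SCHEME)
    assert aln.score == score
    if identity is not None:
        assert aln.identity_pct == identity
    # both sequences fully consumed
    assert aln.query_interval == (0, len(a))
    assert aln.target_interval == (0, len(b))


def test_local_examples():
    aln = local_align("TTTACGTTTT", "ACGT", BIOBIN_SCHEME)
    assert aln.score == 12.0
    assert aln.target_interval == (0, 4)  # target fully covered
    empty = local_align("GGGG", "CCCC", BIOBIN_SCHEME)
    assert empty.score == 0.0 and empty.ops == []
    k24 = "ACGTACGGTCAGTCAGGCATGCAA"
    assert local_align(k24, k24, BIOBIN_SCHEME).score == 72.0


def test_semiglobal_exact_substring(rng):
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
    read = ref[300:400]
    aln = semiglobal_align(read, ref, BIOBIN_SCHEME)
    assert aln.identity_pct == 100.0
    assert aln.target_interval == (300, 400)
    # one substitution drops identity to 99 and costs match -> mismatch
    mutated = read[:50] + ("A" if read[50] != "A" else "C") + read[51:]
    aln2 = semiglobal_align(mutated, ref, BIOBIN_SCHEME)
    assert aln2.identity_pct == 99.0
    assert aln2.score == 99 * 3 - 6


def test_semiglobal_wraps_circular_origin(rng):
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
    read = ref[950:] + ref[:50]
    aln = semiglobal_align(read, ref + ref, BIOBIN_SCHEME)
    assert aln.identity_pct == 100.0
    ts, te = aln.target_interval
    assert ts % 1000 == 950 and te - ts == 100


def test_empty_sequence_rejected():
    for f in (global_align, local_align, semiglobal_align):
        with pytest.raises(ValueError):
            f("", "ACGT")
        with pytest.raises(ValueError):
            f("ACGT", "")


def test_normalized_score_examples():
    k24 = "ACGTACGGTCAGTCAGGCATGCAA"
    aln = local_align(k24, k24, BIOBIN_SCHEME)
    assert normalized_score(aln, 24, BIOBIN_SCHEME) == 100.0
    half = Alignment("local", 36.0, [], (0, 0), (0, 0), 0.0)
    assert normalized_score(half, 24, BIOBIN_SCHEME) == 50.0
    neg = Alignment("global", -24.0, [], (0, 0), (0, 0), 0.0)
    assert normalized_score(neg, 4, BIOBIN_SCHEME) == 0.0  # clamped


def test_scores_match_oracle_on_random_pairs():
    """200 random short pairs agree exactly with the brute-force DP."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        a = "".join("ACGTN"[i] for i in rng.integers(0, 5, rng.integers(1, 21)))
        b = "".join("ACGTN"[i] for i in rng.integers(0, 5, rng.integers(1, 21)))
        assert global_align(a, b, BIOBIN_SCHEME).score == oracle_score(a, b, BIOBIN_TUPLE, "global")
        assert local_align(a, b, BIOBIN_SCHEME).score == oracle_score(a, b, BIOBIN_TUPLE, "local")
        assert semiglobal_align(a, b, BIOBIN_SCHEME).score == oracle_score(
            a, b, BIOBIN_TUPLE, "semiglobal"
        )


def test_score_equals_sum_of_op_contributions(rng):
    """Alignment invariant: the score decomposes over the edit operations."""
    for _ in range(50):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 30)))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 30)))
        for aln in (global_align(a, b), local_align(a, b)):
            s = 0.0
            for op, n in aln.ops:
                if op == "match":
                    s += 3 * n
                elif op == "mismatch":
                    s += -6 * n
                else:
                    s += -10 - 5 * (n - 1)
            if aln.ops:
                assert s == aln.score
            # consumed lengths match the reported intervals
            q = sum(n for op, n in aln.ops if op in ("match", "mismatch", "ins"))
            t = sum(n for op, n in aln.ops if op in ("match", "mismatch", "del"))
            assert q == aln.query_interval[1] - aln.query_interval[0]
            assert t == aln.target_interval[1] - aln.target_interval[0]


@settings(max_examples=60, deadline=None)
@given(dna, dna)
def test_global_symmetry(a, b):
    """score(a,b) == score(b,a) for a symmetric scheme."""
    assert global_align(a, b, BIOBIN_SCHEME).score == global_align(b, a, BIOBIN_SCHEME).score


@settings(max_examples=60, deadline=None)
@given(dna)
def test_self_alignment_scores(x):
    assert global_align(x, x, BIOBIN_SCHEME).score == 3 * len(x)
    assert local_align(x, x, BIOBIN_SCHEME).score >= 0


def test_banded_equals_unbanded_on_low_error_reads(rng):
    """Band >= 50 around the true diagonal is loss-free at ~2% error."""
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    for start in (0, 500, 1500):
        read = list(ref[start : start + 400])
        for p in rng.choice(400, size=8, replace=False):  # ~2% substitutions
            read[p] = "ACGT"[rng.integers(0, 4)]
        read = "".join(read)
        full = semiglobal_align(read, ref, BIOBIN_SCHEME)
        banded = semiglobal_align(read, ref, BIOBIN_SCHEME, band=50, diagonal=start)
        assert banded.score == full.score


def test_band_too_narrow_raises():
    with pytest.raises(AlignmentBandError):
        # the band lies entirely beyond the end of the target
        semiglobal_align("ACGTACGT" * 10, "T" * 500, BIOBIN_SCHEME, band=3, diagonal=600)


def test_matches_biopython_pairwise_aligner(rng):
    """Cross-check against Biopython's independent C implementation."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 3
    aligner.mismatch_score = -6
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -5
    for _ in range(40):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 25)))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(1, 25)))
        assert global_align(a, b, BIOBIN_SCHEME).score == aligner.score(a, b)


def test_reverse_complement():
    assert reverse_complement("ACGTN") == "NACGT"
    assert reverse_complement(reverse_complement("GATTACA")) == "GATTACA"
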