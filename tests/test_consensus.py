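"""Read mapping, pileup accounting and plurality consensus calling."""

import numpy as np
import pytest

from plasmidval.consensus import (
    NoConsensusError,
    build_pileup,
    call_consensus,
    map_reads,
)
from plasmidval.io import SequenceRecord
from plasmidval.simulate import SimConfig, make_pool, simulate_pool

from tests.conftest import random_seq


@pytest.fixture(scope="module")
def circ_ref():
    rng = np.random.default_rng(71)
    return SequenceRecord("ref", random_seq(rng, 1200), circular=True)


def reads_covering(ref, n=12, length=500, offset=97):
    """Deterministic tiling reads (error-free) covering the whole circle."""
    ext = ref.sequence * 2
    out = []
    for i in range(n):
        start = (i * offset * 2) % len(ref.sequence)
        out.append(SequenceRecord(f"t{i}", ext[start : start + length], qualities=[30] * length))
    return out


def test_map_exact_read(circ_ref):
    read = SequenceRecord("r", circ_ref.sequence[100:400], qualities=[30] * 300)
    mapped, stats = map_reads([read], circ_ref)
    assert stats["mapped"] == 1
    aln = mapped[0].alignment
    assert aln.identity_pct == 100.0
    assert aln.target_interval == (100, 400)


def test_map_rejects_foreign_read(circ_ref, rng):
    foreign = SequenceRecord("x", random_seq(rng, 400), qualities=[30] * 400)
    mapped, stats = map_reads([foreign], circ_ref)
    assert mapped == []
    assert stats["no_seed"] + stats["low_identity"] + stats["ambiguous_locus"] == 1


def test_map_wraps_origin_as_single_alignment(circ_ref):
    L = len(circ_ref.sequence)
    read = SequenceRecord("w", (circ_ref.sequence * 2)[L - 150 : L + 150], qualities=[30] * 300)
    mapped, stats = map_reads([read], circ_ref)
    assert stats["mapped"] == 1
    ts, te = mapped[0].alignment.target_interval
    assert ts % L == L - 150 and te - ts == 300  # contiguous, not two clips


def test_pileup_counts(circ_ref):
    reads = reads_covering(circ_ref)
    mapped, _ = map_reads(reads, circ_ref)
    pile = build_pileup(mapped, circ_ref)
    # counts per column sum to coverage, and agree with the base identity
    L = len(circ_ref.sequence)
    cov = pile.coverage
    assert cov.min() >= 1
    sym = {b: i for i, b in enumerate("ACGT")}
    for j in (0, 57, L - 1):
        assert pile.counts[j, sym[circ_ref.sequence[j]]] == cov[j]


def test_empty_pileup_raises(circ_ref):
    pile = build_pileup([], circ_ref)
    with pytest.raises(NoConsensusError):
        call_consensus(pile)


def test_error_free_consensus_round_trip(circ_ref):
    reads = reads_covering(circ_ref)
    mapped, _ = map_reads(reads, circ_ref)
    cons = call_consensus(build_pileup(mapped, circ_ref), min_depth=1)
    assert cons.sequence == circ_ref.sequence
    assert cons.called_interval == (0, len(circ_ref.sequence))


def test_consensus_invariant_to_read_order(circ_ref):
    reads = reads_covering(circ_ref)
    mapped, _ = map_reads(reads, circ_ref)
    fwd = call_consensus(build_pileup(mapped, circ_ref), min_depth=1)
    rev = call_consensus(build_pileup(list(reversed(mapped)), circ_ref), min_depth=1)
    assert fwd.sequence == rev.sequence


def test_uncovered_start_is_trimmed_not_backfilled(rng):
    """Leading columns without reads are absent from the consensus."""
    ref = SequenceRecord("lin", random_seq(rng, 600))
    reads = [
        SequenceRecord(f"r{i}", ref.sequence[2:], qualities=[30] * 598) for i in range(6)
    ]
    mapped, _ = map_reads(reads, ref)
    cons = call_consensus(build_pileup(mapped, ref), min_depth=1)
    assert cons.called_interval == (2, 600)
    assert cons.sequence == ref.sequence[2:]  # never filled from the reference


def test_low_depth_interior_called_n(rng):
    ref = SequenceRecord("lin", random_seq(rng, 300))
    # 6x coverage everywhere except a hole covered by 2 reads only
    reads = [SequenceRecord(f"a{i}", ref.sequence[:140], qualities=[30] * 140) for i in range(6)]
    reads += [SequenceRecord(f"b{i}", ref.sequence[160:], qualities=[30] * 140) for i in range(6)]
    reads += [SequenceRecord(f"m{i}", ref.sequence[100:200], qualities=[30] * 100) for i in range(2)]
    mapped, _ = map_reads(reads, ref)
    cons = call_consensus(build_pileup(mapped, ref), min_depth=5)
    assert "N" * 20 in cons.sequence
    assert set(cons.low_depth_positions) == set(range(140, 160))


def test_subclonal_deletion_counts(rng):
    """7 deletion reads vs 3 wildtype: deletion wins the pileup vote."""
    ref = SequenceRecord("lin", random_seq(rng, 500))
    wt = ref.sequence
    mut = wt[:200] + wt[240:]  # 40-bp deletion
    reads = [SequenceRecord(f"d{i}", mut, qualities=[30] * len(mut)) for i in range(7)]
    reads += [SequenceRecord(f"w{i}", wt, qualities=[30] * len(wt)) for i in range(3)]
    mapped, _ = map_reads(reads, ref)
    pile = build_pileup(mapped, ref)
    from plasmidval.consensus import DEL

    assert all(pile.counts[j, DEL] == 7 for j in range(200, 240))
    cons = call_consensus(pile, min_depth=1)
    assert cons.sequence == mut  # majority allele in the consensus
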