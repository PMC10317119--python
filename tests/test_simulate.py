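"""Simulator: determinism, error model calibration, preparation modes."""

import numpy as np
import pytest

from plasmidval.align import global_align, ScoringScheme, reverse_complement
from plasmidval.io import SequenceRecord
from plasmidval.rotation import CutSpec
from plasmidval.simulate import (
    SimConfig,
    VariantSpec,
    apply_variant,
    make_pool,
    mutate_sequence,
    simulate_pool,
)

from tests.conftest import random_seq


def test_make_pool_marker_mode_and_determinism():
    a = make_pool(6, 1500, 24, seed=9)
    b = make_pool(6, 1500, 24, seed=9)
    assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]
    assert all(r.circular and len(r) == 1524 for r in a)
    # markers are pairwise distinct and absent from every other plasmid
    for i, r in enumerate(a):
        marker = r.sequence[500:524]  # inserted at base_len // 3
        for j, other in enumerate(a):
            if i != j:
                assert marker not in other.sequence * 2


def test_make_pool_dissimilar_mode():
    refs = make_pool(2, 3000, 0, seed=10)
    k = 24
    kmers0 = {refs[0].sequence[i : i + k] for i in range(3000 - k)}
    kmers1 = {refs[1].sequence[i : i + k] for i in range(3000 - k)}
    assert not (kmers0 & kmers1)  # no shared 24-mer between random plasmids


@pytest.mark.parametrize(
    "kind,length,delta",
    [("deletion", 22, -22), ("insertion", 1, 1), ("substitution", 5, 0)],
)
def test_apply_variant_lengths(kind, length, delta, rng):
    ref = SequenceRecord("p", random_seq(rng, 2000), circular=True)
    var, truth = apply_variant(ref, VariantSpec("p", kind, 1200, length), seed=3)
    assert len(var) - len(ref) == delta
    assert truth["position"] == 1200 and truth["kind"] == kind
    if kind == "substitution":
        diff = sum(1 for a, b in zip(ref.sequence, var.sequence) if a != b)
        assert diff == 5  # every substituted base really changed


def test_apply_variant_out_of_bounds(rng):
    ref = SequenceRecord("p", random_seq(rng, 100))
    with pytest.raises(ValueError):
        apply_variant(ref, VariantSpec("p", "deletion", 95, 10))


def test_simulate_pool_deterministic(marker_pool):
    cfg = SimConfig(seed=5)
    r1, t1 = simulate_pool(marker_pool, 5, cfg)
    r2, t2 = simulate_pool(marker_pool, 5, cfg)
    assert [(x.id, x.sequence, x.qualities) for x in r1] == [
        (x.id, x.sequence, x.qualities) for x in r2
    ]
    assert t1.equals(t2)


def test_error_free_cut_site_reads_equal_rotated_reference():
    refs = make_pool(2, 1000, 0, seed=6)
    cuts = [CutSpec(r.id, 137 * (i + 1)) for i, r in enumerate(refs)]
    cfg = SimConfig(sub_rate=0, ins_rate=0, del_rate=0, start_mode="cut_site",
                    end_trim_mean=0, seed=7)
    reads, truth = simulate_pool(refs, 4, cfg, cuts=cuts)
    by_ref = {r.id: r for r in refs}
    cut_by_ref = {c.ref_id: c.cut_position for c in cuts}
    for read, row in zip(reads, truth.itertuples()):
        ref = by_ref[row.ref_id]
        cut = cut_by_ref[row.ref_id]
        expected = ref.sequence[cut:] + ref.sequence[:cut]
        seq = read.sequence if row.strand == "+" else reverse_complement(read.sequence)
        assert seq == expected


def test_cut_site_mode_requires_cuts(marker_pool):
    with pytest.raises(ValueError):
        simulate_pool(marker_pool, 2, SimConfig(start_mode="cut_site", seed=1))


def test_realized_error_rate_near_configured(rng):
    """Alignment-measured error fraction within 1 point of the 10% target."""
    cfg = SimConfig(seed=8)
    template = random_seq(np.random.default_rng(88), 800)
    cheap = ScoringScheme(1, -2, -3, -1)
    n_err = n_cols = 0
    gen = np.random.default_rng(8)
    for _ in range(50):
        read, _ = mutate_sequence(template, gen, cfg)
        aln = global_align(read, template, cheap)
        n_cols += sum(n for op, n in aln.ops)
        n_err += sum(n for op, n in aln.ops if op != "match")
    rate = n_err / n_cols
    assert abs(rate - cfg.total_error) < 0.012


def test_homopolymer_deletions_enriched():
    """Deletion rate inside runs >= 4 tracks the configured multiplier."""
    cfg = SimConfig(seed=9, homopolymer_del_factor=2.0)
    template = ("AAAAAA" + "CGTG" * 3) * 300  # half homopolymer, half mixed
    gen = np.random.default_rng(9)
    tot = {"del_hp": 0, "bases_hp": 0, "del": 0, "bases": 0}
    for _ in range(30):
        _, stats = mutate_sequence(template, gen, cfg)
        for k in tot:
            tot[k] += stats[k]
    hp_rate = tot["del_hp"] / tot["bases_hp"]
    bg_rate = (tot["del"] - tot["del_hp"]) / (tot["bases"] - tot["bases_hp"])
    assert hp_rate / bg_rate == pytest.approx(cfg.homopolymer_del_factor, rel=0.25)


def test_random_start_positions_uniform(marker_pool):
    """Chi-square on 10 bins of start positions, n = 2000."""
    from scipy.stats import chisquare

    cfg = SimConfig(seed=11)
    _, truth = simulate_pool(marker_pool[:1], 2000, cfg)
    L = len(marker_pool[0])
    counts, _ = np.histogram(truth.start, bins=10, range=(0, L))
    assert chisquare(counts).pvalue > 0.01


def test_quality_matches_error_rate():
    assert SimConfig(seed=0).quality == 10  # 10% aggregate error -> Q10
    assert SimConfig(sub_rate=0, ins_rate=0, del_rate=0, seed=0).quality == 60
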