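"""Synthetic plasmid pools and nanopore-style reads.

The generator emulates the two library preparations used for pooled
plasmid sequencing: transposase-based (random start positions on the
circle) and restriction-based (every read starts at the plasmid's cut site,
minus small exponential end trims).  The error model is parametric:
independent per-base substitution/insertion/deletion draws with an
aggregate default of ~10% (0.04/0.03/0.03) and a deletion rate multiplied
inside homopolymer runs of four or more bases -- the dominant error mode of
nanopore base calls.  Read lengths follow a lognormal targeting N50 ~ 6 kb,
truncated at template length.  Everything is driven by a single seed:
identical inputs give byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import reverse_complement
from .io import SequenceRecord
from .rotation import CutSpec

__all__ = [
    "SimConfig",
    "VariantSpec",
    "make_pool",
    "apply_variant",
    "simulate_pool",
    "mutate_sequence",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Error / preparation / length model for simulated reads."""

    sub_rate: float = 0.04
    ins_rate: float = 0.03
    del_rate: float = 0.03
    homopolymer_del_factor: float = 2.0
    start_mode: str = "random"  # "random" (transposase) or "cut_site" (restriction)
    length_mu: float = 8.34  # lognormal log-scale; with sigma 0.6 -> N50 ~ 6 kb
    length_sigma: float = 0.6
    end_trim_mean: float = 20.0
    seed: int = 0

    def __post_init__(self):
        rates = (self.sub_rate, self.ins_rate, self.del_rate)
        if any(r < 0 or r >= 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must lie in [0,1) and sum below 1")
        if self.start_mode not in ("random", "cut_site"):
            raise ValueError("start_mode must be 'random' or 'cut_site'")

    @property
    def total_error(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @property
    def quality(self) -> int:
        """Constant per-base Phred quality consistent with the error rate."""
        if self.total_error <= 0:
            return 60
        return min(60, int(round(-10 * math.log10(self.total_error))))


@dataclass(frozen=True)
class VariantSpec:
    """An injected variant, optionally subclonal."""

    ref_id: str
    kind: str  # insertion | deletion | substitution
    position: int
    length: int = 0
    sequence: Optional[str] = None  # insertion/substitution payload
    subclonal_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion", "substitution"):
            raise ValueError("kind must be insertion, deletion or substitution")
        if not (0 < self.subclonal_fraction <= 1):
            raise ValueError("subclonal_fraction must be in (0, 1]")
        if self.position < 0 or self.length < 0:
            raise ValueError("position and length must be non-negative")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_pool(
    n_plasmids: int,
    base_len: int = 4500,
    marker_len: int = 24,
    seed: int = 0,
    marker_locus: Optional[int] = None,
) -> list[SequenceRecord]:
    """Build a pool of circular reference plasmids (GC ~ 0.5).

    With ``marker_len`` > 0 every plasmid is the same random backbone
    carrying a distinct random marker inserted at a fixed locus; with
    ``marker_len`` = 0 the plasmids are fully random, dissimilar sequences.
    """
    rng = np.random.default_rng(seed)
    if marker_len == 0:
        return [
            SequenceRecord(f"plasmid{i+1:02d}", _random_seq(rng, base_len), circular=True)
            for i in range(n_plasmids)
        ]
    backbone = _random_seq(rng, base_len)
    locus = base_len // 3 if marker_locus is None else marker_locus
    refs: list[SequenceRecord] = []
    used: set[str] = set()
    occupied = backbone * 2 + "#" + reverse_complement(backbone * 2)
    for i in range(n_plasmids):
        for _ in range(100):
            marker = _random_seq(rng, marker_len)
            if marker in used or reverse_complement(marker) in used:
                continue
            if marker in occupied or reverse_complement(marker) in occupied:
                continue
            break
        else:
            raise RuntimeError("could not draw a distinct marker; pool too dense")
        used.add(marker)
        seq = backbone[:locus] + marker + backbone[locus:]
        refs.append(SequenceRecord(f"plasmid{i+1:02d}", seq, circular=True))
    return refs


def apply_variant(
    ref: SequenceRecord, spec: VariantSpec, seed: int = 0
) -> tuple[SequenceRecord, dict]:
    """Apply a variant to a reference; returns (variant record, truth dict)."""
    seq = ref.sequence
    rng = np.random.default_rng(seed)
    if spec.kind == "deletion":
        if spec.position + spec.length > len(seq):
            raise ValueError("deletion runs past the reference end")
        new = seq[: spec.position] + seq[spec.position + spec.length :]
        payload = ""
    elif spec.kind == "insertion":
        if spec.position > len(seq):
            raise ValueError("insertion position out of bounds")
        payload = spec.sequence if spec.sequence is not None else _random_seq(rng, spec.length)
        new = seq[: spec.position] + payload + seq[spec.position :]
    else:
        if spec.position + spec.length > len(seq):
            raise ValueError("substitution runs past the reference end")
        if spec.sequence is not None:
            payload = spec.sequence
        else:
            chars = []
            for ch in seq[spec.position : spec.position + spec.length]:
                choices = [b for b in "ACGT" if b != ch]
                chars.append(choices[rng.integers(0, 3)])
            payload = "".join(chars)
        new = seq[: spec.position] + payload + seq[spec.position + spec.length :]
    label = f"{spec.kind[:3]}{spec.length or len(payload)}@{spec.position}"
    truth = {
        "ref_id": ref.id,
        "kind": spec.kind,
        "position": spec.position,
        "length": spec.length or len(payload),
        "sequence": payload,
    }
    return SequenceRecord(f"{ref.id}|{label}", new, circular=ref.circular), truth


def _homopolymer_mask(seq: str, min_run: int = 4) -> np.ndarray:
    """True at positions inside a homopolymer run of >= min_run bases."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def mutate_sequence(
    template: str, rng: np.random.Generator, config: SimConfig
) -> tuple[str, dict[str, int]]:
    """Apply the error model to a template; returns (read, op statistics).

    Statistics separate deletions inside homopolymer runs (>= 4) from
    background so the enrichment is measurable.
    """
    hp = _homopolymer_mask(template)
    out: list[str] = []
    stats = {
        "sub": 0,
        "ins": 0,
        "del": 0,
        "del_hp": 0,
        "bases_hp": int(hp.sum()),
        "bases": len(template),
    }
    sub, ins = config.sub_rate, config.ins_rate
    dele = config.del_rate
    dele_hp = min(0.95, config.del_rate * config.homopolymer_del_factor)
    draws = rng.random(2 * len(template)).reshape(-1, 2)
    for i, ch in enumerate(template):
        p_del = dele_hp if hp[i] else dele
        r = draws[i, 0]
        if r < p_del:
            stats["del"] += 1
            if hp[i]:
                stats["del_hp"] += 1
        elif r < p_del + sub:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[int(rng.integers(0, 3))])
            stats["sub"] += 1
        else:
            out.append(ch)
        if draws[i, 1] < ins:
            out.append(str(_BASES[int(rng.integers(0, 4))]))
            stats["ins"] += 1
    return "".join(out), stats


def simulate_pool(
    refs: Sequence[SequenceRecord],
    reads_per_plasmid: int,
    config: SimConfig = SimConfig(),
    cuts: Optional[Sequence[CutSpec]] = None,
    variants: Optional[Sequence[VariantSpec]] = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Simulate a pooled read library; returns (reads, truth table).

    ``variants`` attach alternative haplotypes to their references; each
    read is drawn from the variant haplotype with probability
    ``subclonal_fraction``.  In cut_site mode every reference needs a
    CutSpec and reads run cut-to-cut minus exponential end trims; in random
    mode start positions are uniform on the circle and lengths follow the
    lognormal model truncated at template length.
    """
    if reads_per_plasmid <= 0:
        raise ValueError("reads_per_plasmid must be positive")
    cut_by_ref = {c.ref_id: c for c in cuts} if cuts else {}
    if config.start_mode == "cut_site":
        missing = [r.id for r in refs if r.id not in cut_by_ref]
        if missing:
            raise ValueError(f"cut_site mode needs a CutSpec per reference; missing {missing}")
    var_by_ref: dict[str, list[VariantSpec]] = {}
    for v in variants or []:
        var_by_ref.setdefault(v.ref_id, []).append(v)
    for rid, vs in var_by_ref.items():
        if len(vs) > 1:
            raise ValueError(f"{rid}: at most one variant haplotype per reference")

    rng = np.random.default_rng(config.seed)
    q = config.quality
    reads: list[SequenceRecord] = []
    truth_rows = []
    for ref in refs:
        haplotypes: list[tuple[str, str]] = [("ref", ref.sequence)]
        fractions = [1.0]
        for v in var_by_ref.get(ref.id, []):
            var_rec, _ = apply_variant(ref, v, seed=int(rng.integers(0, 2**31 - 1)))
            haplotypes.append((var_rec.id.split("|", 1)[1], var_rec.sequence))
            fractions.append(v.subclonal_fraction)
        for n in range(reads_per_plasmid):
            hap_name, hap_seq = haplotypes[0]
            if len(haplotypes) > 1:
                # single alternative haplotype: draw against its fraction
                if rng.random() < fractions[1]:
                    hap_name, hap_seq = haplotypes[1]
            L = len(hap_seq)
            if config.start_mode == "cut_site":
                cut = cut_by_ref[ref.id].cut_position % L
                lt = int(rng.exponential(config.end_trim_mean)) if config.end_trim_mean > 0 else 0
                rt = int(rng.exponential(config.end_trim_mean)) if config.end_trim_mean > 0 else 0
                length = max(50, L - lt - rt)
                start = (cut + lt) % L
            else:
                start = int(rng.integers(0, L))
                length = int(np.clip(rng.lognormal(config.length_mu, config.length_sigma), 100, L))
            template = (hap_seq * 2)[start : start + length]
            seq, _ = mutate_sequence(template, rng, config)
            strand = "-" if rng.random() < 0.5 else "+"
            if strand == "-":
                seq = reverse_complement(seq)
            if not seq:
                continue
            rid = f"{ref.id}/{n:05d}"
            reads.append(SequenceRecord(rid, seq, qualities=[q] * len(seq)))
            truth_rows.append(
                dict(
                    read_id=rid,
                    ref_id=ref.id,
                    haplotype=hap_name,
                    start=start,
                    strand=strand,
                    true_length=length,
                )
            )
    truth = pd.DataFrame(truth_rows)
    return reads, truth
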