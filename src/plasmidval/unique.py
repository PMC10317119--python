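"""Unique-region discovery: markers that occur in exactly one reference of a
pool, used to attribute reads without barcodes.

A substring is *unique* to a reference when it occurs -- in either
orientation -- in no other reference of the set (circular references are
scanned across the origin via their doubled sequence).  Repeats within the
owning reference do not disqualify a marker: uniqueness is across
references only, which is all the binning step needs.

The scan computes matching statistics against the concatenation of all
other references: for every start position the length of the longest prefix
that still occurs elsewhere.  One past that length is the shortest unique
substring at that start.  Overlapping shortest-unique candidates are merged
into maximal unique runs; runs longer than ``max_marker_len`` are tiled into
bounded windows (each containing a complete shortest-unique substring, so
every reported marker is itself unique), and up to ``max_regions`` windows
are kept, chosen spread across the reference so that downstream bins cover
the whole plasmid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .align import reverse_complement
from .io import SequenceRecord

logger = logging.getLogger("plasmidval")

__all__ = ["UniqueRegion", "find_unique_regions", "extract_context", "regions_to_tsv"]

DEFAULT_MIN_LEN = 4  # ">3 bp"
DEFAULT_FLANK = 20
DEFAULT_MAX_REGIONS = 8
DEFAULT_MAX_MARKER_LEN = 64


@dataclass
class UniqueRegion:
    """A marker interval on one reference.

    ``start``/``end`` are 0-based half-open on the owner; on circular
    references ``end`` may exceed the reference length to denote an
    origin-wrapping marker (coordinates are modulo length).  ``context`` is
    the marker extended by up to ``flank`` reference bases on each side.
    """

    ref_id: str
    start: int
    end: int
    marker: str
    context: str

    def __len__(self) -> int:
        return self.end - self.start


def _scan_text(ref: SequenceRecord) -> str:
    return ref.sequence * 2 if ref.circular else ref.sequence


def find_unique_regions(
    refs: Sequence[SequenceRecord],
    min_len: int = DEFAULT_MIN_LEN,
    max_regions: int = DEFAULT_MAX_REGIONS,
    max_marker_len: int = DEFAULT_MAX_MARKER_LEN,
    flank: int = DEFAULT_FLANK,
) -> dict[str, list[UniqueRegion]]:
    """Find per-reference unique marker regions (>= min_len bases).

    Returns a dict ref_id -> list of UniqueRegion (may be empty, with a
    logged warning, for references indistinguishable from the rest).
    """
    if len(refs) < 2:
        raise ValueError("unique-region scan requires at least 2 references")
    ids = [r.id for r in refs]
    if len(set(ids)) != len(ids):
        raise ValueError("reference ids must be unique")

    # one generalized suffix array over both strands of every reference;
    # matching statistics of each position against all *other* references
    from ._mstats import pool_matching_statistics

    segments: list[tuple[int, str]] = []
    for idx, ref in enumerate(refs):
        t = _scan_text(ref)
        segments.append((idx, t))
        segments.append((idx, reverse_complement(t)))
    all_ms = pool_matching_statistics(segments)

    out: dict[str, list[UniqueRegion]] = {}
    for idx, ref in enumerate(refs):
        L = len(ref.sequence)
        owner_ext = _scan_text(ref)
        # circular: scan every start on the doubled sequence so that
        # origin-wrapping candidates compete with their mod-L copies in the
        # minimality filter; duplicates are removed afterwards
        n_scan = len(owner_ext)
        ms = np.minimum(all_ms[2 * idx], L)  # marker capped at plasmid length

        # shortest-unique candidates: [i, i + ms[i] + 1)
        cands: list[tuple[int, int]] = []
        for i in range(n_scan):
            ulen = ms[i] + 1
            if ulen < min_len:
                ulen = min_len  # any superstring of a unique string is unique
            if i + ulen > len(owner_ext):
                continue  # no unique substring starts here (runs off the end)
            if ulen > L:
                continue
            cands.append((i, i + ulen))
        if not cands:
            logger.warning("%s: no unique region of length >= %d", ref.id, min_len)
            out[ref.id] = []
            continue
        # candidates longer than the marker cap are unusable as markers
        # unless nothing shorter exists anywhere on this reference
        short = [c for c in cands if c[1] - c[0] <= max_marker_len]
        if short:
            cands = short

        # keep locally minimal candidates (no other candidate nested inside)
        minimal: list[tuple[int, int]] = []
        min_end = None
        for i, e in reversed(cands):
            if min_end is None or e < min_end:
                minimal.append((i, e))
                min_end = e
        minimal.reverse()

        # merge overlapping/adjacent minimal candidates into maximal runs
        runs: list[list[tuple[int, int]]] = []
        for iv in minimal:
            if runs and iv[0] <= runs[-1][-1][1]:
                runs[-1].append(iv)
            else:
                runs.append([iv])
        if ref.circular:
            # keep one copy per locus: runs starting in the first copy,
            # minus runs contained (mod L) in another run
            runs = [run for run in runs if run[0][0] < L]
            runs = _dedupe_mod(runs, L)

        regions: list[UniqueRegion] = []
        for run in runs:
            run_start, run_end = run[0][0], max(e for _, e in run)
            if run_end - run_start <= max_marker_len:
                regions.append(_make_region(ref, run_start, run_end, L))
            else:
                regions.extend(_tile_run(ref, run, run_start, run_end, max_marker_len, L))
        # bound the count, preferring positional spread over the reference
        regions = _spread_select(regions, max_regions, L)
        for reg in regions:
            reg.context = extract_context(reg, ref, flank)
        out[ref.id] = regions
        if not regions:
            logger.warning("%s: no unique region of length >= %d", ref.id, min_len)
    return out


def _dedupe_mod(runs: list[list[tuple[int, int]]], L: int) -> list[list[tuple[int, int]]]:
    """Drop runs whose position set (mod L) lies inside another run's."""
    spans = [(run[0][0], max(e for _, e in run)) for run in runs]
    pos_sets = [frozenset(p % L for p in range(s, e)) for s, e in spans]
    keep = []
    for i, run in enumerate(runs):
        contained = any(
            j != i and pos_sets[i] <= pos_sets[j] and not (pos_sets[j] <= pos_sets[i] and j > i)
            for j in range(len(runs))
        )
        if not contained:
            keep.append(run)
    return keep


def _make_region(ref: SequenceRecord, start: int, end: int, L: int) -> UniqueRegion:
    owner_ext = _scan_text(ref)
    start_mod = start % L
    marker = owner_ext[start_mod : start_mod + (end - start)]
    return UniqueRegion(ref.id, start_mod, start_mod + (end - start), marker, "")


def _tile_run(ref, run, run_start, run_end, max_marker_len, L):
    """Cut an over-long unique run into windows of <= max_marker_len, each
    containing a complete shortest-unique candidate (hence unique itself)."""
    tiles = []
    pos = run_start
    k = 0
    while pos < run_end:
        win_end = min(pos + max_marker_len, run_end)
        # advance k to the first candidate fully inside [pos, win_end)
        while k < len(run) and run[k][0] < pos:
            k += 1
        contained = None
        kk = k
        while kk < len(run) and run[kk][0] < win_end:
            if run[kk][1] <= win_end:
                contained = run[kk]
                break
            kk += 1
        if contained is not None:
            tiles.append(_make_region(ref, pos, win_end, L))
            pos = win_end
        else:
            # window too short to hold any unique substring here; grow to the
            # next candidate's end
            if k >= len(run):
                break
            pos = run[k][0]
            end = run[k][1]
            tiles.append(_make_region(ref, pos, end, L))
            pos = end
    return tiles


def _spread_select(regions: list[UniqueRegion], max_regions: int, L: int) -> list[UniqueRegion]:
    if len(regions) <= max_regions:
        return regions
    regions = sorted(regions, key=lambda r: r.start)
    picked_idx = sorted({round(i * (len(regions) - 1) / (max_regions - 1)) for i in range(max_regions)})
    return [regions[i] for i in picked_idx]


def extract_context(region: UniqueRegion, ref: SequenceRecord, flank: int = DEFAULT_FLANK) -> str:
    """Marker plus up to ``flank`` reference bases each side; truncated at
    linear ends, wrapped across the origin for circular references."""
    L = len(ref.sequence)
    if ref.circular:
        f = min(flank, L)
        ext = ref.sequence * 3  # slack on both sides of the origin
        start = region.start + L
        end = region.end + L
        return ext[start - f : end + f]
    start = max(region.start - flank, 0)
    end = min(region.end + flank, L)
    return ref.sequence[start:end]


def regions_to_tsv(regions: dict[str, list[UniqueRegion]], path) -> None:
    lines = ["ref_id\tstart\tend\tmarker\tcontext"]
    for ref_id in regions:
        for r in regions[ref_id]:
            lines.append(f"{r.ref_id}\t{r.start}\t{r.end}\t{r.marker}\t{r.context}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
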