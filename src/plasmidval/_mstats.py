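"""Document-aware matching statistics over a pool of sequences.

For every position of every sequence, compute the length of the longest
prefix of the suffix starting there that occurs anywhere in a *different*
document (both strands of the other sequences are separate segments of the
same document).  Built on a generalized suffix array (numpy rank-doubling)
with Kasai LCPs and two min-LCP sweeps keyed on document changes.

Separator bytes between segments can let a comparison run across a segment
boundary; this can only over-estimate a matching statistic (claiming a
longer shared prefix), which downstream makes candidate unique substrings
longer, never falsely unique.  Callers additionally clip statistics at the
segment end.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pool_matching_statistics"]


def _suffix_array(s: np.ndarray) -> np.ndarray:
    n = len(s)
    rank = s.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, np.int64)
        if k < n:
            key2[:-k] = rank[k:]
        order = np.lexsort((key2, rank))
        new = np.empty(n, np.int64)
        new[order[0]] = 0
        diff = (rank[order[1:]] != rank[order[:-1]]) | (key2[order[1:]] != key2[order[:-1]])
        new[order[1:]] = np.cumsum(diff)
        rank = new
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _kasai_lcp(s: np.ndarray, sa: np.ndarray) -> np.ndarray:
    n = len(s)
    rank = np.empty(n, np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, np.int64)  # lcp[i] = LCP(sa[i-1], sa[i]); lcp[0] = 0
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and s[i + h] == s[j + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


def pool_matching_statistics(segments: list[tuple[int, str]]) -> list[np.ndarray]:
    """Matching statistics against other documents.

    ``segments`` is a list of (doc_id, text).  Returns, per segment, an
    array ms with ms[i] = length of the longest prefix of segment[i:] that
    occurs in any segment of a different doc_id (possibly over-estimated
    across segment boundaries; clip at the segment end if that matters).
    """
    enc = bytes.maketrans(b"ACGTN", bytes([1, 2, 3, 4, 5]))
    parts: list[np.ndarray] = []
    doc_of: list[np.ndarray] = []
    starts: list[int] = []
    pos = 0
    for doc, text in segments:
        starts.append(pos)
        arr = np.frombuffer(text.encode("ascii").translate(enc), dtype=np.uint8)
        parts.append(arr)
        parts.append(np.zeros(1, np.uint8))  # separator
        doc_of.append(np.full(len(arr) + 1, doc, np.int64))
        pos += len(arr) + 1
    s = np.concatenate(parts).astype(np.int64)
    docs = np.concatenate(doc_of)
    n = len(s)
    sa = _suffix_array(s)
    lcp = _kasai_lcp(s, sa)
    doc_sa = docs[sa]

    best = np.zeros(n, np.int64)
    # sweep down: min LCP back to the nearest preceding different-doc suffix
    cur = 0
    for i in range(1, n):
        if doc_sa[i] != doc_sa[i - 1]:
            cur = lcp[i]
        else:
            cur = min(cur, lcp[i])
        if cur > best[i]:
            best[i] = cur
    # sweep up
    cur = 0
    for i in range(n - 2, -1, -1):
        if doc_sa[i] != doc_sa[i + 1]:
            cur = lcp[i + 1]
        else:
            cur = min(cur, lcp[i + 1])
        if cur > best[i]:
            best[i] = cur

    by_pos = np.zeros(n, np.int64)
    by_pos[sa] = best
    out: list[np.ndarray] = []
    for k, (doc, text) in enumerate(segments):
        st = starts[k]
        seg = by_pos[st : st + len(text)].copy()
        # clip at the segment end: a statistic cannot meaningfully extend
        # past the segment (it would span the separator)
        tail = np.arange(len(text), 0, -1)
        np.minimum(seg, tail, out=seg)
        out.append(seg)
    return out
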