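"""Low-level affine-gap dynamic-programming kernels (three-state Gotoh).

Sequences arrive byte-encoded (A=0, C=1, G=2, T=3, N=4); N never matches,
including against N.  Scores are pre-scaled integers (the public layer
multiplies by 2 so that half-point gap penalties stay exact).  A gap of
length k costs ``open + (k-1)*extend``; switching directly between the two
gap states opens a new gap event.

Tie-breaking is deterministic: diagonal (match/mismatch) moves are preferred
over gaps, and deletions (gaps in the query) over insertions, both while
filling and when choosing the final cell.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int64(-(2**40))

# states: 0 = M (diagonal), 1 = X (consumes query; insertion relative to the
# target), 2 = Y (consumes target; deletion from the query's point of view).
# traceback codes: predecessor state 0/1/2; 3 = alignment starts at this cell.

MODE_GLOBAL = 0
MODE_LOCAL = 1
MODE_SEMIGLOBAL = 2


@njit(cache=True)
def fill_full(a, b, match, mismatch, gopen, gext, mode):
    """Fill the full DP matrix; returns (score, end_i, end_j, end_state, tbM, tbX, tbY).

    ``mode``: 0 global, 1 local (Smith-Waterman), 2 semiglobal (query fully
    aligned, target end-gaps free).  For local alignment with no positive
    cell the returned state is 3 (empty alignment, score 0).
    """
    n = a.shape[0]
    m = b.shape[0]
    tbM = np.full((n + 1, m + 1), 4, np.uint8)
    tbX = np.full((n + 1, m + 1), 4, np.uint8)
    tbY = np.full((n + 1, m + 1), 4, np.uint8)

    prevM = np.full(m + 1, NEG, np.int64)
    prevX = np.full(m + 1, NEG, np.int64)
    prevY = np.full(m + 1, NEG, np.int64)
    curM = np.full(m + 1, NEG, np.int64)
    curX = np.full(m + 1, NEG, np.int64)
    curY = np.full(m + 1, NEG, np.int64)

    # row 0
    prevM[0] = 0
    tbM[0, 0] = 3
    if mode == MODE_GLOBAL:
        for j in range(1, m + 1):
            prevY[j] = gopen + (j - 1) * gext
            tbY[0, j] = 0 if j == 1 else 2
    elif mode == MODE_SEMIGLOBAL:
        for j in range(1, m + 1):
            prevM[j] = 0
            tbM[0, j] = 3

    best = np.int64(0) if mode == MODE_LOCAL else NEG
    bi = 0
    bj = 0
    bstate = 3  # local empty-alignment sentinel

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(m + 1):
            curM[j] = NEG
            curX[j] = NEG
            curY[j] = NEG
        # first column
        if mode == MODE_GLOBAL or mode == MODE_SEMIGLOBAL:
            curX[0] = gopen + (i - 1) * gext
            tbX[i, 0] = 0 if i == 1 else 1
        for j in range(1, m + 1):
            # X: gap in target, consumes a[i-1]
            vM = prevM[j] + gopen
            vX = prevX[j] + gext
            vY = prevY[j] + gopen
            # preference on ties: M, then Y, then X
            bv = vM
            bt = np.uint8(0)
            if vY > bv:
                bv = vY
                bt = np.uint8(2)
            if vX > bv:
                bv = vX
                bt = np.uint8(1)
            curX[j] = bv
            tbX[i, j] = bt
            # Y: gap in query, consumes b[j-1]
            vM = curM[j - 1] + gopen
            vY = curY[j - 1] + gext
            vX = curX[j - 1] + gopen
            bv = vM
            bt = np.uint8(0)
            if vY > bv:
                bv = vY
                bt = np.uint8(2)
            if vX > bv:
                bv = vX
                bt = np.uint8(1)
            curY[j] = bv
            tbY[i, j] = bt
            # M: diagonal
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            dM = prevM[j - 1]
            dY = prevY[j - 1]
            dX = prevX[j - 1]
            bv = dM
            bt = np.uint8(0)
            if dY > bv:
                bv = dY
                bt = np.uint8(2)
            if dX > bv:
                bv = dX
                bt = np.uint8(1)
            if mode == MODE_LOCAL and bv < 0:
                bv = np.int64(0)
                bt = np.uint8(3)
            curM[j] = bv + s
            tbM[i, j] = bt
            if mode == MODE_LOCAL and curM[j] > best:
                best = curM[j]
                bi = i
                bj = j
                bstate = 0
        if mode == MODE_SEMIGLOBAL and i == n:
            for j in range(m + 1):
                if curM[j] > best:
                    best = curM[j]
                    bi = i
                    bj = j
                    bstate = 0
                if curX[j] > best:
                    best = curX[j]
                    bi = i
                    bj = j
                    bstate = 1
        pm = prevM; prevM = curM; curM = pm
        px = prevX; prevX = curX; curX = px
        py = prevY; prevY = curY; curY = py

    if mode == MODE_GLOBAL:
        best = prevM[m]
        bi = n
        bj = m
        bstate = 0
        if prevY[m] > best:
            best = prevY[m]
            bstate = 2
        if prevX[m] > best:
            best = prevX[m]
            bstate = 1
    if n == 0 and mode != MODE_LOCAL:
        # degenerate, callers reject empty input before reaching here
        best = prevM[m]
    return best, bi, bj, bstate, tbM, tbX, tbY


@njit(cache=True)
def fill_banded(a, b, match, mismatch, gopen, gext, diag, width):
    """Banded semiglobal fill around target ~= query + diag.

    Returns (ok, score, end_i, end_c, end_state, tbM, tbX, tbY).  Band
    column index c maps to target coordinate j = i + diag - width + c.
    """
    n = a.shape[0]
    m = b.shape[0]
    W = 2 * width + 1
    tbM = np.full((n + 1, W), 4, np.uint8)
    tbX = np.full((n + 1, W), 4, np.uint8)
    tbY = np.full((n + 1, W), 4, np.uint8)

    prevM = np.full(W, NEG, np.int64)
    prevX = np.full(W, NEG, np.int64)
    prevY = np.full(W, NEG, np.int64)
    curM = np.full(W, NEG, np.int64)
    curX = np.full(W, NEG, np.int64)
    curY = np.full(W, NEG, np.int64)

    # row 0: free leading target gap within the band
    for c in range(W):
        j = diag - width + c
        if 0 <= j <= m:
            prevM[c] = 0
            tbM[0, c] = 3

    for i in range(1, n + 1):
        ai = a[i - 1]
        off = i + diag - width  # j of band column 0 in this row
        for c in range(W):
            curM[c] = NEG
            curX[c] = NEG
            curY[c] = NEG
        for c in range(W):
            j = off + c
            if j < 0 or j > m:
                continue
            if j == 0:
                # query overhang before the target start
                curX[c] = gopen + (i - 1) * gext
                tbX[i, c] = 0 if i == 1 else 1
                continue
            # X from (i-1, j): band col c+1 of previous row
            if c + 1 < W:
                vM = prevM[c + 1] + gopen
                vX = prevX[c + 1] + gext
                vY = prevY[c + 1] + gopen
                bv = vM
                bt = np.uint8(0)
                if vY > bv:
                    bv = vY
                    bt = np.uint8(2)
                if vX > bv:
                    bv = vX
                    bt = np.uint8(1)
                curX[c] = bv
                tbX[i, c] = bt
            # Y from (i, j-1): band col c-1 of current row
            if c - 1 >= 0:
                vM = curM[c - 1] + gopen
                vY = curY[c - 1] + gext
                vX = curX[c - 1] + gopen
                bv = vM
                bt = np.uint8(0)
                if vY > bv:
                    bv = vY
                    bt = np.uint8(2)
                if vX > bv:
                    bv = vX
                    bt = np.uint8(1)
                curY[c] = bv
                tbY[i, c] = bt
            # M from (i-1, j-1): band col c of previous row
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            dM = prevM[c]
            dY = prevY[c]
            dX = prevX[c]
            bv = dM
            bt = np.uint8(0)
            if dY > bv:
                bv = dY
                bt = np.uint8(2)
            if dX > bv:
                bv = dX
                bt = np.uint8(1)
            curM[c] = bv + s
            tbM[i, c] = bt
        pm = prevM; prevM = curM; curM = pm
        px = prevX; prevX = curX; curX = px
        py = prevY; prevY = curY; curY = py

    best = NEG
    bc = 0
    bstate = 0
    off = n + diag - width
    for c in range(W):
        j = off + c
        if j < 0 or j > m:
            continue
        if prevM[c] > best:
            best = prevM[c]
            bc = c
            bstate = 0
        if prevX[c] > best:
            best = prevX[c]
            bc = c
            bstate = 1
    ok = best > NEG // 2
    return ok, best, n, bc, bstate, tbM, tbX, tbY
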