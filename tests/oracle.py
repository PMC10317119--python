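"""Independent brute-force three-state affine-gap DP oracle.

Written deliberately apart from the package implementation: plain Python
floats, full matrices, no traceback, no banding.  Gap convention: a gap of
length k costs open + (k-1)*extend; switching between gap states opens a
new gap.  Used to pin expected scores in the aligner tests.
"""

NEG = float("-inf")


def oracle_score(a: str, b: str, scheme: tuple[float, float, float, float], mode: str) -> float:
    match, mis, go, ge = scheme
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        if mode == "global":
            Y[0][j] = go + (j - 1) * ge
        elif mode == "semiglobal":
            M[0][j] = 0.0
    for i in range(1, n + 1):
        if mode in ("global", "semiglobal"):
            X[i][0] = go + (i - 1) * ge
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + go, X[i - 1][j] + ge, Y[i - 1][j] + go)
            Y[i][j] = max(M[i][j - 1] + go, Y[i][j - 1] + ge, X[i][j - 1] + go)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mis
            d = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            if mode == "local":
                d = max(d, 0.0)
            M[i][j] = d + s
    if mode == "global":
        return max(M[n][m], X[n][m], Y[n][m])
    if mode == "local":
        best = 0.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                best = max(best, M[i][j])
        return best
    return max(max(M[n][j], X[n][j]) for j in range(m + 1))
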