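"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: the
alignment oracle is a memoized recursion over explicit alignment moves,
the target-scan oracle is a direct window enumeration, and the growth
oracle is a grid search over slopes.
"""

from functools import lru_cache

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def brute_force_semiglobal_score(
    read: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal semi-global score by exhaustive recursion over moves.

    Free reference end gaps are realised by maximising a *global* affine
    alignment of the read over every substring of the reference.  A gap of
    length L scores gap_open + (L - 1) * gap_extend.
    """

    def global_score(sub: str) -> float:
        @lru_cache(maxsize=None)
        def rec(i: int, j: int, prev: str) -> float:
            if i == len(sub) and j == len(read):
                return 0.0
            best = float("-inf")
            if i < len(sub) and j < len(read):
                s = match if sub[i] == read[j] else mismatch
                best = max(best, s + rec(i + 1, j + 1, "M"))
            if i < len(sub):  # gap in the read row
                s = gap_extend if prev == "D" else gap_open
                best = max(best, s + rec(i + 1, j, "D"))
            if j < len(read):  # gap in the reference row
                s = gap_extend if prev == "I" else gap_open
                best = max(best, s + rec(i, j + 1, "I"))
            return best

        out = rec(0, 0, "start")
        rec.cache_clear()
        return out

    best = float("-inf")
    for s in range(len(ref) + 1):
        for e in range(s, len(ref) + 1):
            best = max(best, global_score(ref[s:e]))
    return best


def brute_force_targets(sequence: str) -> list[tuple[str, str, str]]:
    """All (spacer, pam, strand) 23-nt windows ending in NGG, both strands."""
    sequence = sequence.upper()
    out = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        for i in range(len(seq) - 22):
            window = seq[i : i + 23]
            if window[21:23] == "GG":
                out.append((window[:20], window[20:23], strand))
    return out


def grid_search_slope(days, logs, lo=-2.0, hi=2.0, n=40001) -> float:
    """Slope minimising squared log-residuals, by grid search.

    For each candidate slope the optimal intercept is the mean residual,
    so only the slope needs to be scanned.
    """
    import numpy as np

    days = np.asarray(days, dtype=float)
    logs = np.asarray(logs, dtype=float)
    slopes = np.linspace(lo, hi, n)
    best_slope, best_sse = None, float("inf")
    for s in slopes:
        resid = logs - s * days
        intercept = resid.mean()
        sse = float(((resid - intercept) ** 2).sum())
        if sse < best_sse:
            best_sse, best_slope = sse, s
    return best_slope
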