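"""Low-level dynamic programming kernels for subsequence DTW matching.

The recurrence is the streaming ("SPRING"-style) subsequence variant: every
stream sample may open a fresh alignment at template row 0, and each cell
stores, besides the accumulated distance, the stream index where its warping
path entered row 0 (start-point propagation).  Steps are the unweighted
{(1,1), (1,0), (0,1)} set in (template, stream) coordinates.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# backpointer codes
FRESH = np.int8(0)   # row 0, alignment opens here
DIAG = np.int8(1)    # (j-1, i-1)
HORIZ = np.int8(2)   # (j,   i-1)  stream advances, template stays
VERT = np.int8(3)    # (j-1, i  )  template advances, stream stays


@njit(cache=False)
def subsequence_dp(cost: np.ndarray):
    """Run the subsequence DTW recurrence over a precomputed cost matrix.

    Parameters
    ----------
    cost:
        ``(n, L)`` pairwise distances between stream samples and template
        elements.

    Returns
    -------
    end_dist : (n,) accumulated distance of the best path ending at template
        row ``L-1`` and each stream index.
    end_start : (n,) stream index where that path entered template row 0.
    back : (n, L) int8 backpointer codes for path reconstruction.
    """
    n, L = cost.shape
    D = np.empty((n, L), dtype=np.float64)
    S = np.empty((n, L), dtype=np.int64)
    back = np.empty((n, L), dtype=np.int8)

    for i in range(n):
        # template row 0: alignments always open fresh here
        D[i, 0] = cost[i, 0]
        S[i, 0] = i
        back[i, 0] = FRESH
        for j in range(1, L):
            best = D[i, j - 1]          # vertical: template advances in place
            code = VERT
            start = S[i, j - 1]
            if i > 0:
                d = D[i - 1, j - 1]     # diagonal
                if d < best:
                    best = d
                    code = DIAG
                    start = S[i - 1, j - 1]
                d = D[i - 1, j]         # horizontal
                if d < best:
                    best = d
                    code = HORIZ
                    start = S[i - 1, j]
            D[i, j] = cost[i, j] + best
            S[i, j] = start
            back[i, j] = code

    return D[:, L - 1].copy(), S[:, L - 1].copy(), back


@njit(cache=False)
def brute_force_min_distance(cost: np.ndarray) -> float:
    """Minimum over all (start, end) open-begin-open-end DTW alignments.

    Independent of :func:`subsequence_dp`: for every start index a full
    unconstrained DTW with steps {(1,1),(1,0),(0,1)} is run over the stream
    suffix, and the best accumulated distance at the final template row over
    all end indices is taken.  Quadratic in the stream length; intended for
    oracle checks on short inputs.
    """
    n, L = cost.shape
    best_overall = np.inf
    col = np.empty(L, dtype=np.float64)
    prev = np.empty(L, dtype=np.float64)
    for s in range(n):
        # first column: only vertical moves above (s, 0)
        prev[0] = cost[s, 0]
        for j in range(1, L):
            prev[j] = prev[j - 1] + cost[s, j]
        if prev[L - 1] < best_overall:
            best_overall = prev[L - 1]
        for i in range(s + 1, n):
            col[0] = prev[0] + cost[i, 0]
            for j in range(1, L):
                m = prev[j]
                if prev[j - 1] < m:
                    m = prev[j - 1]
                if col[j - 1] < m:
                    m = col[j - 1]
                col[j] = cost[i, j] + m
            if col[L - 1] < best_overall:
                best_overall = col[L - 1]
            prev, col = col, prev
    return best_overall


def backtrack_path(back: np.ndarray, end: int) -> list[tuple[int, int]]:
    """Reconstruct the (stream_index, template_index) warping path ending at
    ``(end, L-1)``; returned in increasing order."""
    i = end
    j = back.shape[1] - 1
    path = [(i, j)]
    while True:
        code = back[i, j]
        if code == FRESH:
            break
        elif code == DIAG:
            i -= 1
            j -= 1
        elif code == HORIZ:
            i -= 1
        else:  # VERT
            j -= 1
        path.append((i, j))
    path.reverse()
    return path
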