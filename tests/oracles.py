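"""Independent brute-force oracles used only by the tests.

The naive Gotoh dynamic program mirrors the scoring contract of the
package aligner (match +2, mismatch −3, first gap column −5, each
further gap column −2, N matches nothing) but is written independently
and only run at tiny sizes.
"""

from __future__ import annotations

MATCH = 2.0
MISMATCH = -3.0
OPEN = -5.0  # score of the first gap column
EXTEND = -2.0

NEG = float("-inf")


def _sub(a: str, b: str) -> float:
    return MATCH if (a == b and a != "N") else MISMATCH


def naive_local_score(query: str, subject: str) -> float:
    """Smith–Waterman score under the affine convention above."""
    n, m = len(query), len(subject)
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (consumes query)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes subject)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] + OPEN, Ix[i - 1][j] + EXTEND, Iy[i - 1][j] + OPEN)
            Iy[i][j] = max(M[i][j - 1] + OPEN, Iy[i][j - 1] + EXTEND, Ix[i][j - 1] + OPEN)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = max(0.0, diag + _sub(query[i - 1], subject[j - 1]))
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def naive_global_score(query: str, subject: str) -> float:
    """Needleman–Wunsch score under the same affine convention."""
    n, m = len(query), len(subject)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = OPEN + EXTEND * (i - 1)
    for j in range(1, m + 1):
        Iy[0][j] = OPEN + EXTEND * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] + OPEN, Ix[i - 1][j] + EXTEND, Iy[i - 1][j] + OPEN)
            Iy[i][j] = max(M[i][j - 1] + OPEN, Iy[i][j - 1] + EXTEND, Ix[i][j - 1] + OPEN)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            M[i][j] = diag + _sub(query[i - 1], subject[j - 1])
    return max(M[n][m], Ix[n][m], Iy[n][m])


def grid_cell_count(points, tolerance: float = 1.0) -> int:
    """Occupied (floor) grid cells — expected size of a deduplicated set."""
    import math

    return len({(math.floor(lat / tolerance), math.floor(lon / tolerance)) for lat, lon in points})


def simulate_greedy_clustering(seqs, identity_fn, threshold: float) -> int:
    """Count centroids of a greedy pass over *seqs* in the given order."""
    centroids = []
    for s in seqs:
        if not any(identity_fn(s, c) >= threshold for c in centroids):
            centroids.append(s)
    return len(centroids)
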