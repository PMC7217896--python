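"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's optimized code paths: the local
aligner is a full dynamic program that scans every gap length instead of
using the affine three-matrix recurrence; motif counting is a plain
position loop; the pI oracle is a grid search on the charge curve.
"""

from __future__ import annotations

import numpy as np

from hspscan.sequence_properties import (IUPAC, net_charge,
                                         reverse_complement_iupac)
from hspscan.sequence_search import AA_INDEX, NT_INDEX


def naive_local_score(a: str, b: str, matrix, gap_open: float,
                      gap_extend: float, alphabet: str = "aa") -> float:
    """Optimal local alignment score, gap cost open + k*extend, computed
    without the affine-gap optimization (explicit scan over gap lengths)."""
    index = AA_INDEX if alphabet == "aa" else NT_INDEX
    ea = [index.get(c, len(index)) for c in a]
    eb = [index.get(c, len(index)) for c in b]
    n, m = len(ea), len(eb)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            h = H[i - 1][j - 1] + matrix[ea[i - 1], eb[j - 1]]
            for k in range(1, i + 1):
                h = max(h, H[i - k][j] - gap_open - k * gap_extend)
            for k in range(1, j + 1):
                h = max(h, H[i][j - k] - gap_open - k * gap_extend)
            h = max(h, 0.0)
            H[i][j] = h
            best = max(best, h)
    return best


def bisect_lambda(values: np.ndarray, probs: np.ndarray,
                  tol: float = 1e-12) -> float:
    """Karlin-Altschul lambda by plain bisection on sum(p*exp(lam*s)) = 1."""
    def f(lam: float) -> float:
        return float(probs @ np.exp(lam * values)) - 1.0

    lo, hi = 1e-9, 1.0
    while f(hi) < 0:
        hi *= 2.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if hi - lo < tol:
            break
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def naive_motif_count(seq: str, pattern: str, both_strands: bool = True) -> int:
    """Position-by-position IUPAC match count, overlaps included,
    palindromic patterns counted once per position."""
    def forward(pat: str) -> int:
        allowed = [IUPAC[c] for c in pat.upper()]
        k = len(pat)
        return sum(1 for i in range(len(seq) - k + 1)
                   if all(seq[i + j] in allowed[j] for j in range(k)))

    total = forward(pattern)
    rc = reverse_complement_iupac(pattern)
    if both_strands and rc != pattern.upper():
        total += forward(rc)
    return total


def grid_pi(seq: str, pka_table="ipc", step: float = 0.001) -> float:
    """pH grid search minimizing |net charge| (the pI oracle)."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([abs(net_charge(seq, ph, pka_table)) for ph in grid])
    return float(grid[int(np.argmin(charges))])
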