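"""Local alignment and profile scanning with Karlin-Altschul statistics.

This module replaces the external search tools of a classical gene-family
survey: PSSM construction from seed alignments, gapped profile-sequence
scanning (the RPS-BLAST role), exact Smith-Waterman protein/nucleotide
alignment under affine gaps (the BLASTP/BLASTN role), and score
significance via E = K * m * n * exp(-lambda * S).

A single affine-gap Gotoh dynamic-programming kernel serves both search
modes: a sequence-sequence comparison is a profile scan whose per-position
scores are the substitution-matrix rows of the first sequence. Gap cost of
a length-k gap is ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .io_formats import AMINO_ACIDS, SequenceRecord

LN2 = math.log(2.0)

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
NT_INDEX = {a: i for i, a in enumerate("ACGTN")}

#: BLAST-style gapped constants for BLOSUM62 with gap cost 11 + k.
BLOSUM62_GAPPED = (0.267, 0.041)
#: Gapped constants for nucleotide +2/-3 scoring with gap cost 5 + 2k.
NUC_GAPPED = (0.625, 0.41)


def encode_protein(seq: str) -> np.ndarray:
    """Encode amino acids as indices 0..19; X/* become 20 (neutral)."""
    return np.array([AA_INDEX.get(c, 20) for c in seq], dtype=np.int64)


def encode_nucleotide(seq: str) -> np.ndarray:
    return np.array([NT_INDEX.get(c, 4) for c in seq], dtype=np.int64)


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a 21x21 array over ACDEFGHIKLMNPQRSTVWY + X."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    alpha = AMINO_ACIDS + "X"
    m = np.zeros((21, 21))
    for i, a in enumerate(alpha):
        for j, b in enumerate(alpha):
            m[i, j] = blosum[a][b]
    return m


def nucleotide_matrix(match: float = 2.0, mismatch: float = -3.0) -> np.ndarray:
    """Match/mismatch matrix over ACGT + N (N never matches)."""
    m = np.full((5, 5), mismatch)
    np.fill_diagonal(m, match)
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return m


# ---------------------------------------------------------------------------
# Score statistics (Karlin-Altschul)
# ---------------------------------------------------------------------------

@dataclass
class ScoreStatistics:
    """Karlin-Altschul parameters for converting raw scores.

    ``lam`` is in nats per raw-score unit. ``search_space`` is the default
    m*n residue-pair count used when a call site does not supply one.
    """

    lam: float
    K: float
    search_space: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / LN2

    def e_value(self, raw: float, search_space: float | None = None) -> float:
        mn = self.search_space if search_space is None else search_space
        return self.K * mn * math.exp(-self.lam * raw)


def _score_distribution(matrix: np.ndarray, background: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Integer score values and probabilities under the background."""
    scores = np.rint(matrix).astype(int)
    lo, hi = int(scores.min()), int(scores.max())
    probs = np.zeros(hi - lo + 1)
    for i in range(len(background)):
        for j in range(len(background)):
            probs[scores[i, j] - lo] += background[i] * background[j]
    values = np.arange(lo, hi + 1)
    keep = probs > 0
    return values[keep], probs[keep]


def calibrate_statistics(matrix: np.ndarray, background: Sequence[float],
                         search_space: float = 1.0) -> ScoreStatistics:
    """Exact ungapped lambda and series-approximated K for a scoring system.

    lambda solves ``sum_ij p_i p_j exp(lambda * s_ij) = 1`` by bracketed
    root-finding. K uses the classical lattice-case series: with ``sigma``
    the sum over k of ``(1/k) * (E[exp(lambda S_k); S_k<0] + P(S_k>=0))``
    for k-step score sums S_k,

        K = delta * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda delta)))

    where delta is the score lattice span and H the relative entropy.
    Requires at least one positive and one negative score and a negative
    expected score; otherwise no finite lambda exists and ValueError is
    raised.
    """
    background = np.asarray(background, dtype=float)
    background = background / background.sum()
    values, probs = _score_distribution(np.asarray(matrix, float), background)
    if values.max() <= 0 or values.min() >= 0:
        raise ValueError("scoring matrix needs positive and negative entries")
    expected = float(values @ probs)
    if expected >= 0:
        raise ValueError(f"expected score must be negative, got {expected:g}")

    def f(lam: float) -> float:
        return float(probs @ np.exp(lam * values)) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-9, hi, xtol=1e-12))

    delta = int(np.gcd.reduce(np.abs(values[values != 0])))
    # target distribution entropy H (nats per residue pair)
    H = lam * float((values * probs) @ np.exp(lam * values))

    # sigma series over k-fold convolutions of the score distribution
    lo = int(values.min())
    dist = np.zeros(int(values.max()) - lo + 1)
    dist[values - lo] = probs
    conv = dist.copy()
    offset = lo  # score of conv[0]
    sigma = 0.0
    for k in range(1, 1001):
        if k > 1:
            conv = np.convolve(conv, dist)
            offset += lo
        s_vals = np.arange(offset, offset + len(conv))
        neg = s_vals < 0
        term = float(conv[neg] @ np.exp(lam * s_vals[neg])) + float(conv[~neg].sum())
        sigma += term / k
        if term / k < 1e-10:
            break
    K = delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))
    return ScoreStatistics(lam=lam, K=K, search_space=search_space)


# ---------------------------------------------------------------------------
# PSSM profiles
# ---------------------------------------------------------------------------

@dataclass
class PSSMProfile:
    """Position x residue log-odds profile in half-bit units.

    ``scores`` has shape (length, 20) over the alphabet ACDEFGHIKLMNPQRSTVWY
    (column order of :data:`AMINO_ACIDS`); X scores 0 at every position.
    """

    domain_id: str
    scores: np.ndarray
    background: np.ndarray
    gap_open: float = 20.0
    gap_extend: float = 2.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be positions x 20")
        if not np.isfinite(self.scores).all():
            raise ValueError("profile scores must be finite")
        self.background = np.asarray(self.background, dtype=float)
        if not math.isclose(self.background.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def max_score(self) -> float:
        """Sum of per-position maxima: the best attainable ungapped score."""
        return float(self.scores.max(axis=1).sum())


def build_pssm(aligned_seqs: Sequence[str], background: Sequence[float] | None = None,
               pseudocount_weight: float = 1.0, domain_id: str = "profile",
               score_floor: float = -32.0) -> PSSMProfile:
    """Build a half-bit log-odds PSSM from an aligned seed alignment.

    Per column, residue frequencies are mixed with ``pseudocount_weight``
    total pseudocounts distributed by the background; the score is
    ``2 * log2(freq / background)`` rounded to the nearest half-bit
    (i.e. nearest integer in half-bit units). Zero frequencies (possible
    only at zero pseudocount weight) are capped at ``score_floor``.
    All-gap columns are dropped; a zero-column alignment is an error.
    """
    if len(aligned_seqs) < 2:
        raise ValueError("need at least two aligned sequences")
    ncol = len(aligned_seqs[0])
    if any(len(s) != ncol for s in aligned_seqs):
        raise ValueError("aligned sequences must have equal length")
    if ncol == 0:
        raise ValueError("alignment has zero columns")
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    rows = []
    for col in range(ncol):
        counts = np.zeros(20)
        for seq in aligned_seqs:
            ch = seq[col].upper()
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1.0
        n = counts.sum()
        if n == 0:
            continue  # all-gap column
        freq = (counts + pseudocount_weight * background) / (n + pseudocount_weight)
        with np.errstate(divide="ignore"):
            s = 2.0 * np.log2(freq / background)
        s = np.where(np.isfinite(s), np.rint(s), score_floor)
        s = np.maximum(s, score_floor)
        rows.append(s)
    if not rows:
        raise ValueError("alignment has no non-gap columns")
    return PSSMProfile(domain_id=domain_id, scores=np.array(rows),
                       background=background)


def profile_statistics(profile: PSSMProfile, K: float = 0.05,
                       search_space: float = 1.0) -> ScoreStatistics:
    """Ungapped lambda for a profile's half-bit scores under its background.

    Solves ``mean_p sum_a bg_a exp(lambda s_pa) = 1`` (the position-averaged
    normalisation). For well-formed half-bit log-odds this sits near
    ln(2)/2. K is a configured constant: gapped profile theory has no
    analytic value.
    """
    s = profile.scores
    bg = profile.background

    def f(lam: float) -> float:
        return float(np.mean(np.exp(lam * s) @ bg)) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-9, hi, xtol=1e-12))
    return ScoreStatistics(lam=lam, K=K, search_space=search_space)


# ---------------------------------------------------------------------------
# Affine-gap local DP (Gotoh) - numba kernel shared by both search modes
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gotoh_kernel(pscores, seq, gap_open, gap_extend):  # pragma: no cover
    """Local affine-gap DP of a score profile (m x A) against seq (n).

    Returns (best score, end_i, end_j, pointer matrices). Pointer codes in
    ptr_h: 0 stop, 1 diagonal, 2 gap-in-profile (E, consumes seq), 3
    gap-in-seq (F, consumes profile row).
    """
    m = pscores.shape[0]
    n = seq.shape[0]
    NEG = -1e30
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    ptr_h = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptr_e = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1: opened from H
    ptr_f = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    gfirst = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gfirst
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gfirst
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + pscores[i - 1, seq[j - 1]]
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr_h[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr_h, ptr_e, ptr_f


def _traceback(ptr_h, ptr_e, ptr_f, bi, bj):
    """Recover aligned index pairs; -1 marks a gap position."""
    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    state = 0  # 0: in H, 2: in E, 3: in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptr_h[i, j]
            if p == 0:
                break
            if p == 1:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            pairs.append((-1, j - 1))
            opened = ptr_e[i, j]
            j -= 1
            if opened:
                state = 0
        else:
            pairs.append((i - 1, -1))
            opened = ptr_f[i, j]
            i -= 1
            if opened:
                state = 0
    pairs.reverse()
    return pairs


@dataclass
class AlignmentResult:
    """Best local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    identity_pct: float
    aligned_cols: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]


@dataclass
class DomainHit:
    """A profile (domain) match on a protein, 1-based inclusive span."""

    protein_id: str
    domain_id: str
    query_start: int
    query_end: int
    raw_score: float
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start > query_end")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


def smith_waterman(a: SequenceRecord, b: SequenceRecord,
                   matrix: np.ndarray | None = None,
                   gap_open: float = 11.0, gap_extend: float = 1.0,
                   stats: ScoreStatistics | None = None,
                   search_space: float | None = None,
                   identity_over_gaps: bool = True) -> AlignmentResult:
    """Optimal local alignment of two same-alphabet records (Gotoh DP).

    ``identity_pct`` counts identical residue pairs over alignment columns
    (gap columns included when ``identity_over_gaps``, the BLAST-style
    reporting convention). Empty input gives score 0 with identity NaN.
    """
    if a.alphabet != b.alphabet:
        raise ValueError("sequences must share an alphabet")
    if matrix is None:
        matrix = blosum62_matrix() if a.alphabet == "aa" else nucleotide_matrix()
    if stats is None:
        lam, K = BLOSUM62_GAPPED if a.alphabet == "aa" else NUC_GAPPED
        stats = ScoreStatistics(lam, K)
    mn = search_space if search_space is not None else max(1, len(a)) * max(1, len(b))
    if len(a) == 0 or len(b) == 0:
        return AlignmentResult(a.id, b.id, 0.0, stats.bit_score(0.0),
                               stats.e_value(0.0, mn), math.nan, 0,
                               (0, 0), (0, 0))
    enc = encode_protein if a.alphabet == "aa" else encode_nucleotide
    ea, eb = enc(a.sequence), enc(b.sequence)
    pscores = np.ascontiguousarray(np.asarray(matrix, float)[ea])
    score, bi, bj, ph, pe, pf = _gotoh_kernel(pscores, eb,
                                              float(gap_open), float(gap_extend))
    pairs = _traceback(ph, pe, pf, bi, bj)
    if not pairs:
        return AlignmentResult(a.id, b.id, 0.0, stats.bit_score(0.0),
                               stats.e_value(0.0, mn), 0.0, 0, (0, 0), (0, 0))
    ident = sum(1 for i, j in pairs
                if i >= 0 and j >= 0 and a.sequence[i] == b.sequence[j])
    cols = len(pairs) if identity_over_gaps else sum(
        1 for i, j in pairs if i >= 0 and j >= 0)
    qpos = [i for i, _ in pairs if i >= 0]
    spos = [j for _, j in pairs if j >= 0]
    return AlignmentResult(
        query_id=a.id, subject_id=b.id, raw_score=float(score),
        bit_score=stats.bit_score(score), e_value=stats.e_value(score, mn),
        identity_pct=100.0 * ident / cols if cols else 0.0,
        aligned_cols=len(pairs),
        query_span=(min(qpos) + 1, max(qpos) + 1),
        subject_span=(min(spos) + 1, max(spos) + 1))


def scan_profile(protein: SequenceRecord, profile: PSSMProfile,
                 stats: ScoreStatistics | None = None,
                 report_e: float = 10.0, db_length: float | None = None,
                 max_hits: int = 8) -> list[DomainHit]:
    """Scan a protein with a PSSM; greedy non-overlapping gapped hits.

    The best-scoring local profile alignment is taken first; further hits
    are searched in the unconsumed flanks of the protein, so reported hits
    never overlap on protein coordinates. E-values use search space
    m * n with m the protein length and n the profile length (or
    ``db_length`` when scanning against a profile database).
    """
    if protein.alphabet != "aa":
        raise ValueError("profile scanning needs an amino-acid record")
    if len(protein) < 5:
        return []
    if stats is None:
        stats = profile_statistics(profile)
    n = db_length if db_length is not None else profile.length
    mn = len(protein) * n
    pscores = np.ascontiguousarray(
        np.hstack([profile.scores, np.zeros((profile.length, 1))]))

    hits: list[DomainHit] = []
    segments = [(0, len(protein))]  # [lo, hi) protein windows to search
    while segments and len(hits) < max_hits:
        lo, hi = segments.pop()
        if hi - lo < 5:
            continue
        seq = encode_protein(protein.sequence[lo:hi])
        score, bi, bj, ph, pe, pf = _gotoh_kernel(
            pscores, seq, float(profile.gap_open), float(profile.gap_extend))
        if score <= 0:
            continue
        pairs = _traceback(ph, pe, pf, bi, bj)
        spos = [j for _, j in pairs if j >= 0]
        if not spos:
            continue
        q_start, q_end = lo + min(spos) + 1, lo + max(spos) + 1
        e = stats.e_value(score, mn)
        if e <= report_e:
            hits.append(DomainHit(
                protein_id=protein.id, domain_id=profile.domain_id,
                query_start=q_start, query_end=q_end, raw_score=float(score),
                bit_score=stats.bit_score(score), e_value=e))
            segments.append((lo, q_start - 1))
            segments.append((q_end, hi))
    hits.sort(key=lambda h: (-h.raw_score, h.query_start))
    return hits


def filter_homology_hits(hits: Sequence[AlignmentResult], e_max: float = 1e-4,
                         bit_min: float = 100.0) -> list[AlignmentResult]:
    """Keep hits with e_value <= e_max and bit_score strictly above bit_min."""
    return [h for h in hits if h.e_value <= e_max and h.bit_score > bit_min]
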