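"""Homology search against a curated reference AMP set.

Candidates are aligned to reference precursors with BLOSUM62 and affine
gaps (a gap of length g costs open + g*extend; defaults 11/1).  Local
(Smith-Waterman) alignments drive the match decision through a seeded
shuffle-null E-value; global (Needleman-Wunsch, end gaps penalized)
alignments define region-wise identity and positivity percentages, where a
positive column is one whose substitution score is strictly positive and
gap columns count in the denominator.

A candidate whose best match has E < 1e-4 is "known" when full-precursor
identity and positivity both exceed 90%, otherwise "novel"; with no match
below the E threshold it is "no_match".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import AMINO_ACIDS, get_logger
from .precursor_physchem import PrecursorPeptide
from .profile_hmm_screen import _tail_fit

log = get_logger("homology")

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
NEG = float("-inf")


def default_matrix() -> np.ndarray:
    """BLOSUM62 as a 20x20 array over the alphabetical amino-acid order."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = blosum[a][b]
    return mat


_DEFAULT_MATRIX = default_matrix()


@dataclass
class AlignmentResult:
    """A scored pairwise alignment with per-column bookkeeping."""

    query_id: str
    subject_id: str
    mode: str  # local | global
    score: float
    aligned_columns: int
    identities: int
    positives: int
    gaps: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    columns: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.identities <= self.positives <= self.aligned_columns:
            raise ValueError("identities <= positives <= aligned_columns must hold")


def _encode(seq: str) -> list[int]:
    try:
        return [_AA_INDEX[c] for c in seq]
    except KeyError as exc:
        raise ValueError(f"invalid amino-acid symbol {exc.args[0]!r}") from None


def _align(
    a: str,
    b: str,
    matrix: np.ndarray,
    gap_open: float,
    gap_extend: float,
    mode: str,
    query_id: str,
    subject_id: str,
) -> AlignmentResult:
    if not a or not b:
        raise ValueError("alignment requires non-empty sequences")
    ai, bi = _encode(a), _encode(b)
    n, m = len(a), len(b)
    go = gap_open + gap_extend  # first gapped column
    ge = gap_extend
    local = mode == "local"
    # state matrices: M emits (a_i, b_j); X emits (a_i, -); Y emits (-, b_j).
    # Pointer codes name the predecessor state ("." = local start, "0" = origin).
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[""] * (m + 1) for _ in range(n + 1)]
    pX = [[""] * (m + 1) for _ in range(n + 1)]
    pY = [[""] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    if not local:
        for i in range(1, n + 1):
            X[i][0] = -go - (i - 1) * ge
            pX[i][0] = "M" if i == 1 else "X"
        for j in range(1, m + 1):
            Y[0][j] = -go - (j - 1) * ge
            pY[0][j] = "M" if j == 1 else "Y"
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        arow = matrix[ai[i - 1]]
        for j in range(1, m + 1):
            s = arow[bi[j - 1]]
            # tie preference: diagonal (M), then up (X), then left (Y)
            dm, dx, dy = Mp[j - 1], Xp[j - 1], Yp[j - 1]
            best_prev = max(dm, dx, dy)
            if local and best_prev < 0.0:
                best_prev = 0.0
            if best_prev == dm and dm > NEG:
                pM[i][j] = "M"
            elif best_prev == dx and dx > NEG:
                pM[i][j] = "X"
            elif best_prev == dy and dy > NEG:
                pM[i][j] = "Y"
            else:
                pM[i][j] = "."
            Mi[j] = s + best_prev
            open_x, ext_x = Mp[j] - go, Xp[j] - ge
            if open_x >= ext_x:
                Xi[j], pX[i][j] = open_x, "M"
            else:
                Xi[j], pX[i][j] = ext_x, "X"
            open_y, ext_y = Mi[j - 1] - go, Yi[j - 1] - ge
            if open_y >= ext_y:
                Yi[j], pY[i][j] = open_y, "M"
            else:
                Yi[j], pY[i][j] = ext_y, "Y"
    # end cell
    if local:
        score, ei, ej = 0.0, 0, 0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if M[i][j] > score:
                    score, ei, ej = M[i][j], i, j
        state = "M"
        if score == 0.0:  # no positive-scoring local alignment exists
            return AlignmentResult(query_id, subject_id, mode, 0.0, 0, 0, 0, 0,
                                   (0, 0), (0, 0), [])
    else:
        ei, ej = n, m
        candidates = [("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m])]
        score = max(v for _, v in candidates)
        state = next(s for s, v in candidates if v == score)
    # traceback along the stored pointers
    cols: list[tuple[str, str]] = []
    i, j = ei, ej
    while True:
        if i == 0 and j == 0:
            break
        if state == "M":
            nxt = pM[i][j]
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
            if nxt == ".":
                break
            state = nxt
        elif state == "X":
            nxt = pX[i][j]
            cols.append((a[i - 1], "-"))
            i -= 1
            state = nxt
        else:
            nxt = pY[i][j]
            cols.append(("-", b[j - 1]))
            j -= 1
            state = nxt
        if local and state == "M" and (i == 0 or j == 0):  # pragma: no cover
            break
    cols.reverse()
    qs, ss = i, j
    identities = sum(1 for ca, cb in cols if ca == cb and ca != "-")
    positives = sum(
        1 for ca, cb in cols
        if ca != "-" and cb != "-" and matrix[_AA_INDEX[ca]][_AA_INDEX[cb]] > 0
    )
    gaps = sum(1 for ca, cb in cols if ca == "-" or cb == "-")
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id, mode=mode, score=float(score),
        aligned_columns=len(cols), identities=identities, positives=positives,
        gaps=gaps, query_span=(qs, ei), subject_span=(ss, ej), columns=cols,
    )


def local_align(a: str, b: str, matrix: np.ndarray | None = None,
                gap_open: float = 11, gap_extend: float = 1,
                query_id: str = "query", subject_id: str = "subject") -> AlignmentResult:
    """Optimal Smith-Waterman alignment with affine gaps; traceback ties
    prefer diagonal, then up, then left."""
    mat = _DEFAULT_MATRIX if matrix is None else matrix
    return _align(a, b, mat, gap_open, gap_extend, "local", query_id, subject_id)


def global_align(a: str, b: str, matrix: np.ndarray | None = None,
                 gap_open: float = 11, gap_extend: float = 1,
                 query_id: str = "query", subject_id: str = "subject") -> AlignmentResult:
    """Needleman-Wunsch with affine gaps, end gaps penalized; same
    tie-breaking as :func:`local_align`."""
    mat = _DEFAULT_MATRIX if matrix is None else matrix
    return _align(a, b, mat, gap_open, gap_extend, "global", query_id, subject_id)


def identity_positivity(aln: AlignmentResult, matrix: np.ndarray | None = None) -> tuple[float, float]:
    """Percent identity and positivity over all aligned columns (gap
    columns count in the denominator)."""
    if aln.aligned_columns == 0:
        return 0.0, 0.0
    mat = _DEFAULT_MATRIX if matrix is None else matrix
    positives = sum(
        1 for ca, cb in aln.columns
        if ca != "-" and cb != "-" and mat[_AA_INDEX[ca]][_AA_INDEX[cb]] > 0
    )
    return (100.0 * aln.identities / aln.aligned_columns,
            100.0 * positives / aln.aligned_columns)


# --------------------------------------------------------------------------
# empirical significance
# --------------------------------------------------------------------------

def _batch_local_scores(query: str, subjects: np.ndarray, matrix: np.ndarray,
                        gap_open: float, gap_extend: float) -> np.ndarray:
    """Smith-Waterman scores of *query* against many equal-length integer-
    encoded subjects at once (score only, vectorized across subjects)."""
    qi = _encode(query)
    S, m = subjects.shape
    go, ge = gap_open + gap_extend, gap_extend
    very_neg = -1e18
    Mp = np.full((S, m + 1), very_neg)
    Xp = np.full((S, m + 1), very_neg)
    Yp = np.full((S, m + 1), very_neg)
    Mp[:, 0] = 0.0
    best = np.zeros(S)
    zeros = np.zeros((S, m))
    for a in qi:
        s = matrix[a][subjects]  # (S, m)
        Mc = np.full((S, m + 1), very_neg)
        prev = np.maximum(np.maximum(Mp[:, :-1], Xp[:, :-1]), np.maximum(Yp[:, :-1], zeros))
        Mc[:, 1:] = s + prev
        Xc = np.full((S, m + 1), very_neg)
        Xc[:, 1:] = np.maximum(Mp[:, 1:] - go, Xp[:, 1:] - ge)
        # Y scan via max-plus prefix: Y[j] = max_k<j (M[k] - go - (j-1-k) ge)
        t = Mc[:, :-1] - go + np.arange(m) * ge
        Yc = np.full((S, m + 1), very_neg)
        Yc[:, 1:] = np.maximum.accumulate(t, axis=1) - np.arange(m) * ge
        best = np.maximum(best, Mc[:, 1:].max(axis=1))
        Mp, Xp, Yp = Mc, Xc, Yc
    return best


def match_evalue(aln: AlignmentResult, query: str, subject: str, n_targets: int,
                 shuffles: int = 200, seed: int | None = 0,
                 matrix: np.ndarray | None = None,
                 gap_open: float = 11, gap_extend: float = 1) -> float:
    """Empirical E-value of a local alignment score from a seeded shuffle
    null of the subject (exponential tail fitted to the top decile)."""
    if shuffles < 20:
        raise ValueError("at least 20 shuffles are required for a tail fit")
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    mat = _DEFAULT_MATRIX if matrix is None else matrix
    rng = np.random.default_rng(seed)
    enc = np.array(_encode(subject))
    shuffled = np.tile(enc, (shuffles, 1))
    for row in shuffled:
        rng.shuffle(row)
    null = _batch_local_scores(query, shuffled, mat, gap_open, gap_extend)
    t0, beta, sorted_scores = _tail_fit(null)
    if aln.score >= t0:
        p = 0.1 * math.exp(-(aln.score - t0) / beta)
    else:
        p = float(np.mean(sorted_scores >= aln.score))
    return min(n_targets * p, float(n_targets))


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

@dataclass
class AmpClassification:
    """known / novel / no_match verdict for one candidate."""

    candidate_id: str
    status: str
    best_match: str | None
    evalue: float | None
    identity_precursor: float | None
    identity_prepro: float | None
    identity_mature: float | None

    def __post_init__(self) -> None:
        if self.status not in ("known", "novel", "no_match"):
            raise ValueError(f"invalid status {self.status!r}")
        if (self.status == "no_match") != (self.best_match is None):
            raise ValueError("status no_match exactly when there is no best match")
        for pct in (self.identity_precursor, self.identity_prepro, self.identity_mature):
            if pct is not None and not 0 <= pct <= 100:
                raise ValueError("identity percentages must lie in [0, 100]")


def classify(
    candidate: PrecursorPeptide,
    reference: list[PrecursorPeptide],
    evalue_threshold: float = 1e-4,
    known_identity: float = 90.0,
    known_positivity: float = 90.0,
    *,
    n_targets: int | None = None,
    shuffles: int = 200,
    seed: int = 0,
    matrix: np.ndarray | None = None,
    gap_open: float = 11,
    gap_extend: float = 1,
) -> AmpClassification:
    """Classify a split candidate against KR-split reference precursors.

    The best match is the lowest-E local precursor alignment (ties broken
    by subject id).  With no E < threshold match the candidate is
    no_match; otherwise it is known when global full-precursor identity
    AND positivity both exceed the 90% thresholds, else novel.  Region
    identities are global-alignment identities of the corresponding
    precursor/prepro/mature pairs.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    mat = _DEFAULT_MATRIX if matrix is None else matrix
    refs = sorted(reference, key=lambda r: r.id)
    n = n_targets if n_targets is not None else len(refs)
    best: tuple[float, str, PrecursorPeptide] | None = None
    for ref in refs:
        aln = local_align(candidate.precursor, ref.precursor, mat, gap_open,
                          gap_extend, candidate.id, ref.id)
        e = match_evalue(aln, candidate.precursor, ref.precursor, n,
                         shuffles=shuffles, seed=seed, matrix=mat,
                         gap_open=gap_open, gap_extend=gap_extend)
        if best is None or (e, ref.id) < (best[0], best[1]):
            best = (e, ref.id, ref)
    e_best, _, ref_best = best
    if e_best >= evalue_threshold:
        return AmpClassification(candidate.id, "no_match", None, None, None, None, None)
    g_prec = global_align(candidate.precursor, ref_best.precursor, mat,
                          gap_open, gap_extend, candidate.id, ref_best.id)
    id_prec, pos_prec = identity_positivity(g_prec, mat)
    g_prepro = global_align(candidate.prepro, ref_best.prepro, mat,
                            gap_open, gap_extend, candidate.id, ref_best.id)
    g_mature = global_align(candidate.mature, ref_best.mature, mat,
                            gap_open, gap_extend, candidate.id, ref_best.id)
    status = "known" if (id_prec > known_identity and pos_prec > known_positivity) else "novel"
    return AmpClassification(
        candidate_id=candidate.id, status=status, best_match=ref_best.id,
        evalue=e_best, identity_precursor=id_prec,
        identity_prepro=identity_positivity(g_prepro, mat)[0],
        identity_mature=identity_positivity(g_mature, mat)[0],
    )
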