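"""Profile-HMM scoring of candidate peptides against AMP family models.

A profile HMM has M match states with 20-letter emission distributions,
per-node insert states, and silent delete states.  Scoring is uni-local
(local in both sequence and model): a path enters at any match state with
probability 1/M, traverses match/insert/delete states under the model's
transition probabilities, and exits after any match state with probability
1/M; flanking sequence is emitted by the background and cancels in the
log-odds.  ``viterbi_score`` maximises over paths, ``forward_score`` sums
over them; both are computed in log space and reported in bits.

Significance is an E-value over ``n_targets`` searched peptides, either
from exponential-tail forward-score statistics stored on the profile
(fitted once per model by :func:`calibrate_profile`) or from a seeded
shuffle null of the query peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AMINO_ACIDS, get_logger

log = get_logger("hmm")

LN2 = math.log(2.0)
#: Finite stand-in for log(0); keeps the DP free of inf-inf artifacts.
LOG_ZERO = -1e8

# transition-tuple indices, per node: m->m m->i m->d i->m i->i d->m d->d
MM, MI, MD, IM, II, DM, DD = range(7)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class ProfileHMM:
    """One AMP-family profile: emissions, transitions and score statistics.

    ``transitions`` has M+1 rows of 7 probabilities; row 0 is the begin
    node, row k the transitions leaving node k.  ``stats`` maps a score
    type (e.g. ``"FORWARD"``) to an exponential-tail (tau, lambda) pair in
    bits, such that P(S >= s) = exp(-lambda * (s - tau)).
    """

    name: str
    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M, 20)
    transitions: np.ndarray  # (M + 1, 7)
    background: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    insert0_emissions: np.ndarray | None = None
    stats: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.insert0_emissions is None:
            self.insert0_emissions = self.background.copy()
        m = self.length
        if m < 1:
            raise ValueError("a profile needs at least one match state")
        if self.insert_emissions.shape != (m, 20):
            raise ValueError("insert emission shape mismatch")
        if self.transitions.shape != (m + 1, 7):
            raise ValueError(f"expected {m + 1} transition rows of 7, got {self.transitions.shape}")
        for name, rows in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            sums = rows.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError(f"{name} emission rows must sum to 1 (+/- 1e-6)")
        for label, idx in (("m", (MM, MI, MD)), ("i", (IM, II)), ("d", (DM, DD))):
            sums = self.transitions[:, idx].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError(f"{label}-state transition groups must sum to 1 (+/- 1e-6)")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]


@dataclass(frozen=True)
class HmmHit:
    """A significant peptide/family match from the screen."""

    peptide_id: str
    family: str
    viterbi_bits: float
    forward_bits: float
    evalue: float


def _safe_log(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, LOG_ZERO, dtype=float)
    np.log(p, out=out, where=p > 0)
    return np.maximum(out, LOG_ZERO)


def _encode_peptide(pep: str) -> list[int]:
    """Map residues to emission columns; X (ambiguity) becomes -1 and is
    scored with log-odds 0 everywhere."""
    idx = []
    for c in pep:
        if c == "X":
            idx.append(-1)
        elif c in _AA_INDEX:
            idx.append(_AA_INDEX[c])
        else:
            raise ValueError(f"invalid amino-acid symbol {c!r}")
    return idx


def _log_odds(hmm: ProfileHMM) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    bg = _safe_log(hmm.background)
    lo_match = _safe_log(hmm.match_emissions) - bg
    lo_ins = _safe_log(hmm.insert_emissions) - bg
    lt = _safe_log(hmm.transitions)
    return lo_match, lo_ins, lt


def _logaddexp(x: float, y: float) -> float:
    if x < y:
        x, y = y, x
    if y <= LOG_ZERO:
        return x
    return x + math.log1p(math.exp(y - x))


def _score(hmm: ProfileHMM, pep: str, forward: bool) -> float:
    seq = _encode_peptide(pep)
    if not seq:
        return 0.0
    m = hmm.length
    lo_match, lo_ins, lt = _log_odds(hmm)
    entry = exit_ = -math.log(m)
    combine = _logaddexp if forward else max
    reduce_ = np.logaddexp if forward else np.maximum

    neg = np.full(m, 2 * LOG_ZERO)
    vm = neg.copy()
    vi = neg.copy()
    vd = neg.copy()
    # transitions leaving node j (1-based) feed state j+1; shift for vector ops
    t_mm = lt[1:m, MM]
    t_im = lt[1:m, IM]
    t_dm = lt[1:m, DM]
    t_mi = lt[1:, MI]
    t_ii = lt[1:, II]
    t_md = lt[1:m, MD]
    t_dd = lt[1:m, DD]
    best = 2 * LOG_ZERO
    for a in seq:
        em = np.zeros(m) if a < 0 else lo_match[:, a]
        ins = np.zeros(m) if a < 0 else lo_ins[:, a]
        prev = reduce_(vm[:-1] + t_mm, reduce_(vi[:-1] + t_im, vd[:-1] + t_dm))
        vm_new = em.copy()
        vm_new[0] += entry
        vm_new[1:] += reduce_(np.full(m - 1, entry), prev)
        vi = ins + reduce_(vm + t_mi, vi + t_ii)
        vd_new = neg.copy()
        for j in range(1, m):
            vd_new[j] = combine(vm_new[j - 1] + t_md[j - 1], vd_new[j - 1] + t_dd[j - 1])
        vm, vd = vm_new, vd_new
        row_best = float((vm + exit_).max()) if not forward else None
        if forward:
            best = _logaddexp(best, float(np.logaddexp.reduce(vm + exit_)))
        else:
            best = max(best, row_best)
    return best / LN2


def viterbi_score(hmm: ProfileHMM, pep: str) -> float:
    """Best uni-local path log-odds score of *pep* under *hmm*, in bits.

    The empty peptide scores 0 (the empty alignment).
    """
    return _score(hmm, pep, forward=False)


def forward_score(hmm: ProfileHMM, pep: str) -> float:
    """Log-sum of all uni-local path log-odds, in bits; always at least the
    Viterbi score."""
    return _score(hmm, pep, forward=True)


# --------------------------------------------------------------------------
# significance
# --------------------------------------------------------------------------

def _tail_fit(scores: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Fit an exponential tail to the top decile of null scores.

    Returns (t0, beta): P(S >= s) = 0.1 * exp(-(s - t0) / beta) for s >= t0.
    """
    scores = np.sort(np.asarray(scores, dtype=float))
    t0 = float(np.quantile(scores, 0.9))
    excess = scores[scores >= t0] - t0
    beta = max(float(excess.mean()), 1e-9)
    return t0, beta, scores


def _shuffle_null(
    hmm: ProfileHMM, pep: str, shuffles: int, seed: int | None
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    letters = np.array(list(pep))
    out = np.empty(shuffles)
    for i in range(shuffles):
        rng.shuffle(letters)
        out[i] = forward_score(hmm, "".join(letters))
    return out


def hit_evalue(
    score_bits: float,
    hmm: ProfileHMM,
    n_targets: int,
    *,
    pep: str | None = None,
    shuffles: int = 200,
    seed: int | None = 0,
) -> float:
    """E-value of a forward score over a search of *n_targets* peptides.

    Uses the profile's stored forward-score tail statistics when present:
    E = n_targets * exp(-lambda * (score - tau)), capped at n_targets.
    Otherwise estimates the tail from *shuffles* seeded shuffles of *pep*.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if "FORWARD" in hmm.stats:
        tau, lam = hmm.stats["FORWARD"]
        return min(n_targets * math.exp(-lam * (score_bits - tau)), float(n_targets))
    if pep is None:
        raise ValueError(
            f"profile {hmm.name!r} carries no score statistics and no peptide "
            "was supplied for a shuffle null"
        )
    null = _shuffle_null(hmm, pep, shuffles, seed)
    t0, beta, sorted_scores = _tail_fit(null)
    if score_bits >= t0:
        p = 0.1 * math.exp(-(score_bits - t0) / beta)
    else:
        p = float(np.mean(sorted_scores >= score_bits))
    return min(n_targets * p, float(n_targets))


def calibrate_profile(
    hmm: ProfileHMM,
    seed: int = 0,
    n: int = 200,
    length: int = 50,
) -> ProfileHMM:
    """Fit forward-score tail statistics from random background peptides
    and store them on the profile (in place).

    After calibration P(S >= tau) = 1, so a score equal to tau has E-value
    n_targets.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    scores = np.empty(n)
    for i in range(n):
        pep = "".join(rng.choice(letters, size=length, p=hmm.background))
        scores[i] = forward_score(hmm, pep)
    t0, beta, _ = _tail_fit(scores)
    lam = 1.0 / beta
    tau = t0 + math.log(0.1) / lam
    hmm.stats["FORWARD"] = (tau, lam)
    return hmm


def screen(
    peptides,
    hmms: list[ProfileHMM],
    threshold: float = 0.001,
    *,
    seed: int = 0,
    n_targets: int | None = None,
) -> list[HmmHit]:
    """Score every (peptide, family) pair and keep those with E < threshold.

    *peptides* may be :class:`~ampseine.orf_discovery.OrfCandidate` objects
    or ``(id, sequence)`` pairs.  Profiles without stored score statistics
    are calibrated once (seeded) before scoring.  Hits are sorted by
    ascending E-value; duplicated profiles yield duplicate hits and a
    logged warning.
    """
    entries = []
    for p in peptides:
        if hasattr(p, "protein"):
            entries.append((p.orf_id, p.protein))
        else:
            pid, seq = p
            entries.append((pid, seq))
    names = [h.name for h in hmms]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        log.warning("duplicate profile names %s: duplicate hits will be reported", sorted(dupes))
    n = n_targets if n_targets is not None else max(len(entries), 1)
    hits: list[HmmHit] = []
    for hmm in hmms:
        if "FORWARD" not in hmm.stats:
            log.info("profile %s has no score statistics; calibrating", hmm.name)
            calibrate_profile(hmm, seed=seed)
        for pid, seq in entries:
            fwd = forward_score(hmm, seq)
            e = hit_evalue(fwd, hmm, n)
            if e < threshold:
                hits.append(HmmHit(
                    peptide_id=pid, family=hmm.name,
                    viterbi_bits=viterbi_score(hmm, seq),
                    forward_bits=fwd, evalue=e,
                ))
    hits.sort(key=lambda h: (h.evalue, h.peptide_id, h.family))
    return hits
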