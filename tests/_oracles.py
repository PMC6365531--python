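"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle recomputes a quantity by exhaustive enumeration or direct
re-summation, independently of the implementation paths it checks.
"""

from __future__ import annotations

import math

from ampseine.io_formats import AMINO_ACIDS
from ampseine.orf_discovery import START_CODONS, STOP_CODONS, translate_frame
from ampseine.orf_discovery import reverse_complement

LN2 = math.log(2.0)
_NEG = -1e12


def enumerate_path_scores(hmm, pep: str) -> list[float]:
    """Log-odds (nats) of every uni-local path: enter any match state with
    probability 1/M, exit after any match with probability 1/M."""
    m = hmm.length
    idx = [AMINO_ACIDS.index(c) for c in pep]
    L = len(pep)
    MM, MI, MD, IM, II, DM, DD = range(7)

    def lo_m(j, a):
        p = hmm.match_emissions[j - 1][a]
        return _NEG if p == 0 else math.log(p / hmm.background[a])

    def lo_i(j, a):
        p = hmm.insert_emissions[j - 1][a]
        return _NEG if p == 0 else math.log(p / hmm.background[a])

    def lt(j, t):
        p = hmm.transitions[j][t]
        return _NEG if p == 0 else math.log(p)

    ent = -math.log(m)
    scores: list[float] = []

    def rec(state, j, i, acc):
        if state == "M":
            scores.append(acc + ent)  # exit option
            if i < L and j + 1 <= m:
                rec("M", j + 1, i + 1, acc + lt(j, MM) + lo_m(j + 1, idx[i]))
            if i < L:
                rec("I", j, i + 1, acc + lt(j, MI) + lo_i(j, idx[i]))
            if j + 1 <= m:
                rec("D", j + 1, i, acc + lt(j, MD))
        elif state == "I":
            if i < L and j + 1 <= m:
                rec("M", j + 1, i + 1, acc + lt(j, IM) + lo_m(j + 1, idx[i]))
            if i < L:
                rec("I", j, i + 1, acc + lt(j, II))
        else:
            if i < L and j + 1 <= m:
                rec("M", j + 1, i + 1, acc + lt(j, DM) + lo_m(j + 1, idx[i]))
            if j + 1 <= m:
                rec("D", j + 1, i, acc + lt(j, DD))

    for start in range(L):
        for j in range(1, m + 1):
            rec("M", j, start + 1, ent + lo_m(j, idx[start]))
    return scores


def viterbi_oracle_bits(hmm, pep: str) -> float:
    paths = enumerate_path_scores(hmm, pep)
    return max(paths) / LN2 if paths else 0.0


def forward_oracle_bits(hmm, pep: str) -> float:
    paths = enumerate_path_scores(hmm, pep)
    if not paths:
        return 0.0
    top = max(paths)
    return (top + math.log(sum(math.exp(s - top) for s in paths))) / LN2


def orf_oracle(sequence: str, strand_mode: str) -> set[tuple[str, int, int, str]]:
    """Complete ORFs by scanning every (start codon, first in-frame stop)
    pair directly."""
    out: set[tuple[str, int, int, str]] = set()
    strands = [("+", sequence)]
    if strand_mode == "both":
        strands.append(("-", reverse_complement(sequence)))
    for strand, seq in strands:
        for s in range(len(seq) - 2):
            if seq[s:s + 3] not in START_CODONS:
                continue
            for e in range(s + 3, len(seq) - 2, 3):
                if seq[e:e + 3] in STOP_CODONS:
                    protein = translate_frame(seq[s:e], 0)
                    if protein:
                        out.add((strand, s, e + 3, protein))
                    break
    return out


def codon_oracle(seq: str, frame: int) -> str:
    """Translation via an independently written codon lookup."""
    table = {}
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    n = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                table[b1 + b2 + b3] = aas[n]
                n += 1
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append(table.get(codon, "X"))
    return "".join(out)


def best_chain_oracle(runs) -> int:
    """Best colinear chain score by exhaustive subset search (<= 8 runs)."""
    from itertools import combinations

    from ampseine.gene_models import chain_score, _chainable

    best = 0
    n = len(runs)
    for r in range(1, n + 1):
        for combo in combinations(range(n), r):
            chain = [runs[i] for i in combo]
            if all(_chainable(chain[i], chain[i + 1]) for i in range(len(chain) - 1)):
                best = max(best, chain_score(chain))
    return best
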