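"""Transcript-to-genome mapping and exon/intron gene-model reconstruction.

A minimal spliced mapper for near-identical transcript/genome pairs: exact
k-mer seeding (k = 31, both genome strands), merging of seeds into
diagonal runs, dynamic-programming colinear chaining, and conversion of
chained runs into exon blocks, opening an intron wherever the genome-side
gap is at least 40 bp (smaller gaps are absorbed into exons).  Exon
junctions are then shifted by up to 5 bp - keeping the transcript
sequence intact - to place introns at canonical GT..AG dinucleotides when
such a placement exists; introns without one are flagged non-canonical.

All coordinates are 0-based half-open.  For minus-strand models the
transcript coordinates refer to the reverse-complemented transcript, so
exons are ascending on both axes; donor/acceptor dinucleotides are always
reported on the gene's strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .io_formats import TranscriptRecord, get_logger
from .orf_discovery import reverse_complement

log = get_logger("genemodel")

DEFAULT_K = 31
MIN_INTRON = 40
SPLICE_WINDOW = 5


@dataclass
class ExonBlock:
    """One exon: matched genome/transcript spans on a single diagonal set."""

    scaffold_id: str
    genome_span: tuple[int, int]
    transcript_span: tuple[int, int]
    strand: str
    matches: int

    def __post_init__(self) -> None:
        g = self.genome_span[1] - self.genome_span[0]
        t = self.transcript_span[1] - self.transcript_span[0]
        if g != t:
            raise ValueError(f"exon genome span ({g}) and transcript span ({t}) differ")
        if self.matches > g:
            raise ValueError("matches cannot exceed the span length")


@dataclass
class Intron:
    span: tuple[int, int]  # genome interval, forward coordinates
    donor: str  # on the gene's strand
    acceptor: str
    canonical: bool

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]


@dataclass
class GeneModel:
    transcript_id: str
    scaffold_id: str
    strand: str
    exons: list[ExonBlock]
    introns: list[Intron] = field(default_factory=list)
    coverage: float = 0.0

    def __post_init__(self) -> None:
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.genome_span[0] < prev.genome_span[1]:
                raise ValueError("exons must be ordered and non-overlapping on the genome")
            if cur.transcript_span[0] < prev.transcript_span[1]:
                raise ValueError("exons must be ordered and non-overlapping on the transcript")
        if len(self.introns) != max(len(self.exons) - 1, 0):
            raise ValueError("one intron is required between each pair of consecutive exons")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def gene_span_bp(self) -> int:
        if not self.exons:
            return 0
        return self.exons[-1].genome_span[1] - self.exons[0].genome_span[0]


# --------------------------------------------------------------------------
# seeding and chaining
# --------------------------------------------------------------------------

def seed_matches(transcript: str, scaffold: str, k: int = DEFAULT_K) -> list[tuple[int, int, str]]:
    """All exact k-mer matches (transcript_pos, genome_pos, strand) against
    both strands of the scaffold.

    Minus-strand transcript positions refer to the reverse-complemented
    transcript.
    """
    if k < 11:
        raise ValueError("seed length below 11 is not supported")
    out: list[tuple[int, int, str]] = []
    for strand, tseq in (("+", transcript), ("-", reverse_complement(transcript))):
        index: dict[str, list[int]] = {}
        for t in range(len(tseq) - k + 1):
            index.setdefault(tseq[t:t + k], []).append(t)
        for g in range(len(scaffold) - k + 1):
            for t in index.get(scaffold[g:g + k], ()):
                out.append((t, g, strand))
    out.sort(key=lambda m: (m[2], m[0], m[1]))
    return out


@dataclass(frozen=True)
class _Run:
    """A maximal diagonal run of consecutive k-mer matches, in bases."""

    t_start: int
    g_start: int
    length: int

    @property
    def t_end(self) -> int:
        return self.t_start + self.length

    @property
    def g_end(self) -> int:
        return self.g_start + self.length


def diagonal_runs(matches: list[tuple[int, int]], k: int) -> list[_Run]:
    """Merge (t, g) seed positions on common diagonals into maximal runs."""
    by_diag: dict[int, list[int]] = {}
    for t, g in matches:
        by_diag.setdefault(g - t, []).append(t)
    runs: list[_Run] = []
    for diag, ts in by_diag.items():
        ts.sort()
        start = prev = ts[0]
        for t in ts[1:]:
            if t == prev + 1:
                prev = t
            else:
                runs.append(_Run(start, start + diag, prev - start + k))
                start = prev = t
        runs.append(_Run(start, start + diag, prev - start + k))
    runs.sort(key=lambda r: (r.t_start, r.g_start))
    return runs


def chain_score(chain: list[_Run]) -> int:
    """Matched bases covered by a colinear chain (overlaps counted once)."""
    total = 0
    for i, run in enumerate(chain):
        if i == 0:
            total += run.length
        else:
            prev = chain[i - 1]
            overlap = max(0, prev.t_end - run.t_start, prev.g_end - run.g_start)
            total += run.length - overlap
    return total


def _chainable(prev: _Run, cur: _Run) -> bool:
    if cur.t_start <= prev.t_start or cur.g_start <= prev.g_start:
        return False
    overlap = max(0, prev.t_end - cur.t_start, prev.g_end - cur.g_start)
    return overlap < cur.length


def best_chain(runs: list[_Run]) -> list[_Run]:
    """Highest-scoring colinear chain by quadratic dynamic programming
    (ties resolved toward the earlier predecessor, hence deterministic)."""
    if not runs:
        return []
    n = len(runs)
    score = [r.length for r in runs]
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            if _chainable(runs[j], runs[i]):
                overlap = max(0, runs[j].t_end - runs[i].t_start,
                              runs[j].g_end - runs[i].g_start)
                cand = score[j] + runs[i].length - overlap
                if cand > score[i]:
                    score[i] = cand
                    back[i] = j
    end = max(range(n), key=lambda i: (score[i], -runs[i].t_start))
    chain: list[_Run] = []
    while end != -1:
        chain.append(runs[end])
        end = back[end]
    chain.reverse()
    return chain


def chain_blocks(
    matches: list[tuple[int, int]],
    k: int = DEFAULT_K,
    min_intron: int = MIN_INTRON,
    scaffold_id: str = "scaffold",
    strand: str = "+",
) -> list[ExonBlock]:
    """Chain single-strand seed matches into exon blocks.

    Genome-side gaps of at least *min_intron* bp open introns; smaller
    gaps are absorbed into the surrounding exon.
    """
    runs = best_chain(diagonal_runs(matches, k))
    if not runs:
        return []
    # trim overlaps (a junction ambiguity extends both neighbouring runs)
    trimmed: list[_Run] = [runs[0]]
    for run in runs[1:]:
        prev = trimmed[-1]
        overlap = max(0, prev.t_end - run.t_start, prev.g_end - run.g_start)
        if overlap:
            run = _Run(run.t_start + overlap, run.g_start + overlap,
                       run.length - overlap)
        trimmed.append(run)
    blocks: list[ExonBlock] = []
    cur_t = [trimmed[0].t_start, trimmed[0].t_end]
    cur_g = [trimmed[0].g_start, trimmed[0].g_end]
    cur_matches = trimmed[0].length
    for run in trimmed[1:]:
        genome_gap = run.g_start - cur_g[1]
        if genome_gap >= min_intron:
            blocks.append(ExonBlock(scaffold_id, (cur_g[0], cur_g[1]),
                                    (cur_t[0], cur_t[1]), strand, cur_matches))
            cur_t = [run.t_start, run.t_end]
            cur_g = [run.g_start, run.g_end]
            cur_matches = run.length
        else:
            # absorb: spans must stay equal-length, so grow both sides to the
            # larger extent (an exon-internal indel keeps the block single)
            grow = max(run.t_end - cur_t[1], run.g_end - cur_g[1])
            cur_t[1] += grow
            cur_g[1] += grow
            cur_matches += run.length
    blocks.append(ExonBlock(scaffold_id, (cur_g[0], cur_g[1]),
                            (cur_t[0], cur_t[1]), strand, cur_matches))
    for b in blocks:
        b.matches = min(b.matches, b.genome_span[1] - b.genome_span[0])
    return blocks


# --------------------------------------------------------------------------
# model assembly and refinement
# --------------------------------------------------------------------------

def _intron_dinucleotides(scaffold: str, span: tuple[int, int], strand: str) -> tuple[str, str]:
    s, e = span
    if strand == "+":
        return scaffold[s:s + 2], scaffold[e - 2:e]
    return reverse_complement(scaffold[e - 2:e]), reverse_complement(scaffold[s:s + 2])


def _build_model(transcript_id: str, scaffold_id: str, scaffold: str,
                 blocks: list[ExonBlock], strand: str, transcript_len: int) -> GeneModel:
    introns = []
    for prev, cur in zip(blocks, blocks[1:]):
        span = (prev.genome_span[1], cur.genome_span[0])
        donor, acceptor = _intron_dinucleotides(scaffold, span, strand)
        introns.append(Intron(span, donor, acceptor,
                              canonical=(donor == "GT" and acceptor == "AG")))
    covered = sum(b.transcript_span[1] - b.transcript_span[0] for b in blocks)
    return GeneModel(
        transcript_id=transcript_id, scaffold_id=scaffold_id, strand=strand,
        exons=blocks, introns=introns,
        coverage=covered / transcript_len if transcript_len else 0.0,
    )


def refine_splice_sites(model: GeneModel, scaffold: str,
                        window: int = SPLICE_WINDOW) -> GeneModel:
    """Shift exon junctions by up to *window* bp to canonical GT..AG introns.

    A shift is admissible only when the transcript sequence is preserved,
    i.e. the bases entering one exon equal the bases leaving the other.
    Candidate shifts are tried closest-first, ties leftmost on the +
    strand.  Idempotent on already-canonical models; introns with no
    admissible GT..AG placement keep their coordinates and are flagged
    non-canonical.
    """
    exons = [replace(e) for e in model.exons]
    introns: list[Intron] = []
    for idx, intron in enumerate(model.introns):
        left, right = exons[idx], exons[idx + 1]
        start, end = left.genome_span[1], right.genome_span[0]
        dinucs = _intron_dinucleotides(scaffold, (start, end), model.strand)
        if dinucs == ("GT", "AG"):
            introns.append(Intron((start, end), "GT", "AG", True))
            continue
        contiguous = left.transcript_span[1] == right.transcript_span[0]
        applied = False
        if contiguous:
            for shift in sorted(range(-window, window + 1), key=lambda s: (abs(s), s)):
                if shift == 0:
                    continue
                ns, ne = start + shift, end + shift
                if ns <= left.genome_span[0] or ne >= right.genome_span[1]:
                    continue
                if ns < 0 or ne + 2 > len(scaffold):
                    continue
                if shift > 0:
                    same = scaffold[start:start + shift] == scaffold[end:end + shift]
                else:
                    same = scaffold[ns:start] == scaffold[ne:end]
                if not same:
                    continue
                if _intron_dinucleotides(scaffold, (ns, ne), model.strand) != ("GT", "AG"):
                    continue
                left.genome_span = (left.genome_span[0], left.genome_span[1] + shift)
                left.transcript_span = (left.transcript_span[0],
                                        left.transcript_span[1] + shift)
                right.genome_span = (right.genome_span[0] + shift, right.genome_span[1])
                right.transcript_span = (right.transcript_span[0] + shift,
                                         right.transcript_span[1])
                for e in (left, right):
                    e.matches = min(e.matches, e.genome_span[1] - e.genome_span[0])
                introns.append(Intron((ns, ne), "GT", "AG", True))
                applied = True
                break
        if not applied:
            donor, acceptor = dinucs
            log.debug("%s intron %d (%s..%s) has no canonical placement",
                      model.transcript_id, idx, donor, acceptor)
            introns.append(Intron((start, end), donor, acceptor, False))
    return GeneModel(
        transcript_id=model.transcript_id, scaffold_id=model.scaffold_id,
        strand=model.strand, exons=exons, introns=introns, coverage=model.coverage,
    )


def map_transcript(
    transcript: TranscriptRecord,
    scaffold: TranscriptRecord,
    k: int = DEFAULT_K,
    min_intron: int = MIN_INTRON,
    refine: bool = True,
) -> GeneModel | None:
    """Map one transcript onto one scaffold and return the better-strand
    gene model (None when no seed matches at all)."""
    matches = seed_matches(transcript.sequence, scaffold.sequence, k)
    best_model: GeneModel | None = None
    best_score = -1
    for strand in "+-":
        sub = [(t, g) for t, g, s in matches if s == strand]
        if not sub:
            continue
        blocks = chain_blocks(sub, k, min_intron, scaffold.id, strand)
        score = sum(b.matches for b in blocks)
        if score > best_score:  # '+' wins ties by evaluation order
            model = _build_model(transcript.id, scaffold.id, scaffold.sequence,
                                 blocks, strand, len(transcript.sequence))
            best_model, best_score = model, score
    if best_model is not None and refine:
        best_model = refine_splice_sites(best_model, scaffold.sequence)
    return best_model


def model_stats(model: GeneModel) -> tuple[int, int, list[int]]:
    """(exon count, gene span in bp, intron sizes)."""
    return model.exon_count, model.gene_span_bp, [i.length for i in model.introns]
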