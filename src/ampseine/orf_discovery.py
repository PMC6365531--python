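"""Complete-ORF discovery in transcripts.

Scans each reading frame (sense strand by default; the source RNA-seq
libraries are strand-specific) for complete open reading frames: a run
starting at an ATG or GTG codon and terminated by an in-frame stop codon
inside the transcript.  Nested ORFs sharing a stop are all emitted, one per
eligible start codon.  Candidates are then filtered on length (20-100
residues by default, stop excluded) and start residue (Met or Val).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import TranscriptRecord, get_logger

log = get_logger("orf")

START_CODONS = ("ATG", "GTG")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
#: Standard genetic code; codons containing N (or any non-ACGT symbol)
#: translate to X, stops to "*".
CODON_TABLE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfCandidate:
    """A complete translated ORF located on a transcript.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the given
    strand (i.e. on the reverse-complemented sequence for ``-``) and span
    start codon through stop codon, so ``nt_end - nt_start`` equals
    ``3 * (len(protein) + 1)``.
    """

    transcript_id: str
    frame: int
    strand: str
    nt_start: int
    nt_end: int
    protein: str
    complete: bool = True

    @property
    def start_residue(self) -> str:
        return self.protein[0]

    @property
    def orf_id(self) -> str:
        """Stable unique id: transcript, strand and on-strand span."""
        return f"{self.transcript_id}:{self.strand}:{self.nt_start}-{self.nt_end}"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.nt_end - self.nt_start != 3 * (len(self.protein) + 1):
            raise ValueError(
                f"ORF span {self.nt_start}-{self.nt_end} inconsistent with "
                f"protein length {len(self.protein)}"
            )
        if "*" in self.protein:
            raise ValueError("protein must not contain a stop symbol")


def translate_frame(seq: str, frame: int) -> str:
    """Translate *seq* from *frame* under the standard code.

    The trailing partial codon is dropped; stops render as ``*`` and codons
    containing ambiguity (N) as ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(out)


def find_complete_orfs(rec: TranscriptRecord, strand_mode: str = "sense") -> list[OrfCandidate]:
    """Emit every complete ORF of *rec*, deterministically ordered by
    strand then start coordinate.

    ``strand_mode="both"`` additionally scans the reverse complement.
    """
    if strand_mode not in ("sense", "both"):
        raise ValueError(f"strand_mode must be 'sense' or 'both', got {strand_mode!r}")
    strands = [("+", rec.sequence)]
    if strand_mode == "both":
        strands.append(("-", reverse_complement(rec.sequence)))
    out: list[OrfCandidate] = []
    for strand, seq in strands:
        found: list[OrfCandidate] = []
        for frame in range(3):
            starts: list[int] = []
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i:i + 3]
                if codon in STOP_CODONS:
                    for s in starts:
                        protein = translate_frame(seq[s:i], 0)
                        if not protein:  # start codon immediately before stop
                            continue
                        found.append(OrfCandidate(
                            transcript_id=rec.id, frame=frame, strand=strand,
                            nt_start=s, nt_end=i + 3, protein=protein,
                        ))
                    starts.clear()
                elif codon in START_CODONS:
                    starts.append(i)
        found.sort(key=lambda o: (o.nt_start, o.nt_end))
        out.extend(found)
    return out


def filter_candidates(
    orfs: list[OrfCandidate],
    min_len: int = 20,
    max_len: int = 100,
    allowed_starts: frozenset[str] | set[str] = frozenset("MV"),
) -> list[OrfCandidate]:
    """Retain complete ORFs within the length bounds (inclusive, residues
    excluding the stop) whose first residue is an allowed start."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} exceeds max_len {max_len}")
    kept = [
        o for o in orfs
        if o.complete
        and min_len <= len(o.protein) <= max_len
        and o.start_residue in allowed_starts
    ]
    log.debug("filter_candidates kept %d of %d ORFs", len(kept), len(orfs))
    return kept
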