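"""Deterministic generators of synthetic inputs for every pipeline stage.

Each generator is a pure function of its spec and seed and returns the
ground truth alongside the data: planted precursor transcripts among
decoys, toy AMP-family profiles, single-gene genomes with GT..AG introns,
and overdispersed (negative-binomial) count tables with a control/treated
design.  Defaults mirror the biology the pipeline targets: precursor ORFs
of 20-100 residues starting with Met or Val, mature peptides of 19-33
residues with net positive charge, genes of 1-4 exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CountTable, TranscriptRecord
from .orf_discovery import (CODON_TABLE, find_complete_orfs, filter_candidates,
                            reverse_complement)
from .precursor_physchem import find_kr_sites, net_charge, split_precursor
from .profile_hmm_screen import ProfileHMM
from .gene_models import ExonBlock, GeneModel, Intron

#: Residues that carry no formal charge (His excluded from the charged set
#: by the net-charge convention, but kept out of mature fillers anyway to
#: keep planted charges unambiguous).
NEUTRAL_RESIDUES = "AGILNPQSTVFWYM"
BASIC_RESIDUES = "KR"
ACIDIC_RESIDUES = "DE"

_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)

_BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def _back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codons; the start residue is pinned to ATG/GTG so
    ORF discovery can recover the planted start."""
    codons = []
    for i, aa in enumerate(protein):
        if i == 0:
            codons.append("ATG" if aa == "M" else "GTG")
        else:
            options = _CODONS_FOR[aa]
            codons.append(options[rng.integers(len(options))])
    return "".join(codons)


# --------------------------------------------------------------------------
# precursor transcripts and decoys
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecursorSpec:
    """Recipe for one planted AMP precursor transcript."""

    prepro_length: int = 30
    mature_length: int = 25
    mature_basic_count: int = 5
    mature_acidic_count: int = 1
    start_residue: str = "M"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.start_residue not in ("M", "V"):
            raise ValueError("start residue must be M or V")
        if self.prepro_length < 3:
            raise ValueError("prepro needs at least start + KR")
        if self.prepro_length + self.mature_length > 100:
            raise ValueError("precursor must stay within 100 residues")
        if self.mature_basic_count <= self.mature_acidic_count:
            raise ValueError("planted mature peptides must be net cationic")
        if self.mature_basic_count + self.mature_acidic_count > self.mature_length:
            raise ValueError("charged residues exceed the mature length")


@dataclass(frozen=True)
class PlantedPrecursor:
    """Ground truth for one planted precursor."""

    transcript_id: str
    protein: str
    prepro: str
    mature: str
    cds_span: tuple[int, int]  # incl. stop codon, transcript coordinates
    net_charge: int


def _random_mature(spec: PrecursorSpec, rng: np.random.Generator) -> str:
    """Mature region with the exact planted charge composition and no
    internal K-R dipeptide (which would move the last-KR cut)."""
    neutral = list(NEUTRAL_RESIDUES)
    for _ in range(1000):
        residues = [neutral[rng.integers(len(neutral))] for _ in range(spec.mature_length)]
        pos = rng.permutation(spec.mature_length)
        for p in pos[:spec.mature_basic_count]:
            residues[p] = BASIC_RESIDUES[rng.integers(2)]
        for p in pos[spec.mature_basic_count:
                     spec.mature_basic_count + spec.mature_acidic_count]:
            residues[p] = ACIDIC_RESIDUES[rng.integers(2)]
        mature = "".join(residues)
        if "KR" not in mature:
            return mature
    raise RuntimeError("could not draw a KR-free mature region")  # pragma: no cover


def make_precursor_transcript(
    spec: PrecursorSpec, transcript_id: str = "planted",
) -> tuple[TranscriptRecord, PlantedPrecursor]:
    """A transcript whose single strong ORF encodes prepro + KR + mature,
    embedded in random UTRs, plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    neutral = list(NEUTRAL_RESIDUES)
    mid = "".join(neutral[rng.integers(len(neutral))]
                  for _ in range(spec.prepro_length - 3))
    mature = _random_mature(spec, rng)
    prepro = spec.start_residue + mid + "KR"
    protein = prepro + mature
    cds = _back_translate(protein, rng)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    # an in-frame stop just upstream of the CDS guarantees the planted ORF is
    # also the maximal one (no upstream in-frame start can extend it)
    utr5 = _random_bases(rng, int(rng.integers(20, 101)) - 3) + \
        ("TAA", "TAG", "TGA")[rng.integers(3)]
    utr3 = _random_bases(rng, int(rng.integers(20, 101)))
    sequence = utr5 + cds + stop + utr3
    rec = TranscriptRecord(id=transcript_id, description="synthetic planted precursor",
                           sequence=sequence)
    truth = PlantedPrecursor(
        transcript_id=transcript_id, protein=protein, prepro=prepro, mature=mature,
        cds_span=(len(utr5), len(utr5) + len(cds) + 3),
        net_charge=spec.mature_basic_count - spec.mature_acidic_count,
    )
    return rec, truth


def _amp_like(rec: TranscriptRecord) -> bool:
    """Does the transcript carry a complete 20-100 aa M/V-start ORF with a
    K-R site and a cationic mature part (the candidate definition)?"""
    for orf in filter_candidates(find_complete_orfs(rec, "sense")):
        if find_kr_sites(orf.protein):
            split = split_precursor(orf.protein, "last_kr", id=rec.id)
            if net_charge(split.mature) > 0:
                return True
    return False


def make_decoys(
    n: int,
    length_range: tuple[int, int] = (300, 900),
    seed: int = 0,
    id_prefix: str = "decoy",
) -> list[TranscriptRecord]:
    """i.i.d. uniform-base transcripts, rejection-sampled so that none
    contains an AMP-like candidate ORF."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[TranscriptRecord] = []
    while len(out) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        rec = TranscriptRecord(id=f"{id_prefix}{len(out) + 1:04d}",
                               description="synthetic decoy",
                               sequence=_random_bases(rng, length))
        if not _amp_like(rec):
            out.append(rec)
    return out


# --------------------------------------------------------------------------
# toy profiles
# --------------------------------------------------------------------------

def make_hmm(consensus: str, conservation: float = 0.9, name: str = "toyfam") -> ProfileHMM:
    """A profile that emits *consensus* with per-state probability
    *conservation* (remainder uniform over the other 19 residues), with
    match-heavy transitions (m->m 0.9).  Deterministic."""
    from .io_formats import AMINO_ACIDS

    if not consensus:
        raise ValueError("consensus must be non-empty")
    if not 0 < conservation <= 1:
        raise ValueError("conservation must lie in (0, 1]")
    m = len(consensus)
    match = np.full((m, 20), (1.0 - conservation) / 19.0)
    for i, aa in enumerate(consensus):
        j = AMINO_ACIDS.index(aa)
        match[i, :] = (1.0 - conservation) / 19.0
        match[i, j] = conservation
    if conservation == 1.0:
        match = np.zeros((m, 20))
        for i, aa in enumerate(consensus):
            match[i, AMINO_ACIDS.index(aa)] = 1.0
    insert = np.full((m, 20), 1 / 20)
    transitions = np.tile([0.9, 0.05, 0.05, 0.5, 0.5, 0.5, 0.5], (m + 1, 1))
    transitions[m] = [0.95, 0.05, 0.0, 0.5, 0.5, 1.0, 0.0]
    return ProfileHMM(name=name, match_emissions=match, insert_emissions=insert,
                      transitions=transitions, background=np.full(20, 0.05))


# --------------------------------------------------------------------------
# genomes with planted genes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """Recipe for a single planted gene: 1-4 exons, GT..AG introns."""

    exon_lengths: tuple[int, ...] = (300, 400)
    intron_lengths: tuple[int, ...] = (900,)
    strand: str = "+"
    flank_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= len(self.exon_lengths) <= 4:
            raise ValueError("1 to 4 exons are supported")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need exactly exons - 1 introns")
        if any(i < 60 for i in self.intron_lengths):
            raise ValueError("introns must be at least 60 bp")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


def make_genome_with_gene(
    spec: GeneSpec, transcript: TranscriptRecord, scaffold_id: str = "scaffold1",
) -> tuple[TranscriptRecord, GeneModel]:
    """Embed *transcript* as a spliced gene in a random scaffold.

    The transcript is cut at the spec's exon lengths; GT..AG introns are
    inserted between exons; the whole gene (reverse-complemented for minus
    strand) sits between random flanks.  Returns the scaffold and the true
    gene model (transcript coordinates on the aligned strand).
    """
    tlen = len(transcript.sequence)
    if tlen != sum(spec.exon_lengths):
        raise ValueError(
            f"transcript length {tlen} != sum of exon lengths {sum(spec.exon_lengths)}"
        )
    rng = np.random.default_rng(spec.seed)
    exon_seqs = []
    offset = 0
    for length in spec.exon_lengths:
        exon_seqs.append(transcript.sequence[offset:offset + length])
        offset += length
    intron_seqs = ["GT" + _random_bases(rng, n - 4) + "AG" for n in spec.intron_lengths]
    gene_parts = [exon_seqs[0]]
    for intron, exon in zip(intron_seqs, exon_seqs[1:]):
        gene_parts.extend([intron, exon])
    gene_seq = "".join(gene_parts)
    flank5 = _random_bases(rng, spec.flank_length)
    flank3 = _random_bases(rng, spec.flank_length)
    insert = gene_seq if spec.strand == "+" else reverse_complement(gene_seq)
    scaffold_seq = flank5 + insert + flank3
    scaffold = TranscriptRecord(id=scaffold_id, description="synthetic scaffold",
                                sequence=scaffold_seq)
    # true coordinates: gene-strand offsets of each exon within gene_seq
    offsets = []
    pos = 0
    for i, length in enumerate(spec.exon_lengths):
        offsets.append((pos, pos + length))
        if i < len(spec.intron_lengths):
            pos += length + spec.intron_lengths[i]
    f = spec.flank_length
    glen = len(gene_seq)
    exons: list[ExonBlock] = []
    tpos = 0
    tspans = []
    for length in spec.exon_lengths:
        tspans.append((tpos, tpos + length))
        tpos += length
    if spec.strand == "+":
        for (gs, ge), (ts, te) in zip(offsets, tspans):
            exons.append(ExonBlock(scaffold_id, (f + gs, f + ge), (ts, te), "+", ge - gs))
    else:
        for (gs, ge), (ts, te) in zip(reversed(offsets), reversed(tspans)):
            exons.append(ExonBlock(
                scaffold_id,
                (f + glen - ge, f + glen - gs),
                (tlen - te, tlen - ts),
                "-", ge - gs,
            ))
    introns = []
    for prev, cur in zip(exons, exons[1:]):
        span = (prev.genome_span[1], cur.genome_span[0])
        introns.append(Intron(span, "GT", "AG", True))
    truth = GeneModel(transcript_id=transcript.id, scaffold_id=scaffold_id,
                      strand=spec.strand, exons=exons, introns=introns, coverage=1.0)
    return scaffold, truth


def random_transcript(length: int, seed: int = 0, id: str = "tx") -> TranscriptRecord:
    rng = np.random.default_rng(seed)
    return TranscriptRecord(id=id, description="synthetic transcript",
                            sequence=_random_bases(rng, length))


# --------------------------------------------------------------------------
# count tables
# --------------------------------------------------------------------------

def make_counts(
    n_features: int,
    n_per_group: int,
    effect: float = 1.0,
    dispersion: float = 0.1,
    base_mean: float = 100.0,
    n_affected: int = 0,
    seed: int = 0,
    groups: tuple[str, str] = ("control", "treated"),
) -> tuple[CountTable, list[str]]:
    """Negative-binomial count table with a two-group design.

    The first *n_affected* features carry the fold *effect* in the second
    group; the returned id list names them.  Mean/variance follow
    var = mu + dispersion * mu^2.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if not 0 <= n_affected <= n_features:
        raise ValueError("n_affected out of range")
    rng = np.random.default_rng(seed)
    feature_ids = [f"feat{i + 1:05d}" for i in range(n_features)]
    sample_ids = [f"{groups[0]}_{j + 1}" for j in range(n_per_group)] + \
                 [f"{groups[1]}_{j + 1}" for j in range(n_per_group)]
    labels = [groups[0]] * n_per_group + [groups[1]] * n_per_group

    def draw(mu: float, size) -> np.ndarray:
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p, size=size)

    counts = np.empty((n_features, 2 * n_per_group), dtype=np.int64)
    counts[:, :n_per_group] = draw(base_mean, (n_features, n_per_group))
    counts[:n_affected, n_per_group:] = draw(base_mean * effect, (n_affected, n_per_group))
    counts[n_affected:, n_per_group:] = draw(base_mean, (n_features - n_affected, n_per_group))
    tbl = CountTable(feature_ids=feature_ids, sample_ids=sample_ids,
                     counts=counts, sample_groups=labels)
    return tbl, feature_ids[:n_affected]
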