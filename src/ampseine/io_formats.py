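"""Readers and writers for the external formats the pipeline touches.

FASTA (nucleotide and amino acid), HMMER3/f ASCII profile files, GFF3 gene
models, TSV count tables, and YAML configs.  All coordinates are 0-based
half-open internally; the GFF3 writer is the single place where conversion
to 1-based inclusive happens.
"""

from __future__ import annotations

import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import yaml
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover - type-only imports, avoids cycles
    from .gene_models import GeneModel
    from .profile_hmm_screen import ProfileHMM

__all__ = [
    "FormatError",
    "TranscriptRecord",
    "CountTable",
    "read_fasta",
    "write_fasta",
    "read_hmmer3_profiles",
    "write_hmmer3_profiles",
    "write_gff3",
    "read_count_table",
    "write_count_table",
    "load_yaml",
    "get_logger",
    "configure_logging",
]

#: Alphabetical amino-acid ordering used by HMMER3 profile columns and by
#: every emission array in this package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

NUCLEOTIDES = set("ACGTN")
PROTEIN_LETTERS = set(AMINO_ACIDS) | {"X"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# --------------------------------------------------------------------------
# logging plumbing
# --------------------------------------------------------------------------

def get_logger(name: str = "ampseine") -> logging.Logger:
    return logging.getLogger(name if name.startswith("ampseine") else f"ampseine.{name}")


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Route package logs to stderr (and optionally a file)."""
    root = logging.getLogger("ampseine")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(fmt)
    root.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        root.addHandler(fh)


log = get_logger("io")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """One named nucleotide sequence from a transcriptome."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"transcript {self.id!r}: whitespace inside sequence")


@dataclass
class CountTable:
    """Feature-by-sample table of non-negative integer read counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (features, samples), integer
    sample_groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts are not allowed")
        if self.sample_groups and len(self.sample_groups) != len(self.sample_ids):
            raise ValueError("one group label per sample is required")

    def samples_in(self, group: str) -> list[int]:
        """Column indices of the samples carrying *group*'s label."""
        return [i for i, g in enumerate(self.sample_groups) if g == group]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[TranscriptRecord]:
    """Read a FASTA file into :class:`TranscriptRecord` objects, in file order.

    Sequences are uppercase-normalized.  For nucleotide input, U is mapped
    to T with a logged warning; characters outside {A,C,G,T,N} are rejected.
    Duplicate ids raise :class:`FormatError`; an empty file yields an empty
    list with a warning.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    warned_u = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            if "U" in seq:
                if not warned_u:
                    log.warning("%s: RNA alphabet detected, mapping U to T", path)
                    warned_u = True
                seq = seq.replace("U", "T")
            bad = set(seq) - NUCLEOTIDES
        else:
            bad = set(seq) - PROTEIN_LETTERS
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains invalid {alphabet} "
                f"characters {sorted(bad)}"
            )
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(TranscriptRecord(id=rec.id, description=desc, sequence=seq))
    if not records:
        log.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable, path: str | Path, wrap: int = 60) -> None:
    """Write records (anything with id/description/sequence) as FASTA,
    wrapped at *wrap* columns."""
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


# --------------------------------------------------------------------------
# HMMER3/f ASCII profiles
# --------------------------------------------------------------------------
# Model lines store emission and transition probabilities as negative
# natural-log values, with "*" denoting probability zero.  Only the text
# HMMER3/f dialect is supported; binary profiles are rejected.

def _encode(p: float) -> str:
    if p <= 0.0:
        return "*"
    return f"{-math.log(p):.9f}"


def _decode(tok: str) -> float:
    if tok == "*":
        return 0.0
    return math.exp(-float(tok))


def write_hmmer3_profiles(hmms: Sequence["ProfileHMM"], path: str | Path) -> None:
    """Serialize profiles to a HMMER3/f ASCII file (round-trips with
    :func:`read_hmmer3_profiles`)."""
    with open(path, "w") as fh:
        for hmm in hmms:
            fh.write("HMMER3/f [ampseine | profile file]\n")
            fh.write(f"NAME  {hmm.name}\n")
            fh.write(f"LENG  {hmm.length}\n")
            fh.write("ALPH  amino\n")
            fh.write("RF    no\nMM    no\nCONS  no\nCS    no\nMAP   yes\n")
            for kind, (tau, lam) in sorted(hmm.stats.items()):
                fh.write(f"STATS LOCAL {kind} {tau:10.5f} {lam:8.5f}\n")
            fh.write("HMM      " + "  ".join(f"{a:>11}" for a in AMINO_ACIDS) + "\n")
            fh.write("         " + "  ".join(
                f"{t:>11}" for t in ("m->m", "m->i", "m->d", "i->m", "i->i", "d->m", "d->d")) + "\n")
            fh.write("  COMPO  " + "  ".join(f"{_encode(p):>11}" for p in hmm.background) + "\n")
            fh.write("         " + "  ".join(f"{_encode(p):>11}" for p in hmm.insert0_emissions) + "\n")
            fh.write("         " + "  ".join(f"{_encode(p):>11}" for p in hmm.transitions[0]) + "\n")
            for k in range(1, hmm.length + 1):
                fh.write(f"{k:>7}  " + "  ".join(
                    f"{_encode(p):>11}" for p in hmm.match_emissions[k - 1]) + f"  {k} - - - -\n")
                fh.write("         " + "  ".join(
                    f"{_encode(p):>11}" for p in hmm.insert_emissions[k - 1]) + "\n")
                fh.write("         " + "  ".join(
                    f"{_encode(p):>11}" for p in hmm.transitions[k]) + "\n")
            fh.write("//\n")


def _parse_values(tokens: Sequence[str], n: int, where: str) -> np.ndarray:
    if len(tokens) < n:
        raise FormatError(f"{where}: expected {n} values, found {len(tokens)}")
    return np.array([_decode(t) for t in tokens[:n]])


def read_hmmer3_profiles(path: str | Path) -> list["ProfileHMM"]:
    """Parse every profile from a HMMER3/f ASCII file.

    Emission rows are converted to probabilities (each row sums to 1 within
    1e-6 or a :class:`FormatError` is raised); "*" parses to probability 0.
    """
    from .profile_hmm_screen import ProfileHMM

    path = Path(path)
    lines = Path(path).read_text().splitlines()
    pos = 0
    profiles: list[ProfileHMM] = []
    while pos < len(lines):
        while pos < len(lines) and not lines[pos].strip():
            pos += 1
        if pos >= len(lines):
            break
        header = lines[pos]
        if not header.startswith("HMMER3/f"):
            raise FormatError(
                f"{path}:{pos + 1}: not a HMMER3/f ASCII profile "
                f"(only the text HMMER3/f dialect is supported)"
            )
        pos += 1
        name = None
        leng = None
        alph = None
        stats: dict[str, tuple[float, float]] = {}
        while pos < len(lines):
            line = lines[pos]
            tok = line.split()
            if tok and tok[0] == "HMM":
                break
            if not tok:
                pos += 1
                continue
            key = tok[0]
            if key == "NAME":
                name = tok[1]
            elif key == "LENG":
                leng = int(tok[1])
            elif key == "ALPH":
                alph = tok[1].lower()
            elif key == "STATS" and len(tok) >= 5 and tok[1] == "LOCAL":
                stats[tok[2]] = (float(tok[3]), float(tok[4]))
            pos += 1
        if name is None or leng is None:
            raise FormatError(f"{path}: profile missing NAME or LENG header")
        if alph != "amino":
            raise FormatError(f"{path}: profile {name!r} has non-amino alphabet {alph!r}")
        pos += 2  # the HMM column-header line and the transition-header line
        background = np.full(20, 1 / 20)
        if pos < len(lines) and lines[pos].split()[:1] == ["COMPO"]:
            background = _parse_values(lines[pos].split()[1:], 20, f"{path}:{pos + 1} COMPO")
            pos += 1
        insert0 = _parse_values(lines[pos].split(), 20, f"{path}:{pos + 1} insert-0 emissions")
        pos += 1
        transitions = [_parse_values(lines[pos].split(), 7, f"{path}:{pos + 1} node-0 transitions")]
        pos += 1
        match_emissions = []
        insert_emissions = []
        k = 0
        while pos < len(lines):
            tok = lines[pos].split()
            if tok and tok[0] == "//":
                pos += 1
                break
            k += 1
            if not tok or not tok[0].isdigit() or int(tok[0]) != k:
                raise FormatError(
                    f"{path}:{pos + 1}: expected node {k} (LENG {leng}) of profile {name!r}"
                )
            match_emissions.append(_parse_values(tok[1:], 20, f"{path}:{pos + 1} match emissions"))
            insert_emissions.append(
                _parse_values(lines[pos + 1].split(), 20, f"{path}:{pos + 2} insert emissions"))
            transitions.append(
                _parse_values(lines[pos + 2].split(), 7, f"{path}:{pos + 3} transitions"))
            pos += 3
        if k != leng:
            raise FormatError(
                f"{path}: profile {name!r}: LENG {leng} does not match {k} parsed match states"
            )
        hmm = ProfileHMM(
            name=name,
            match_emissions=np.array(match_emissions),
            insert_emissions=np.array(insert_emissions),
            transitions=np.array(transitions),
            background=background,
            insert0_emissions=insert0,
            stats=stats,
        )
        profiles.append(hmm)
    return profiles


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def write_gff3(
    models: Sequence["GeneModel"],
    path: str | Path,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write gene models as GFF3 gene/mRNA/exon features.

    Internal 0-based half-open spans become 1-based inclusive coordinates
    here (and only here).  Output is sorted by scaffold then gene start.
    """
    rows = []
    for model in models:
        if not model.exons:
            continue
        start = model.exons[0].genome_span[0]
        end = model.exons[-1].genome_span[1]
        if start < 0:
            raise FormatError(f"model {model.transcript_id!r}: negative coordinate")
        if scaffold_lengths is not None:
            limit = scaffold_lengths.get(model.scaffold_id)
            if limit is not None and end > limit:
                raise FormatError(
                    f"model {model.transcript_id!r}: exon span ends at {end} beyond "
                    f"scaffold {model.scaffold_id!r} length {limit}"
                )
        rows.append((model.scaffold_id, start, end, model))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold, start, end, model in rows:
            gid = f"gene:{model.transcript_id}"
            mid = f"mRNA:{model.transcript_id}"
            common = f"{scaffold}\tampseine"
            fh.write(f"{common}\tgene\t{start + 1}\t{end}\t.\t{model.strand}\t.\tID={gid}\n")
            fh.write(
                f"{common}\tmRNA\t{start + 1}\t{end}\t.\t{model.strand}\t.\t"
                f"ID={mid};Parent={gid}\n"
            )
            for i, exon in enumerate(model.exons, 1):
                es, ee = exon.genome_span
                fh.write(
                    f"{common}\texon\t{es + 1}\t{ee}\t.\t{model.strand}\t.\t"
                    f"ID={mid}.exon{i};Parent={mid}\n"
                )


# --------------------------------------------------------------------------
# count tables
# --------------------------------------------------------------------------

def read_count_table(path: str | Path, group_map: Mapping[str, str]) -> CountTable:
    """Read a TSV of integer read counts (rows features, columns samples)
    and attach the sample -> group labelling."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = [str(c) for c in df.columns]
    feature_ids = [str(i) for i in df.index]
    counts = np.zeros((len(feature_ids), len(sample_ids)), dtype=np.int64)
    for i, fid in enumerate(feature_ids):
        for j, sid in enumerate(sample_ids):
            cell = df.iat[i, j]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                raise FormatError(f"{path}: missing count for feature {fid!r}, sample {sid!r}")
            try:
                value = int(str(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer count {cell!r} for feature {fid!r}, sample {sid!r}"
                ) from None
            if value < 0:
                raise FormatError(f"{path}: negative count for feature {fid!r}, sample {sid!r}")
            counts[i, j] = value
    missing = [s for s in sample_ids if s not in group_map]
    if missing:
        raise FormatError(f"{path}: samples without group label: {missing}")
    groups = [group_map[s] for s in sample_ids]
    return CountTable(feature_ids=feature_ids, sample_ids=sample_ids,
                      counts=counts, sample_groups=groups)


def write_count_table(tbl: CountTable, path: str | Path) -> None:
    tbl.to_dataframe().to_csv(path, sep="\t", index_label="feature_id")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level YAML mapping expected")
    return data
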