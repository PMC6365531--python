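"""End-to-end discovery orchestration.

Runs ORF discovery -> profile-HMM screen -> last-KR split ->
physicochemical characterization -> homology classification (plus the
optional expression and gene-model stages) over on-disk inputs, writing
every stage's intermediate to the output directory so each filtering
decision is auditable.  One report row is produced per retained
transcript: when several ORFs of one transcript pass the screen, the one
with the lowest screen E-value (ties: longer protein, then earlier start)
represents it.

Runs are deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import expression_quant, gene_models, homology_classify
from .io_formats import (get_logger, load_yaml, read_count_table, read_fasta,
                         read_hmmer3_profiles, write_fasta, write_gff3)
from .orf_discovery import OrfCandidate, filter_candidates, find_complete_orfs
from .precursor_physchem import (DEFAULT_PKA_SET, profile_peptide,
                                 split_precursor)
from .profile_hmm_screen import calibrate_profile, screen

log = get_logger("pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Paths and thresholds for one discovery run."""

    transcriptome: str
    hmm_library: str
    reference: str | None = None
    genome: str | None = None
    counts: str | None = None
    sample_groups: dict[str, str] = field(default_factory=dict)
    control_group: str | None = None
    treated_group: str | None = None

    min_orf_len: int = 20
    max_orf_len: int = 100
    strand_mode: str = "sense"
    allowed_starts: str = "MV"
    screen_evalue: float = 0.001
    match_evalue: float = 1e-4
    known_identity: float = 90.0
    known_positivity: float = 90.0
    scale: float = 1e8
    alpha: float = 0.05
    pka_set: str = DEFAULT_PKA_SET
    seed_k: int = 31
    min_intron: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_orf_len", "max_orf_len", "screen_evalue", "match_evalue",
                     "known_identity", "known_positivity", "scale", "alpha",
                     "seed_k", "min_intron"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    data = load_yaml(path)
    try:
        return PipelineConfig(**data)
    except TypeError as exc:
        raise ValueError(f"invalid config {path}: {exc}") from None


@dataclass
class DiscoveryReport:
    """Per-candidate rows plus known/novel/no_match summary counts."""

    rows: pd.DataFrame
    summary: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.rows):
            counted = sum(v for k, v in self.summary.items()
                          if k in ("known", "novel", "no_match", "unclassified"))
            if counted != len(self.rows):
                raise ValueError("summary counts must agree with the report rows")


_REPORT_COLUMNS = [
    "transcript_id", "orf_id", "strand", "nt_start", "nt_end", "protein",
    "family", "screen_evalue", "prepro", "mature", "net_charge", "avg_mass",
    "pI", "mature_length", "status", "best_match", "match_evalue",
    "identity_precursor", "identity_prepro", "identity_mature",
]


def _best_orf_per_transcript(
    candidates: list[OrfCandidate], best_e: dict[str, float],
    best_family: dict[str, str],
) -> list[tuple[OrfCandidate, float, str]]:
    per_tx: dict[str, tuple[OrfCandidate, float, str]] = {}
    for orf in candidates:
        if orf.orf_id not in best_e:
            continue
        entry = (orf, best_e[orf.orf_id], best_family[orf.orf_id])
        cur = per_tx.get(orf.transcript_id)
        if cur is None:
            per_tx[orf.transcript_id] = entry
            continue
        old_orf, old_e, _ = cur
        if (entry[1], -len(orf.protein), orf.nt_start) < (old_e, -len(old_orf.protein),
                                                          old_orf.nt_start):
            per_tx[orf.transcript_id] = entry
    return [per_tx[t] for t in sorted(per_tx)]


def run_discovery(cfg: PipelineConfig, outdir: str | Path) -> DiscoveryReport:
    """Execute the discovery cascade; intermediates land in *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- ORF discovery ------------------------------------------------------
    try:
        records = read_fasta(cfg.transcriptome)
        orfs: list[OrfCandidate] = []
        for rec in records:
            orfs.extend(find_complete_orfs(rec, cfg.strand_mode))
        candidates = filter_candidates(orfs, cfg.min_orf_len, cfg.max_orf_len,
                                       set(cfg.allowed_starts))
    except Exception as exc:
        raise PipelineError("orf_discovery", str(exc)) from exc
    log.info("%d transcripts -> %d complete ORFs -> %d candidates",
             len(records), len(orfs), len(candidates))

    class _Faa:
        def __init__(self, orf: OrfCandidate):
            self.id = orf.orf_id
            self.description = (f"transcript={orf.transcript_id} strand={orf.strand} "
                                f"span={orf.nt_start}-{orf.nt_end}")
            self.sequence = orf.protein

    write_fasta([_Faa(o) for o in candidates], outdir / "orfs.faa")

    # -- profile-HMM screen -------------------------------------------------
    try:
        hmms = read_hmmer3_profiles(cfg.hmm_library)
        for hmm in hmms:
            if "FORWARD" not in hmm.stats:
                calibrate_profile(hmm, seed=cfg.seed)
        hits = screen(candidates, hmms, cfg.screen_evalue, seed=cfg.seed)
    except Exception as exc:
        raise PipelineError("profile_hmm_screen", str(exc)) from exc
    pd.DataFrame(
        [(h.peptide_id, h.family, h.viterbi_bits, h.forward_bits, h.evalue) for h in hits],
        columns=["peptide_id", "family", "viterbi_bits", "forward_bits", "evalue"],
    ).to_csv(outdir / "hits.tsv", sep="\t", index=False)

    best_e: dict[str, float] = {}
    best_family: dict[str, str] = {}
    for h in hits:  # hits are sorted by ascending E
        if h.peptide_id not in best_e:
            best_e[h.peptide_id] = h.evalue
            best_family[h.peptide_id] = h.family
    chosen = _best_orf_per_transcript(candidates, best_e, best_family)
    for orf in candidates:
        if orf.orf_id not in best_e:
            log.debug("rejected %s: no profile hit below E %g", orf.orf_id, cfg.screen_evalue)

    # -- split + characterize -----------------------------------------------
    rows = []
    splits = []
    for orf, e, family in chosen:
        try:
            split = split_precursor(orf.protein, "last_kr", id=orf.transcript_id)
        except ValueError:
            log.info("rejected %s: no K-R convertase site", orf.orf_id)
            continue
        prof = profile_peptide(split, cfg.pka_set)
        splits.append((orf, e, family, split, prof))
    for orf, e, family, split, prof in splits:
        rows.append({
            "transcript_id": orf.transcript_id, "orf_id": orf.orf_id,
            "strand": orf.strand, "nt_start": orf.nt_start, "nt_end": orf.nt_end,
            "protein": orf.protein, "family": family, "screen_evalue": e,
            "prepro": split.prepro, "mature": split.mature,
            "net_charge": prof.net_charge, "avg_mass": round(prof.avg_mass, 1),
            "pI": round(prof.pI, 1), "mature_length": prof.length,
            "status": "unclassified", "best_match": None, "match_evalue": None,
            "identity_precursor": None, "identity_prepro": None,
            "identity_mature": None,
        })

    # -- homology classification --------------------------------------------
    if cfg.reference is not None and rows:
        try:
            refs = []
            for rec in read_fasta(cfg.reference, alphabet="protein"):
                try:
                    refs.append(split_precursor(rec.sequence, "last_kr", id=rec.id))
                except ValueError:
                    log.warning("reference %s has no K-R site; skipped", rec.id)
            if refs:
                for row, (orf, e, family, split, prof) in zip(rows, splits):
                    cls = homology_classify.classify(
                        split, refs, cfg.match_evalue, cfg.known_identity,
                        cfg.known_positivity, seed=cfg.seed)
                    row.update({
                        "status": cls.status, "best_match": cls.best_match,
                        "match_evalue": cls.evalue,
                        "identity_precursor": cls.identity_precursor,
                        "identity_prepro": cls.identity_prepro,
                        "identity_mature": cls.identity_mature,
                    })
        except Exception as exc:
            raise PipelineError("homology_classify", str(exc)) from exc

    report = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False)
    summary = {status: int((report["status"] == status).sum())
               for status in ("known", "novel", "no_match", "unclassified")}
    summary["candidates"] = len(report)

    # -- expression (optional) ----------------------------------------------
    if cfg.counts is not None:
        try:
            tbl = read_count_table(cfg.counts, cfg.sample_groups)
            norm = expression_quant.normalize_counts(tbl, cfg.scale)
            summaries = expression_quant.summarize(norm, tbl)
            pd.DataFrame([asdict(s) for s in summaries]).to_csv(
                outdir / "expression.tsv", sep="\t", index=False)
            if cfg.control_group and cfg.treated_group:
                comps = expression_quant.compare_treatment(
                    norm, tbl, cfg.control_group, cfg.treated_group)
                pd.DataFrame([asdict(c) for c in comps]).to_csv(
                    outdir / "comparisons.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError("expression_quant", str(exc)) from exc

    # -- gene models (optional) ---------------------------------------------
    if cfg.genome is not None and rows:
        try:
            scaffolds = read_fasta(cfg.genome)
            wanted = {row["transcript_id"] for row in rows}
            models = []
            for rec in records:
                if rec.id not in wanted:
                    continue
                per_scaffold = []
                for scaffold in scaffolds:
                    model = gene_models.map_transcript(rec, scaffold, cfg.seed_k,
                                                       cfg.min_intron)
                    if model is not None and model.exons:
                        per_scaffold.append(model)
                if not per_scaffold:
                    continue
                best_cov = max(m.coverage for m in per_scaffold)
                # partial models on further scaffolds are reported, not stitched
                models.extend(m for m in per_scaffold
                              if m.coverage >= min(0.1, best_cov))
            write_gff3(models, outdir / "models.gff3",
                       {s.id: len(s.sequence) for s in scaffolds})
            pd.DataFrame(
                [(m.transcript_id, m.scaffold_id, m.strand, m.exon_count,
                  m.gene_span_bp, ";".join(str(i.length) for i in m.introns),
                  m.coverage, all(i.canonical for i in m.introns))
                 for m in models],
                columns=["transcript_id", "scaffold_id", "strand", "exons",
                         "gene_span_bp", "intron_sizes", "coverage",
                         "all_canonical"],
            ).to_csv(outdir / "gene_models.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError("gene_models", str(exc)) from exc

    log.info("discovery summary: %s", summary)
    return DiscoveryReport(rows=report, summary=summary)
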