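import numpy as np
import pytest

from ampseine.io_formats import TranscriptRecord
from ampseine.gene_models import (chain_blocks, diagonal_runs, best_chain,
                                  chain_score, map_transcript, model_stats,
                                  refine_splice_sites, seed_matches, _Run)
from ampseine.orf_discovery import reverse_complement
from ampseine.synthetic_data import (GeneSpec, make_genome_with_gene,
                                     random_transcript)

from _oracles import best_chain_oracle


def _bases(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSeedMatches:
    def test_verbatim_copy_gives_full_diagonal(self, rng):
        tx = _bases(rng, 120)
        scaffold = _bases(rng, 50) + tx + _bases(rng, 50)
        plus = [(t, g) for t, g, s in seed_matches(tx, scaffold, 31) if s == "+"]
        assert len(plus) >= 120 - 31 + 1
        assert {g - t for t, g in plus} >= {50}

    def test_reverse_complement_on_minus_strand(self, rng):
        tx = _bases(rng, 100)
        scaffold = _bases(rng, 40) + reverse_complement(tx) + _bases(rng, 40)
        strands = {s for _, _, s in seed_matches(tx, scaffold, 31)}
        assert "-" in strands

    def test_matches_double_loop_oracle(self, rng):
        k = 11
        tx = _bases(rng, 60)
        scaffold = _bases(rng, 80) + tx[10:40] + _bases(rng, 30)
        oracle = set()
        for strand, tseq in (("+", tx), ("-", reverse_complement(tx))):
            for t in range(len(tseq) - k + 1):
                for g in range(len(scaffold) - k + 1):
                    if tseq[t:t + k] == scaffold[g:g + k]:
                        oracle.add((t, g, strand))
        assert set(seed_matches(tx, scaffold, k)) == oracle

    def test_tiny_k_rejected(self):
        with pytest.raises(ValueError):
            seed_matches("A" * 40, "A" * 40, 5)


class TestChaining:
    def test_single_contiguous_match_one_block(self, rng):
        tx = _bases(rng, 200)
        scaffold = _bases(rng, 100) + tx + _bases(rng, 100)
        matches = [(t, g) for t, g, s in seed_matches(tx, scaffold) if s == "+"]
        blocks = chain_blocks(matches)
        assert len(blocks) == 1
        assert blocks[0].genome_span == (100, 300)
        assert blocks[0].transcript_span == (0, 200)

    def test_two_exons_split_by_intron(self, rng):
        tx = _bases(rng, 500)
        intron = "GT" + _bases(rng, 496) + "AG"
        scaffold = _bases(rng, 100) + tx[:250] + intron + tx[250:] + _bases(rng, 100)
        matches = [(t, g) for t, g, s in seed_matches(tx, scaffold) if s == "+"]
        blocks = chain_blocks(matches)
        assert len(blocks) == 2
        assert blocks[0].genome_span[1] == 350
        assert blocks[1].genome_span[0] == 850

    def test_small_genome_gap_absorbed_into_exon(self, rng):
        tx = _bases(rng, 300)
        scaffold = _bases(rng, 50) + tx[:150] + _bases(rng, 20) + tx[150:] + _bases(rng, 50)
        matches = [(t, g) for t, g, s in seed_matches(tx, scaffold) if s == "+"]
        blocks = chain_blocks(matches, min_intron=40)
        assert len(blocks) == 1

    def test_chain_dp_equals_exhaustive_search(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 9))
            runs = [_Run(int(rng.integers(0, 400)), int(rng.integers(0, 400)),
                         int(rng.integers(20, 120))) for _ in range(n)]
            runs.sort(key=lambda r: (r.t_start, r.g_start))
            assert chain_score(best_chain(runs)) == best_chain_oracle(runs)

    def test_no_matches_empty_model(self):
        assert chain_blocks([]) == []


class TestRefineSpliceSites:
    def test_already_canonical_unchanged(self, rng):
        spec = GeneSpec(exon_lengths=(200, 300), intron_lengths=(100,), seed=3)
        tx = random_transcript(500, seed=4)
        scaffold, truth = make_genome_with_gene(spec, tx)
        model = map_transcript(tx, scaffold, refine=False)
        refined = refine_splice_sites(model, scaffold.sequence)
        again = refine_splice_sites(refined, scaffold.sequence)
        assert [e.genome_span for e in refined.exons] == \
            [e.genome_span for e in again.exons]
        assert all(i.canonical for i in refined.introns)

    def test_ambiguous_junction_placed_at_gt_ag(self, rng):
        # exon2 begins with the same 2 bases the intron begins with, so the
        # chained junction can slide; only one placement yields GT..AG
        exon1 = _bases(rng, 150)
        exon2 = "GTCA" + _bases(rng, 146)
        intron = "GT" + "CA" + _bases(rng, 90) + "AG" + "GT"
        # chained placement may sit 2 bp right of the truth; refinement must
        # slide it back onto GT..AG
        tx = exon1 + exon2
        scaffold = _bases(rng, 60) + exon1 + intron[:-2] + exon2 + _bases(rng, 60)
        model = map_transcript(tx_rec(tx), sc_rec(scaffold))
        assert model.exon_count == 2
        (intr,) = model.introns
        assert (intr.donor, intr.acceptor) == ("GT", "AG")
        assert intr.canonical

    def test_gc_ag_intron_flagged_not_shifted(self, rng):
        # exon2 starts TT and exon1 ends AA, so the junction cannot slide
        exon1 = _bases(rng, 148) + "AA"
        exon2 = "TT" + _bases(rng, 148)
        intron = "GC" + _bases(rng, 96) + "CG"
        tx = exon1 + exon2
        scaffold = _bases(rng, 60) + exon1 + intron + exon2 + _bases(rng, 60)
        model = map_transcript(tx_rec(tx), sc_rec(scaffold))
        assert model.exon_count == 2
        (intr,) = model.introns
        assert not intr.canonical
        assert intr.span == (210, 310)
        assert (intr.donor, intr.acceptor) == ("GC", "CG")


def tx_rec(seq):
    return TranscriptRecord(id="tx", description="", sequence=seq)


def sc_rec(seq):
    return TranscriptRecord(id="sc", description="", sequence=seq)


class TestModelRecovery:
    def test_constructed_two_exon_fixture_span(self):
        spec = GeneSpec(exon_lengths=(300, 400), intron_lengths=(900,), seed=5)
        tx = random_transcript(700, seed=6)
        scaffold, truth = make_genome_with_gene(spec, tx)
        model = map_transcript(tx, scaffold)
        exons, span, introns = model_stats(model)
        assert (exons, span, introns) == (2, 1600, [900])
        assert truth.gene_span_bp == 1600

    def test_single_exon_no_introns(self):
        spec = GeneSpec(exon_lengths=(400,), intron_lengths=(), seed=7)
        tx = random_transcript(400, seed=8)
        scaffold, _ = make_genome_with_gene(spec, tx)
        model = map_transcript(tx, scaffold)
        assert model_stats(model)[0] == 1
        assert model.introns == []

    def test_four_exon_gene_recovered(self):
        spec = GeneSpec(exon_lengths=(150, 200, 250, 300),
                        intron_lengths=(80, 500, 1200), seed=9)
        tx = random_transcript(900, seed=10)
        scaffold, truth = make_genome_with_gene(spec, tx)
        model = map_transcript(tx, scaffold)
        assert model.exon_count == 4
        assert [e.genome_span for e in model.exons] == \
            [e.genome_span for e in truth.exons]

    def test_minus_strand_gene_mirrored(self):
        spec_p = GeneSpec(exon_lengths=(200, 300), intron_lengths=(150,),
                          strand="+", seed=11)
        spec_m = GeneSpec(exon_lengths=(200, 300), intron_lengths=(150,),
                          strand="-", seed=11)
        tx = random_transcript(500, seed=12)
        sc_p, truth_p = make_genome_with_gene(spec_p, tx)
        sc_m, truth_m = make_genome_with_gene(spec_m, tx)
        mp = map_transcript(tx, sc_p)
        mm = map_transcript(tx, sc_m)
        assert (mp.strand, mm.strand) == ("+", "-")
        assert mp.gene_span_bp == mm.gene_span_bp == truth_m.gene_span_bp

    def test_splice_out_reconstructs_transcript(self):
        spec = GeneSpec(exon_lengths=(250, 350), intron_lengths=(200,), seed=13)
        tx = random_transcript(600, seed=14)
        scaffold, _ = make_genome_with_gene(spec, tx)
        model = map_transcript(tx, scaffold)
        assert model.coverage == 1.0
        spliced = "".join(scaffold.sequence[s:e]
                          for s, e in (ex.genome_span for ex in model.exons))
        if model.strand == "-":
            spliced = reverse_complement(spliced)
        assert spliced == tx.sequence

    def test_recovery_rate_over_random_genes(self, rng):
        exact_count = exact_bounds = 0
        n = 15
        for i in range(n):
            n_ex = int(rng.integers(1, 5))
            exons = tuple(int(rng.integers(100, 601)) for _ in range(n_ex))
            introns = tuple(int(rng.integers(60, 5001)) for _ in range(n_ex - 1))
            spec = GeneSpec(exon_lengths=exons, intron_lengths=introns,
                            strand="+-"[int(rng.integers(2))], seed=3000 + i)
            tx = random_transcript(sum(exons), seed=4000 + i, id=f"tx{i}")
            scaffold, truth = make_genome_with_gene(spec, tx)
            model = map_transcript(tx, scaffold)
            if model and model.exon_count == truth.exon_count:
                exact_count += 1
                if all(m.genome_span == t.genome_span
                       for m, t in zip(model.exons, truth.exons)):
                    exact_bounds += 1
        assert exact_count / n >= 0.95
        assert exact_bounds / n >= 0.9
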