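import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from ampseine.io_formats import AMINO_ACIDS
from ampseine.homology_classify import (classify, global_align,
                                        identity_positivity, local_align,
                                        match_evalue)
from ampseine.precursor_physchem import split_precursor


def _pairwise(mode):
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # our convention: a gap of length g costs 11 + g, i.e. 12 then 1
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    aligner.mode = mode
    return aligner


def _random_pep(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), n))


class TestAlignment:
    def test_self_alignment_full_identity(self):
        aln = local_align("SMLSVLKNLG", "SMLSVLKNLG")
        identity, positivity = identity_positivity(aln)
        assert identity == positivity == 100.0
        assert aln.gaps == 0

    def test_all_negative_pairs_give_empty_local_alignment(self):
        aln = local_align("KK", "DD")
        assert aln.score == 0.0
        assert aln.aligned_columns == 0

    def test_global_gap_column(self):
        aln = global_align("A", "AA")
        assert aln.aligned_columns == 2
        assert aln.gaps == 1

    def test_equal_strings_global(self):
        aln = global_align("KWCKW", "KWCKW")
        assert aln.aligned_columns == 5
        assert identity_positivity(aln)[0] == 100.0

    def test_scores_match_independent_dp_oracle(self, rng):
        loc, glob = _pairwise("local"), _pairwise("global")
        for _ in range(100):
            a = _random_pep(rng, int(rng.integers(3, 13)))
            b = _random_pep(rng, int(rng.integers(3, 13)))
            assert local_align(a, b).score == pytest.approx(loc.score(a, b))
            assert global_align(a, b).score == pytest.approx(glob.score(a, b))

    def test_score_symmetric_for_symmetric_matrix(self, rng):
        for _ in range(30):
            a = _random_pep(rng, int(rng.integers(4, 20)))
            b = _random_pep(rng, int(rng.integers(4, 20)))
            assert local_align(a, b).score == local_align(b, a).score
            assert global_align(a, b).score == global_align(b, a).score

    def test_identity_positivity_match_per_column_scan(self, rng):
        blosum = substitution_matrices.load("BLOSUM62")
        for _ in range(30):
            a = _random_pep(rng, 20)
            b = _random_pep(rng, 20)
            aln = global_align(a, b)
            ident = sum(1 for ca, cb in aln.columns if ca == cb and ca != "-")
            pos = sum(1 for ca, cb in aln.columns
                      if "-" not in (ca, cb) and blosum[ca][cb] > 0)
            got_i, got_p = identity_positivity(aln)
            assert got_i == pytest.approx(100 * ident / aln.aligned_columns)
            assert got_p == pytest.approx(100 * pos / aln.aligned_columns)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "KW")


class TestMatchEvalue:
    def test_self_match_highly_significant(self, rng):
        q = _random_pep(rng, 60)
        aln = local_align(q, q)
        assert match_evalue(aln, q, q, 100, seed=3) < 1e-4

    def test_monotone_in_score(self, rng):
        q = _random_pep(rng, 40)
        s = _random_pep(rng, 40)
        aln = local_align(q, s)
        base = match_evalue(aln, q, s, 10, seed=1)
        stronger = type(aln)(**{**aln.__dict__, "score": aln.score + 10})
        assert match_evalue(stronger, q, s, 10, seed=1) <= base

    def test_unrelated_pairs_rarely_significant(self, rng):
        # an unrelated pair's score is exchangeable with its own shuffle
        # null, so its E-value is roughly uniform: E >= 0.1 about 90% of
        # the time, and never anywhere near the match threshold
        evalues = []
        for i in range(40):
            a = _random_pep(rng, 50)
            b = _random_pep(rng, 50)
            evalues.append(match_evalue(local_align(a, b), a, b, 1, seed=i))
        assert np.mean([e >= 0.1 for e in evalues]) >= 0.80
        assert all(e > 1e-4 for e in evalues)

    def test_too_few_shuffles_rejected(self, rng):
        q = _random_pep(rng, 20)
        with pytest.raises(ValueError, match="shuffles"):
            match_evalue(local_align(q, q), q, q, 1, shuffles=10)


class TestClassify:
    def _mutate(self, precursor, fraction, rng):
        kr = precursor.rfind("KR")
        prec = list(precursor)
        editable = [p for p in rng.permutation(len(prec))
                    if p not in (kr, kr + 1)]
        for p in editable[: int(fraction * len(prec))]:
            prec[p] = rng.choice([a for a in AMINO_ACIDS if a != prec[p]])
        return "".join(prec)

    def test_identical_candidate_is_known(self, precursors):
        ref = split_precursor(precursors["HP4"], id="refA")
        cls = classify(ref, [ref])
        assert cls.status == "known"
        assert cls.identity_precursor == 100.0
        assert cls.identity_mature == 100.0

    def test_twenty_percent_mutant_is_novel(self, precursors, rng):
        ref = split_precursor(precursors["HP4"], id="refA")
        mutant = split_precursor(self._mutate(precursors["HP4"], 0.2, rng), id="mut")
        cls = classify(mutant, [ref])
        assert cls.status == "novel"
        assert cls.evalue < 1e-4
        assert cls.identity_precursor < 90.0

    def test_unrelated_candidate_is_no_match(self, precursors, rng):
        ref = split_precursor(precursors["HP4"], id="refA")
        random_prec = "M" + "".join(rng.choice(list("AGILNPQSTVFWY"), 40)) + "KR" \
            + "".join(rng.choice(list("AGILNPQSTVFWYK"), 20))
        cand = split_precursor(random_prec, id="rand")
        cls = classify(cand, [ref])
        assert cls.status == "no_match"
        assert cls.best_match is None and cls.evalue is None

    def test_invariant_to_reference_order(self, precursors, rng):
        refs = [split_precursor(precursors[p], id=p) for p in ("HP4", "HP8", "HP9")]
        cand = split_precursor(self._mutate(precursors["HP8"], 0.1, rng), id="c")
        assert classify(cand, refs) == classify(cand, list(reversed(refs)))

    def test_known_novel_boundary_tracks_identity_threshold(self, precursors, rng):
        ref = split_precursor(precursors["HP2"], id="ref")
        near = split_precursor(self._mutate(precursors["HP2"], 0.04, rng), id="near")
        far = split_precursor(self._mutate(precursors["HP2"], 0.30, rng), id="far")
        assert classify(near, [ref]).status == "known"
        assert classify(far, [ref]).status == "novel"

    def test_empty_reference_rejected(self, precursors):
        cand = split_precursor(precursors["HP2"], id="c")
        with pytest.raises(ValueError):
            classify(cand, [])
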