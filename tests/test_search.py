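"""Translated-search engine: translation rules, Smith-Waterman oracle
behaviour, Karlin-Altschul statistics, and the seeded heuristic's
dominance/symmetry/consistency properties."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from evescan import simulate as sim
from evescan.io import GenomeAssembly, ProteinRecord, reverse_complement
from evescan.search import (
    evalue_from_score,
    seeded_translated_search,
    six_frame_translate,
    smith_waterman_protein,
    translate,
    translated_search_space,
)


class TestTranslation:
    @pytest.mark.parametrize("nt,aa", [
        ("ATGAAA", "MK"),
        ("ATGNAA", "MX"),       # N-containing codon -> X
        ("TAATAG", "**"),       # stops retained
        ("ATGAA", "M"),         # trailing partial codon dropped
    ])
    def test_standard_code(self, nt, aa):
        assert translate(nt) == aa

    def test_six_frames_and_reverse_complement(self):
        frames = {f.frame: f.aa for f in six_frame_translate("c", "TTTCAT")}
        assert frames[1] == "FH"
        assert frames[-1] == "MK"  # revcomp ATGAAA

    def test_frame_coordinate_map_roundtrip(self):
        seq = "ACGTACGTACGTACGTAC"
        for ft in six_frame_translate("c", seq):
            for a0 in range(len(ft.aa)):
                lo, hi = ft.nt_interval(a0, a0 + 1)
                assert 0 <= lo < hi <= len(seq) and hi - lo == 3
                codon = seq[lo:hi]
                if ft.frame < 0:
                    codon = reverse_complement(codon)
                assert translate(codon) == ft.aa[a0]

    def test_search_space_counts_all_six_frames(self):
        g = GenomeAssembly({"c": "A" * 100})
        assert translated_search_space(g) == 2 * (33 + 33 + 32)


class TestSmithWaterman:
    def test_identity_diagonal(self, scheme):
        a = smith_waterman_protein("MKV", "MKV", scheme)
        assert a.score == 14  # 5 + 5 + 4 on the BLOSUM62 diagonal
        assert a.identity == 100.0
        assert (a.query_start, a.query_end) == (0, 3)

    def test_all_negative_scores_give_empty(self, scheme):
        a = smith_waterman_protein("AAAA", "WWWW", scheme)
        assert a.score == 0 and a.aligned_query == ""

    def test_empty_input(self, scheme):
        assert smith_waterman_protein("", "MKV", scheme).score == 0

    def test_gap_cost_convention(self, scheme):
        # single-residue gap costs gap_open + gap_extend = 12
        a = smith_waterman_protein("MKKV", "MKV", scheme)
        recomputed = scheme.score_alignment(a.aligned_query, a.aligned_subject)
        assert recomputed == a.score

    def test_matches_independent_aligner(self, scheme):
        """Cross-check against Bio.Align.PairwiseAligner on stop-free inputs."""
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(0)
        for _ in range(25):
            q = sim.random_aa(rng, int(rng.integers(10, 60)))
            s = sim.random_aa(rng, int(rng.integers(10, 120)))
            ours = smith_waterman_protein(q, s, scheme).score
            theirs = aligner.score(q, s) if q and s else 0
            assert ours == max(0, int(theirs))

    def test_stop_scores_minus_four(self, scheme):
        assert scheme.score_pair("*", "M") == -4
        assert scheme.score_pair("*", "*") == -4


class TestKarlinAltschul:
    def test_closed_form_example(self, scheme):
        e, bits = evalue_from_score(50, 1000, 1000, scheme)
        assert e == pytest.approx(0.0653, rel=1e-2)
        assert bits == pytest.approx((0.267 * 50 - math.log(0.041)) / math.log(2))

    @given(st.integers(min_value=1, max_value=400))
    def test_strictly_decreasing_in_score(self, s):
        e1, _ = evalue_from_score(s, 500, 10_000)
        e2, _ = evalue_from_score(s + 1, 500, 10_000)
        assert e2 < e1

    def test_linear_in_search_space(self):
        e1, _ = evalue_from_score(100, 500, 10_000)
        e2, _ = evalue_from_score(100, 500, 20_000)
        assert e2 == pytest.approx(2 * e1)

    def test_nonpositive_lengths_error(self):
        with pytest.raises(ValueError):
            evalue_from_score(10, 0, 100)


@pytest.fixture(scope="module")
def planted():
    """Small genome with one perfect-identity implant per strand."""
    virus = sim.simulate_totivirus(11)
    host = sim.random_host_genome(11, {"c1": 60_000})
    genome, truth = sim.implant_eves(
        11, host, virus.proteins, n_loci=2,
        identity_range=(1.0, 1.0), frameshift_prob=0.0, strand_mix=0.5,
        fragment_aa_range=(150, 200), min_spacing=2000,
    )
    return virus, genome, truth


class TestSeededSearch:
    def test_planted_signal_recovered_at_truth_coordinates(self, planted, scheme):
        """Each perfect-identity implant yields a hit covering its interval on
        the right strand (chance matches may extend it by a few codons)."""
        hits = seeded_translated_search(planted[0].proteins, planted[1], scheme)
        assert hits
        for l in planted[2].loci:
            match = [h for h in hits
                     if h.subject_start <= l.start and h.subject_end >= l.end
                     and h.subject_start >= l.start - 9 and h.subject_end <= l.end + 9]
            assert match, f"{l.locus_id} not recovered"
            assert match[0].strand == l.strand
            assert match[0].percent_identity >= 98.0

    def test_strand_symmetry(self, planted, scheme):
        virus, genome, _ = planted
        hits_f = seeded_translated_search(virus.proteins, genome, scheme)
        rc = GenomeAssembly({c: reverse_complement(s) for c, s in genome.contigs.items()})
        hits_r = seeded_translated_search(virus.proteins, rc, scheme)
        key_f = sorted((h.raw_score, h.subject_end - h.subject_start) for h in hits_f)
        key_r = sorted((h.raw_score, h.subject_end - h.subject_start) for h in hits_r)
        assert key_f == key_r
        L = len(genome.contigs["c1"])
        mirrored = sorted((L - h.subject_end, L - h.subject_start, -np.sign(h.frame))
                          for h in hits_r)
        original = sorted((h.subject_start, h.subject_end, np.sign(h.frame))
                          for h in hits_f)
        assert mirrored == original

    def test_hit_scores_dominated_by_oracle(self, planted, scheme):
        virus, genome, _ = planted
        hits = seeded_translated_search(virus.proteins, genome, scheme)
        frames = {(ft.contig_id, ft.frame): ft.aa
                  for ft in six_frame_translate("c1", genome.contigs["c1"])}
        for h in hits:
            q = virus.proteins.get(h.query_id).sequence
            oracle = smith_waterman_protein(q, frames[(h.contig_id, h.frame)], scheme)
            assert h.raw_score <= oracle.score

    def test_score_recomputable_from_aligned_strings(self, planted, scheme):
        virus, genome, _ = planted
        for h in seeded_translated_search(virus.proteins, genome, scheme):
            assert scheme.score_alignment(h.aligned_query, h.aligned_subject) == h.raw_score
            sub_res = sum(c != "-" for c in h.aligned_subject)
            assert h.subject_end - h.subject_start == 3 * sub_res

    def test_coordinates_map_back_to_aligned_residues(self, planted, scheme):
        virus, genome, _ = planted
        for h in seeded_translated_search(virus.proteins, genome, scheme):
            nt = genome.contigs[h.contig_id][h.subject_start:h.subject_end]
            if h.frame < 0:
                nt = reverse_complement(nt)
            assert translate(nt) == h.aligned_subject.replace("-", "")

    def test_evalue_zero_gives_empty(self, planted, scheme):
        virus, genome, _ = planted
        assert seeded_translated_search(virus.proteins, genome, scheme, evalue_max=0) == []

    def test_seed_k_validation(self, planted, scheme):
        virus, genome, _ = planted
        with pytest.raises(ValueError):
            seeded_translated_search(virus.proteins, genome, scheme, seed_k=2)

    def test_no_hits_on_random_genome(self, scheme):
        virus = sim.simulate_totivirus(12)
        clean = sim.random_host_genome(99, {"c1": 100_000})
        assert seeded_translated_search(virus.proteins, clean, scheme, evalue_max=1e-10) == []
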