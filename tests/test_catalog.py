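"""Locus cataloguing: merging rules, stringency flags, reciprocal
screening, cognate-virus assignment and flank-extended ORF calls."""

import random

import pytest

from conftest import make_hit
from evescan import simulate as sim
from evescan.catalog import (
    apply_stringency,
    assign_best_hit,
    merge_hits,
    predict_orf_with_flanks,
    reciprocal_filter,
)
from evescan.io import GenomeAssembly, ProteinRecord, ViralProteinSet, reverse_complement
from evescan.search import ScoringScheme


class TestMergeHits:
    def test_gap_rule(self):
        hits = [make_hit(sstart=100, send=400), make_hit(sstart=600, send=900)]
        loci = merge_hits(hits, max_gap_nt=1000)
        assert len(loci) == 1 and (loci[0].start, loci[0].end) == (100, 900)
        loci = merge_hits(hits, max_gap_nt=100)  # gap of 200 > 100
        assert [(l.start, l.end) for l in loci] == [(100, 400), (600, 900)]

    def test_single_hit_is_identity(self):
        loci = merge_hits([make_hit(sstart=10, send=310)])
        assert len(loci) == 1 and (loci[0].start, loci[0].end) == (10, 310)

    def test_opposite_strands_never_merge(self):
        hits = [make_hit(frame=1, sstart=100, send=400),
                make_hit(frame=-2, sstart=450, send=700)]
        assert len(merge_hits(hits, max_gap_nt=10_000)) == 2

    def test_frames_may_differ_within_locus(self):
        hits = [make_hit(frame=1, sstart=100, send=400),
                make_hit(frame=2, sstart=450, send=700)]
        loci = merge_hits(hits, max_gap_nt=1000)
        assert len(loci) == 1 and len(loci[0].member_hits) == 2

    def test_evalue_merge_threshold_is_strict(self):
        hits = [make_hit(sstart=0, send=300, evalue=1e-5)]  # not < 1e-5
        assert merge_hits(hits, evalue_merge=1e-5) == []

    def test_idempotent_and_order_invariant(self):
        hits = [make_hit(sstart=s, send=s + 300, evalue=1e-8)
                for s in (0, 200, 2000, 5000, 5100)]
        loci = merge_hits(hits, max_gap_nt=500)
        for seed in range(5):
            shuffled = hits[:]
            random.Random(seed).shuffle(shuffled)
            again = merge_hits(shuffled, max_gap_nt=500)
            assert [(l.locus_id, l.start, l.end) for l in again] == \
                   [(l.locus_id, l.start, l.end) for l in loci]
        remerged = merge_hits([h for l in loci for h in l.member_hits], max_gap_nt=500)
        assert [(l.start, l.end) for l in remerged] == [(l.start, l.end) for l in loci]

    def test_locus_contains_all_member_hits(self):
        hits = [make_hit(sstart=s, send=s + 300) for s in (0, 100, 250)]
        for locus in merge_hits(hits):
            for h in locus.member_hits:
                assert locus.start <= h.subject_start < h.subject_end <= locus.end


class TestStringency:
    @pytest.mark.parametrize("length,evalue,expected", [
        (349, 1e-20, False),   # length boundary: >= 350 required
        (350, 1e-11, True),    # both at the passing edge
        (5000, 1e-9, False),   # e-value boundary is strict
        (350, 1e-10, False),   # e-value exactly at the cutoff fails
    ])
    def test_boundaries(self, length, evalue, expected):
        loci = merge_hits([make_hit(sstart=0, send=length, evalue=evalue)],
                          evalue_merge=1.0)
        flagged = apply_stringency(loci)
        assert len(flagged) == 1  # flagged, never removed
        assert flagged[0].passes_stringent is expected


@pytest.fixture(scope="module")
def planted_locus(scheme):
    """One clean implant, catalogued from a real search."""
    from evescan.search import seeded_translated_search

    virus = sim.simulate_totivirus(21)
    host = sim.random_host_genome(21, {"c1": 50_000})
    genome, truth = sim.implant_eves(
        21, host, virus.proteins, n_loci=1, identity_range=(0.9, 0.9),
        frameshift_prob=0.0, strand_mix=0.0, fragment_aa_range=(150, 150),
        min_spacing=2000,
    )
    hits = seeded_translated_search(virus.proteins, genome, scheme)
    loci = merge_hits(hits)
    assert len(loci) == 1
    return virus, genome, truth, loci[0]


class TestReciprocalAndAssignment:
    def test_planted_viral_locus_is_kept(self, planted_locus, scheme):
        virus, genome, _, locus = planted_locus
        decoys = sim.random_decoy_proteins(21, n=20)
        out = reciprocal_filter(locus, genome, decoys, virus.proteins, scheme)
        assert out.reciprocal_kept is True and not out.reciprocal_tie

    def test_decoy_derived_locus_is_dropped(self, scheme):
        """A locus that is actually a decoy-protein insertion must lose the
        reciprocal comparison even though it weakly resembles a viral protein."""
        rng_decoys = sim.random_decoy_proteins(33, n=5, length_range=(200, 200))
        decoy = rng_decoys.records[0]
        # a 'viral' protein 60% identical to the decoy: decoy wins reciprocity
        mutated, _ = sim._decay_protein(sim._rng(33, 77), decoy.sequence, 0.6)
        viral = ViralProteinSet([ProteinRecord("virusP", "vX", "CP", mutated)])
        host = sim.random_host_genome(33, {"c1": 20_000})
        genome, truth = sim.implant_eves(
            33, host, ViralProteinSet([decoy]), n_loci=1, identity_range=(1.0, 1.0),
            frameshift_prob=0.0, strand_mix=0.0, fragment_aa_range=(200, 200),
            min_spacing=1000,
        )
        from evescan.search import seeded_translated_search
        from evescan.catalog import merge_hits as mh

        hits = seeded_translated_search(viral, genome, scheme, evalue_max=1.0)
        loci = mh(hits, evalue_merge=1.0)
        assert loci, "weak viral similarity should still seed a candidate locus"
        out = reciprocal_filter(loci[0], genome, rng_decoys, viral, scheme)
        assert out.reciprocal_kept is False

    def test_empty_decoy_set_keeps_with_warning(self, planted_locus, scheme):
        virus, genome, _, locus = planted_locus
        empty = ViralProteinSet([])
        with pytest.warns(UserWarning):
            out = reciprocal_filter(locus, genome, empty, virus.proteins, scheme)
        assert out.reciprocal_kept is True

    def test_best_hit_assignment_prefers_closer_virus(self, planted_locus, scheme):
        virus, genome, truth, locus = planted_locus
        src = virus.proteins.get(truth.loci[0].source_protein_id)
        # second panel member: a far-decayed copy of the same protein
        far, _ = sim._decay_protein(sim._rng(21, 88), src.sequence, 0.55)
        panel = ViralProteinSet(list(virus.proteins)
                                + [ProteinRecord("farP", "virusB", src.gene_label, far)])
        out = assign_best_hit(locus, genome, panel, scheme)
        assert out.best_hit is not None
        assert out.best_hit.protein_id == src.protein_id
        assert out.best_hit.gene_label == src.gene_label
        # implant decayed to 90% aa identity; the reported value is the best
        # alignment's own identity, which flank extension can dilute a little
        assert 75.0 <= out.best_hit.percent_identity <= 100.0

    def test_no_hit_leaves_locus_unassigned(self, planted_locus, scheme):
        _, genome, _, locus = planted_locus
        unrelated = sim.random_decoy_proteins(55, n=2)
        out = assign_best_hit(locus, genome, unrelated, scheme)
        assert out.best_hit is None


class TestOrfPrediction:
    def _locus(self, contig_len, start, end):
        return merge_hits([make_hit(sstart=start, send=end)])[0]

    def test_orf_spanning_locus_boundary_found(self):
        rng = sim._rng(41, 1)
        # build: background | ORF(600 nt incl stop) | background; locus covers
        # only the ORF's 3' part, so the call crosses into the 5' flank
        prot = "M" + sim.random_aa(rng, 198)
        orf = sim.back_translate(rng, prot) + "TAA"
        assert len(orf) == 600
        left = sim.random_nt(rng, 3000)
        right = sim.random_nt(rng, 3000)
        seq = left + orf + right
        genome = GenomeAssembly({"c1": seq})
        locus = self._locus(len(seq), 3300, 3650)  # 3' half of the ORF
        calls = predict_orf_with_flanks(locus, genome, flank_nt=2000, min_orf_nt=550)
        overlapping = [c for c in calls if c.overlaps_locus]
        assert any(c.orf_start == 3000 and c.orf_end == 3600 and c.strand == "+"
                   for c in overlapping)
        primary = [c for c in calls if c.is_primary]
        assert len(primary) == 1
        assert primary[0].protein.startswith("M") and "*" not in primary[0].protein
        assert primary[0].length_nt % 3 == 0

    def test_window_clipped_at_contig_start(self):
        rng = sim._rng(42, 1)
        seq = sim.random_nt(rng, 1500)
        genome = GenomeAssembly({"c1": seq})
        locus = self._locus(1500, 10, 400)
        # must not raise despite flank extending past position 0 and the end
        calls = predict_orf_with_flanks(locus, genome, flank_nt=2000, min_orf_nt=30)
        for c in calls:
            assert 0 <= c.orf_start < c.orf_end <= 1500

    def test_no_atg_gives_empty(self):
        genome = GenomeAssembly({"c1": "C" * 900})
        locus = self._locus(900, 100, 500)
        assert predict_orf_with_flanks(locus, genome, min_orf_nt=30) == []

    def test_minus_strand_orf_coordinates(self):
        rng = sim._rng(43, 1)
        prot = "M" + sim.random_aa(rng, 98)
        orf = sim.back_translate(rng, prot) + "TGA"
        seq = sim.random_nt(rng, 800) + reverse_complement(orf) + sim.random_nt(rng, 800)
        genome = GenomeAssembly({"c1": seq})
        locus = self._locus(len(seq), 820, 1050)
        calls = predict_orf_with_flanks(locus, genome, flank_nt=500, min_orf_nt=290)
        minus = [c for c in calls if c.strand == "-" and c.orf_start == 800]
        assert minus and minus[0].orf_end == 800 + 300
        assert minus[0].protein == prot
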