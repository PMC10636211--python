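"""Generator contracts: determinism, construction guarantees, and the
statistical expectations the downstream analyses rely on."""

import numpy as np
import pytest

from evescan import simulate as sim
from evescan.polymorphism import OrthologAlignment, p_distance
from evescan.search import translate


class TestTotivirus:
    def test_two_orfs_translate_to_returned_proteins(self):
        v = sim.simulate_totivirus(1, 7000, 700, 900)
        assert len(v.genome) == 7000
        assert [o[2] for o in v.orfs] == ["CP", "RdRp"]
        for start, end, label in v.orfs:
            aa = translate(v.genome[start:end])
            assert aa.startswith("M") and aa.endswith("*") and "*" not in aa[:-1]
            rec = next(r for r in v.proteins if r.gene_label == label)
            assert aa[:-1] == rec.sequence

    def test_same_seed_is_byte_identical(self):
        a, b = sim.simulate_totivirus(7), sim.simulate_totivirus(7)
        assert a.genome == b.genome and a.orfs == b.orfs
        assert [r.sequence for r in a.proteins] == [r.sequence for r in b.proteins]

    def test_infeasible_lengths_error(self):
        with pytest.raises(ValueError):
            sim.simulate_totivirus(1, genome_length=5000, cp_length_aa=3000, rdrp_length_aa=900)


@pytest.fixture(scope="module")
def implanted():
    virus = sim.simulate_totivirus(2)
    host = sim.random_host_genome(2, {"chr1": 1_000_000})
    return sim.implant_eves(2, host, virus.proteins, n_loci=20)


@pytest.fixture(scope="module")
def cohort():
    virus = sim.simulate_totivirus(5)
    host = sim.random_host_genome(5, {"chr1": 500_000})
    genome, truth = sim.implant_eves(5, host, virus.proteins, n_loci=5)
    inds = [f"i{k}" for k in range(4)]
    sim.assign_presence(5, truth, inds)
    return genome, truth, inds


class TestImplantEves:

    def test_twenty_nonoverlapping_truth_intervals(self, implanted):
        genome, truth = implanted
        assert len(truth.loci) == 20
        ivs = sorted((l.start, l.end) for l in truth.loci)
        assert all(a[1] <= b[0] for a, b in zip(ivs, ivs[1:]))
        assert all(0 <= l.start < l.end <= len(genome.contigs[l.contig_id])
                   for l in truth.loci)

    def test_truth_consistency_translation_attains_identity(self, implanted):
        """Frameshift-free implants translate back to the recorded decayed
        fragment, whose identity to the source matches the recorded value."""
        from evescan.io import reverse_complement

        genome, truth = implanted
        virus = sim.simulate_totivirus(2)
        checked = 0
        for l in truth.loci:
            if l.n_frameshifts:
                continue
            nt = genome.contigs[l.contig_id][l.start:l.end]
            if l.strand == "-":
                nt = reverse_complement(nt)
            assert translate(nt) == l.fragment_aa
            src = virus.proteins.get(l.source_protein_id).sequence
            frag = src[l.fragment_aa_start:l.fragment_aa_end]
            ident = sum(a == b for a, b in zip(frag, l.fragment_aa)) / len(frag)
            assert ident == pytest.approx(l.identity_realized, abs=1 / len(frag))
            checked += 1
        assert checked >= 5

    def test_perfect_identity_no_frameshift_translates_exactly(self):
        virus = sim.simulate_totivirus(3)
        host = sim.random_host_genome(3, {"chr1": 200_000})
        genome, truth = sim.implant_eves(
            3, host, virus.proteins, n_loci=3,
            identity_range=(1.0, 1.0), frameshift_prob=0.0,
        )
        for l in truth.loci:
            src = virus.proteins.get(l.source_protein_id).sequence
            assert l.fragment_aa == src[l.fragment_aa_start:l.fragment_aa_end]
            assert l.identity_realized == 1.0

    def test_determinism_and_strand_mix(self, implanted):
        _, truth = implanted
        virus = sim.simulate_totivirus(2)
        host = sim.random_host_genome(2, {"chr1": 1_000_000})
        _, truth2 = sim.implant_eves(2, host, virus.proteins, n_loci=20)
        assert [(l.start, l.end, l.strand) for l in truth.loci] == \
               [(l.start, l.end, l.strand) for l in truth2.loci]
        strands = {l.strand for l in truth.loci}
        assert strands == {"+", "-"}

    def test_cannot_place_errors(self):
        virus = sim.simulate_totivirus(4)
        host = sim.random_host_genome(4, {"tiny": 5000})
        with pytest.raises(ValueError):
            sim.implant_eves(4, host, virus.proteins, n_loci=10)


class TestReadsAndVariants:
    def test_poisson_read_count_expectation(self, cohort):
        genome, truth, inds = cohort
        placements = sim.simulate_read_alignments(
            5, truth, inds, depth_present=30, depth_absent=0, read_length=100,
            contig_lengths={c: len(s) for c, s in genome.contigs.items()},
        )
        for ind in inds:
            for l in truth.loci:
                n = sum(1 for p in placements
                        if p.individual_id == ind and l.start - 100 < p.start < l.end)
                expected = 30 * (l.length_nt + 99) / 100
                if truth.presence[ind][l.locus_id]:
                    assert abs(n - expected) < 4 * np.sqrt(expected)
                else:
                    assert n == 0

    def test_read_determinism(self, cohort):
        genome, truth, inds = cohort
        kw = dict(depth_present=30, depth_absent=0, read_length=100)
        assert sim.simulate_read_alignments(9, truth, inds, **kw) == \
               sim.simulate_read_alignments(9, truth, inds, **kw)

    def test_variant_density_expectation(self, cohort):
        genome, truth, inds = cohort
        sites = sim.simulate_variants(5, truth, genome, 6.0, inds)
        assert sites == sim.simulate_variants(5, truth, genome, 6.0, inds)
        counts = []
        for ind in inds:
            for l in truth.loci:
                if not truth.presence[ind][l.locus_id]:
                    continue
                n = sum(1 for s in sites
                        if s.individual_id == ind and l.start <= s.position < l.end)
                counts.append(n / (l.length_nt / 1000))
        assert np.mean(counts) == pytest.approx(6.0, abs=1.5)
        assert sim.simulate_variants(5, truth, genome, 0.0, inds) == []


class TestOrthologs:
    def test_rate_zero_rows_identical(self):
        alns, labels = sim.simulate_ortholog_alignments(
            1, 5, length=500, rate_classes=[("frozen", 1.0, 0.0)])
        assert len(alns) == 5
        for rows in alns.values():
            assert rows[0] == rows[1] == rows[2]

    def test_realized_p_distance_matches_rate(self):
        alns, _ = sim.simulate_ortholog_alignments(
            1, 6, length=10_000, rate_classes=[("mid", 1.0, 0.3)])
        for oid, rows in alns.items():
            assert p_distance(OrthologAlignment(oid, rows)) == pytest.approx(0.3, abs=0.02)

    def test_count_contract_and_labels(self):
        alns, labels = sim.simulate_ortholog_alignments(2, 1462, length=60)
        assert len(alns) == 1462 and len(labels) == 1462
        assert sum(v == "fast" for v in labels.values()) == 73
        assert sum(v == "slow" for v in labels.values()) == 73


class TestSrnaReads:
    def test_pirna_band_mass_by_length_mean(self):
        tx = sim.random_nt(np.random.default_rng(0), 2000)
        long_reads = sim.simulate_srna_reads(1, tx, 500, 26, 1)
        frac = np.mean([24 <= len(r) <= 29 for r in long_reads])
        assert frac >= 0.9
        short_reads = sim.simulate_srna_reads(1, tx, 500, 21, 1)
        assert np.mean([24 <= len(r) <= 29 for r in short_reads]) < 0.1

    def test_reads_are_exact_substrings_of_either_strand(self):
        from evescan.io import reverse_complement

        tx = sim.random_nt(np.random.default_rng(1), 500)
        rc = reverse_complement(tx)
        for r in sim.simulate_srna_reads(2, tx, 100):
            assert 18 <= len(r) <= 30
            assert r in tx or r in rc
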