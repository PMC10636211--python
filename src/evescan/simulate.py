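"""Synthetic inputs with known ground truth.

Every generator emulates the statistical structure the analysis assumes:
a totivirus-like genome with two ORFs (CP, RdRp); host contigs carrying
mutationally decayed viral fragments on either strand; per-individual read
placements at controlled depth over loci that are present or absent per
individual; per-individual variant sets at a controlled site density;
three-taxon ortholog alignments at controlled substitution rates; and
small-RNA read sets with controlled length distributions.

Determinism: a single integer seed drives one named generator per
simulator (``SeedSequence([seed, stream])``), so adding one simulator does
not shift another's random stream.

Deliberate simplifications: back-translation uses uniform synonymous
codons (codon usage is irrelevant to protein-space detection), protein
decay draws substitutions uniformly over non-identical residues, and reads
carry no sequencing errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io import (
    GenomeAssembly,
    ProteinRecord,
    ReadPlacement,
    VariantSite,
    ViralProteinSet,
    reverse_complement,
)

# named sub-streams, one per simulator
_STREAM_VIRUS = 1
_STREAM_HOST = 2
_STREAM_IMPLANT = 3
_STREAM_READS = 4
_STREAM_VARIANTS = 5
_STREAM_ORTHOLOGS = 6
_STREAM_SRNA = 7
_STREAM_DECOY = 8
_STREAM_PRESENCE = 9

_NT = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _codons_by_aa() -> dict[str, list[str]]:
    table = unambiguous_dna_by_id[1]
    rev: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        rev.setdefault(aa, []).append(codon)
    return rev


_REV_TABLE = _codons_by_aa()


def random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(_NT[rng.integers(0, 4, size=length)])


def random_aa(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def back_translate(rng: np.random.Generator, protein: str) -> str:
    """Nucleotide sequence translating to ``protein``, uniform synonymous codons."""
    return "".join(rng.choice(_REV_TABLE[aa]) for aa in protein)


# ---------------------------------------------------------------------------
# truth records

@dataclass
class ImplantedLocus:
    locus_id: str
    contig_id: str
    start: int
    end: int  # half-open, final coordinates after any indels
    strand: str  # '+' or '-'
    source_protein_id: str
    fragment_aa_start: int
    fragment_aa_end: int
    identity_target: float
    identity_realized: float
    n_frameshifts: int
    fragment_aa: str  # decayed protein fragment actually implanted

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class SimTruth:
    """Ground truth shared by the acceptance tests."""

    loci: list[ImplantedLocus] = field(default_factory=list)
    presence: dict[str, dict[str, bool]] = field(default_factory=dict)  # individual -> locus -> bool
    variant_density: dict[str, float] = field(default_factory=dict)  # locus -> sites per kb
    rate_classes: dict[str, str] = field(default_factory=dict)  # ortholog -> class name

    def locus(self, locus_id: str) -> ImplantedLocus:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(locus_id)


# ---------------------------------------------------------------------------
# virus and host genomes

@dataclass
class SimulatedVirus:
    genome: str
    proteins: ViralProteinSet
    orfs: list[tuple[int, int, str]]  # (start, end, gene_label), half-open nt


def simulate_totivirus(
    seed: int,
    genome_length: int = 7000,
    cp_length_aa: int = 700,
    rdrp_length_aa: int = 900,
    virus_id: str = "ToLV-sim1",
) -> SimulatedVirus:
    """A totivirus-like genome: one RNA segment with two intact ORFs (CP, RdRp).

    Each ORF is ATG + coding codons + stop; translations (including the
    initial M) are returned as the CP and RdRp protein records.
    """
    if cp_length_aa <= 0 or rdrp_length_aa <= 0 or genome_length <= 0:
        raise ValueError("lengths must be positive")
    orf_nt = 3 * (cp_length_aa + 1) + 3 * (rdrp_length_aa + 1)
    overhead = genome_length - orf_nt
    if overhead < 60:
        raise ValueError(
            f"genome_length={genome_length} cannot hold CP {cp_length_aa} aa + "
            f"RdRp {rdrp_length_aa} aa plus untranslated overhead"
        )
    rng = _rng(seed, _STREAM_VIRUS)
    leader = 20 + int(rng.integers(0, overhead - 40 + 1))
    spacer = int(rng.integers(10, max(11, overhead - leader - 10)))
    spacer = min(spacer, overhead - leader - 10)
    proteins = []
    orf_seqs = []
    for label, length_aa in (("CP", cp_length_aa), ("RdRp", rdrp_length_aa)):
        prot = "M" + random_aa(rng, length_aa - 1)
        stop = str(rng.choice(["TAA", "TAG", "TGA"]))
        orf_seqs.append(back_translate(rng, prot) + stop)
        proteins.append(ProteinRecord(f"{virus_id}_{label}", virus_id, label, prot))
    cp_start = leader
    cp_end = cp_start + len(orf_seqs[0])
    rdrp_start = cp_end + spacer
    rdrp_end = rdrp_start + len(orf_seqs[1])
    trailer = genome_length - rdrp_end
    genome = (
        random_nt(rng, leader) + orf_seqs[0] + random_nt(rng, spacer)
        + orf_seqs[1] + random_nt(rng, trailer)
    )
    assert len(genome) == genome_length
    orfs = [(cp_start, cp_end, "CP"), (rdrp_start, rdrp_end, "RdRp")]
    return SimulatedVirus(genome, ViralProteinSet(proteins), orfs)


def random_host_genome(seed: int, contig_lengths: dict[str, int]) -> GenomeAssembly:
    """Random ACGT host contigs (EVE-free background)."""
    rng = _rng(seed, _STREAM_HOST)
    return GenomeAssembly({cid: random_nt(rng, n) for cid, n in contig_lengths.items()})


def random_decoy_proteins(
    seed: int, n: int = 50, length_range: tuple[int, int] = (200, 400)
) -> ViralProteinSet:
    """Random host/background proteome stand-in for the reciprocal filter."""
    rng = _rng(seed, _STREAM_DECOY)
    recs = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        recs.append(ProteinRecord(f"decoy{i:03d}", "", "other", random_aa(rng, length)))
    return ViralProteinSet(recs)


# ---------------------------------------------------------------------------
# EVE implantation

def _decay_protein(rng: np.random.Generator, fragment: str, identity: float) -> tuple[str, float]:
    """Substitute uniformly chosen positions until the target aa identity."""
    n = len(fragment)
    n_sub = int(round((1.0 - identity) * n))
    n_sub = min(n_sub, n)
    positions = rng.choice(n, size=n_sub, replace=False) if n_sub else np.array([], dtype=int)
    seq = list(fragment)
    for p in positions:
        alternatives = _AA20.replace(seq[p], "")
        seq[p] = str(rng.choice(list(alternatives)))
    realized = 1.0 - n_sub / n
    return "".join(seq), realized


def implant_eves(
    seed: int,
    host_genome: GenomeAssembly,
    proteins: ViralProteinSet,
    n_loci: int = 20,
    identity_range: tuple[float, float] = (0.6, 1.0),
    frameshift_prob: float = 0.5,
    strand_mix: float = 0.5,
    fragment_aa_range: tuple[int, int] = (135, 830),
    min_spacing: int = 3000,
) -> tuple[GenomeAssembly, SimTruth]:
    """Overwrite host contigs with decayed viral fragments; record exact truth.

    Each locus is a back-translated protein fragment mutated to a sampled
    aa identity, optionally carrying 1-2 single-base indels (frameshifts),
    written onto the + or - strand.  Implants are placed non-overlapping
    with at least ``min_spacing`` nt between them; contig lengths are
    unchanged (the implant replaces background sequence).
    """
    lo, hi = identity_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("identity_range must lie in (0, 1]")
    rng = _rng(seed, _STREAM_IMPLANT)
    contigs = {cid: list(seq) for cid, seq in host_genome.contigs.items()}
    contig_ids = list(contigs)
    # distribute loci round-robin, longest contigs first
    lengths = np.array([len(contigs[c]) for c in contig_ids], dtype=float)
    order = np.argsort(-lengths)
    counts = np.zeros(len(contig_ids), dtype=int)
    for i in range(n_loci):
        counts[order[i % len(contig_ids)]] += 1
    truth = SimTruth()
    locus_no = 0
    max_frag_nt = 3 * fragment_aa_range[1] + 2
    for ci, cid in enumerate(contig_ids):
        k = int(counts[ci])
        if k == 0:
            continue
        clen = len(contigs[cid])
        slot = clen // k
        if slot < max_frag_nt + min_spacing:
            raise ValueError(
                f"contig {cid!r} too short to place {k} non-overlapping loci "
                f"with spacing {min_spacing}"
            )
        for s in range(k):
            rec = proteins.records[int(rng.integers(0, len(proteins.records)))]
            frag_hi = min(fragment_aa_range[1], len(rec.sequence))
            frag_lo = min(fragment_aa_range[0], frag_hi)
            frag_len = int(rng.integers(frag_lo, frag_hi + 1))
            frag_start = int(rng.integers(0, len(rec.sequence) - frag_len + 1))
            fragment = rec.sequence[frag_start:frag_start + frag_len]
            identity = float(rng.uniform(lo, hi))
            decayed, realized = _decay_protein(rng, fragment, identity)
            nt = back_translate(rng, decayed)
            n_fs = 0
            if rng.random() < frameshift_prob:
                n_fs = int(rng.integers(1, 3))
                for _ in range(n_fs):
                    p = int(rng.integers(1, len(nt) - 1))
                    if rng.random() < 0.5:
                        nt = nt[:p] + str(rng.choice(["A", "C", "G", "T"])) + nt[p:]
                    else:
                        nt = nt[:p] + nt[p + 1:]
            strand = "-" if rng.random() < strand_mix else "+"
            insert = reverse_complement(nt) if strand == "-" else nt
            lo_pos = s * slot + min_spacing // 2
            hi_pos = (s + 1) * slot - len(insert) - min_spacing // 2
            if hi_pos <= lo_pos:
                hi_pos = lo_pos + 1
            start = int(rng.integers(lo_pos, hi_pos))
            end = start + len(insert)
            contigs[cid][start:end] = list(insert)
            locus_no += 1
            truth.loci.append(ImplantedLocus(
                locus_id=f"locus{locus_no:02d}",
                contig_id=cid,
                start=start,
                end=end,
                strand=strand,
                source_protein_id=rec.protein_id,
                fragment_aa_start=frag_start,
                fragment_aa_end=frag_start + frag_len,
                identity_target=identity,
                identity_realized=realized,
                n_frameshifts=n_fs,
                fragment_aa=decayed,
            ))
    assembly = GenomeAssembly({cid: "".join(chars) for cid, chars in contigs.items()})
    return assembly, truth


# ---------------------------------------------------------------------------
# read placements, variants

def assign_presence(
    seed: int, truth: SimTruth, individuals: list[str], presence_prob: float = 0.5
) -> None:
    """Fill the per-individual presence map in the truth table (in place)."""
    rng = _rng(seed, _STREAM_PRESENCE)
    truth.presence = {
        ind: {l.locus_id: bool(rng.random() < presence_prob) for l in truth.loci}
        for ind in individuals
    }


def simulate_read_alignments(
    seed: int,
    truth: SimTruth,
    individuals: list[str],
    depth_present: float = 30.0,
    depth_absent: float = 0.0,
    read_length: int = 100,
    contig_lengths: dict[str, int] | None = None,
    background_depth: float = 0.0,
) -> list[ReadPlacement]:
    """Poisson-tiled reads over each locus per individual.

    For a locus of length L, read starts are drawn uniformly over
    [start - read_length + 1, end) with count ~ Poisson(d * (L + rl - 1) / rl),
    so the expected per-base depth at interior positions equals d
    (``depth_present`` where the truth says present, ``depth_absent``
    otherwise).  Optional ``background_depth`` tiles whole contigs, which
    feeds the genome-wide individual QC.
    """
    if depth_present < 0 or depth_absent < 0 or background_depth < 0:
        raise ValueError("depths must be >= 0")
    if not truth.presence:
        raise ValueError("truth.presence is empty; call assign_presence first")
    rng = _rng(seed, _STREAM_READS)
    rl = read_length
    placements: list[ReadPlacement] = []
    contig_lengths = contig_lengths or {}
    for ind in individuals:
        for locus in truth.loci:
            present = truth.presence[ind][locus.locus_id]
            d = depth_present if present else depth_absent
            if d <= 0:
                continue
            L = locus.length_nt
            span = L + rl - 1
            n_reads = int(rng.poisson(d * span / rl))
            clen = contig_lengths.get(locus.contig_id, 0)
            for _ in range(n_reads):
                s = int(rng.integers(locus.start - rl + 1, locus.end))
                e = s + rl
                if s < 0:
                    s = 0
                if clen and e > clen:
                    e = clen
                if e - s <= 0:
                    continue
                placements.append(ReadPlacement(ind, locus.contig_id, s, e - s))
        if background_depth > 0:
            for cid, clen in contig_lengths.items():
                n_reads = int(rng.poisson(background_depth * clen / rl))
                starts = rng.integers(0, max(1, clen - rl + 1), size=n_reads)
                for s in starts:
                    placements.append(ReadPlacement(ind, cid, int(s), min(rl, clen - int(s))))
    return placements


def simulate_variants(
    seed: int,
    truth: SimTruth,
    genome: GenomeAssembly,
    sites_per_kb_by_locus: dict[str, float] | float,
    individuals: list[str] | None = None,
) -> list[VariantSite]:
    """Uniform variant positions within each locus at the stated density.

    Per individual and locus the number of distinct sites is
    Poisson(density * L / 1000); individuals for which the presence map says
    the locus is absent get no sites.
    """
    rng = _rng(seed, _STREAM_VARIANTS)
    if individuals is None:
        individuals = sorted(truth.presence)
    sites: list[VariantSite] = []
    for ind in individuals:
        for locus in truth.loci:
            if truth.presence and not truth.presence.get(ind, {}).get(locus.locus_id, True):
                continue
            density = (
                sites_per_kb_by_locus.get(locus.locus_id, 0.0)
                if isinstance(sites_per_kb_by_locus, dict)
                else float(sites_per_kb_by_locus)
            )
            if density < 0:
                raise ValueError("variant densities must be >= 0")
            if density == 0:
                continue
            L = locus.length_nt
            n = int(rng.poisson(density * L / 1000.0))
            n = min(n, L)
            if n == 0:
                continue
            positions = np.sort(rng.choice(L, size=n, replace=False)) + locus.start
            seq = genome.contigs[locus.contig_id]
            for p in positions:
                ref = seq[p]
                if ref == "N":
                    ref = "A"
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                sites.append(VariantSite(ind, locus.contig_id, int(p), ref, alt, True))
    return sites


# ---------------------------------------------------------------------------
# ortholog alignments

def _pair_rate_to_site_rate(r: float) -> float:
    """Per-row mutation probability m giving pairwise difference fraction r.

    Rows mutate independently from a common ancestor, each site with
    probability m to a uniformly chosen different base; two rows then differ
    at a site with probability 2m(1-m) + (2/3)m^2.  Solving for m:
    (4/3)m^2 - 2m + r = 0.
    """
    if not 0.0 <= r <= 0.74:
        raise ValueError("pairwise rate must be in [0, 0.74]")
    return (2.0 - float(np.sqrt(4.0 - 16.0 * r / 3.0))) * 3.0 / 8.0


def simulate_ortholog_alignments(
    seed: int,
    n_orthologs: int,
    length: int = 10_000,
    taxa: int = 3,
    rate_classes: list[tuple[str, float, float]] | None = None,
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Gap-free ``taxa``-row alignments with controlled pairwise p-distance.

    ``rate_classes`` is a list of (class_name, fraction, pairwise_rate);
    fractions must sum to 1.  Returns (alignments keyed by ortholog id,
    truth class labels).  Expected pairwise difference fraction of every
    row pair equals the assigned rate.
    """
    if rate_classes is None:
        rate_classes = [("fast", 0.05, 0.4), ("mid", 0.90, 0.2), ("slow", 0.05, 0.05)]
    fractions = [f for _, f, _ in rate_classes]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("rate-class fractions must sum to 1")
    counts = [int(np.floor(f * n_orthologs)) for f in fractions]
    counts[int(np.argmax(fractions))] += n_orthologs - sum(counts)
    rng = _rng(seed, _STREAM_ORTHOLOGS)
    alignments: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    og = 0
    for (name, _frac, rate), count in zip(rate_classes, counts):
        m = _pair_rate_to_site_rate(rate)
        for _ in range(count):
            og += 1
            oid = f"og{og:05d}"
            anc = rng.integers(0, 4, size=length)
            rows = []
            for _t in range(taxa):
                row = anc.copy()
                mask = rng.random(length) < m
                shift = rng.integers(1, 4, size=int(mask.sum()))
                row[mask] = (row[mask] + shift) % 4
                rows.append("".join(_NT[row]))
            alignments[oid] = rows
            labels[oid] = name
    return alignments, labels


# ---------------------------------------------------------------------------
# small RNA reads

def simulate_srna_reads(
    seed: int,
    transcript: str,
    n_reads: int = 200,
    length_mean: float = 26.0,
    length_sd: float = 1.0,
) -> list[str]:
    """Exact substrings of the transcript (either strand) with clipped-normal
    lengths on [18, 30]."""
    if len(transcript) < 30:
        raise ValueError("transcript must be at least 30 nt")
    rng = _rng(seed, _STREAM_SRNA)
    lengths = np.clip(np.rint(rng.normal(length_mean, length_sd, size=n_reads)), 18, 30).astype(int)
    rc = reverse_complement(transcript)
    reads = []
    for L in lengths:
        src = transcript if rng.random() < 0.5 else rc
        start = int(rng.integers(0, len(src) - L + 1))
        reads.append(src[start:start + int(L)])
    return reads
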