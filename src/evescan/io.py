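"""Readers/writers and shared record conventions for the pipeline.

All internal coordinates are 0-based half-open on the forward strand;
strand is stored separately as ``+``/``-``.  1-based SAM/VCF coordinates
are converted at the boundary, never inside the pipeline.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO

_NT_KEEP = set("ACGTN")
_AA_KEEP = set("ACDEFGHIKLMNPQRSTVWYX")

GENE_LABELS = ("CP", "RdRp", "other")


@dataclass
class GenomeAssembly:
    """Host genome: ordered map of contig id to uppercase ACGTN sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not cid:
                raise ValueError("empty contig id")
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r}")
            bad = set(seq) - _NT_KEEP
            if bad:
                raise ValueError(f"contig {cid!r} has non-ACGTN characters: {sorted(bad)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    source_virus_id: str
    gene_label: str  # CP | RdRp | other
    sequence: str

    def __post_init__(self) -> None:
        if self.gene_label not in GENE_LABELS:
            raise ValueError(f"gene_label must be one of {GENE_LABELS}")
        if "*" in self.sequence:
            raise ValueError(f"protein {self.protein_id!r} contains a stop character")
        bad = set(self.sequence) - _AA_KEEP
        if bad:
            raise ValueError(f"protein {self.protein_id!r} has invalid residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ViralProteinSet:
    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        ids = [r.protein_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate protein ids")

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, protein_id: str) -> ProteinRecord:
        for r in self.records:
            if r.protein_id == protein_id:
                return r
        raise KeyError(protein_id)


@dataclass(frozen=True)
class ReadPlacement:
    """One mapped read: half-open interval [start, start+length) on a contig."""

    individual_id: str
    contig_id: str
    start: int
    length: int
    multimap_count: int = 1

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.multimap_count < 1:
            raise ValueError("multimap_count must be >= 1")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class VariantSite:
    individual_id: str
    contig_id: str
    position: int  # 0-based
    ref_allele: str
    alt_allele: str
    genotype_is_nonref: bool = True

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


def normalize_nucleotide(seq: str) -> str:
    """Uppercase; every character outside ACGT (incl. U and ambiguity codes) -> N."""
    up = seq.upper()
    return "".join(c if c in "ACGT" else "N" for c in up)


def normalize_protein(seq: str) -> str:
    """Uppercase; residues outside the 20 amino acids -> X.  Stops are an error."""
    up = seq.upper()
    if "*" in up:
        raise ValueError("protein sequence contains a stop character")
    return "".join(c if c in _AA_KEEP else "X" for c in up)


def _parse_protein_header(description: str) -> tuple[str, str, str]:
    """Header convention: ``>id virus=<virus_id> gene=<CP|RdRp|other>``."""
    parts = description.split()
    pid = parts[0]
    virus, gene = "", "other"
    for tok in parts[1:]:
        if tok.startswith("virus="):
            virus = tok[len("virus="):]
        elif tok.startswith("gene="):
            g = tok[len("gene="):]
            gene = g if g in GENE_LABELS else "other"
    return pid, virus, gene


def read_fasta(path: str | Path, moltype: str = "nucleotide") -> GenomeAssembly | ViralProteinSet:
    """Read a FASTA file as a :class:`GenomeAssembly` or :class:`ViralProteinSet`.

    moltype: ``nucleotide`` (default) or ``protein``.  Records are kept in
    file order; sequences are case-normalized and ambiguity codes collapse
    to N (nucleotide) / X (protein).  Duplicate ids and empty records are
    hard errors.
    """
    path = Path(path)
    if moltype not in ("nucleotide", "protein"):
        raise ValueError("moltype must be 'nucleotide' or 'protein'")
    if moltype == "nucleotide":
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate id {rec.id!r} in {path}")
            seq = normalize_nucleotide(str(rec.seq))
            if not seq:
                raise ValueError(f"empty record {rec.id!r} in {path}")
            contigs[rec.id] = seq
        return GenomeAssembly(contigs)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid, virus, gene = _parse_protein_header(rec.description)
        if pid in seen:
            raise ValueError(f"duplicate id {pid!r} in {path}")
        seen.add(pid)
        seq = normalize_protein(str(rec.seq))
        if not seq:
            raise ValueError(f"empty record {pid!r} in {path}")
        records.append(ProteinRecord(pid, virus, gene, seq))
    return ViralProteinSet(records)


def write_fasta(obj: GenomeAssembly | ViralProteinSet, path: str | Path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if isinstance(obj, GenomeAssembly):
            items: Iterable[tuple[str, str]] = obj.contigs.items()
            for cid, seq in items:
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
        else:
            for rec in obj:
                fh.write(f">{rec.protein_id} virus={rec.source_virus_id} gene={rec.gene_label}\n")
                for i in range(0, len(rec.sequence), width):
                    fh.write(rec.sequence[i:i + width] + "\n")


def read_alignments(
    path: str | Path,
    dialect: str = "tsv",
    individual_id: str | None = None,
    drop_secondary: bool = False,
) -> list[ReadPlacement]:
    """Read mapped-read placements from SAM or a plain TSV.

    SAM: unmapped records are skipped; the 1-based POS becomes a 0-based
    start and the reference-consumed CIGAR length becomes the placement
    length.  Secondary/multi-mapped alignments are retained by default
    (multi-mapped reads are kept for depth, as in the source protocol);
    pass ``drop_secondary=True`` to discard them.

    TSV columns: individual, contig, start (0-based), length, multimap_count.
    """
    path = Path(path)
    if dialect == "sam":
        placements: list[ReadPlacement] = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            sample = individual_id
            if sample is None:
                rgs = fh.header.to_dict().get("RG", [])
                sample = rgs[0].get("SM", "sample") if rgs else "sample"
            for rec in fh:
                if rec.is_unmapped:
                    continue
                if drop_secondary and (rec.is_secondary or rec.is_supplementary):
                    continue
                length = rec.reference_length
                if not length:
                    continue
                mm = 1
                if rec.has_tag("NH"):
                    mm = max(1, int(rec.get_tag("NH")))
                placements.append(
                    ReadPlacement(sample, rec.reference_name, rec.reference_start, length, mm)
                )
        return placements
    if dialect == "tsv":
        placements = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "individual":  # header row
                    continue
                try:
                    ind, contig, start, length, mm = fields[:5]
                    placements.append(ReadPlacement(ind, contig, int(start), int(length), int(mm)))
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed placement line: {line!r}") from exc
        return placements
    raise ValueError("dialect must be 'sam' or 'tsv'")


def write_alignments_tsv(placements: Iterable[ReadPlacement], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["individual", "contig", "start", "length", "multimap_count"])
        for p in placements:
            w.writerow([p.individual_id, p.contig_id, p.start, p.length, p.multimap_count])


def _vcf_sites(path: Path) -> Iterator[VariantSite]:
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for sample, call in rec.samples.items():
                gt = call.get("GT")
                if gt is None or all(a is None for a in gt):
                    warnings.warn(f"{path}: record at POS={rec.pos} sample {sample}: missing GT, skipped")
                    continue
                nonref = [a for a in gt if a not in (None, 0)]
                if not nonref:
                    continue
                alt = rec.alleles[nonref[0]]
                yield VariantSite(sample, rec.contig, rec.pos - 1, rec.ref, alt, True)


def read_variants(path: str | Path, dialect: str = "vcf") -> list[VariantSite]:
    """Read non-reference variant sites per sample from VCF (or equivalent TSV).

    One :class:`VariantSite` is emitted per record per sample whose genotype
    carries at least one non-reference allele; 1-based POS becomes 0-based.
    Records with a missing GT are skipped with a warning.

    TSV columns: individual, contig, position (0-based), ref, alt.
    """
    path = Path(path)
    if dialect == "vcf":
        return list(_vcf_sites(path))
    if dialect == "tsv":
        sites: list[VariantSite] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "individual":
                    continue
                try:
                    ind, contig, pos, ref, alt = fields[:5]
                    sites.append(VariantSite(ind, contig, int(pos), ref, alt, True))
                except (ValueError, IndexError) as exc:
                    raise ValueError(f"{path}:{lineno}: malformed variant line: {line!r}") from exc
        return sites
    raise ValueError("dialect must be 'vcf' or 'tsv'")


def write_variants_tsv(sites: Iterable[VariantSite], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["individual", "contig", "position", "ref", "alt"])
        for s in sites:
            w.writerow([s.individual_id, s.contig_id, s.position, s.ref_allele, s.alt_allele])


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
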