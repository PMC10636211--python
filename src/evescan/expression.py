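"""Transcript abundance, small-RNA size profiling, and contig triage.

FPKM normalises fragment counts by target length (kb) and library size
(millions of mapped fragments).  Small-RNA profiling maps 18-30 nt reads
to a transcript by perfect match on either strand and summarises the read
length distribution; a concentration of mapped lengths in 24-29 nt is the
piRNA signature.  Contig triage applies the three-way filter used when
screening assembled contigs for novel toti-like viruses: coverage > 20x,
length > 2000 bp, best e-value < 1e-20 (all strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import reverse_complement

PIRNA_BAND = (24, 29)
SRNA_RANGE = (18, 30)


@dataclass(frozen=True)
class ExpressionRecord:
    target_id: str
    fragments: int
    target_length_nt: int
    library_fragments: int

    @property
    def fpkm(self) -> float:
        return self.fragments / ((self.target_length_nt / 1000.0)
                                 * (self.library_fragments / 1e6))


def fpkm_quantify(
    fragment_counts: dict[str, int],
    target_lengths: dict[str, int],
    library_size: int,
) -> list[ExpressionRecord]:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    records = []
    for tid, count in fragment_counts.items():
        length = target_lengths[tid]
        if length <= 0:
            raise ValueError(f"target {tid!r} has non-positive length")
        if count < 0:
            raise ValueError("fragment counts must be >= 0")
        records.append(ExpressionRecord(tid, count, length, library_size))
    return records


@dataclass
class SrnaSizeProfile:
    target_id: str
    counts: dict[int, int]  # read length -> mapped reads
    total_mapped: int
    pirna_flag: bool

    @property
    def pirna_fraction(self) -> float:
        if self.total_mapped == 0:
            return 0.0
        lo, hi = PIRNA_BAND
        return sum(c for L, c in self.counts.items() if lo <= L <= hi) / self.total_mapped


def srna_size_profile(
    reads: list[str],
    transcript: str,
    target_id: str = "transcript",
    min_len: int = SRNA_RANGE[0],
    max_len: int = SRNA_RANGE[1],
    pirna_band: tuple[int, int] = PIRNA_BAND,
    min_reads: int = 50,
    min_fraction: float = 0.5,
) -> SrnaSizeProfile:
    """Map small-RNA reads to a transcript by perfect match (either strand)
    and profile their lengths.

    Only reads with length in [min_len, max_len] are considered; a read
    maps iff it is an exact substring of the transcript or its reverse
    complement, and counts once however many positions it matches.  The
    piRNA flag requires total_mapped >= ``min_reads`` and a fraction of
    mapped lengths in ``pirna_band`` >= ``min_fraction``.
    """
    if not transcript:
        raise ValueError("transcript must be non-empty")
    transcript = transcript.upper()
    rc = reverse_complement(transcript)
    counts = {L: 0 for L in range(min_len, max_len + 1)}
    total = 0
    for read in reads:
        read = read.upper()
        L = len(read)
        if L < min_len or L > max_len:
            continue
        if read in transcript or read in rc:
            counts[L] += 1
            total += 1
    lo, hi = pirna_band
    frac = (sum(c for L, c in counts.items() if lo <= L <= hi) / total) if total else 0.0
    flag = total >= min_reads and frac >= min_fraction
    return SrnaSizeProfile(target_id, counts, total, flag)


@dataclass(frozen=True)
class ContigTriage:
    contig_id: str
    coverage_x: float
    length_nt: int
    best_evalue: float
    kept: bool


def triage_virus_contigs(
    contigs: list[tuple[str, float, int, float]],
    min_coverage: float = 20.0,
    min_length: int = 2000,
    max_evalue: float = 1e-20,
) -> list[ContigTriage]:
    """Virus-discovery triage of assembled contigs.

    Each input is (contig_id, coverage_x, length_nt, best_evalue); a contig
    is kept iff coverage > min_coverage AND length > min_length AND
    e-value < max_evalue, all strict inequalities.
    """
    return [
        ContigTriage(cid, cov, length, ev,
                     cov > min_coverage and length > min_length and ev < max_evalue)
        for cid, cov, length, ev in contigs
    ]


def deg_filter(
    table: pd.DataFrame,
    log2fc_col: str = "log2FoldChange",
    padj_col: str = "padj",
    min_abs_log2fc: float = 1.0,
    max_padj: float = 0.05,
) -> pd.DataFrame:
    """Generic differential-expression table filter: |log2 ratio| > 1 and
    adjusted p < 0.05 by default (the model fit itself happens upstream)."""
    mask = (table[log2fc_col].abs() > min_abs_log2fc) & (table[padj_col] < max_padj)
    return table[mask].copy()


def size_profile_table(profiles: list[SrnaSizeProfile]) -> pd.DataFrame:
    """Per-length histogram export for size-distribution panels."""
    rows = []
    for p in profiles:
        for L in sorted(p.counts):
            rows.append({"target": p.target_id, "length": L, "reads": p.counts[L]})
    return pd.DataFrame(rows, columns=["target", "length", "reads"])
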