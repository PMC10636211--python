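"""Per-EVE polymorphism levels and the fast/slow-evolving gene baseline.

The polymorphism level of a target (EVE locus or gene) in one individual
is the number of distinct non-reference variant positions inside the
target interval, scaled to variants per kb; SNPs and indels each count as
one position.  Evolutionary-rate baselines come from single-copy ortholog
alignments: alignments with more than 10% gapped columns are dropped, each
retained alignment is summarised by its mean pairwise p-distance, and the
top/bottom 5% (floor) of the ranking form the fast- (FEG) and
slow-evolving (SEG) gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VariantSite


@dataclass(frozen=True)
class PolymorphismRecord:
    individual_id: str
    target_id: str
    variant_sites: int
    target_length_nt: int

    @property
    def level(self) -> float:
        """Variants per kb."""
        return 1000.0 * self.variant_sites / self.target_length_nt


def polymorphism_level(
    variants: list[VariantSite],
    contig_id: str,
    start: int,
    end: int,
    individual_id: str,
    target_id: str | None = None,
) -> PolymorphismRecord:
    """Distinct non-reference variant positions of one individual inside
    [start, end), scaled per kb.  Duplicate records at a position count once."""
    if end - start <= 0:
        raise ValueError("zero-length interval")
    positions = {
        v.position
        for v in variants
        if v.individual_id == individual_id
        and v.contig_id == contig_id
        and start <= v.position < end
        and v.genotype_is_nonref
    }
    return PolymorphismRecord(
        individual_id, target_id or f"{contig_id}:{start}-{end}", len(positions), end - start
    )


@dataclass
class OrthologAlignment:
    ortholog_id: str
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def gap_fraction(self) -> float:
        """Fraction of columns containing a gap in any row."""
        arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in self.rows]
        gap = ord("-")
        gapped = np.zeros(self.n_columns, dtype=bool)
        for a in arrs:
            gapped |= a == gap
        return float(gapped.mean())

    @property
    def p_distance(self) -> float:
        return p_distance(self)


def p_distance(alignment: OrthologAlignment) -> float:
    """Mean pairwise difference fraction over columns ungapped in each pair.

    For each row pair: differences / columns with no gap in either row;
    the ortholog value is the mean over all pairs.  An alignment with a
    pair sharing no ungapped column is an error.
    """
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in alignment.rows]
    gap = ord("-")
    dists = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            ok = (arrs[i] != gap) & (arrs[j] != gap)
            n = int(ok.sum())
            if n == 0:
                raise ValueError(
                    f"{alignment.ortholog_id}: no ungapped columns between rows {i} and {j}"
                )
            dists.append(float((arrs[i][ok] != arrs[j][ok]).sum()) / n)
    return float(np.mean(dists))


def filter_poorly_aligned(
    alignments: list[OrthologAlignment], max_gap_fraction: float = 0.10
) -> list[OrthologAlignment]:
    """Drop alignments with more than ``max_gap_fraction`` gapped columns
    (strictly more; a gap fraction exactly at the bound is retained)."""
    return [a for a in alignments if a.gap_fraction <= max_gap_fraction]


@dataclass(frozen=True)
class RateClass:
    ortholog_id: str
    rate_class: str  # FEG | SEG | neither
    p_distance: float


def classify_feg_seg(alignments: list[OrthologAlignment]) -> list[RateClass]:
    """Rank gap-filtered alignments by p-distance (descending); the first
    floor(0.05 n) are FEGs, the last floor(0.05 n) are SEGs.

    Ties are broken by ortholog id for determinism.  With fewer than 20
    alignments both classes are empty (with a warning).
    """
    n = len(alignments)
    k = int(np.floor(0.05 * n))
    values = sorted(
        ((a.ortholog_id, p_distance(a)) for a in alignments),
        key=lambda t: (-t[1], t[0]),
    )
    if n < 20:
        warnings.warn(f"only {n} alignments; FEG/SEG classes left empty")
        return [RateClass(oid, "neither", d) for oid, d in values]
    out = []
    for rank, (oid, d) in enumerate(values):
        if rank < k:
            cls = "FEG"
        elif rank >= n - k:
            cls = "SEG"
        else:
            cls = "neither"
        out.append(RateClass(oid, cls, d))
    return out


def compare_levels(groups: dict[str, list[PolymorphismRecord]]) -> pd.DataFrame:
    """Per-group distribution summary (n, median, quartiles) of polymorphism
    levels, suitable for violin plotting; empty groups are flagged."""
    rows = []
    for name, records in groups.items():
        levels = np.array([r.level for r in records])
        if levels.size == 0:
            rows.append({"group": name, "n": 0, "median": np.nan,
                         "q1": np.nan, "q3": np.nan, "empty": True})
        else:
            rows.append({
                "group": name,
                "n": int(levels.size),
                "median": float(np.median(levels)),
                "q1": float(np.percentile(levels, 25)),
                "q3": float(np.percentile(levels, 75)),
                "empty": False,
            })
    return pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3", "empty"])


def read_ortholog_fasta(path) -> OrthologAlignment:
    """Read one aligned multi-FASTA as an ortholog alignment."""
    from Bio import SeqIO

    rows = []
    oid = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if oid is None:
            oid = rec.id.split("|")[0]
        rows.append(str(rec.seq).upper())
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return OrthologAlignment(oid or "ortholog", rows)
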