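"""From raw translated hits to a vetted EVE locus catalogue.

Consecutive hits on the same contig and strand are merged into loci
(frames may differ within a locus, reflecting frameshift decay), flagged
against the stringent e-value/length criteria, screened with a reciprocal
search against a background proteome, assigned their cognate virus by
best bit score, and annotated with flank-extended ORF predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .io import GenomeAssembly, ProteinRecord, ViralProteinSet, reverse_complement
from .search import (
    ScoringScheme,
    TranslatedHit,
    seeded_translated_search,
    translate,
)


@dataclass(frozen=True)
class BestHit:
    virus_id: str
    protein_id: str
    gene_label: str
    percent_identity: float
    evalue: float
    bit_score: float


@dataclass
class EveLocus:
    locus_id: str
    contig_id: str
    start: int
    end: int  # 0-based half-open
    strand: str
    member_hits: list[TranslatedHit]
    best_hit: BestHit | None = None
    passes_stringent: bool = False
    reciprocal_kept: bool | None = None
    reciprocal_tie: bool = False

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("locus must span at least 1 nt")
        for h in self.member_hits:
            if h.contig_id != self.contig_id or h.strand != self.strand:
                raise ValueError("member hits must share the locus contig and strand")

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def member_hit_ids(self) -> list[str]:
        return [h.hit_id for h in self.member_hits]

    @property
    def best_member_evalue(self) -> float:
        return min(h.evalue for h in self.member_hits)

    def sequence(self, genome: GenomeAssembly) -> str:
        """Forward-strand locus sequence (strand handling is the caller's)."""
        try:
            return genome.contigs[self.contig_id][self.start:self.end]
        except KeyError as exc:
            raise ValueError(f"contig {self.contig_id!r} not in genome") from exc


def merge_hits(
    hits: list[TranslatedHit], max_gap_nt: int = 1000, evalue_merge: float = 1e-5
) -> list[EveLocus]:
    """Merge consecutive hits (same contig and strand, e-value < ``evalue_merge``)
    whose intervals are separated by at most ``max_gap_nt`` into loci.

    Loci on opposite strands are never merged.  Locus ids are derived from
    the merged coordinates, so the result is independent of input order and
    the operation is idempotent.
    """
    eligible = [h for h in hits if h.evalue < evalue_merge]
    groups: dict[tuple[str, str], list[TranslatedHit]] = {}
    for h in eligible:
        groups.setdefault((h.contig_id, h.strand), []).append(h)
    loci: list[EveLocus] = []
    for (contig, strand), members in groups.items():
        members.sort(key=lambda h: (h.subject_start, h.subject_end, h.query_id, h.frame))
        cluster: list[TranslatedHit] = []
        cluster_end = None
        for h in members:
            if cluster and h.subject_start - cluster_end > max_gap_nt:
                loci.append(_make_locus(contig, strand, cluster))
                cluster = []
                cluster_end = None
            cluster.append(h)
            cluster_end = h.subject_end if cluster_end is None else max(cluster_end, h.subject_end)
        if cluster:
            loci.append(_make_locus(contig, strand, cluster))
    loci.sort(key=lambda l: (l.contig_id, l.start, l.end, l.strand))
    return loci


def _make_locus(contig: str, strand: str, members: list[TranslatedHit]) -> EveLocus:
    start = min(h.subject_start for h in members)
    end = max(h.subject_end for h in members)
    return EveLocus(
        locus_id=f"{contig}:{start}-{end}({strand})",
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        member_hits=list(members),
    )


def apply_stringency(
    loci: list[EveLocus], evalue_max: float = 1e-10, min_len_nt: int = 350
) -> list[EveLocus]:
    """Flag (never remove) loci meeting the stringent criteria: best member
    e-value < ``evalue_max`` and length >= ``min_len_nt``."""
    out = []
    for locus in loci:
        ok = locus.best_member_evalue < evalue_max and locus.length_nt >= min_len_nt
        out.append(replace_flag(locus, passes_stringent=ok))
    return out


def replace_flag(locus: EveLocus, **kw) -> EveLocus:
    new = EveLocus(
        locus_id=locus.locus_id,
        contig_id=locus.contig_id,
        start=locus.start,
        end=locus.end,
        strand=locus.strand,
        member_hits=locus.member_hits,
        best_hit=locus.best_hit,
        passes_stringent=locus.passes_stringent,
        reciprocal_kept=locus.reciprocal_kept,
        reciprocal_tie=locus.reciprocal_tie,
    )
    for k, v in kw.items():
        setattr(new, k, v)
    return new


def _search_locus_against(
    locus: EveLocus,
    genome: GenomeAssembly,
    proteins: list[ProteinRecord],
    scheme: ScoringScheme,
    evalue_max: float,
) -> list[TranslatedHit]:
    """Translated search of the locus sequence against a protein panel.

    Emulates a translated-query search by reusing the engine with roles
    swapped: each panel protein is the query, the locus is the genome.
    """
    seq = locus.sequence(genome)
    mini = GenomeAssembly({locus.locus_id: seq})
    return seeded_translated_search(proteins, mini, scheme, evalue_max=evalue_max)


def reciprocal_filter(
    locus: EveLocus,
    genome: GenomeAssembly,
    decoy_proteins: ViralProteinSet,
    viral_proteins: ViralProteinSet,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-3,
) -> EveLocus:
    """Re-search the locus against background + viral proteins; keep the
    locus iff the top bit-score hit is viral.  Ties keep the locus flagged.
    """
    scheme = scheme or ScoringScheme()
    if len(decoy_proteins) == 0:
        warnings.warn(f"{locus.locus_id}: empty decoy set; reciprocal filter is vacuous")
        return replace_flag(locus, reciprocal_kept=True, reciprocal_tie=False)
    viral_ids = {r.protein_id for r in viral_proteins}
    panel = list(viral_proteins) + list(decoy_proteins)
    hits = _search_locus_against(locus, genome, panel, scheme, evalue_max)
    if not hits:
        # nothing matches at all; locus has no protein-level support either way
        return replace_flag(locus, reciprocal_kept=False, reciprocal_tie=False)
    best_score = max(h.bit_score for h in hits)
    top = [h for h in hits if h.bit_score == best_score]
    top_viral = any(h.query_id in viral_ids for h in top)
    top_decoy = any(h.query_id not in viral_ids for h in top)
    tie = top_viral and top_decoy
    return replace_flag(locus, reciprocal_kept=top_viral, reciprocal_tie=tie)


def assign_best_hit(
    locus: EveLocus,
    genome: GenomeAssembly,
    viral_proteins: ViralProteinSet,
    scheme: ScoringScheme | None = None,
    evalue_max: float = 1e-3,
) -> EveLocus:
    """Assign the cognate virus: best bit-score translated hit of the locus
    sequence against the viral protein panel (identity is that alignment's)."""
    scheme = scheme or ScoringScheme()
    hits = _search_locus_against(locus, genome, list(viral_proteins), scheme, evalue_max)
    if not hits:
        return replace_flag(locus, best_hit=None)
    best = max(hits, key=lambda h: (h.bit_score, -h.subject_start))
    rec = viral_proteins.get(best.query_id)
    return replace_flag(locus, best_hit=BestHit(
        virus_id=rec.source_virus_id,
        protein_id=rec.protein_id,
        gene_label=rec.gene_label,
        percent_identity=round(best.percent_identity, 1),
        evalue=best.evalue,
        bit_score=best.bit_score,
    ))


# ---------------------------------------------------------------------------
# ORF prediction

@dataclass(frozen=True)
class OrfCall:
    locus_id: str
    orf_start: int  # genome coords, half-open, includes the stop codon
    orf_end: int
    strand: str
    protein: str  # translation without the stop, starts with M
    overlaps_locus: bool
    is_primary: bool = False

    @property
    def length_nt(self) -> int:
        return self.orf_end - self.orf_start


def _orfs_in_seq(seq: str, min_orf_nt: int) -> list[tuple[int, int, str]]:
    """Complete ORFs (ATG..stop) in the forward frames of ``seq``.

    For each stop codon the longest ORF (first ATG after the previous
    in-frame stop) is reported, as conventional ORF finders do.
    Returned intervals are half-open and include the stop codon.
    """
    out = []
    for off in range(3):
        aa = translate(seq[off:])
        start_aa = None
        for i, c in enumerate(aa):
            if c == "M" and start_aa is None:
                start_aa = i
            elif c == "*":
                if start_aa is not None:
                    nt_start = off + 3 * start_aa
                    nt_end = off + 3 * (i + 1)
                    if nt_end - nt_start >= min_orf_nt:
                        out.append((nt_start, nt_end, aa[start_aa:i]))
                start_aa = None
    return out


def predict_orf_with_flanks(
    locus: EveLocus,
    genome: GenomeAssembly,
    flank_nt: int = 2000,
    min_orf_nt: int = 300,
) -> list[OrfCall]:
    """All complete ORFs (both strands, >= ``min_orf_nt``) in the locus window
    extended by ``flank_nt`` on both sides (clipped at contig bounds); each is
    marked for locus overlap and the longest overlapping one is primary."""
    contig = genome.contigs[locus.contig_id]
    w_lo = max(0, locus.start - flank_nt)
    w_hi = min(len(contig), locus.end + flank_nt)
    window = contig[w_lo:w_hi]
    calls: list[OrfCall] = []
    for nt_start, nt_end, prot in _orfs_in_seq(window, min_orf_nt):
        g_start, g_end = w_lo + nt_start, w_lo + nt_end
        overlaps = g_start < locus.end and locus.start < g_end
        calls.append(OrfCall(locus.locus_id, g_start, g_end, "+", prot, overlaps))
    rc = reverse_complement(window)
    for nt_start, nt_end, prot in _orfs_in_seq(rc, min_orf_nt):
        g_start = w_lo + (len(window) - nt_end)
        g_end = w_lo + (len(window) - nt_start)
        overlaps = g_start < locus.end and locus.start < g_end
        calls.append(OrfCall(locus.locus_id, g_start, g_end, "-", prot, overlaps))
    calls.sort(key=lambda c: (c.orf_start, c.orf_end, c.strand))
    overlapping = [c for c in calls if c.overlaps_locus]
    if overlapping:
        primary = max(overlapping, key=lambda c: (c.length_nt, -c.orf_start))
        calls = [
            OrfCall(c.locus_id, c.orf_start, c.orf_end, c.strand, c.protein,
                    c.overlaps_locus, is_primary=(c is primary))
            for c in calls
        ]
    return calls


# ---------------------------------------------------------------------------
# exports

def loci_to_table(loci: list[EveLocus]):
    """BED-like locus catalogue table (0-based half-open coordinates)."""
    import pandas as pd

    rows = []
    for l in loci:
        rows.append({
            "contig": l.contig_id,
            "start": l.start,
            "end": l.end,
            "locus_id": l.locus_id,
            "strand": l.strand,
            "length_nt": l.length_nt,
            "n_hits": len(l.member_hits),
            "best_member_evalue": l.best_member_evalue,
            "passes_stringent": l.passes_stringent,
            "reciprocal_kept": l.reciprocal_kept,
            "best_virus": l.best_hit.virus_id if l.best_hit else "",
            "best_protein": l.best_hit.protein_id if l.best_hit else "",
            "best_gene": l.best_hit.gene_label if l.best_hit else "",
            "best_identity": l.best_hit.percent_identity if l.best_hit else float("nan"),
            "best_evalue": l.best_hit.evalue if l.best_hit else float("nan"),
        })
    return pd.DataFrame(rows)


def orfs_to_gff3(calls: list[OrfCall], contig_id: str) -> str:
    """GFF3 export of ORF calls (1-based inclusive, per the format)."""
    lines = ["##gff-version 3"]
    for i, c in enumerate(calls, 1):
        attrs = f"ID=orf{i};locus={c.locus_id};overlaps_locus={str(c.overlaps_locus).lower()}"
        if c.is_primary:
            attrs += ";primary=true"
        lines.append("\t".join([
            contig_id, "evescan", "ORF", str(c.orf_start + 1), str(c.orf_end),
            ".", c.strand, "0", attrs,
        ]))
    return "\n".join(lines) + "\n"
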