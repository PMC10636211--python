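"""Configuration and end-to-end orchestration of the EVE analysis workflow.

``run_simulate`` produces a full synthetic study bundle with ground truth;
``run_discover`` chains search -> merge -> stringency -> reciprocal ->
assignment -> ORF prediction into a locus catalogue; ``run_population``
chains QC -> depth -> presence -> PCA and variants -> polymorphism ->
FEG/SEG comparison.  Every threshold lives in :class:`PipelineConfig` with
the study's printed values as defaults, and a run manifest records the
seed and thresholds so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import simulate as sim
from .catalog import (
    EveLocus,
    apply_stringency,
    assign_best_hit,
    loci_to_table,
    merge_hits,
    predict_orf_with_flanks,
    reciprocal_filter,
)
from .io import (
    GenomeAssembly,
    ReadPlacement,
    VariantSite,
    ViralProteinSet,
    write_alignments_tsv,
    write_fasta,
    write_variants_tsv,
)
from .polymorphism import (
    OrthologAlignment,
    PolymorphismRecord,
    classify_feg_seg,
    compare_levels,
    filter_poorly_aligned,
    polymorphism_level,
)
from .presence import (
    PresenceCall,
    call_presence,
    covered_fraction_matrix,
    depth_profile,
    presence_matrix,
    presence_matrix_pca,
    qc_individual,
)
from .search import ScoringScheme, seeded_translated_search

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """All tunable thresholds, with the study's printed values as defaults."""

    seed: int = 42
    # search
    evalue_search: float = 1e-5  # loose stage feeding the 1e-5 merge
    seed_k: int = 4
    x_drop: int = 20
    gapped_trigger: int = 40
    band: int = 32
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    # catalogue
    evalue_merge: float = 1e-5
    max_gap_nt: int = 1000
    stringent_evalue: float = 1e-10
    min_len_nt: int = 350
    orf_flank_nt: int = 2000
    min_orf_nt: int = 300
    # presence
    presence_profile: str = "strict"  # strict | relaxed
    # polymorphism
    max_gap_fraction: float = 0.10
    top_bottom_fraction: float = 0.05
    # sRNA
    pirna_min_reads: int = 50
    pirna_min_fraction: float = 0.5
    # simulation (study conditions)
    host_contig_length: int = 1_000_000
    n_loci: int = 20
    identity_low: float = 0.6
    identity_high: float = 1.0
    frameshift_prob: float = 0.5
    strand_mix: float = 0.5
    n_individuals: int = 10
    depth_present: float = 30.0
    depth_absent: float = 0.0
    read_length: int = 100
    eve_sites_per_kb: float = 6.0
    n_orthologs: int = 1000
    ortholog_length: int = 10_000

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            gap_open=self.gap_open, gap_extend=self.gap_extend,
            lam=self.karlin_lambda, K=self.karlin_k,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def manifest(self) -> dict:
        return {"tool": "evescan", "version": __version__,
                "config": dataclasses.asdict(self)}


@dataclass
class SimBundle:
    """Everything the pipeline consumes, with ground truth."""

    genome: GenomeAssembly
    control_genome: GenomeAssembly
    proteins: ViralProteinSet
    decoys: ViralProteinSet
    truth: sim.SimTruth
    individuals: list[str]
    placements: list[ReadPlacement]
    variants: list[VariantSite]
    orthologs: dict[str, list[str]]
    ortholog_truth: dict[str, str]


def run_simulate(config: PipelineConfig, outdir: str | Path | None = None) -> SimBundle:
    """Generate the full synthetic study bundle (and optionally write it)."""
    seed = config.seed
    virus = sim.simulate_totivirus(seed)
    host = sim.random_host_genome(seed, {"chr1": config.host_contig_length})
    genome, truth = sim.implant_eves(
        seed, host, virus.proteins,
        n_loci=config.n_loci,
        identity_range=(config.identity_low, config.identity_high),
        frameshift_prob=config.frameshift_prob,
        strand_mix=config.strand_mix,
    )
    control = sim.random_host_genome(seed + 1, {"chr1": config.host_contig_length})
    decoys = sim.random_decoy_proteins(seed)
    individuals = [f"ind{i:02d}" for i in range(1, config.n_individuals + 1)]
    sim.assign_presence(seed, truth, individuals)
    contig_lengths = {cid: len(s) for cid, s in genome.contigs.items()}
    placements = sim.simulate_read_alignments(
        seed, truth, individuals,
        depth_present=config.depth_present,
        depth_absent=config.depth_absent,
        read_length=config.read_length,
        contig_lengths=contig_lengths,
    )
    variants = sim.simulate_variants(seed, truth, genome, config.eve_sites_per_kb, individuals)
    orthologs, og_truth = sim.simulate_ortholog_alignments(
        seed, config.n_orthologs, length=config.ortholog_length
    )
    truth.rate_classes = og_truth
    truth.variant_density = {l.locus_id: config.eve_sites_per_kb for l in truth.loci}
    bundle = SimBundle(genome, control, virus.proteins, decoys, truth,
                       individuals, placements, variants, orthologs, og_truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, outdir / "genome.fasta")
        write_fasta(control, outdir / "control_genome.fasta")
        write_fasta(virus.proteins, outdir / "viral_proteins.fasta")
        write_fasta(decoys, outdir / "decoy_proteins.fasta")
        write_alignments_tsv(placements, outdir / "placements.tsv")
        write_variants_tsv(variants, outdir / "variants.tsv")
        truth_rows = [{
            "locus_id": l.locus_id, "contig": l.contig_id, "start": l.start,
            "end": l.end, "strand": l.strand, "source_protein": l.source_protein_id,
            "identity": round(l.identity_realized, 4), "frameshifts": l.n_frameshifts,
        } for l in truth.loci]
        pd.DataFrame(truth_rows).to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
        presence_rows = [
            {"individual": ind, "locus_id": lid, "present": int(flag)}
            for ind, m in truth.presence.items() for lid, flag in m.items()
        ]
        pd.DataFrame(presence_rows).to_csv(outdir / "truth_presence.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(config.manifest(), fh, indent=2, sort_keys=True)
    return bundle


@dataclass
class DiscoverResult:
    hits: list
    loci: list[EveLocus]
    catalogue: pd.DataFrame


def run_discover(
    config: PipelineConfig,
    genome: GenomeAssembly,
    proteins: ViralProteinSet,
    decoys: ViralProteinSet | None = None,
    outdir: str | Path | None = None,
    predict_orfs: bool = False,
) -> DiscoverResult:
    """search -> merge -> stringency -> reciprocal -> assignment (-> ORFs).

    The returned catalogue contains only loci that pass the stringent
    e-value/length criteria and survive the reciprocal filter; ``loci``
    carries every merged locus with its flags.
    """
    scheme = config.scheme()
    hits = seeded_translated_search(
        proteins, genome, scheme,
        seed_k=config.seed_k, x_drop=config.x_drop,
        evalue_max=config.evalue_search,
        gapped_trigger=config.gapped_trigger, band=config.band,
    )
    loci = merge_hits(hits, max_gap_nt=config.max_gap_nt, evalue_merge=config.evalue_merge)
    loci = apply_stringency(loci, evalue_max=config.stringent_evalue, min_len_nt=config.min_len_nt)
    out = []
    for locus in loci:
        if locus.passes_stringent and decoys is not None:
            locus = reciprocal_filter(locus, genome, decoys, proteins, scheme)
        locus = assign_best_hit(locus, genome, proteins, scheme)
        out.append(locus)
    loci = out
    kept = [
        l for l in loci
        if l.passes_stringent and (l.reciprocal_kept is None or l.reciprocal_kept)
    ]
    catalogue = loci_to_table(kept)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        loci_to_table(loci).to_csv(outdir / "loci_all.tsv", sep="\t", index=False)
        catalogue.to_csv(outdir / "catalogue.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(config.manifest(), fh, indent=2, sort_keys=True)
        if predict_orfs:
            from .catalog import orfs_to_gff3

            gff_parts = []
            for locus in kept:
                calls = predict_orf_with_flanks(
                    locus, genome, flank_nt=config.orf_flank_nt, min_orf_nt=config.min_orf_nt
                )
                gff_parts.append(orfs_to_gff3(calls, locus.contig_id))
            (outdir / "orfs.gff3").write_text("".join(gff_parts) or "##gff-version 3\n")
    return DiscoverResult(hits=hits, loci=loci, catalogue=catalogue)


@dataclass
class PopulationResult:
    qc: pd.DataFrame
    calls: list[PresenceCall]
    presence: pd.DataFrame
    covered: pd.DataFrame
    pca_scores: pd.DataFrame | None
    polymorphism: pd.DataFrame
    summary: pd.DataFrame


def run_population(
    config: PipelineConfig,
    loci: list[EveLocus],
    genome: GenomeAssembly,
    placements: list[ReadPlacement],
    variants: list[VariantSite],
    orthologs: dict[str, list[str]] | None = None,
    gene_sites_per_kb: dict[str, float] | None = None,
    outdir: str | Path | None = None,
    apply_qc: bool = True,
) -> PopulationResult:
    """QC -> depth -> presence -> PCA; variants -> levels -> FEG/SEG summary.

    ``apply_qc=False`` reports genome-wide depth per individual but does not
    exclude anyone — appropriate when the placements cover target loci only
    (locus-targeted simulation) rather than whole-genome resequencing.
    """
    profile = config.presence_profile
    individuals = sorted({p.individual_id for p in placements})
    qc_rows = []
    included = []
    for ind in individuals:
        q = qc_individual(placements, genome, profile, individual_id=ind)
        qc_rows.append({"individual": ind,
                        "genome_wide_mean_depth": q.genome_wide_mean_depth,
                        "included": q.included if apply_qc else True,
                        "min_depth_required": q.min_depth_required})
        if q.included or not apply_qc:
            included.append(ind)
    qc = pd.DataFrame(qc_rows, columns=["individual", "genome_wide_mean_depth",
                                        "included", "min_depth_required"])
    by_ind: dict[str, list[ReadPlacement]] = {ind: [] for ind in included}
    for p in placements:
        if p.individual_id in by_ind:
            by_ind[p.individual_id].append(p)
    calls: list[PresenceCall] = []
    for ind in included:
        for locus in loci:
            prof = depth_profile(by_ind[ind], locus, individual_id=ind)
            calls.append(call_presence(prof, profile))
    pres = presence_matrix(calls) if calls else pd.DataFrame()
    cov = covered_fraction_matrix(calls) if calls else pd.DataFrame()
    pca_scores = None
    if len(pres) >= 2 and pres.shape[1] >= 2:
        pca_scores = presence_matrix_pca(cov).scores
    # polymorphism levels per individual x locus, restricted to pairs where
    # at least half of the locus region is covered in that individual
    covered_enough = {(c.individual_id, c.locus_id) for c in calls if c.covered_fraction > 0.5}
    poly_records: list[PolymorphismRecord] = []
    for ind in included:
        for locus in loci:
            if (ind, locus.locus_id) not in covered_enough:
                continue
            poly_records.append(polymorphism_level(
                variants, locus.contig_id, locus.start, locus.end, ind, locus.locus_id
            ))
    poly = pd.DataFrame([{
        "individual": r.individual_id, "target": r.target_id,
        "variant_sites": r.variant_sites, "length_nt": r.target_length_nt,
        "level_per_kb": r.level,
    } for r in poly_records], columns=["individual", "target", "variant_sites",
                                       "length_nt", "level_per_kb"])
    groups: dict[str, list[PolymorphismRecord]] = {"EVE": poly_records}
    if orthologs:
        alignments = filter_poorly_aligned(
            [OrthologAlignment(oid, rows) for oid, rows in orthologs.items()],
            config.max_gap_fraction,
        )
        classes = classify_feg_seg(alignments)
        if gene_sites_per_kb:
            feg_ids = {c.ortholog_id for c in classes if c.rate_class == "FEG"}
            seg_ids = {c.ortholog_id for c in classes if c.rate_class == "SEG"}
            groups["FEG"] = [
                PolymorphismRecord("pooled", oid, int(round(gene_sites_per_kb[oid])), 1000)
                for oid in sorted(feg_ids) if oid in gene_sites_per_kb
            ]
            groups["SEG"] = [
                PolymorphismRecord("pooled", oid, int(round(gene_sites_per_kb[oid])), 1000)
                for oid in sorted(seg_ids) if oid in gene_sites_per_kb
            ]
    summary = compare_levels(groups)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        qc.to_csv(outdir / "individual_qc.tsv", sep="\t", index=False)
        if len(pres):
            pres.to_csv(outdir / "presence_matrix.tsv", sep="\t")
            cov.to_csv(outdir / "covered_fraction_matrix.tsv", sep="\t")
        if pca_scores is not None:
            pca_scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        poly.to_csv(outdir / "polymorphism_levels.tsv", sep="\t", index=False)
        summary.to_csv(outdir / "level_summary.tsv", sep="\t", index=False)
    return PopulationResult(qc, calls, pres, cov, pca_scores, poly, summary)
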