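#!/usr/bin/env python
"""Polymorphism levels of EVE loci against fast/slow-evolving gene baselines.

Computes per-individual variants-per-kb levels for every catalogued locus
(restricted to individual x locus pairs with > 50% breadth), classifies
the 1,000 simulated ortholog alignments into FEGs and SEGs by p-distance
ranking, scores the classification against the planted rate classes, and
summarises the level distributions; a violin plot goes with the tables
under results/polymorphism/.
"""

from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from evescan.pipeline import PipelineConfig, run_discover, run_population, run_simulate
from evescan.polymorphism import OrthologAlignment, classify_feg_seg, filter_poorly_aligned

OUT = Path("results/polymorphism")


def main() -> None:
    cfg = PipelineConfig()
    bundle = run_simulate(cfg)
    res = run_discover(cfg, bundle.genome, bundle.proteins, bundle.decoys)
    kept = [l for l in res.loci
            if l.passes_stringent and (l.reciprocal_kept is None or l.reciprocal_kept)]
    pop = run_population(cfg, kept, bundle.genome, bundle.placements,
                         bundle.variants, outdir=OUT, apply_qc=False)
    levels = pop.polymorphism["level_per_kb"]
    print(f"EVE polymorphism records: {len(levels)} "
          f"(median {levels.median():.2f} /kb at simulated density "
          f"{cfg.eve_sites_per_kb} /kb)")

    alns = filter_poorly_aligned(
        [OrthologAlignment(k, v) for k, v in bundle.orthologs.items()],
        cfg.max_gap_fraction)
    classes = classify_feg_seg(alns)
    table = pd.DataFrame([{"ortholog": c.ortholog_id, "class": c.rate_class,
                           "p_distance": c.p_distance,
                           "planted": bundle.ortholog_truth[c.ortholog_id]}
                          for c in classes])
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "rate_classes.tsv", sep="\t", index=False)
    feg = table[table["class"] == "FEG"]
    seg = table[table["class"] == "SEG"]
    print(f"FEG: {len(feg)} genes (p-distance {feg.p_distance.min():.3f}-"
          f"{feg.p_distance.max():.3f}), planted-fast recovered: "
          f"{(feg.planted == 'fast').sum()}/{(table.planted == 'fast').sum()}")
    print(f"SEG: {len(seg)} genes (p-distance {seg.p_distance.min():.3f}-"
          f"{seg.p_distance.max():.3f}), planted-slow recovered: "
          f"{(seg.planted == 'slow').sum()}/{(table.planted == 'slow').sum()}")

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.violinplot([levels.to_numpy()], positions=[0], showmedians=True)
    ax.set_xticks([0], ["EVE loci"])
    ax.set_ylabel("variants per kb")
    ax.set_title("Polymorphism level of catalogued EVE loci")
    fig.tight_layout()
    fig.savefig(OUT / "polymorphism_violin.png", dpi=120)
    print(f"summary:\n{pop.summary.to_string(index=False)}")
    print(f"tables and violin plot under {OUT}/")


if __name__ == "__main__":
    main()
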