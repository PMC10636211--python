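#!/usr/bin/env python
"""Hypergeometric term enrichment of a differential-expression gene list.

Builds a synthetic annotation universe (2,000 genes, 20 terms) with one
term genuinely enriched among the DEGs, applies the generic DEG filter
(|log2 ratio| > 1, adjusted p < 0.05), and computes per-term upper-tail
hypergeometric P-values with optional Benjamini-Hochberg adjustment.
Writes results/enrichment/enrichment.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from evescan.enrichment import enrich_terms
from evescan.expression import deg_filter

OUT = Path("results/enrichment")
SEED = 42


def main() -> None:
    rng = np.random.default_rng(SEED)
    genes = [f"g{i:04d}" for i in range(2000)]
    rows = []
    for t in range(20):
        members = rng.choice(genes, size=int(rng.integers(30, 120)), replace=False)
        rows += [{"gene": g, "term": f"term{t:02d}"} for g in members]
    ann = pd.DataFrame(rows)

    # DE table: term00 members get strong shifts, the rest are mostly null
    term0 = set(ann[ann.term == "term00"].gene)
    de = pd.DataFrame({
        "gene": genes,
        "log2FoldChange": [rng.normal(2.5, 0.5) if g in term0 and rng.random() < 0.6
                           else rng.normal(0, 0.5) for g in genes],
        "padj": [rng.uniform(0, 0.01) if g in term0 and rng.random() < 0.8
                 else rng.uniform(0, 1) for g in genes],
    })
    degs = deg_filter(de)["gene"].tolist()
    table = enrich_terms(ann, degs, adjust=True).sort_values("P")
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    top = table.iloc[0]
    print(f"DEGs after filter: {len(degs)} of {len(genes)} genes")
    print(f"top term: {top.term}  (N={top.N}, n={top.n}, M={top.M}, m={top.m}, "
          f"P={top.P:.3e}, adjusted={top.adjusted_P:.3e})")
    n_sig = (table.adjusted_P < 0.05).sum()
    print(f"terms with adjusted P < 0.05: {n_sig} (term00 is the planted signal)")
    print(f"table written to {OUT / 'enrichment.tsv'}")


if __name__ == "__main__":
    main()
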