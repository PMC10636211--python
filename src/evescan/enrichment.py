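"""Hypergeometric enrichment of gene sets (GO-style terms).

The enrichment P-value of a term is the upper-tail hypergeometric
probability

    P = 1 - sum_{i=0}^{m-1} C(M, i) * C(N - M, n - i) / C(N, n)
      = Pr(X >= m),  X ~ Hypergeometric(N, M, n)

with N annotated genes in total, n DEGs among them, M genes in the term
and m DEGs in the term.  The sum is evaluated in log space (log-gamma
binomial coefficients) to avoid overflow; raw P-values mirror the source
protocol, with Benjamini-Hochberg adjustment available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class EnrichmentQuery:
    """(N, n, M, m): annotated genes, DEGs, genes in term, DEGs in term."""

    N: int
    n: int
    M: int
    m: int

    def __post_init__(self) -> None:
        if not (0 <= self.m <= min(self.n, self.M)):
            raise ValueError("require 0 <= m <= min(n, M)")
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError("require M <= N and n <= N")
        if self.N <= 0:
            raise ValueError("N must be positive")


def _log_binom(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    return gammaln(np.asarray(a) + 1) - gammaln(np.asarray(b) + 1) - gammaln(np.asarray(a) - np.asarray(b) + 1)


def hypergeometric_p(query: EnrichmentQuery) -> float:
    """Upper-tail (inclusive) hypergeometric P-value, Pr(X >= m).

    m = 0 gives exactly 1.  Strictly decreasing in m for fixed (N, n, M),
    and symmetric under swapping n and M.
    """
    N, n, M, m = query.N, query.n, query.M, query.m
    if m == 0:
        return 1.0
    upper = min(n, M)
    i = np.arange(m, upper + 1)
    log_terms = _log_binom(M, i) + _log_binom(N - M, n - i) - _log_binom(N, n)
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, >= raw)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_terms(
    annotations: pd.DataFrame,
    degs: list[str] | set[str],
    gene_col: str = "gene",
    term_col: str = "term",
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-term enrichment table from a gene->term annotation table.

    ``annotations`` has one row per (gene, term) pair; N is the number of
    annotated genes, n the number of DEGs among them.  Output columns:
    term, N, n, M, m, P (and adjusted_P when ``adjust``).
    """
    genes = set(annotations[gene_col])
    degs_in = set(degs) & genes
    N, n = len(genes), len(degs_in)
    rows = []
    for term, sub in annotations.groupby(term_col, sort=True):
        term_genes = set(sub[gene_col])
        M = len(term_genes)
        m = len(term_genes & degs_in)
        P = hypergeometric_p(EnrichmentQuery(N, n, M, m))
        rows.append({"term": term, "N": N, "n": n, "M": M, "m": m, "P": P})
    table = pd.DataFrame(rows, columns=["term", "N", "n", "M", "m", "P"])
    if adjust and len(table):
        table["adjusted_P"] = bh_adjust(table["P"].to_numpy())
    return table
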