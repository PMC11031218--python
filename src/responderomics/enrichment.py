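"""Hypergeometric term enrichment and gene-list overlap significance.

Given a gene list of size n drawn from a universe of size N, a term with K
members in the universe, and an observed overlap of k genes, the
enrichment p-value is the upper hypergeometric tail P(X >= k) and the fold
enrichment is (k/n)/(K/N), observed overlap rate over its null
expectation.  The tail is accumulated in log space so small p-values stay
accurate.  The DAVID-style EASE variant replaces k by k - 1 in the tail,
which penalizes single-gene overlaps (k <= 1 gives p = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from responderomics.errors import ConfigError, DataError
from responderomics.io_formats import GeneSetCollection


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    description: str
    overlap_k: int
    list_n: int
    term_K: int
    universe_N: int
    fold_enrichment: float
    p_value: float
    overlap_genes: tuple[str, ...] = ()


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n), log-space.

    Parameters follow the sampling story: N universe genes of which K are
    in the term; n genes drawn (the gene list); k of them land in the term.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise DataError(f"inconsistent margins k={k}, K={K}, n={n}, N={N}")
    if k <= 0:
        return 1.0
    lo = max(0, n + K - N)  # support lower bound
    hi = min(K, n)
    upper = math.exp(logsumexp(hypergeom.logpmf(np.arange(k, hi + 1), N, K, n)))
    if upper <= 0.5 or k == lo:
        return float(min(1.0, upper))
    # absolute error scales with the accumulated mass: when the upper tail
    # is the heavy side, sum the light lower tail and complement instead
    below = math.exp(logsumexp(hypergeom.logpmf(np.arange(lo, k), N, K, n)))
    return float(min(1.0, max(0.0, 1.0 - below)))


def _fold(k: int, K: int, n: int, N: int) -> float:
    if n == 0 or K == 0:
        raise DataError("fold enrichment undefined for empty list or term")
    return (k / n) / (K / N)


def term_enrichment(
    gene_list: list[str],
    universe: list[str],
    genesets: GeneSetCollection,
    min_count: int = 5,
    p_threshold: float = 0.05,
    mode: str = "standard",
) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of ``gene_list`` over every term.

    Terms are intersected with the universe before testing.  Only terms
    with overlap >= ``min_count`` and p <= ``p_threshold`` are returned,
    sorted by ascending p (ties by term id).  ``mode="ease"`` computes the
    conservative EASE tail (k replaced by k - 1).
    """
    if mode not in ("standard", "ease"):
        raise ConfigError(f"unknown enrichment mode {mode!r}")
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    stray = sorted(set(gene_list) - uni)
    if stray:
        raise DataError(f"genes in list but not in universe: {stray[:10]}")
    lst = set(gene_list)
    N, n = len(uni), len(lst)
    rows: list[EnrichmentRow] = []
    for term, (desc, genes) in genesets:
        members = set(genes) & uni
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(lst & members)
        k = len(overlap)
        if k < min_count:
            continue
        if mode == "ease":
            p = 1.0 if k <= 1 else hypergeom_tail(k - 1, K, n, N)
        else:
            p = hypergeom_tail(k, K, n, N)
        if p > p_threshold:
            continue
        rows.append(
            EnrichmentRow(
                term_id=term,
                description=desc,
                overlap_k=k,
                list_n=n,
                term_K=K,
                universe_N=N,
                fold_enrichment=_fold(k, K, n, N),
                p_value=p,
                overlap_genes=tuple(overlap),
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def overlap_test(
    list_a: list[str], list_b: list[str], universe: list[str]
) -> tuple[int, float, float]:
    """Significance of the overlap between two gene lists (Venn statistic).

    ``list_a`` plays the role of the term and ``list_b`` the draw; by
    hypergeometric symmetry the p-value does not depend on which is which.
    Returns (overlap size, fold enrichment, p).  k = 0 gives fold 0, p 1.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty universe")
    for name, lst in (("list_a", list_a), ("list_b", list_b)):
        stray = sorted(set(lst) - uni)
        if stray:
            raise DataError(f"genes in {name} but not in universe: {stray[:10]}")
    a, b = set(list_a), set(list_b)
    k = len(a & b)
    N = len(uni)
    p = hypergeom_tail(k, len(a), len(b), N)
    fold = _fold(k, len(a), len(b), N)
    return k, fold, p


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Result rows as a DataFrame in the documented column order."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "description": r.description,
                "overlap_k": r.overlap_k,
                "list_n": r.list_n,
                "term_K": r.term_K,
                "universe_N": r.universe_N,
                "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value,
                "overlap_genes": ",".join(r.overlap_genes),
            }
            for r in rows
        ],
        columns=[
            "term_id",
            "description",
            "overlap_k",
            "list_n",
            "term_K",
            "universe_N",
            "fold_enrichment",
            "p_value",
            "overlap_genes",
        ],
    )
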