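"""Hypergeometric over-representation testing with BH-FDR correction.

A query gene set (e.g. genes carrying nonsynonymous SNPs in one group)
is tested against each annotation term: with ``N`` genes in the
universe, ``K`` of them annotated to the term, ``n`` in the query and
``k`` in the overlap, the p-value is the upper tail P(X >= k) of
Hypergeom(N, K, n).  p-values are BH-adjusted within each term category
(BP/CC/MF/pathway) by default, mirroring standard GO-tool behavior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class TermMap:
    term_id: str
    term_name: str
    category: str
    gene_ids: frozenset

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"term {self.term_id} has an empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    fdr: float


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) (survival function, stable in
    log space inside scipy).  k = 0 returns exactly 1."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def read_term_map(path: str) -> list[TermMap]:
    """Read a 3- or 4-column TSV term map: term_id, category, gene_id
    [, term_name]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if not {"term_id", "category", "gene_id"} <= set(cols):
        raise ValueError(
            f"term map needs columns term_id, category, gene_id; found {cols}"
        )
    terms = []
    for (tid, cat), sub in df.groupby(["term_id", "category"], sort=True):
        name = sub["term_name"].iloc[0] if "term_name" in cols else tid
        terms.append(TermMap(tid, str(name), str(cat), frozenset(sub["gene_id"])))
    return terms


def enrich(
    query_genes: Iterable[str],
    term_maps: Sequence[TermMap],
    universe: Iterable[str],
    *,
    fdr_scope: str = "category",
) -> list[EnrichmentResult]:
    """Test every term with at least one universe gene against a query set.

    Query genes outside the universe are logged and dropped.  ``fdr_scope``
    is ``"category"`` (BH within BP/CC/MF/pathway separately, the default)
    or ``"global"``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
    N, n = len(universe), len(query)

    partial = []
    for t in term_maps:
        term_in_universe = t.gene_ids & universe
        K = len(term_in_universe)
        if K == 0:
            continue
        k = len(term_in_universe & query)
        p = hypergeometric_upper_tail(N, K, n, k)
        partial.append((t, K, k, p))

    if fdr_scope == "global":
        scopes = {"": [i for i in range(len(partial))]}
    elif fdr_scope == "category":
        scopes = {}
        for i, (t, *_rest) in enumerate(partial):
            scopes.setdefault(t.category, []).append(i)
    else:
        raise ValueError("fdr_scope must be 'category' or 'global'")

    fdr = np.empty(len(partial))
    for idx in scopes.values():
        fdr[idx] = bh_adjust([partial[i][3] for i in idx])

    return [
        EnrichmentResult(
            term_id=t.term_id, term_name=t.term_name, category=t.category,
            N=N, K=K, n=n, k=k, p_value=p, fdr=float(q),
        )
        for (t, K, k, p), q in zip(partial, fdr)
    ]


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in results])
    if not df.empty:
        df = df.sort_values(["category", "p_value", "term_id"], kind="stable")
    return df.reset_index(drop=True)
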