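"""Pathway enrichment of overlap gene sets and cross-dataset meta-analysis.

For each disease-model dataset, the genes it shares with a reference
signature are tested against a GMT collection with a hypergeometric
upper-tail test (the overlap sets carry no meaningful internal ranking once
intersected, so a fixed-set test is used rather than a rank scan). Per-term
evidence is then combined across datasets as the sum of -log10 p — rank
equivalent to Fisher's combined statistic — and the top terms reported.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .overlap import _lgamma_table, log_hypergeom_upper_tail
from .signatures import GeneSetCollection, Signature, Universe, normalize_symbol

log = logging.getLogger(__name__)

__all__ = ["overlap_gene_set", "enrich", "meta_rank"]

_LN10 = np.log(10.0)

ENRICH_COLUMNS = (
    "dataset",
    "term",
    "overlap",
    "term_size",
    "query_size",
    "universe_n",
    "p",
    "log10_p",
)


def overlap_gene_set(dataset: Signature, reference: Signature) -> frozenset[str]:
    """Direction-agnostic intersection of two signatures' symbol sets."""
    return dataset.symbols & reference.symbols


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Universe,
    dataset: str = "",
) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene set against every term.

    Terms are intersected with the universe before testing (``term_size`` is
    the post-intersection size); no multiple-testing correction is applied,
    as the table feeds a ranking-based meta-analysis. An empty query yields
    all p = 1 with a warning.
    """
    qset = frozenset(normalize_symbol(s) for s in query)
    outside = qset - universe.symbols
    if outside:
        raise ValueError(
            f"query has {len(outside)} genes outside the universe "
            f"(e.g. {sorted(outside)[:3]})"
        )
    if not qset:
        log.warning("enrich: empty query gene set; all p = 1")
    N = universe.n
    tab = _lgamma_table(N)
    rows = []
    for term, genes in collection.sets.items():
        tset = genes & universe.symbols
        K = len(tset)
        x = len(qset & tset)
        if K == 0 or not qset:
            lp = 0.0
        else:
            lp = log_hypergeom_upper_tail(N, K, len(qset), x, _table=tab)
        rows.append(
            {
                "dataset": dataset,
                "term": term,
                "overlap": x,
                "term_size": K,
                "query_size": len(qset),
                "universe_n": N,
                "p": float(np.exp(lp)) if lp > -745 else 5e-324,
                "log10_p": lp / _LN10,
            }
        )
    return pd.DataFrame(rows, columns=list(ENRICH_COLUMNS))


def meta_rank(all_rows: pd.DataFrame, top_k: int = 15) -> pd.DataFrame:
    """Combine per-dataset enrichment rows into a ranked meta table.

    Per term, ``meta_score`` is the sum of -log10 p over the datasets where
    the term was tested. Rows are sorted by meta_score descending with ties
    broken by term name; ``rank`` is 1-based and the table is truncated to
    ``top_k`` terms.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if all_rows.empty:
        raise ValueError("no enrichment rows to meta-analyze")
    grouped = (
        all_rows.groupby("term", sort=False)
        .agg(
            meta_score=("log10_p", lambda s: float(-np.sum(s))),
            n_datasets_tested=("dataset", "nunique"),
        )
        .reset_index()
    )
    grouped = grouped.sort_values(
        ["meta_score", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped.head(top_k).reset_index(drop=True)
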