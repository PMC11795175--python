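"""Signed similarity indices and their cross-dataset correlations.

Each overlap comparison is condensed to a single signed number: the
similarity index, -log10 of the overall overlap p-value, carrying a positive
sign when the dominant correlation between the two signatures is concordant
and a negative sign when it is discordant. A strongly negative maturity index,
for instance, means a dataset's expression changes run opposite to normal
maturation — the "immature dentate gyrus" pattern.

Per-dataset indices against the three reference signatures (maturity, brain
pH, neural hyperexcitation) are assembled into a table, and the three
pairwise Pearson correlations across datasets quantify whether immaturity,
acidification, and hyperexcitation co-occur across disease models. Before any
index is computed, the three reference signatures are made pairwise disjoint
so the correlations cannot be driven by shared member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import OverlapResult, compare
from .signatures import Signature, Universe

log = logging.getLogger(__name__)

__all__ = [
    "REFERENCE_NAMES",
    "INDEX_COLUMNS",
    "SimilarityIndex",
    "CorrelationResult",
    "disjointify",
    "similarity_index",
    "index_from_p",
    "build_index_table",
    "correlate",
]

REFERENCE_NAMES = ("maturity", "ph", "hyperexcitation")
INDEX_COLUMNS = ("maturity_index", "ph_index", "hyperexcitation_index")


@dataclass(frozen=True)
class SimilarityIndex:
    """Signed -log10 overlap p against one reference signature."""

    value: float
    reference: str
    source_p: float
    source_log10_p: float


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise correlation of two index columns across datasets."""

    pair: tuple[str, str]
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def disjointify(
    maturity: Signature, ph: Signature, hyper: Signature
) -> tuple[Signature, Signature, Signature]:
    """Remove every gene shared by two or more of the three references.

    Idempotent; errors out if any signature would be emptied. Removal counts
    per pair are logged.
    """
    sigs = {"maturity": maturity, "ph": ph, "hyperexcitation": hyper}
    names = list(sigs)
    shared: set[str] = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            both = sigs[a].symbols & sigs[b].symbols
            if both:
                log.info("disjointify: %s/%s share %d genes (removed)", a, b, len(both))
            shared |= both
    out = []
    for name in names:
        trimmed = sigs[name].subset(sigs[name].symbols - shared)
        if trimmed.n == 0:
            raise ValueError(f"disjointify emptied the {name} signature")
        out.append(trimmed)
    return tuple(out)  # type: ignore[return-value]


def index_from_p(overall_p: float, dominant: str, log10_p: float | None = None) -> float:
    """Signed -log10 of an overlap p: + if dominant positive, - if negative."""
    if dominant not in ("positive", "negative"):
        raise ValueError(f"unknown dominant direction {dominant!r}")
    if log10_p is None:
        if not (0.0 < overall_p <= 1.0):
            raise ValueError("overall_p must lie in (0, 1]")
        log10_p = float(np.log10(overall_p))
    if log10_p == 0.0:
        return 0.0
    magnitude = -log10_p
    return magnitude if dominant == "positive" else -magnitude


def similarity_index(result: OverlapResult, reference: str | None = None) -> SimilarityIndex:
    """Transform an :class:`OverlapResult` into its signed similarity index."""
    value = index_from_p(result.overall_p, result.dominant, result.overall_log10_p)
    return SimilarityIndex(
        value=value,
        reference=reference or result.reference,
        source_p=result.overall_p,
        source_log10_p=result.overall_log10_p,
    )


def build_index_table(
    datasets: Mapping[str, Signature],
    references: Mapping[str, Signature],
    universe: Universe,
) -> pd.DataFrame:
    """Per-dataset maturity/pH/hyperexcitation indices.

    One row per dataset in input order with columns ``dataset``,
    ``maturity_index``, ``ph_index``, ``hyperexcitation_index`` and an
    ``incomplete`` flag. A failing comparison leaves NaN and flags the row;
    incomplete rows are excluded listwise from downstream correlations.
    """
    missing = [r for r in REFERENCE_NAMES if r not in references]
    if missing:
        raise ValueError(f"missing reference signatures: {missing}")
    if not datasets:
        raise ValueError("no datasets supplied")
    rows = []
    for name, sig in datasets.items():
        row: dict[str, object] = {"dataset": name, "incomplete": False}
        for ref, col in zip(REFERENCE_NAMES, INDEX_COLUMNS):
            try:
                res = compare(sig, references[ref], universe)
                row[col] = similarity_index(res, ref).value
            except Exception as exc:  # recorded, not fatal: other rows proceed
                log.error("index for %r vs %s failed: %s", name, ref, exc)
                row[col] = np.nan
                row["incomplete"] = True
        rows.append(row)
    return pd.DataFrame(rows, columns=["dataset", *INDEX_COLUMNS, "incomplete"])


def correlate(
    table: pd.DataFrame,
    pair: Sequence[str] = ("maturity_index", "ph_index"),
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate two index columns across datasets.

    Pearson r (default) with the two-sided p from the t transform on n-2
    degrees of freedom, plus the ordinary least-squares line; ``spearman``
    substitutes the rank correlation for r/p while keeping the OLS line.
    """
    xcol, ycol = pair
    sub = table
    if "incomplete" in sub.columns:
        sub = sub[~sub["incomplete"].astype(bool)]
    sub = sub[[xcol, ycol]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError(f"need >= 3 complete rows for correlation, have {n}")
    x = sub[xcol].to_numpy(dtype=float)
    y = sub[ycol].to_numpy(dtype=float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in an index column; correlation undefined")
    ols = stats.linregress(x, y)
    if method == "pearson":
        r, p = float(ols.rvalue), float(ols.pvalue)
    elif method == "spearman":
        rho = stats.spearmanr(x, y)
        r, p = float(rho.statistic), float(rho.pvalue)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        pair=(xcol, ycol),
        r=r,
        p=p,
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        n=n,
    )
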