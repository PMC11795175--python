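"""Rank-based signature overlap: the running Fisher test.

Two signatures are compared with a running hypergeometric scan: the query
signature is ranked by absolute score, and at every rank cutoff (evaluated
only at tie-group boundaries) the overlap between the top-k query genes and
the reference gene set is scored with a hypergeometric upper-tail p-value.
The scan minimum is Bonferroni-corrected by the number of cutoffs evaluated.

A full comparison runs the scan five times: once unsigned (full query ranking
against the full reference set, giving the overall overlap p-value) and once
per directional pair (query-up vs reference-up, down/down, up/down, down/up).
Concordant (same-direction) and discordant (opposite-direction) evidence is
summed on the -log10 scale to call the dominant correlation direction, which
later signs the similarity index.

All tail probabilities are computed in log space (gammaln + logsumexp over
the shorter tail), so extreme overlaps never underflow: the -log10 p survives
even where the linear-scale probability is below float range.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .signatures import GeneEntry, Signature, Universe

log = logging.getLogger(__name__)

__all__ = [
    "PAIRS",
    "ScanResult",
    "DirectionalOverlap",
    "OverlapResult",
    "hypergeom_upper_tail",
    "log_hypergeom_upper_tail",
    "directional_partition",
    "running_scan",
    "compare",
    "write_overlap_json",
    "summarize_overlaps",
]

#: The four directional sub-tests, query direction first.
PAIRS = ("up-up", "down-down", "up-down", "down-up")
CONCORDANT_PAIRS = ("up-up", "down-down")
DISCORDANT_PAIRS = ("up-down", "down-up")

_LN10 = math.log(10.0)
_TINY = 5e-324  # smallest subnormal float; linear-scale floor after underflow

_lgamma_cache: dict[int, np.ndarray] = {}


def _lgamma_table(nmax: int) -> np.ndarray:
    """gammaln(0..nmax+1) lookup; log C(a,b) = t[a+1]-t[b+1]-t[a-b+1]."""
    tab = _lgamma_cache.get(nmax)
    if tab is None:
        tab = gammaln(np.arange(nmax + 2, dtype=float))
        if len(_lgamma_cache) > 8:
            _lgamma_cache.clear()
        _lgamma_cache[nmax] = tab
    return tab


def _check_args(N: int, K: int, n: int, x: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric arguments N={N}, K={K}, n={n}")
    if not (max(0, K + n - N) <= x <= min(K, n)):
        raise ValueError(
            f"overlap x={x} outside support [{max(0, K + n - N)}, {min(K, n)}] "
            f"for N={N}, K={K}, n={n}"
        )


def log_hypergeom_upper_tail(
    N: int, K: int, n: int, x: int, _table: np.ndarray | None = None
) -> float:
    """Natural log of P(X >= x) for X ~ Hypergeometric(N, K, n).

    Above the mode the upper tail is summed directly (log-sum-exp), keeping
    full relative accuracy for small p; at or below the mode — where p is
    bounded away from 0 — the complement of the lower tail is used instead.
    """
    _check_args(N, K, n, x)
    xmin = max(0, K + n - N)
    xmax = min(K, n)
    if x <= xmin:
        return 0.0
    tab = _table if _table is not None else _lgamma_table(N)
    log_cnn = tab[N + 1] - tab[n + 1] - tab[N - n + 1]

    def _logpmf(i: np.ndarray) -> np.ndarray:
        return (
            tab[K + 1]
            - tab[i + 1]
            - tab[K - i + 1]
            + tab[N - K + 1]
            - tab[n - i + 1]
            - tab[(N - K) - (n - i) + 1]
            - log_cnn
        )

    mode = (n + 1) * (K + 1) // (N + 2)
    if x > mode:
        i = np.arange(x, xmax + 1)
        return float(min(0.0, logsumexp(_logpmf(i))))
    # x <= mode: P(X <= x-1) < P(X <= mode) is safely below 1
    i = np.arange(xmin, x)
    cdf = math.exp(float(logsumexp(_logpmf(i))))
    return float(math.log1p(-min(cdf, 1.0 - 1e-16)))


def hypergeom_upper_tail(N: int, K: int, n: int, x: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, K, n), exact in (0, 1]."""
    p = math.exp(log_hypergeom_upper_tail(N, K, n, x))
    return p if p > 0.0 else _TINY


@dataclass(frozen=True)
class ScanResult:
    """Outcome of one running hypergeometric scan."""

    p_raw: float
    p_corrected: float
    log10_p_raw: float
    log10_p_corrected: float
    k_best: int
    n_cutoffs: int
    overlap_at_best: int = 0


def running_scan(
    ranked: Sequence[GeneEntry],
    reference_set: Iterable[str],
    universe_n: int,
) -> ScanResult:
    """Scan rank cutoffs of ``ranked`` against ``reference_set``.

    Cutoffs are evaluated only where the absolute score changes between
    consecutive entries (tie-group boundaries), so every tie group enters the
    scan as a block. The minimum scan p is Bonferroni-corrected by the number
    of cutoffs evaluated; ``k_best`` is the smallest cutoff attaining it.

    Degenerate inputs (empty query or empty reference set) return p = 1.
    """
    refset = frozenset(reference_set)
    K = len(refset)
    if not ranked or K == 0:
        return ScanResult(1.0, 1.0, 0.0, 0.0, 0, 0)
    if K > universe_n or len(ranked) > universe_n:
        raise ValueError("signature larger than universe")
    abs_scores = np.array([abs(e.score) for e in ranked])
    member = np.array([e.key in refset for e in ranked])
    cum = np.cumsum(member)
    m = len(ranked)
    is_boundary = np.ones(m, dtype=bool)
    is_boundary[:-1] = abs_scores[:-1] != abs_scores[1:]
    ks = np.nonzero(is_boundary)[0] + 1
    tab = _lgamma_table(universe_n)
    best_log = 0.0
    best_k = int(ks[0])
    best_x = int(cum[ks[0] - 1])
    for k in ks:
        x = int(cum[k - 1])
        lp = log_hypergeom_upper_tail(universe_n, K, int(k), x, _table=tab)
        if lp < best_log:
            best_log = lp
            best_k = int(k)
            best_x = x
    n_cutoffs = len(ks)
    log_corr = min(0.0, best_log + math.log(n_cutoffs))
    p_raw = math.exp(best_log)
    p_corr = math.exp(log_corr)
    return ScanResult(
        p_raw=p_raw if p_raw > 0 else _TINY,
        p_corrected=p_corr if p_corr > 0 else _TINY,
        log10_p_raw=best_log / _LN10,
        log10_p_corrected=log_corr / _LN10,
        k_best=best_k,
        n_cutoffs=n_cutoffs,
        overlap_at_best=best_x,
    )


@dataclass(frozen=True)
class DirectionalOverlap:
    """One of the four directional sub-tests of a comparison."""

    pair: str
    overlap_genes: frozenset[str]
    k_best: int
    p_raw: float
    p_corrected: float
    log10_p_raw: float
    log10_p_corrected: float
    n_cutoffs: int

    @property
    def count(self) -> int:
        return len(self.overlap_genes)


@dataclass(frozen=True)
class OverlapResult:
    """Full output of one query-vs-reference signature comparison."""

    query: str
    reference: str
    universe_n: int
    total_shared: int
    directional: Mapping[str, DirectionalOverlap]
    overall_p: float
    overall_log10_p: float
    dominant: str
    concordant_score: float
    discordant_score: float

    def to_dict(self) -> dict:
        return {
            "query": self.query,
            "reference": self.reference,
            "universe_n": self.universe_n,
            "total_shared": self.total_shared,
            "overall_p": self.overall_p,
            "overall_log10_p": self.overall_log10_p,
            "dominant": self.dominant,
            "concordant_score": self.concordant_score,
            "discordant_score": self.discordant_score,
            "directional": {
                pair: {
                    "count": d.count,
                    "overlap_genes": sorted(d.overlap_genes),
                    "k_best": d.k_best,
                    "p_raw": d.p_raw,
                    "p_corrected": d.p_corrected,
                    "log10_p_corrected": d.log10_p_corrected,
                    "n_cutoffs": d.n_cutoffs,
                }
                for pair, d in self.directional.items()
            },
        }


def directional_partition(
    query: Signature, reference: Signature
) -> dict[str, tuple[tuple[GeneEntry, ...], frozenset[str], frozenset[str]]]:
    """Split the query/reference intersection into the four direction pairs.

    Returns, per pair, the ranked query-side entries, the reference-side gene
    set, and their overlap. The four overlap sets are pairwise disjoint and
    union to the full intersection, because every entry has nonzero direction.
    """
    qup, qdn = query.up_entries, query.down_entries
    rup, rdn = reference.up_symbols, reference.down_symbols
    out = {}
    for pair, qents, rset in (
        ("up-up", qup, rup),
        ("down-down", qdn, rdn),
        ("up-down", qup, rdn),
        ("down-up", qdn, rup),
    ):
        overlap = frozenset(e.key for e in qents) & rset
        out[pair] = (qents, rset, overlap)
    return out


def compare(query: Signature, reference: Signature, universe: Universe) -> OverlapResult:
    """Run the full running-Fisher comparison of two signatures.

    The scan always runs over the query side (a ranked list); the reference
    side enters as a fixed gene set. The overall p ignores direction; the four
    directional scans feed the concordant/discordant evidence scores and the
    dominant-direction call.
    """
    universe.require_contains(query)
    universe.require_contains(reference)
    N = universe.n
    parts = directional_partition(query, reference)
    total_shared = len(query.symbols & reference.symbols)

    directional: dict[str, DirectionalOverlap] = {}
    for pair, (qents, rset, overlap) in parts.items():
        scan = running_scan(qents, rset, N)
        directional[pair] = DirectionalOverlap(
            pair=pair,
            overlap_genes=overlap,
            k_best=scan.k_best,
            p_raw=scan.p_raw,
            p_corrected=scan.p_corrected,
            log10_p_raw=scan.log10_p_raw,
            log10_p_corrected=scan.log10_p_corrected,
            n_cutoffs=scan.n_cutoffs,
        )

    overall = running_scan(query.entries, reference.symbols, N)
    concordant = -sum(directional[p].log10_p_corrected for p in CONCORDANT_PAIRS)
    discordant = -sum(directional[p].log10_p_corrected for p in DISCORDANT_PAIRS)
    if concordant == discordant and concordant > 0:
        log.warning(
            "compare %r vs %r: concordant/discordant tie (%.3g); calling positive",
            query.name,
            reference.name,
            concordant,
        )
    dominant = "positive" if concordant >= discordant else "negative"
    return OverlapResult(
        query=query.name,
        reference=reference.name,
        universe_n=N,
        total_shared=total_shared,
        directional=directional,
        overall_p=overall.p_corrected,
        overall_log10_p=overall.log10_p_corrected,
        dominant=dominant,
        concordant_score=concordant,
        discordant_score=discordant,
    )


def write_overlap_json(result: OverlapResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def summarize_overlaps(results: Iterable[OverlapResult]) -> pd.DataFrame:
    """One-row-per-comparison summary table (counts, corrected p's, call)."""
    rows = []
    for r in results:
        row = {
            "query": r.query,
            "reference": r.reference,
            "universe_n": r.universe_n,
            "total_shared": r.total_shared,
            "overall_p": r.overall_p,
            "dominant": r.dominant,
        }
        for pair in PAIRS:
            d = r.directional[pair]
            row[f"n_{pair}"] = d.count
            row[f"p_{pair}"] = d.p_corrected
        rows.append(row)
    return pd.DataFrame(rows)
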