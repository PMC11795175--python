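"""Independent brute-force oracles used to validate the package's statistics.

Everything here is deliberately naive: exact integer enumeration with
``math.comb`` for hypergeometric tails, and a literal all-cutoff scan for the
running overlap test. These implementations share no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction


def hypergeom_tail_oracle(N: int, K: int, n: int, x: int) -> float:
    """Exact P(X >= x) by enumerating every tail term with integer combs."""
    total = math.comb(N, n)
    acc = 0
    for i in range(max(x, max(0, K + n - N)), min(K, n) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return float(min(Fraction(acc, total), Fraction(1)))


def scan_oracle(ranked_pairs, reference_set, universe_n):
    """Literal running scan: every tie-group boundary, exact tails.

    ``ranked_pairs`` is a list of (symbol, abs_score) already sorted by
    |score| descending. Returns (p_raw, p_corrected, k_best, n_cutoffs).
    """
    refset = set(reference_set)
    if not ranked_pairs or not refset:
        return 1.0, 1.0, 0, 0
    K = len(refset)
    best_p, best_k = None, None
    n_cutoffs = 0
    hits = 0
    for i, (sym, score) in enumerate(ranked_pairs):
        hits += sym in refset
        is_boundary = (
            i == len(ranked_pairs) - 1 or score != ranked_pairs[i + 1][1]
        )
        if not is_boundary:
            continue
        n_cutoffs += 1
        p = hypergeom_tail_oracle(universe_n, K, i + 1, hits)
        if best_p is None or p < best_p:
            best_p, best_k = p, i + 1
    return best_p, min(1.0, best_p * n_cutoffs), best_k, n_cutoffs


def compare_oracle(query, reference, universe_n):
    """Brute-force counterpart of the full signature comparison.

    ``query``/``reference`` are mappings symbol -> signed score. Returns a
    dict with the overall and four directional scan results and the
    dominant-direction call, mirroring the package's conventions.
    """
    def ranked(d):
        return sorted(
            ((s, abs(v)) for s, v in d.items()), key=lambda t: (-t[1], t[0])
        )

    qup = {s: v for s, v in query.items() if v > 0}
    qdn = {s: v for s, v in query.items() if v < 0}
    rup = {s for s, v in reference.items() if v > 0}
    rdn = {s for s, v in reference.items() if v < 0}
    out = {
        "up-up": scan_oracle(ranked(qup), rup, universe_n),
        "down-down": scan_oracle(ranked(qdn), rdn, universe_n),
        "up-down": scan_oracle(ranked(qup), rdn, universe_n),
        "down-up": scan_oracle(ranked(qdn), rup, universe_n),
        "overall": scan_oracle(ranked(query), set(reference), universe_n),
    }
    conc = -sum(
        math.log10(out[p][1]) for p in ("up-up", "down-down")
    )
    disc = -sum(
        math.log10(out[p][1]) for p in ("up-down", "down-up")
    )
    out["dominant"] = "positive" if conc >= disc else "negative"
    return out


def pearson_oracle(x, y):
    """Closed-form Pearson r computed directly from the definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def welch_oracle(a, b):
    """Closed-form Welch t and df; two-sided p via the incomplete beta tail."""
    from scipy.special import betainc

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(betainc(df / 2, 0.5, df / (df + t * t)))
    return t, df, p
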