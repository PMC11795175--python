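"""Gene signatures, gene-set collections, and cross-species symbol handling.

A *signature* is a named list of genes with signed effect scores (log2 fold
changes, or meta-analysis S-values used in their place), ranked by absolute
score. Signatures are the common currency of the package: differential
expression calling produces them, the running-Fisher overlap test consumes
them, and the synthetic generator emits them.

Symbols are compared case-insensitively throughout. Upper-casing doubles as
the default cross-species bridge (mouse ``Fos`` vs human ``FOS``); an explicit
ortholog table can be supplied where symbol identity is not good enough.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneEntry",
    "Signature",
    "Universe",
    "OrthologMap",
    "GeneSetCollection",
    "SignatureFormatError",
    "normalize_symbol",
    "read_deg_table",
    "write_deg_table",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "harmonize",
    "build_universe",
]


class SignatureFormatError(ValueError):
    """Raised when an input table or GMT file violates the expected format."""


def normalize_symbol(symbol: str) -> str:
    """Trim whitespace and upper-case a gene symbol."""
    s = symbol.strip().upper()
    if not s:
        raise ValueError("gene symbol is empty after whitespace trimming")
    return s


@dataclass(frozen=True)
class GeneEntry:
    """One gene in a signature: symbol, signed score, optional p-value.

    The score is a log2 fold change or an equivalent signed statistic; its
    sign is the gene's direction of change and must be nonzero, because the
    directional overlap tests partition every signature into an up- and a
    down-regulated half.
    """

    symbol: str
    score: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbol", str(self.symbol))
        object.__setattr__(self, "score", float(self.score))
        if self.p_value is not None:
            object.__setattr__(self, "p_value", float(self.p_value))
        if not self.symbol.strip():
            raise ValueError("gene symbol is empty")
        if not math.isfinite(self.score):
            raise ValueError(f"non-finite score for {self.symbol!r}")
        if self.score == 0.0:
            raise ValueError(f"zero score for {self.symbol!r}: direction undefined")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of (0,1] for {self.symbol!r}")

    @property
    def direction(self) -> int:
        """+1 for up-regulated, -1 for down-regulated."""
        return 1 if self.score > 0 else -1

    @property
    def key(self) -> str:
        return normalize_symbol(self.symbol)


def _rank_key(entry: GeneEntry) -> tuple[float, str]:
    # |score| descending; symbol lexicographic breaks ties. The running scan
    # only evaluates cutoffs at tie-group boundaries, so the lexicographic
    # order never influences a p-value.
    return (-abs(entry.score), entry.key)


@dataclass(frozen=True)
class Signature:
    """A named, species-tagged gene list ranked by absolute score."""

    name: str
    species: str
    entries: tuple[GeneEntry, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.entries, key=_rank_key))
        keys = [e.key for e in ordered]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate symbols in signature {self.name!r}: {dupes[:5]}")
        object.__setattr__(self, "entries", ordered)

    @classmethod
    def from_entries(
        cls, name: str, species: str, entries: Iterable[GeneEntry]
    ) -> "Signature":
        """Build a signature, merging duplicate symbols by maximum |score|.

        Among duplicates with equal |score| the first occurrence wins, so the
        result is stable under row duplication of an input file.
        """
        best: dict[str, GeneEntry] = {}
        merged = 0
        for e in entries:
            prev = best.get(e.key)
            if prev is None:
                best[e.key] = e
            else:
                merged += 1
                if abs(e.score) > abs(prev.score):
                    best[e.key] = e
        if merged:
            log.warning(
                "signature %r: merged %d duplicate symbol rows (kept max |score|)",
                name,
                merged,
            )
        return cls(name=name, species=species, entries=tuple(best.values()))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(e.key for e in self.entries)

    @property
    def ranked_symbols(self) -> list[str]:
        return [e.key for e in self.entries]

    @property
    def up_entries(self) -> tuple[GeneEntry, ...]:
        return tuple(e for e in self.entries if e.score > 0)

    @property
    def down_entries(self) -> tuple[GeneEntry, ...]:
        return tuple(e for e in self.entries if e.score < 0)

    @property
    def up_symbols(self) -> frozenset[str]:
        return frozenset(e.key for e in self.up_entries)

    @property
    def down_symbols(self) -> frozenset[str]:
        return frozenset(e.key for e in self.down_entries)

    def subset(self, keep: Iterable[str]) -> "Signature":
        """Restrict to the given (case-normalized) symbols, preserving rank."""
        keepset = {normalize_symbol(s) for s in keep}
        return Signature(
            name=self.name,
            species=self.species,
            entries=tuple(e for e in self.entries if e.key in keepset),
        )

    def negated(self) -> "Signature":
        """Flip the sign of every score (up/down sets swap)."""
        return Signature(
            name=self.name,
            species=self.species,
            entries=tuple(
                GeneEntry(e.symbol, -e.score, e.p_value) for e in self.entries
            ),
        )


@dataclass(frozen=True)
class Universe:
    """The background gene population of the hypergeometric tests.

    Every signature compared under a universe must be contained in it; its
    size N is the denominator population of every overlap and enrichment test.
    """

    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("universe is empty")
        object.__setattr__(self, "symbols", frozenset(map(normalize_symbol, self.symbols)))

    @property
    def n(self) -> int:
        return len(self.symbols)

    def require_contains(self, sig: Signature) -> None:
        missing = sig.symbols - self.symbols
        if missing:
            raise ValueError(
                f"signature {sig.name!r} has {len(missing)} symbols outside the "
                f"universe (e.g. {sorted(missing)[:3]}); restrict it first"
            )


@dataclass(frozen=True)
class OrthologMap:
    """Functional mapping from source-species to target-species symbols."""

    pairs: Mapping[str, str]

    def __post_init__(self) -> None:
        norm = {normalize_symbol(k): normalize_symbol(v) for k, v in self.pairs.items()}
        object.__setattr__(self, "pairs", norm)

    def get(self, symbol: str) -> str | None:
        return self.pairs.get(normalize_symbol(symbol))


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT contents) for enrichment testing."""

    sets: Mapping[str, frozenset[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers


def read_deg_table(
    path: str | Path,
    score_column_is_log2: bool = True,
    name: str | None = None,
    species: str = "unknown",
) -> Signature:
    """Read a DEG table (TSV with ``gene``, ``log2fc``/``score``, optional
    ``p_value``) into a ranked :class:`Signature`.

    Linear fold changes (``score_column_is_log2=False``) are converted to
    log2; rows with zero or non-finite scores are rejected with a logged
    count; duplicate symbols keep the entry with the largest |score|.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise SignatureFormatError(f"{path}: empty file") from exc
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols:
        raise SignatureFormatError(f"{path}: missing required column 'gene'")
    score_col = cols.get("log2fc") or cols.get("score")
    if score_col is None:
        raise SignatureFormatError(f"{path}: missing 'log2fc' or 'score' column")
    p_col = cols.get("p_value")
    if df.empty:
        raise SignatureFormatError(f"{path}: table has no rows")

    entries: list[GeneEntry] = []
    rejected = 0
    for row in df.itertuples(index=False):
        sym = str(getattr(row, cols["gene"]))
        raw = float(getattr(row, score_col))
        if not score_column_is_log2:
            score = math.log2(raw) if raw > 0 and math.isfinite(raw) else math.nan
        else:
            score = raw
        if not math.isfinite(score) or score == 0.0 or not sym.strip():
            rejected += 1
            continue
        p = None
        if p_col is not None:
            praw = float(getattr(row, p_col))
            p = praw if math.isfinite(praw) else None
        entries.append(GeneEntry(sym, score, p))
    if rejected:
        log.warning("%s: rejected %d rows with zero/non-finite scores", path, rejected)
    if not entries:
        raise SignatureFormatError(f"{path}: no usable rows")
    return Signature.from_entries(name or path.stem, species, entries)


def write_deg_table(sig: Signature, path: str | Path) -> None:
    """Write a signature as a TSV readable by :func:`read_deg_table`.

    Scores are written with ``repr`` so a round trip preserves them to full
    float precision and hence the exact ranking.
    """
    path = Path(path)
    has_p = any(e.p_value is not None for e in sig.entries)
    with open(path, "w") as fh:
        fh.write("gene\tlog2fc" + ("\tp_value" if has_p else "") + "\n")
        for e in sig.entries:
            row = f"{e.symbol}\t{e.score!r}"
            if has_p:
                row += "\t" + ("" if e.p_value is None else repr(e.p_value))
            fh.write(row + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file (set name, description, member genes)."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise SignatureFormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            genes = frozenset(
                normalize_symbol(g) for g in fields[2:] if g.strip()
            )
            if name in sets:
                raise SignatureFormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                dropped += 1
                log.warning("%s:%d: dropping empty set %r", path, lineno, name)
                continue
            sets[name] = genes
    if dropped:
        log.warning("%s: dropped %d empty sets", path, dropped)
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.provenance or 'na'}\t{genes}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV (``source_gene``, ``target_gene``)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "source_gene" not in cols or "target_gene" not in cols:
        raise SignatureFormatError(
            f"{path}: expected columns 'source_gene' and 'target_gene'"
        )
    pairs = dict(
        zip(
            df[cols["source_gene"]].astype(str),
            df[cols["target_gene"]].astype(str),
        )
    )
    return OrthologMap(pairs=pairs)


# ---------------------------------------------------------------------------
# harmonization & universe


def harmonize(sig: Signature, ortholog_map: OrthologMap | None = None) -> Signature:
    """Translate a signature onto a common symbol space.

    With no map, symbols are simply upper-cased (symbol-identity ortholog
    proxy). With a map, symbols are translated and unmapped entries dropped;
    collisions onto one target keep the entry with the largest |score|.
    Lossy steps are logged, never fatal.
    """
    if ortholog_map is None:
        entries = [GeneEntry(e.key, e.score, e.p_value) for e in sig.entries]
        return Signature.from_entries(sig.name, sig.species, entries)
    kept: list[GeneEntry] = []
    dropped = 0
    for e in sig.entries:
        target = ortholog_map.get(e.symbol)
        if target is None:
            dropped += 1
            continue
        kept.append(GeneEntry(target, e.score, e.p_value))
    if dropped:
        log.warning("harmonize %r: dropped %d unmapped symbols", sig.name, dropped)
    return Signature.from_entries(sig.name, sig.species, kept)


def build_universe(
    assayed_lists: Sequence[Iterable[str]], mode: str = "intersection"
) -> Universe:
    """Build the background universe from one or more assayed-gene lists.

    ``intersection`` (default) keeps only genes measured on every platform;
    ``union`` keeps genes measured on any.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown universe mode {mode!r}")
    normed = [frozenset(map(normalize_symbol, lst)) for lst in assayed_lists]
    normed = [s for s in normed if s]
    if not normed:
        raise ValueError("no non-empty assayed lists supplied")
    if mode == "intersection":
        result = frozenset.intersection(*normed)
        if not result:
            raise ValueError(
                "intersection of assayed lists is empty; consider mode='union'"
            )
    else:
        result = frozenset.union(*normed)
    log.info("universe built (%s mode): N = %d", mode, len(result))
    return Universe(symbols=result)
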