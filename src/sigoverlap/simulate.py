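"""Synthetic study generator with planted, bookkept overlap structure.

Generates every input the pipeline consumes: three reference signatures
(maturity, brain pH, neural hyperexcitation), per-dataset two-group
expression matrices with planted concordant/discordant overlaps against each
reference, and a GMT collection with one planted enriched term — all
deterministically from a single seed, with full truth records so recovery is
testable.

The expression model is deliberately simple and sufficient for rank-based
statistics: per-gene control means are drawn on the log2 scale, planted genes
shift the case mean by ±effect_log2fc (jittered per gene), and per-sample
residual noise is Gaussian on the log2 scale. The pH signature mimics a
meta-analysis product: a fixed count of up- and down-regulated genes whose
signed S-value-like scores stand in for fold changes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import yaml

from .deg import ExpressionMatrix
from .indices import REFERENCE_NAMES
from .signatures import (
    GeneEntry,
    GeneSetCollection,
    Signature,
    Universe,
    write_deg_table,
    write_gmt,
)

log = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_references",
    "generate_dataset",
    "generate_cohort",
    "truth_signature",
    "write_study",
]

REF_SPECIES = {"maturity": "mouse", "ph": "human", "hyperexcitation": "rat"}


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs.

    Signature-size defaults emulate the study conditions: a ~39-up/~268-down
    pH gene list with signed scores, a maturity contrast of several hundred
    genes, and a large hyperexcitation signature (1200 by default — a
    scaled-down stand-in for the ~7000-gene seizure signature, configurable
    up to full scale). Effect size and noise give two-group designs of 3 vs 3
    realistic power for the fold-change/t-test DEG criterion.
    """

    seed: int
    universe_size: int = 5000
    maturity_size: int = 800
    ph_up_size: int = 39
    ph_down_size: int = 268
    hyper_size: int = 1200
    n_case: int = 3
    n_control: int = 3
    effect_log2fc: float = 1.0
    noise_sd: float = 0.25
    background_deg_fraction: float = 0.02
    disjoint_references: bool = True

    def __post_init__(self) -> None:
        sizes = (
            self.maturity_size,
            self.ph_up_size + self.ph_down_size,
            self.hyper_size,
        )
        if any(s <= 0 for s in sizes):
            raise ValueError("signature sizes must be positive")
        if self.disjoint_references:
            if sum(sizes) > self.universe_size:
                raise ValueError("disjoint references exceed the universe size")
        elif max(sizes) > self.universe_size:
            raise ValueError("a signature exceeds the universe size")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 samples per group")
        if self.noise_sd < 0 or self.effect_log2fc <= 0:
            raise ValueError("noise_sd must be >= 0 and effect_log2fc > 0")
        if not (0 <= self.background_deg_fraction < 1):
            raise ValueError("background_deg_fraction must lie in [0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticStudy:
    """A generated cohort: references, matrices, truth, gene sets."""

    config: SyntheticConfig
    universe: Universe
    references: dict[str, Signature]
    datasets: dict[str, ExpressionMatrix]
    truth: dict[str, dict]
    gmt: GeneSetCollection
    planted_term: str | None = None


def _universe_symbols(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _signed_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    mags = rng.lognormal(mean=-0.5, sigma=0.6, size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    return mags * signs


def generate_references(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> dict[str, Signature]:
    """Draw the three reference signatures; deterministic given the seed.

    Maturity and hyperexcitation get log-normal |log2FC| magnitudes with
    random signs; the pH signature gets exactly ``ph_up_size`` positive and
    ``ph_down_size`` negative S-value-like scores. With
    ``disjoint_references`` the three gene sets are pairwise disjoint by
    construction.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    symbols = np.array(_universe_symbols(cfg.universe_size))
    n_ph = cfg.ph_up_size + cfg.ph_down_size
    if cfg.disjoint_references:
        pool = rng.permutation(symbols)
        mat_syms = pool[: cfg.maturity_size]
        ph_syms = pool[cfg.maturity_size : cfg.maturity_size + n_ph]
        hyp_syms = pool[cfg.maturity_size + n_ph : cfg.maturity_size + n_ph + cfg.hyper_size]
    else:
        mat_syms = rng.choice(symbols, cfg.maturity_size, replace=False)
        ph_syms = rng.choice(symbols, n_ph, replace=False)
        hyp_syms = rng.choice(symbols, cfg.hyper_size, replace=False)

    mat_scores = _signed_scores(rng, cfg.maturity_size)
    maturity = Signature(
        "maturity",
        REF_SPECIES["maturity"],
        tuple(GeneEntry(s, v) for s, v in zip(mat_syms, mat_scores)),
    )
    ph_mags = rng.lognormal(mean=-0.5, sigma=0.6, size=n_ph)
    ph_signs = np.concatenate(
        [np.ones(cfg.ph_up_size), -np.ones(cfg.ph_down_size)]
    )
    ph = Signature(
        "ph",
        REF_SPECIES["ph"],
        tuple(GeneEntry(s, v) for s, v in zip(ph_syms, ph_mags * ph_signs)),
    )
    hyp_scores = _signed_scores(rng, cfg.hyper_size)
    hyper = Signature(
        "hyperexcitation",
        REF_SPECIES["hyperexcitation"],
        tuple(GeneEntry(s, v) for s, v in zip(hyp_syms, hyp_scores)),
    )
    return {"maturity": maturity, "ph": ph, "hyperexcitation": hyper}


def generate_dataset(
    cfg: SyntheticConfig,
    name: str,
    planted: Mapping[str, tuple[float, float]],
    references: Mapping[str, Signature],
    rng: np.random.Generator,
    planting_order: Mapping[str, list[str]] | None = None,
) -> tuple[ExpressionMatrix, dict]:
    """One two-group expression matrix with planted overlaps.

    ``planted`` maps each reference name to its (rho_concordant,
    rho_discordant) pair: the floor of rho x reference-size genes are shifted
    in the same (concordant) or opposite (discordant) direction as their
    reference score. Off-reference background DEGs are planted at
    ``background_deg_fraction`` with random directions. The returned truth
    record lists every planted gene with its intended direction.
    """
    symbols = _universe_symbols(cfg.universe_size)
    ref_gene_pool: set[str] = set()
    for ref in references.values():
        ref_gene_pool |= set(ref.symbols)

    score_of = {
        rname: {e.key: e.score for e in ref.entries}
        for rname, ref in references.items()
    }
    directions: dict[str, int] = {}
    truth: dict = {"references": {}, "background": [], "directions": {}}
    for rname in REFERENCE_NAMES:
        rho_c, rho_d = planted.get(rname, (0.0, 0.0))
        if not (0 <= rho_c and 0 <= rho_d and rho_c + rho_d <= 1):
            raise ValueError(f"invalid rho pair for {rname}: {(rho_c, rho_d)}")
        ref = references[rname]
        n_c = math.floor(rho_c * ref.n)
        n_d = math.floor(rho_d * ref.n)
        if n_c + n_d > ref.n:
            raise ValueError(f"planted counts exceed {rname} signature size")
        if planting_order is not None and rname in planting_order:
            order = list(planting_order[rname])
        else:
            order = list(rng.permutation(ref.ranked_symbols))
        conc = order[:n_c]
        disc = order[n_c : n_c + n_d]
        for g in conc:
            directions[g] = 1 if score_of[rname][g] > 0 else -1
        for g in disc:
            directions[g] = -1 if score_of[rname][g] > 0 else 1
        truth["references"][rname] = {"concordant": conc, "discordant": disc}

    off_ref = [s for s in symbols if s not in ref_gene_pool]
    n_bg = math.floor(cfg.background_deg_fraction * len(off_ref))
    bg = list(rng.choice(np.array(off_ref), n_bg, replace=False)) if n_bg else []
    for g in bg:
        directions[g] = int(rng.choice([-1, 1]))
    truth["background"] = bg
    truth["directions"] = {g: int(d) for g, d in directions.items()}

    g = cfg.universe_size
    ctrl_mean = rng.normal(7.0, 1.5, size=g)
    delta = np.zeros(g)
    idx = {s: i for i, s in enumerate(symbols)}
    for gene, d in directions.items():
        delta[idx[gene]] = d * cfg.effect_log2fc * rng.uniform(0.9, 1.1)
    case_mean = ctrl_mean + delta

    n_s = cfg.n_control + cfg.n_case
    noise = rng.normal(0.0, cfg.noise_sd, size=(g, n_s)) if cfg.noise_sd > 0 else np.zeros((g, n_s))
    values = np.empty((g, n_s))
    values[:, : cfg.n_control] = ctrl_mean[:, None] + noise[:, : cfg.n_control]
    values[:, cfg.n_control :] = case_mean[:, None] + noise[:, cfg.n_control :]
    samples = tuple(
        [f"{name}_ctrl{i+1}" for i in range(cfg.n_control)]
        + [f"{name}_case{i+1}" for i in range(cfg.n_case)]
    )
    groups = ("control",) * cfg.n_control + ("case",) * cfg.n_case
    mat = ExpressionMatrix(
        name=name,
        genes=tuple(symbols),
        values=values,
        samples=samples,
        groups=groups,
        scale="log2",
        species="mouse",
    )
    return mat, truth


def truth_signature(mat: ExpressionMatrix, fc_threshold: float = 1.2) -> Signature:
    """Signature of genes whose group-mean |log2 FC| exceeds the cutoff.

    The deterministic limit of DEG calling: with zero residual noise the
    replicates are identical, the t-test carries no information, and the
    fold-change filter alone recovers exactly the planted genes.
    """
    case = mat.values[:, mat.case_mask].mean(axis=1)
    ctrl = mat.values[:, ~mat.case_mask].mean(axis=1)
    l2fc = case - ctrl if mat.scale == "log2" else np.log2(case / ctrl)
    cut = math.log2(fc_threshold)
    entries = [
        GeneEntry(gene, float(fc))
        for gene, fc in zip(mat.genes, l2fc)
        if abs(fc) > cut
    ]
    return Signature.from_entries(mat.name, mat.species, entries)


def _default_trend(s: float) -> dict[str, tuple[float, float]]:
    """Disease-severity schedule: with growing severity the dataset becomes
    more discordant with maturity and pH and more concordant with
    hyperexcitation, emulating co-varying immaturity/acidification/
    hyperexcitation signatures."""
    grow = 0.05 + 0.45 * s
    return {
        "maturity": (0.03, grow),
        "ph": (0.03, grow),
        "hyperexcitation": (grow, 0.03),
    }


def _null_trend(s: float) -> dict[str, tuple[float, float]]:
    return {r: (0.0, 0.0) for r in REFERENCE_NAMES}


TRENDS: dict[str, Callable[[float], dict[str, tuple[float, float]]]] = {
    "ad-like": _default_trend,
    "null": _null_trend,
}


def generate_cohort(
    cfg: SyntheticConfig,
    n_datasets: int = 20,
    trend: str | Callable[[float], dict[str, tuple[float, float]]] = "ad-like",
    n_terms: int = 30,
    term_size: int = 40,
    out_dir: str | Path | None = None,
) -> SyntheticStudy:
    """Generate a full multi-dataset study.

    Per-dataset planting fractions follow the trend schedule over a severity
    grid, and planting uses one fixed permutation per reference so planted
    gene sets are nested across datasets (low-severity cores are shared by
    all). The GMT collection holds random terms plus one planted term drawn
    from the genes every dataset plants against the maturity reference.
    """
    if n_datasets < 3:
        raise ValueError("need >= 3 datasets for downstream correlations")
    trend_fn = TRENDS[trend] if isinstance(trend, str) else trend
    rng = np.random.default_rng(cfg.seed)
    references = generate_references(cfg, rng)
    universe = Universe(symbols=frozenset(_universe_symbols(cfg.universe_size)))
    planting_order = {
        rname: list(rng.permutation(sorted(ref.symbols)))
        for rname, ref in references.items()
    }
    severities = np.linspace(0.1, 0.95, n_datasets)
    datasets: dict[str, ExpressionMatrix] = {}
    truth: dict[str, dict] = {}
    for i, s in enumerate(severities):
        name = f"ADmodel{i+1:02d}"
        mat, t = generate_dataset(
            cfg,
            name,
            trend_fn(float(s)),
            references,
            rng,
            planting_order=planting_order,
        )
        datasets[name] = mat
        truth[name] = t

    symbols = np.array(_universe_symbols(cfg.universe_size))
    sets: dict[str, frozenset[str]] = {}
    planted_term: str | None = None
    core = set.intersection(
        *(
            set(truth[d]["references"]["maturity"]["concordant"])
            | set(truth[d]["references"]["maturity"]["discordant"])
            for d in truth
        )
    )
    if len(core) >= min(term_size, 10):
        take = min(term_size, len(core))
        planted_term = "PLANTED_SET"
        sets[planted_term] = frozenset(
            rng.choice(sorted(core), take, replace=False)
        )
    for j in range(n_terms - (1 if planted_term else 0)):
        sets[f"RAND_SET_{j+1:02d}"] = frozenset(
            rng.choice(symbols, term_size, replace=False)
        )
    gmt = GeneSetCollection(sets=sets, provenance="synthetic")

    study = SyntheticStudy(
        config=cfg,
        universe=universe,
        references=references,
        datasets=datasets,
        truth=truth,
        gmt=gmt,
        planted_term=planted_term,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write the study as the TSV/GMT fixture tree the pipeline consumes."""
    out = Path(out_dir)
    (out / "references").mkdir(parents=True, exist_ok=True)
    (out / "datasets").mkdir(exist_ok=True)
    for rname, ref in study.references.items():
        write_deg_table(ref, out / "references" / f"{rname}.tsv")
    for name, mat in study.datasets.items():
        mat.to_tsv(
            out / "datasets" / f"{name}.tsv",
            groups_path=out / "datasets" / f"{name}.groups.tsv",
        )
    write_gmt(study.gmt, out / "collection.gmt")
    with open(out / "universe.txt", "w") as fh:
        fh.write("\n".join(sorted(study.universe.symbols)) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {"planted_term": study.planted_term, "datasets": study.truth},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(study.config.to_dict(), fh, sort_keys=True)
    log.info("synthetic study written to %s", out)
    return out
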