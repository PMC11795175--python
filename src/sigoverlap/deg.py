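"""Differential-expression calling from two-group expression matrices.

A gene is called differentially expressed when its absolute fold change
exceeds 1.2 and its two-sided Welch t-test p-value is below 0.05 (both
strict). No multiple-testing correction is applied at this stage: the
downstream overlap statistics are rank-based and consume the full DEG list,
so the raw-p criterion matches how such disease-model gene lists are
conventionally defined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import GeneEntry, Signature

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEGParams",
    "fold_change",
    "welch_t",
    "call_degs",
]

GROUPS = ("case", "control")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with a two-group design.

    ``scale`` is ``"log2"`` (values already log-transformed) or ``"linear"``
    (strictly positive intensities). Fold changes are case over control.
    """

    name: str
    genes: tuple[str, ...]
    values: np.ndarray
    samples: tuple[str, ...]
    groups: tuple[str, ...]
    scale: str = "log2"
    species: str = "mouse"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "samples", tuple(self.samples))
        object.__setattr__(self, "groups", tuple(self.groups))
        if values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample required")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; use {GROUPS}")
        for g in GROUPS:
            if self.groups.count(g) < 2:
                raise ValueError(f"need >= 2 samples in group {g!r}")
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and not (values > 0).all():
            raise ValueError("linear-scale matrix must be strictly positive")

    @property
    def case_mask(self) -> np.ndarray:
        return np.array([g == "case" for g in self.groups])

    def to_tsv(self, path: str | Path, groups_path: str | Path | None = None) -> None:
        df = pd.DataFrame(self.values, columns=list(self.samples))
        df.insert(0, "gene", list(self.genes))
        df.to_csv(path, sep="\t", index=False)
        if groups_path is not None:
            pd.DataFrame({"sample": self.samples, "group": self.groups}).to_csv(
                groups_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        groups: str | Path | Mapping[str, str],
        scale: str = "log2",
        name: str | None = None,
        species: str = "mouse",
    ) -> "ExpressionMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if df.columns[0].lower() != "gene":
            raise ValueError(f"{path}: first column must be 'gene'")
        if not isinstance(groups, Mapping):
            gdf = pd.read_csv(groups, sep="\t")
            groups = dict(zip(gdf["sample"].astype(str), gdf["group"].astype(str)))
        samples = tuple(df.columns[1:])
        missing = [s for s in samples if s not in groups]
        if missing:
            raise ValueError(f"{path}: samples without group assignment: {missing[:5]}")
        return cls(
            name=name or path.stem,
            genes=tuple(df.iloc[:, 0].astype(str)),
            values=df.iloc[:, 1:].to_numpy(dtype=float),
            samples=samples,
            groups=tuple(groups[s] for s in samples),
            scale=scale,
            species=species,
        )


@dataclass(frozen=True)
class DEGParams:
    """DEG thresholds: linear fold-change cutoff and raw p cutoff."""

    fc_threshold: float = 1.2
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must exceed 1")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0,1)")

    @property
    def log2_fc_threshold(self) -> float:
        return math.log2(self.fc_threshold)


def fold_change(
    row: Sequence[float], groups: Sequence[str], scale: str = "log2"
) -> float:
    """Signed log2 fold change (case over control) for one gene's row."""
    row = np.asarray(row, dtype=float)
    case = row[[g == "case" for g in groups]]
    ctrl = row[[g == "control" for g in groups]]
    if scale == "linear":
        mc, mx = float(ctrl.mean()), float(case.mean())
        if mc <= 0 or mx <= 0:
            raise ValueError("non-positive group mean on linear scale")
        return math.log2(mx / mc)
    if scale == "log2":
        return float(case.mean() - ctrl.mean())
    raise ValueError(f"unknown scale {scale!r}")


def welch_t(row_a: Sequence[float], row_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, p)``. When both groups have zero variance no evidence is
    computable and ``(0.0, 1.0)`` is returned with a warning.
    """
    a = np.asarray(row_a, dtype=float)
    b = np.asarray(row_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        log.warning("welch_t: both groups have zero variance; returning p = 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _welch_rows(case: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch test per gene row; degenerate rows get p = 1."""
    t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = (case.var(axis=1, ddof=1) == 0.0) & (ctrl.var(axis=1, ddof=1) == 0.0)
    if degenerate.any():
        log.warning(
            "call_degs: %d genes with zero variance in both groups (p set to 1)",
            int(degenerate.sum()),
        )
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    bad = ~np.isfinite(p)
    if bad.any():
        # e.g. one group constant and identical means -> nan from scipy
        t[bad] = 0.0
        p[bad] = 1.0
    return t, p


def call_degs(mat: ExpressionMatrix, params: DEGParams = DEGParams()) -> Signature:
    """Call DEGs: |log2 FC| > log2(fc_threshold) AND p < p_threshold, strict.

    Scores of the returned signature are the signed log2 fold changes;
    per-gene Welch p-values are attached.
    """
    case = mat.values[:, mat.case_mask]
    ctrl = mat.values[:, ~mat.case_mask]
    if mat.scale == "linear":
        mcase = case.mean(axis=1)
        mctrl = ctrl.mean(axis=1)
        if (mcase <= 0).any() or (mctrl <= 0).any():
            raise ValueError("non-positive group mean on linear scale")
        l2fc = np.log2(mcase / mctrl)
    else:
        l2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    _, p = _welch_rows(case, ctrl)
    keep = (np.abs(l2fc) > params.log2_fc_threshold) & (p < params.p_threshold)
    entries = [
        GeneEntry(mat.genes[i], float(l2fc[i]), float(p[i]))
        for i in np.nonzero(keep)[0]
    ]
    log.info("call_degs %r: %d / %d genes pass", mat.name, len(entries), len(mat.genes))
    return Signature.from_entries(mat.name, mat.species, entries)
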