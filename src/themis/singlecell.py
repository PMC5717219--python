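"""Bayesian assignment of single cells to normal / parent / child clones.

The regions come from a two-tumor-clone bulk decomposition: clonal 2-copy
(no-CNA) segments give each cell its baseline coverage rate; clonal 1-copy
(LOH) segments separate tumor from normal cells; subclonal 1-copy segments
separate the child clone (which carries them) from its parent (which does
not).  Per-segment read counts are modeled as Poisson with rate proportional
to segment length times the class's relative copy number (copies/2, so LOH
regions sit at 0.5), with the per-cell baseline rate fitted from the clonal
2-copy regions.  The three expected coverage signatures in (clonal LOH,
subclonal LOH) are therefore ~(1.0, 1.0) for normal cells, ~(0.5, 1.0) for
parent cells and ~(0.5, 0.5) for child cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

REGION_CLASSES = ("clonal_2copy", "clonal_loh", "subclonal_loh")
CLASS_LABELS = ("normal", "parent", "child")

#: expected relative copy (copies / 2) per cell class and region class
RELATIVE_COPY = {
    "normal": {"clonal_2copy": 1.0, "clonal_loh": 1.0, "subclonal_loh": 1.0},
    "parent": {"clonal_2copy": 1.0, "clonal_loh": 0.5, "subclonal_loh": 1.0},
    "child": {"clonal_2copy": 1.0, "clonal_loh": 0.5, "subclonal_loh": 0.5},
}


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int   # 1-based closed
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionSet:
    """The three genomic region classes used by the classifier."""

    clonal_2copy: list = field(default_factory=list)
    clonal_loh: list = field(default_factory=list)
    subclonal_loh: list = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict = {}
        for rc in REGION_CLASSES:
            for r in getattr(self, rc):
                by_chrom.setdefault(r.chrom, []).append((r.start, r.end, rc))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s1, e1, c1), (s2, e2, c2) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"overlapping regions on {chrom}: "
                        f"{c1} [{s1},{e1}] vs {c2} [{s2},{e2}]")

    def lengths(self, region_class: str) -> np.ndarray:
        return np.array([r.length for r in getattr(self, region_class)], dtype=float)

    def n_segments(self, region_class: str) -> int:
        return len(getattr(self, region_class))


@dataclass
class CellCoverage:
    """Per-cell read counts over the region-set segments."""

    cell_id: str
    counts: dict                        # region class -> int array per segment
    total_reads: int
    short_read_fraction: float = 0.0
    qc_pass: bool = True


def derive_regions(decomposition) -> RegionSet:
    """Region classes from a two-tumor-clone bulk decomposition.

    clonal 2-copy: no-CNA (AB) segments; clonal LOH: 1-copy segments of the
    parent clone (clone 1); subclonal LOH: 1-copy segments of the child
    clone (clone 2).
    """
    if decomposition.n_clones != 2:
        raise ValueError("region derivation expects a 2-tumor-clone decomposition")
    seg = decomposition.segments
    seg = seg[seg["n_sites"] >= 1]

    def pick(mask) -> list:
        return [Region(str(r.chrom), int(r.start), int(r.end))
                for r in seg[mask].itertuples()]

    out = RegionSet(
        clonal_2copy=pick(seg["genotype"] == "AB"),
        clonal_loh=pick((seg["total_copies"] == 1) & (seg["clone"] == 1)),
        subclonal_loh=pick((seg["total_copies"] == 1) & (seg["clone"] == 2)),
    )
    if not out.clonal_loh or not out.subclonal_loh:
        warnings.warn("decomposition has no LOH segments for one or more classes; "
                      "the classifier cannot separate the corresponding clones")
    return out


def qc_filter(cells: Sequence[CellCoverage], min_reads: int = 10000,
              short_read_fraction_max: float = 0.3):
    """Drop cells with too few reads or too large a short-read fraction."""
    kept, excluded = [], []
    for c in cells:
        ok = c.total_reads >= min_reads and c.short_read_fraction <= short_read_fraction_max
        c.qc_pass = bool(ok)
        (kept if ok else excluded).append(c)
    return kept, excluded


def classify_cell(cov: CellCoverage, regions: RegionSet,
                  priors: Optional[Sequence[float]] = None):
    """Assign one cell to normal / parent / child with a posterior vector.

    Per-class likelihood is a product over segments of Poisson counts at
    rate baseline * relative_copy * length, with the baseline rate fitted
    from the cell's clonal 2-copy coverage.  A cell with zero baseline
    coverage is unclassifiable and reported distinctly as label ``unknown``
    with no posterior.
    """
    pri = np.full(3, 1.0 / 3.0) if priors is None else np.asarray(priors, float)
    if pri.shape != (3,) or np.any(pri < 0) or not np.isclose(pri.sum(), 1.0):
        raise ValueError("priors must be a probability vector over the 3 classes")
    base_len = regions.lengths("clonal_2copy").sum()
    base_count = float(np.sum(cov.counts.get("clonal_2copy", 0)))
    if base_len <= 0 or base_count <= 0:
        return "unknown", None
    lam = base_count / base_len  # reads per bp at relative copy 1
    logliks = np.zeros(3)
    for k, label in enumerate(CLASS_LABELS):
        for rc in REGION_CLASSES:
            lens = regions.lengths(rc)
            if lens.size == 0:
                continue
            counts = np.asarray(cov.counts.get(rc, np.zeros_like(lens)), dtype=np.int64)
            mu = np.maximum(lam * lens * RELATIVE_COPY[label][rc], 1e-12)
            logliks[k] += float(poisson.logpmf(counts, mu).sum())
    post = logliks + np.log(np.maximum(pri, 1e-300))
    post -= post.max()
    post = np.exp(post)
    post /= post.sum()
    return CLASS_LABELS[int(np.argmax(post))], post


def classify_cells(cells: Sequence[CellCoverage], regions: RegionSet,
                   priors: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Classify many cells; returns a tidy assignment table."""
    rows = []
    for c in cells:
        label, post = classify_cell(c, regions, priors)
        rows.append({
            "cell_id": c.cell_id,
            "label": label,
            "p_normal": float(post[0]) if post is not None else np.nan,
            "p_parent": float(post[1]) if post is not None else np.nan,
            "p_child": float(post[2]) if post is not None else np.nan,
        })
    return pd.DataFrame(rows)
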