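"""Allelic copy-number genotype states and their expected observation signals.

A tumor genotype is an allelic copy-number state: ``total_copies`` copies of
the locus of which ``alt_copies`` carry the alternative allele.  The label
convention writes reference copies as ``A`` and alternative copies as ``B``,
so ``AB`` is the diploid heterozygous (no-CNA) state, ``A`` a hemizygous
deletion of the B allele, ``AAB`` a single-copy gain of the A allele, and so
on.  The homozygous deletion (0 copies) is written ``∅``.

Two deterministic functions couple a genotype and a cellular prevalence ``p``
(the fraction of cells in the biopsy carrying the event) to the expected bulk
signals: the expected allelic ratio (the population-weighted fraction of
alternative-allele copies) and the expected tumor/normal log2 depth ratio.
Both are means of Gaussian observation models; they are never estimated from
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

#: Copy number of the locus in normal cells.
NORMAL_TOTAL = 2

#: Floor applied to the population-average copy number before taking log2,
#: so a homozygous deletion at prevalence 1 has a finite expected log ratio.
MIN_EFFECTIVE_COPIES = 0.01

GERMLINE = "germline"
SOMATIC = "somatic"

_SITE_TYPE_ALIASES = {
    GERMLINE: GERMLINE,
    "het": GERMLINE,
    0: GERMLINE,
    SOMATIC: SOMATIC,
    "som": SOMATIC,
    1: SOMATIC,
}


def normal_alt_copies(site_type: Union[str, int]) -> int:
    """Alternative-allele copies in a normal cell: 1 at germline-het sites, 0 at somatic sites."""
    try:
        canonical = _SITE_TYPE_ALIASES[site_type]
    except (KeyError, TypeError):
        raise ValueError(f"unknown site type: {site_type!r}") from None
    return 1 if canonical == GERMLINE else 0


@dataclass(frozen=True, order=True)
class Genotype:
    """An allelic copy-number state (n total copies, a of them alternative)."""

    total_copies: int
    alt_copies: int

    def __post_init__(self) -> None:
        if not (0 <= self.alt_copies <= self.total_copies):
            raise ValueError(
                f"invalid genotype: need 0 <= alt <= total, got "
                f"({self.total_copies}, {self.alt_copies})"
            )

    @property
    def label(self) -> str:
        if self.total_copies == 0:
            return "∅"
        n_ref = self.total_copies - self.alt_copies
        return "A" * n_ref + "B" * self.alt_copies

    @property
    def is_null(self) -> bool:
        """True for the designated no-CNA state AB (2 copies, 1 alternative)."""
        return self.total_copies == 2 and self.alt_copies == 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_genotypes(c_max: int) -> list[Genotype]:
    """All genotypes with 0 <= alt <= total <= ``c_max``, ordered by total then alt.

    The ordering is fixed (total-copies major, alt-copies minor) so that state
    indices are reproducible across runs.  The count is
    ``sum_{n=0..c_max} (n+1)``; c_max=5 gives 21 states.
    """
    if c_max < 0:
        raise ValueError(f"c_max must be >= 0, got {c_max}")
    return [Genotype(n, a) for n in range(c_max + 1) for a in range(n + 1)]


def null_genotype_index(genotypes: Sequence[Genotype]) -> int:
    """Index of the unique no-CNA state AB in an enumerated genotype list."""
    for i, g in enumerate(genotypes):
        if g.is_null:
            return i
    raise ValueError("genotype list has no AB (2,1) state; c_max must be >= 2")


def _check_prevalence(p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"prevalence must be in [0, 1], got {p}")


def expected_allelic_ratio(g: Genotype, p: float, site_type: Union[str, int]) -> float:
    """Expected allelic ratio for genotype ``g`` at carrier prevalence ``p``.

    Mixes ``p`` tumor cells carrying ``g`` with ``1-p`` normal cells:

        (n_alt * p + n_alt_normal * (1-p)) / (n * p + 2 * (1-p))

    where the normal alternative copy number is 1 at germline-het sites and 0
    at somatic-SNV sites.  A vanishing denominator (homozygous deletion at
    p=1) is mapped to 0.5, treating the undefined ratio as pure mapping noise.
    """
    _check_prevalence(p)
    n_alt_normal = normal_alt_copies(site_type)
    denom = g.total_copies * p + NORMAL_TOTAL * (1.0 - p)
    if denom <= 0.0:
        return 0.5
    return (g.alt_copies * p + n_alt_normal * (1.0 - p)) / denom


def expected_log_ratio(g: Genotype, p: float, c_m: float = 0.0) -> float:
    """Expected tumor/normal log2 depth ratio, offset by the biopsy constant ``c_m``.

    The population-average copy number ``n*p + 2*(1-p)`` is floored at
    :data:`MIN_EFFECTIVE_COPIES` before the log so total deletion stays finite.
    """
    _check_prevalence(p)
    effective = g.total_copies * p + NORMAL_TOTAL * (1.0 - p)
    effective = max(effective, MIN_EFFECTIVE_COPIES)
    return float(np.log2(effective / NORMAL_TOTAL) + c_m)


def invert_allelic_ratio(g: Genotype, ratio: float, site_type: Union[str, int]) -> float:
    """Solve the expected-allelic-ratio formula for the prevalence ``p``.

    Given an observed allelic ratio and an assumed genotype, returns the
    carrier prevalence at which the expected ratio equals the observation.
    For example, a somatic site with ratio 0.3 implies p = 0.6 under AB but
    p ≈ 0.857 under AAB, which is why copy number must be modeled jointly
    with SNVs.

    Raises ``ValueError`` when the expected ratio does not depend on p for
    this genotype/site-type (e.g. AB at a germline site) or when the solution
    falls outside [0, 1].
    """
    n_alt_normal = normal_alt_copies(site_type)
    denom = g.alt_copies - n_alt_normal - ratio * (g.total_copies - NORMAL_TOTAL)
    if abs(denom) < 1e-12:
        raise ValueError(
            f"allelic ratio is constant in p for genotype {g.label} at a "
            f"{site_type} site; prevalence is unidentifiable"
        )
    p = (NORMAL_TOTAL * ratio - n_alt_normal) / denom
    if not (-1e-9 <= p <= 1.0 + 1e-9):
        raise ValueError(
            f"no prevalence in [0, 1] yields ratio {ratio} under genotype {g.label}"
        )
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Vectorized forms used by the emission model.

def genotype_arrays(genotypes: Sequence[Genotype]) -> tuple[np.ndarray, np.ndarray]:
    """(total_copies, alt_copies) as integer arrays over a genotype list."""
    n = np.array([g.total_copies for g in genotypes], dtype=np.int64)
    a = np.array([g.alt_copies for g in genotypes], dtype=np.int64)
    return n, a


def allelic_ratio_means(
    n: np.ndarray, a: np.ndarray, phi: np.ndarray, site_type: Union[str, int]
) -> np.ndarray:
    """Expected allelic ratios on the (genotype, clone) product grid.

    ``n``/``a`` have shape (G,), ``phi`` holds per-clone carrier prevalences
    with shape (Z,); the result has shape (G, Z).
    """
    n_alt_normal = normal_alt_copies(site_type)
    p = np.asarray(phi, dtype=float)[None, :]
    denom = n[:, None] * p + NORMAL_TOTAL * (1.0 - p)
    numer = a[:, None] * p + n_alt_normal * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(denom > 0.0, numer / np.where(denom > 0.0, denom, 1.0), 0.5)
    return mu


def log_ratio_means(n: np.ndarray, phi: np.ndarray, c_m: float) -> np.ndarray:
    """Expected log2 depth ratios on the (genotype, clone) product grid."""
    p = np.asarray(phi, dtype=float)[None, :]
    effective = np.maximum(n[:, None] * p + NORMAL_TOTAL * (1.0 - p), MIN_EFFECTIVE_COPIES)
    return np.log2(effective / NORMAL_TOTAL) + c_m
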