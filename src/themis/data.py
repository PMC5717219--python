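"""Container for per-site bulk sequencing observations.

The model consumes one row per genomic site: chromosome, 1-based position,
site type (germline heterozygous ``het`` or somatic SNV ``som``) and, per
biopsy, the allelic ratio A and the tumor/normal log2 depth ratio L.
``SiteData`` stores these as dense arrays, derives the chromosome-start
indicator S (true at the first site of each chromosome) and the inter-site
distance H in base pairs, and validates the ordering contract: within a
chromosome positions strictly increase, and each chromosome forms one
contiguous block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

SITE_TYPE_CODES = {"het": 0, "som": 1}
SITE_TYPE_LABELS = {0: "het", 1: "som"}


class SiteTableError(ValueError):
    """Raised for malformed site tables (unsorted, duplicated, non-numeric)."""


@dataclass(frozen=True)
class SiteRecord:
    """A single genomic site with per-biopsy observations."""

    chrom: str
    pos: int
    site_type: int          # 0 germline-het, 1 somatic-SNV
    chrom_start: bool       # S_t
    distance: float         # H_t in bp; 1.0 placeholder at chromosome starts
    obs_allelic: np.ndarray   # (M,) allelic ratios
    obs_logratio: np.ndarray  # (M,) log2 depth ratios


class SiteData:
    """Validated, ordered site-level observations for one or more biopsies."""

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        site_type: Sequence[int],
        A: np.ndarray,
        L: np.ndarray,
        validate: bool = True,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.site_type = np.asarray(site_type, dtype=np.int8)
        A = np.atleast_2d(np.asarray(A, dtype=float))
        L = np.atleast_2d(np.asarray(L, dtype=float))
        self.A = A
        self.L = L
        if validate:
            self._validate_shapes()
        self.start, self.h = self._positional_fields()
        if validate:
            self._validate_values()

    # -- construction -----------------------------------------------------

    def _validate_shapes(self) -> None:
        T = len(self.pos)
        if T == 0:
            raise SiteTableError("site table is empty")
        for name, arr in (("chrom", self.chrom), ("site_type", self.site_type)):
            if len(arr) != T:
                raise SiteTableError(f"{name} length {len(arr)} != {T}")
        if self.A.shape[1] != T or self.L.shape[1] != T:
            raise SiteTableError("observation arrays do not match the site count")
        if self.A.shape[0] != self.L.shape[0]:
            raise SiteTableError("allelic-ratio and log-ratio biopsy counts differ")

    def _positional_fields(self) -> tuple[np.ndarray, np.ndarray]:
        start = np.zeros(self.n_sites, dtype=bool)
        start[0] = True
        start[1:] = self.chrom[1:] != self.chrom[:-1]
        h = np.ones(self.n_sites, dtype=float)
        diffs = self.pos[1:] - self.pos[:-1]
        h[1:] = np.where(start[1:], 1.0, diffs)
        return start, h

    def _validate_values(self) -> None:
        seen: dict = {}
        for i, c in enumerate(self.chrom):
            if c in seen and not (self.chrom[i - 1] == c):
                raise SiteTableError(
                    f"chromosome {c!r} appears in non-contiguous blocks (site {i + 1})"
                )
            seen[c] = True
        interior = ~self.start
        bad = np.where(interior & (self.h < 1))[0]
        if bad.size:
            i = int(bad[0])
            if self.h[i] == 0:
                raise SiteTableError(
                    f"duplicated position {self.pos[i]} on {self.chrom[i]} (site {i + 1})"
                )
            raise SiteTableError(
                f"positions not strictly increasing on {self.chrom[i]} (site {i + 1})"
            )
        if not np.all(np.isfinite(self.A)) or np.any(self.A < 0) or np.any(self.A > 1):
            raise SiteTableError("allelic ratios must be finite and in [0, 1]")
        if not np.all(np.isfinite(self.L)):
            raise SiteTableError("log ratios must be finite")
        if not np.all((self.site_type == 0) | (self.site_type == 1)):
            raise SiteTableError("site_type codes must be 0 (het) or 1 (som)")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteData":
        """Build from a DataFrame with columns chrom, pos, type and per-biopsy
        allelic_ratio_<m> / log_ratio_<m> pairs (or unsuffixed for one biopsy)."""
        required = {"chrom", "pos", "type"}
        missing = required - set(df.columns)
        if missing:
            raise SiteTableError(f"missing columns: {sorted(missing)}")
        if "allelic_ratio" in df.columns and "log_ratio" in df.columns:
            a_cols, l_cols = ["allelic_ratio"], ["log_ratio"]
        else:
            a_cols, l_cols = [], []
            m = 1
            while f"allelic_ratio_{m}" in df.columns:
                if f"log_ratio_{m}" not in df.columns:
                    raise SiteTableError(f"allelic_ratio_{m} present without log_ratio_{m}")
                a_cols.append(f"allelic_ratio_{m}")
                l_cols.append(f"log_ratio_{m}")
                m += 1
            if not a_cols:
                raise SiteTableError("no allelic_ratio/log_ratio columns found")
        try:
            site_type = df["type"].map(SITE_TYPE_CODES)
        except Exception as exc:  # pragma: no cover - defensive
            raise SiteTableError(f"bad site types: {exc}")
        if site_type.isna().any():
            row = int(site_type.index[site_type.isna()][0])
            raise SiteTableError(f"unknown site type {df['type'].iloc[row]!r} (row {row + 1})")
        A = df[a_cols].to_numpy(dtype=float).T
        L = df[l_cols].to_numpy(dtype=float).T
        return cls(df["chrom"].astype(str).to_numpy(), df["pos"].to_numpy(),
                   site_type.to_numpy(), A, L)

    # -- views -------------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_biopsies(self) -> int:
        return self.A.shape[0]

    @property
    def chromosomes(self) -> list:
        """Chromosome names in order of first appearance."""
        out, last = [], None
        for c in self.chrom:
            if c != last:
                out.append(c)
                last = c
        return out

    def select_biopsy(self, m: int) -> "SiteData":
        """Single-biopsy view (biopsy index 0-based)."""
        return SiteData(self.chrom, self.pos, self.site_type,
                        self.A[m : m + 1], self.L[m : m + 1], validate=False)

    def select_sites(self, mask: np.ndarray) -> "SiteData":
        """Row subset; chromosome-start flags and distances are recomputed."""
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise SiteTableError("site selection is empty")
        return SiteData(self.chrom[mask], self.pos[mask], self.site_type[mask],
                        self.A[:, mask], self.L[:, mask], validate=False)

    def subset_chromosomes(self, names: Sequence) -> "SiteData":
        names = set(names)
        mask = np.array([c in names for c in self.chrom])
        if not mask.any():
            raise SiteTableError(f"no sites on chromosomes {sorted(names)}")
        return SiteData(self.chrom[mask], self.pos[mask], self.site_type[mask],
                        self.A[:, mask], self.L[:, mask], validate=False)

    def records(self) -> Iterator[SiteRecord]:
        for t in range(self.n_sites):
            yield SiteRecord(
                chrom=str(self.chrom[t]), pos=int(self.pos[t]),
                site_type=int(self.site_type[t]), chrom_start=bool(self.start[t]),
                distance=float(self.h[t]),
                obs_allelic=self.A[:, t].copy(), obs_logratio=self.L[:, t].copy(),
            )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "chrom": self.chrom,
            "pos": self.pos,
            "type": [SITE_TYPE_LABELS[int(d)] for d in self.site_type],
        }
        for m in range(self.n_biopsies):
            data[f"allelic_ratio_{m + 1}"] = self.A[m]
            data[f"log_ratio_{m + 1}"] = self.L[m]
        return pd.DataFrame(data)

    def __len__(self) -> int:
        return self.n_sites

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"SiteData(T={self.n_sites}, M={self.n_biopsies}, "
                f"chromosomes={self.chromosomes})")
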