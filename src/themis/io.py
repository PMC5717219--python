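"""File formats: site tables, segment TSV/BED, parameter JSON, Newick, coverage.

Conventions: site tables and segment TSVs use 1-based closed coordinates;
BED exports use the standard 0-based half-open convention.  All writers are
deterministic given identical inputs.
"""

from __future__ import annotations

import json
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import SiteData, SiteTableError
from .singlecell import REGION_CLASSES, CellCoverage, Region, RegionSet

SITE_COLUMNS = ("chrom", "pos", "type")


def read_site_table(path) -> SiteData:
    """Read and validate a tab-separated site table.

    Expected columns: chrom, pos, type (het|som), then per biopsy
    allelic_ratio_<m> and log_ratio_<m> (unsuffixed accepted for a single
    biopsy).  Malformed rows are reported with their line number; unsorted or
    duplicated positions are an error, never silently fixed.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:
        raise SiteTableError(f"cannot parse {path}: {exc}") from None
    num_cols = [c for c in df.columns if c not in ("chrom", "type")]
    for col in num_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.where(bad)[0][0]) + 2  # header is line 1
            raise SiteTableError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at line {line}")
        if coerced.isna().any():
            line = int(np.where(coerced.isna())[0][0]) + 2
            raise SiteTableError(f"{path}: missing value in column {col!r} at line {line}")
        df[col] = coerced
    try:
        return SiteData.from_frame(df)
    except SiteTableError as exc:
        # the container reports 1-based site indices; convert to file lines
        msg = str(exc)
        if "(site " in msg:
            idx = int(msg.rsplit("(site ", 1)[1].rstrip(")"))
            msg = f"{msg[: msg.rindex('(site')]}(line {idx + 1})"
        raise SiteTableError(f"{path}: {msg}") from None


def write_site_table(sites: SiteData, path) -> None:
    sites.to_frame().to_csv(path, sep="\t", index=False)


def write_segments(segments: pd.DataFrame, tsv_path, bed_path) -> None:
    """Segment table as 1-based closed TSV plus 0-based half-open BED."""
    segments.to_csv(tsv_path, sep="\t", index=False)
    with open(bed_path, "w") as fh:
        for r in segments.itertuples():
            name = f"{r.genotype}|clone{r.clone}|{r.status}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def write_outputs(decomposition, outdir) -> dict:
    """Standard single-run outputs: segments TSV + BED and a parameter dump."""
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "segments_tsv": os.path.join(outdir, "segments.tsv"),
        "segments_bed": os.path.join(outdir, "segments.bed"),
        "params_json": os.path.join(outdir, "params.json"),
    }
    write_segments(decomposition.segments, paths["segments_tsv"], paths["segments_bed"])
    payload = {
        "params": decomposition.params.to_dict(),
        "prevalence_levels": decomposition.prevalence.levels.tolist(),
        "cell_fractions": (decomposition.prevalence.cell_fractions.tolist()
                           if decomposition.prevalence.ordered else None),
        "loglik": float(decomposition.loglik),
        "n_clones": int(decomposition.n_clones),
    }
    with open(paths["params_json"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths


def write_selection_report(report, path) -> None:
    report.to_json(path)


def write_tree(tree, outdir) -> dict:
    """Newick tree plus the per-edge mutation count table."""
    from .phylogeny import edge_mutation_table

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tree_newick": os.path.join(outdir, "phylogeny.nwk"),
        "edges_tsv": os.path.join(outdir, "edge_mutations.tsv"),
    }
    with open(paths["tree_newick"], "w") as fh:
        fh.write(tree.to_newick() + "\n")
    edge_mutation_table(tree).to_csv(paths["edges_tsv"], sep="\t", index=False)
    return paths


def write_regions_bed(regions: RegionSet, outdir) -> dict:
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for rc in REGION_CLASSES:
        p = os.path.join(outdir, f"{rc}.bed")
        with open(p, "w") as fh:
            for r in getattr(regions, rc):
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{rc}\n")
        paths[rc] = p
    return paths


def read_regions_bed(paths: dict) -> RegionSet:
    """Region set from three BED files keyed by region class."""
    kwargs = {}
    for rc in REGION_CLASSES:
        regions = []
        with open(paths[rc]) as fh:
            for line in fh:
                if not line.strip():
                    continue
                chrom, start, end = line.split("\t")[:3]
                regions.append(Region(chrom, int(start) + 1, int(end)))
        kwargs[rc] = regions
    return RegionSet(**kwargs)


def write_cell_coverage(cells: Sequence[CellCoverage], regions: RegionSet, path) -> None:
    """Coverage as a tidy TSV: cell_id, chrom, start, end, count."""
    rows = []
    for c in cells:
        for rc in REGION_CLASSES:
            for r, count in zip(getattr(regions, rc), c.counts.get(rc, [])):
                rows.append((c.cell_id, r.chrom, r.start, r.end, int(count)))
    pd.DataFrame(rows, columns=["cell_id", "chrom", "start", "end", "count"]).to_csv(
        path, sep="\t", index=False)


def read_cell_coverage(path, regions: RegionSet,
                       qc_table: Optional[pd.DataFrame] = None) -> list[CellCoverage]:
    """Coverage TSV -> per-cell counts aligned to the region-set segments.

    Rows are matched to segments by exact (chrom, start, end); unmatched
    rows raise.  An optional QC table (cell_id, total_reads,
    short_read_fraction) overrides the totals derived from the counts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    index = {}
    for rc in REGION_CLASSES:
        for i, r in enumerate(getattr(regions, rc)):
            index[(r.chrom, r.start, r.end)] = (rc, i)
    qc = {}
    if qc_table is not None:
        for r in qc_table.itertuples():
            qc[str(r.cell_id)] = (int(r.total_reads), float(r.short_read_fraction))
    cells = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        counts = {rc: np.zeros(regions.n_segments(rc), dtype=np.int64)
                  for rc in REGION_CLASSES}
        for r in group.itertuples():
            key = (str(r.chrom), int(r.start), int(r.end))
            if key not in index:
                raise SiteTableError(
                    f"{path}: coverage interval {key} matches no region segment")
            rc, i = index[key]
            counts[rc][i] = int(r.count)
        total = int(sum(c.sum() for c in counts.values()))
        short = 0.0
        if str(cell_id) in qc:
            total, short = qc[str(cell_id)]
        cells.append(CellCoverage(cell_id=str(cell_id), counts=counts,
                                  total_reads=total, short_read_fraction=short))
    return cells
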