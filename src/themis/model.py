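"""Model-level API: a CloneHMM built from site data, fit() -> CloneHMMResults.

The model couples two hidden Markov chains over genomic sites — the allelic
copy-number genotype G_t and the clone index Z_t — with distance-dependent
transitions, Gaussian emissions for the allelic ratio and tumor/normal log
depth ratio, and grid-valued cellular prevalences tied across sites.
``fit`` runs the full training pipeline (EM for variances and priors, grid
maximization for prevalences, two-pass log-ratio offset calibration,
Viterbi decoding) and returns a results object carrying the decoded
segments, clone prevalences, fitted parameters and fit diagnostics.
"""

from __future__ import annotations

import io as _io
from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import SiteData
from .inference import ClonalDecomposition, degrees_of_freedom, run_themis
from .selection import SelectionReport, bic as _bic, select_num_clones


class CloneHMM:
    """Clonal-decomposition model for one or more biopsies of a patient.

    Parameters
    ----------
    sites : SiteData or pandas.DataFrame
        Per-site observations (see :class:`themis.data.SiteData`).
    n_clones : int or "auto"
        Number of tumor clones |Z|; "auto" selects it by the configured
        strategy (BIC by default) before the final fit.
    config, **kwargs
        A :class:`themis.config.RunConfig`, optionally overridden by keyword.
    """

    def __init__(self, sites, n_clones: Union[int, str] = 2,
                 config: Optional[RunConfig] = None, **kwargs) -> None:
        if isinstance(sites, pd.DataFrame):
            sites = SiteData.from_frame(sites)
        if not isinstance(sites, SiteData):
            raise TypeError("sites must be a SiteData or DataFrame")
        self.sites = sites
        self.config = (config or RunConfig()).replace(n_clones=n_clones, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CloneHMM":
        return cls(SiteData.from_frame(df), **kwargs)

    @classmethod
    def from_table(cls, path, **kwargs) -> "CloneHMM":
        from .io import read_site_table

        return cls(read_site_table(path), **kwargs)

    def fit(self, **overrides) -> "CloneHMMResults":
        """Train the model and decode the most probable clonal decomposition."""
        cfg = self.config.replace(**overrides)
        selection = None
        if cfg.n_clones == "auto":
            selection = select_num_clones(self.sites, cfg)
            cfg = cfg.replace(n_clones=selection.chosen_n_clones)
        decomposition = run_themis(self.sites, cfg)
        return CloneHMMResults(self, decomposition, selection=selection)


class CloneHMMResults:
    """Fitted-model results: decoded path and segments, prevalences, parameters."""

    def __init__(self, model: CloneHMM, decomposition: ClonalDecomposition,
                 selection: Optional[SelectionReport] = None) -> None:
        self.model = model
        self.decomposition = decomposition
        self.selection = selection

    # delegated views ------------------------------------------------------

    @property
    def params(self):
        return self.decomposition.params

    @property
    def prevalence(self):
        return self.decomposition.prevalence

    @property
    def path(self):
        return self.decomposition.path

    @property
    def segments(self) -> pd.DataFrame:
        return self.decomposition.segments

    @property
    def genotypes(self):
        return self.decomposition.genotypes

    @property
    def loglik(self) -> float:
        return self.decomposition.loglik

    @property
    def trace(self):
        return self.decomposition.trace

    @property
    def n_clones(self) -> int:
        return self.decomposition.n_clones

    @property
    def clone_prevalences(self) -> pd.DataFrame:
        """Carrier prevalence and cell fraction per biopsy and clone."""
        prev = self.decomposition.prevalence
        rows = []
        for m in range(prev.n_biopsies):
            for z in range(prev.n_clones):
                rows.append({
                    "biopsy": m + 1,
                    "clone": z + 1,
                    "carrier_prevalence": float(prev.levels[m, z]),
                    "cell_fraction": float(prev.cell_fractions[m, z]),
                })
        return pd.DataFrame(rows)

    def site_assignments(self) -> pd.DataFrame:
        return self.decomposition.site_assignments()

    def bic(self) -> float:
        n = self.decomposition.sites.n_sites * self.decomposition.sites.n_biopsies
        return _bic(self.loglik, degrees_of_freedom(self.params), n)

    def summary(self) -> str:
        """Plain-text fit summary."""
        dec = self.decomposition
        sites = dec.sites
        n_het = int((sites.site_type == 0).sum())
        n_som = sites.n_sites - n_het
        seg = dec.segments
        buf = _io.StringIO()
        w = buf.write
        bar = "=" * 64
        w(f"{'Clone HMM results':^64}\n{bar}\n")
        w(f"Sites:            {sites.n_sites} ({n_het} germline-het, {n_som} somatic)\n")
        w(f"Biopsies:         {sites.n_biopsies}\n")
        w(f"Genotype states:  {len(dec.genotypes)} (c_max={dec.config.c_max})\n")
        w(f"Clones:           {dec.n_clones}")
        if self.selection is not None:
            w(f"  (selected by {self.selection.method})")
        w("\n")
        w(f"Log-likelihood:   {dec.loglik:.3f}\n")
        w(f"BIC:              {self.bic():.3f}\n")
        offs = ", ".join(f"{c:.3f}" for c in dec.params.offsets)
        w(f"Log-ratio offset: {offs}\n")
        w(f"EM iterations:    {len(dec.trace)}\n")
        w("-" * 64 + "\n")
        w(" biopsy  clone  carrier_prev  cell_fraction\n")
        for _, r in self.clone_prevalences.iterrows():
            w(f" {int(r['biopsy']):>6} {int(r['clone']):>6}"
              f" {r['carrier_prevalence']:>13.2f} {r['cell_fraction']:>14.2f}\n")
        w("-" * 64 + "\n")
        counts = seg["status"].value_counts().to_dict()
        w(f"Segments:         {len(seg)} "
          f"(normal {counts.get('normal', 0)}, clonal {counts.get('clonal', 0)}, "
          f"subclonal {counts.get('subclonal', 0)})\n")
        return buf.getvalue()

    def save(self, outdir) -> dict:
        """Write segments (TSV + BED), parameters (JSON) and, when clone-number
        selection ran, the selection report."""
        from .io import write_outputs, write_selection_report
        import os

        paths = write_outputs(self.decomposition, outdir)
        if self.selection is not None:
            p = os.path.join(str(outdir), "selection.json")
            write_selection_report(self.selection, p)
            paths["selection"] = p
        return paths

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<CloneHMMResults: {self.n_clones} clones, "
                f"loglik={self.loglik:.2f}>")
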