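"""Choosing the number of subclones: BIC and chromosome-fold cross-validation.

Both strategies start from a small clone count and increase it until the
criterion deteriorates, at which point no larger model is evaluated.  BIC is
``-2 ln L + k ln n`` with the free-parameter count documented in
:func:`themis.inference.degrees_of_freedom`; cross-validation randomly
partitions the chromosomes into folds, trains on all but one fold and scores
the held-out chromosomes with the Viterbi path log likelihood of the trained
model, normalized per site for comparability across candidates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import SiteData
from .inference import degrees_of_freedom, run_themis, viterbi_decode


def bic(loglik: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2 ln L + k ln n (smaller is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * math.log(n)


@dataclass
class SelectionReport:
    """Outcome of clone-number selection."""

    candidates: list
    bic_scores: dict = field(default_factory=dict)
    cv_scores: dict = field(default_factory=dict)
    chosen_n_clones: int = 0
    method: str = "bic"

    def to_dict(self) -> dict:
        return {
            "candidates": [int(c) for c in self.candidates],
            "bic_scores": {str(k): float(v) for k, v in self.bic_scores.items()},
            "cv_scores": {str(k): float(v) for k, v in self.cv_scores.items()},
            "chosen_n_clones": int(self.chosen_n_clones),
            "method": self.method,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def chromosome_folds(chromosomes: Sequence, folds: int, seed: int) -> list[list]:
    """Seed-deterministic partition of the chromosomes into ``folds`` sets."""
    if len(chromosomes) < folds:
        raise ValueError(
            f"cannot build {folds} folds from {len(chromosomes)} chromosomes")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(chromosomes))
    out: list[list] = [[] for _ in range(folds)]
    for i, idx in enumerate(perm):
        out[i % folds].append(chromosomes[idx])
    return out


def cross_validate(
    sites: SiteData,
    config: Optional[RunConfig] = None,
    candidates: Sequence[int] = (2, 3),
    folds: int = 3,
    seed: Optional[int] = None,
    detail: bool = False,
):
    """Mean held-out per-site Viterbi score for each candidate clone count.

    With ``detail=True`` also returns the per-fold scores, which the
    selection driver uses for its paired parsimony comparison.
    """
    cfg = config or RunConfig()
    seed = cfg.seed if seed is None else seed
    parts = chromosome_folds(sites.chromosomes, folds, seed)
    scores: dict[int, list] = {int(nZ): [] for nZ in candidates}
    for f, held in enumerate(parts):
        train_chroms = [c for p in parts for c in p if p is not held]
        train = sites.subset_chromosomes(train_chroms)
        test = sites.subset_chromosomes(held)
        for nZ in candidates:
            dec = run_themis(train, cfg.replace(n_clones=int(nZ)))
            path = viterbi_decode(test, dec.params, dec.prevalence, dec.genotypes)
            scores[int(nZ)].append(path.loglik / test.n_sites)
    means = {nZ: float(np.mean(v)) for nZ, v in scores.items()}
    if detail:
        return means, {nZ: list(map(float, v)) for nZ, v in scores.items()}
    return means


def select_num_clones(
    sites: SiteData,
    config: Optional[RunConfig] = None,
    strategy: Optional[str] = None,
    nZ_start: Optional[int] = None,
    nZ_max: Optional[int] = None,
) -> SelectionReport:
    """Increase the clone count until the criterion deteriorates.

    With ``bic`` the full model is fitted for each candidate and the smallest
    score wins; with ``cv`` the mean held-out Viterbi score must keep
    improving.  The first deterioration stops the search, so the candidate
    after the optimum is the last one evaluated.
    """
    cfg = config or RunConfig()
    strategy = strategy or cfg.selection_strategy
    start = nZ_start if nZ_start is not None else cfg.n_clones_start
    stop = nZ_max if nZ_max is not None else cfg.n_clones_max
    if strategy not in ("bic", "cv"):
        raise ValueError(f"unknown selection strategy {strategy!r}")
    if strategy == "cv" and len(sites.chromosomes) < cfg.cv_folds:
        raise ValueError(
            f"cross-validation needs at least {cfg.cv_folds} chromosomes")
    report = SelectionReport(candidates=[], method=strategy)
    best_nZ, best_score, best_folds = None, None, None
    n_points = sites.n_sites * sites.n_biopsies
    for nZ in range(start, stop + 1):
        report.candidates.append(nZ)
        if strategy == "bic":
            dec = run_themis(sites, cfg.replace(n_clones=nZ))
            score = bic(dec.loglik, degrees_of_freedom(dec.params), n_points)
            report.bic_scores[nZ] = score
            better = best_score is None or score < best_score
            folds_here = None
        else:
            means, per_fold = cross_validate(sites, cfg, candidates=[nZ],
                                             folds=cfg.cv_folds, seed=cfg.seed,
                                             detail=True)
            score = means[nZ]
            folds_here = np.asarray(per_fold[nZ])
            report.cv_scores[nZ] = score
            if best_score is None:
                better = True
            else:
                # one-standard-error parsimony rule on the paired fold
                # differences: a larger model counts as better only when its
                # mean held-out improvement exceeds the standard error of
                # that improvement, so training wobble cannot add clones
                diffs = folds_here - best_folds
                se = float(np.std(diffs, ddof=1) / np.sqrt(len(diffs))) \
                    if len(diffs) > 1 else 0.0
                better = float(np.mean(diffs)) > se
        if better:
            best_nZ, best_score, best_folds = nZ, score, folds_here
        else:
            break  # criterion deteriorated: larger models are not evaluated
    report.chosen_n_clones = int(best_nZ)
    return report


def export_bivariate(sites: SiteData, m: int = 0) -> pd.DataFrame:
    """Allelic ratio vs log ratio at germline heterozygous sites of biopsy m.

    The bivariate scatter is the naive visual aid for counting prevalence
    levels of LOH events; plotting is left to the user.
    """
    mask = sites.site_type == 0
    return pd.DataFrame({
        "chrom": sites.chrom[mask],
        "pos": sites.pos[mask],
        "allelic_ratio": sites.A[m][mask],
        "log_ratio": sites.L[m][mask],
    })
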