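"""Exact inference and EM training for the joint (genotype, clone) chain.

The hidden state at each genomic site is a pair (G_t, Z_t): the allelic
copy-number genotype and the index of the clone carrying the event.  Both
chains share the distance-dependent transition kernel of
:mod:`themis.emissions` and restart from trained priors at each chromosome
start.  Cellular prevalences live on a discrete grid and are tied across
sites; they are estimated by maximizing the marginal likelihood over grid
configurations (exhaustively when the configuration count is small,
otherwise by iterated conditional modes), while the Gaussian variances,
transition-decay variances and start priors are estimated by EM.

Prevalence bookkeeping follows a within-biopsy chain convention: the decoded
levels phi^1 > phi^2 > ... are carrier fractions of each clone's events
(what the emission means consume), and clone *cell* fractions are successive
differences phi^z - phi^{z+1}.  A biopsy whose parent clone events are
carried by 75% of cells and child events by 35% therefore reports clone
prevalences of 40% and 35%.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import _kernels
from .config import RunConfig
from .data import SiteData, SITE_TYPE_LABELS
from .emissions import (
    ModelParams,
    emission_loglik_matrix,
    emission_means,
    stay_probability_matrix,
)
from .genotypes import Genotype, enumerate_genotypes, null_genotype_index

logger = logging.getLogger(__name__)

SIGMA2_BOUNDS = (1e-2, 1e4)  # search range for transition-decay variances


# ---------------------------------------------------------------------------
# Containers

@dataclass
class PrevalenceConfig:
    """Per-biopsy, per-clone carrier-prevalence levels.

    ``levels[m, z]`` is the fraction of cells in biopsy m carrying the events
    of clone z.  In single-biopsy (ordered) mode the levels are strictly
    decreasing in z, which both breaks label switching and encodes the
    within-biopsy chain (clone z's carriers include all deeper clones); the
    per-clone cell fractions are then the successive differences.
    """

    levels: np.ndarray
    grid: Optional[np.ndarray] = None
    ordered: bool = True

    def __post_init__(self) -> None:
        self.levels = np.atleast_2d(np.asarray(self.levels, dtype=float))
        if np.any(self.levels < 0) or np.any(self.levels > 1):
            raise ValueError("prevalence levels must be in [0, 1]")
        if self.ordered:
            diffs = np.diff(self.levels, axis=1)
            if self.levels.shape[1] > 1 and np.any(diffs >= -1e-12):
                raise ValueError("ordered prevalence levels must strictly decrease")

    @property
    def n_biopsies(self) -> int:
        return self.levels.shape[0]

    @property
    def n_clones(self) -> int:
        return self.levels.shape[1]

    @property
    def cell_fractions(self) -> np.ndarray:
        """Clone cell fractions under the within-biopsy chain convention."""
        nxt = np.concatenate(
            [self.levels[:, 1:], np.zeros((self.n_biopsies, 1))], axis=1
        )
        return self.levels - nxt

    def level_indices(self, grid: np.ndarray) -> np.ndarray:
        return np.abs(self.levels[..., None] - grid[None, None, :]).argmin(axis=-1)


@dataclass
class HiddenPath:
    """A decoded joint state sequence with its path log score."""

    genotype_path: np.ndarray
    clone_path: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        if len(self.genotype_path) != len(self.clone_path):
            raise ValueError("genotype and clone paths must have equal length")


@dataclass
class FBResult:
    """Forward-backward output: per-frame posteriors and transition statistics."""

    gamma: np.ndarray      # (T, G, Z) posterior over joint states
    stay_G: np.ndarray     # (T, G) expected same-genotype transition mass
    stay_Z: np.ndarray     # (T, Z) expected same-clone transition mass
    loglik: float          # exact marginal log likelihood of the observations


@dataclass
class ClonalDecomposition:
    """Full single-run output: decoded path, segments, prevalences, parameters."""

    path: HiddenPath
    prevalence: PrevalenceConfig
    segments: pd.DataFrame
    params: ModelParams
    loglik: float               # marginal loglik including the prevalence prior
    chain_loglik: float         # marginal loglik of the chain alone
    genotypes: list = field(default_factory=list)
    trace: list = field(default_factory=list)
    cm_history: list = field(default_factory=list)
    config: Optional[RunConfig] = None
    sites: Optional[SiteData] = None

    @property
    def n_clones(self) -> int:
        return self.prevalence.n_clones

    @property
    def clone_prevalences(self) -> np.ndarray:
        """Per-biopsy clone cell fractions (M, Z)."""
        return self.prevalence.cell_fractions

    def site_assignments(self) -> pd.DataFrame:
        """Per-site decoded genotype, clone and clonality status."""
        sites = self.sites
        if sites is None:
            raise ValueError("decomposition was built without a site reference")
        gl = [self.genotypes[g].label for g in self.path.genotype_path]
        tot = np.array([self.genotypes[g].total_copies for g in self.path.genotype_path])
        alt = np.array([self.genotypes[g].alt_copies for g in self.path.genotype_path])
        status = decode_status(sites, self.path, self.genotypes)
        return pd.DataFrame({
            "chrom": sites.chrom,
            "pos": sites.pos,
            "type": [SITE_TYPE_LABELS[int(d)] for d in sites.site_type],
            "genotype": gl,
            "total_copies": tot,
            "alt_copies": alt,
            "clone": self.path.clone_path + 1,
            "status": status,
        })


# ---------------------------------------------------------------------------
# Chain plumbing

def _chain_inputs(sites, genotypes, params, phi, n_clones):
    logE = emission_loglik_matrix(sites, genotypes, params, phi)
    rhoG = stay_probability_matrix(sites.h, params.var_G, len(genotypes))
    rhoZ = stay_probability_matrix(sites.h, params.var_Z, n_clones)
    return logE, rhoG, rhoZ


def forward_backward(
    sites: SiteData,
    params: ModelParams,
    prev: PrevalenceConfig,
    genotypes: Optional[Sequence[Genotype]] = None,
) -> FBResult:
    """Exact posteriors over the joint chain and the marginal log likelihood."""
    if sites.n_sites == 0:
        raise ValueError("empty site list")
    genotypes = list(genotypes) if genotypes is not None else enumerate_genotypes(5)
    nZ = prev.n_clones
    logE, rhoG, rhoZ = _chain_inputs(sites, genotypes, params, prev.levels, nZ)
    if not np.all(np.isfinite(logE)):
        raise ValueError("non-finite emission log likelihoods (NaN observations?)")
    alpha, beta, scale, emax, ll = _kernels.forward_backward_kernel(
        logE, rhoG, rhoZ, sites.start, params.prior_G, params.prior_Z
    )
    gamma = alpha * beta
    gamma /= gamma.sum(axis=(1, 2), keepdims=True)
    stay_G, stay_Z = _kernels.transition_stats_kernel(
        logE, rhoG, rhoZ, sites.start, alpha, beta, scale, emax
    )
    return FBResult(gamma=gamma, stay_G=stay_G, stay_Z=stay_Z, loglik=float(ll))


def chain_loglik(sites, params, prev, genotypes) -> float:
    """Marginal log likelihood only (no posteriors kept)."""
    logE, rhoG, rhoZ = _chain_inputs(sites, genotypes, params, prev.levels, prev.n_clones)
    _, _, _, _, ll = _kernels.forward_backward_kernel(
        logE, rhoG, rhoZ, sites.start, params.prior_G, params.prior_Z
    )
    return float(ll)


def viterbi_decode(
    sites: SiteData,
    params: ModelParams,
    prev: PrevalenceConfig,
    genotypes: Optional[Sequence[Genotype]] = None,
) -> HiddenPath:
    """Jointly most probable (genotype, clone) sequence; ties go to the lowest index."""
    if sites.n_sites == 0:
        raise ValueError("empty site list")
    genotypes = list(genotypes) if genotypes is not None else enumerate_genotypes(5)
    nZ = prev.n_clones
    logE, rhoG, rhoZ = _chain_inputs(sites, genotypes, params, prev.levels, nZ)
    with np.errstate(divide="ignore"):
        lstayG = np.log(rhoG)
        lstayZ = np.log(rhoZ)
        KG, KZ = len(genotypes), nZ
        lmoveG = (np.log(np.maximum(1.0 - rhoG, 1e-300)) - np.log(max(KG - 1, 1))
                  if KG > 1 else np.full_like(rhoG, -np.inf))
        lmoveZ = (np.log(np.maximum(1.0 - rhoZ, 1e-300)) - np.log(max(KZ - 1, 1))
                  if KZ > 1 else np.full_like(rhoZ, -np.inf))
        lpiG = np.log(np.maximum(params.prior_G, 1e-300))
        lpiZ = np.log(np.maximum(params.prior_Z, 1e-300))
    g, z, ll = _kernels.viterbi_kernel(
        logE, lstayG, lmoveG, lstayZ, lmoveZ, sites.start, lpiG, lpiZ
    )
    return HiddenPath(genotype_path=g, clone_path=z, loglik=float(ll))


# ---------------------------------------------------------------------------
# EM

def _update_emission_variances(sites, genotypes, params, prev, gamma):
    mu_A, mu_L = emission_means(genotypes, params, prev.levels)
    d = sites.site_type.astype(np.int64)
    for m in range(sites.n_biopsies):
        for dd in (0, 1):
            mask = d == dd
            if not mask.any():
                continue
            w = gamma[mask]
            x = sites.A[m][mask]
            s0 = w.sum(axis=0)
            s1 = np.einsum("t,tgz->gz", x, w)
            s2 = np.einsum("t,tgz->gz", x * x, w)
            mu = mu_A[m, dd]
            sq = float((s2 - 2.0 * mu * s1 + mu * mu * s0).sum())
            params.var_A[m, dd] = max(sq / mask.sum(), 1e-8)
        x = sites.L[m]
        s0 = gamma.sum(axis=0)
        s1 = np.einsum("t,tgz->gz", x, gamma)
        s2 = np.einsum("t,tgz->gz", x * x, gamma)
        mu = mu_L[m]
        sq = float((s2 - 2.0 * mu * s1 + mu * mu * s0).sum())
        params.var_L[m] = max(sq / sites.n_sites, 1e-8)


def _transition_objective(sig2, lh2, stay, move, K):
    """Expected log likelihood of one state's transitions as a function of sigma^2."""
    ratio = np.exp(-lh2 / (2.0 * sig2))
    rho = ratio * (K - 1) / K + 1.0 / K
    val = float(np.dot(stay, np.log(rho)))
    valid = lh2 > 0
    if valid.any():
        log1m = np.log1p(-ratio[valid]) + np.log((K - 1) / K)
        val += float(np.dot(move[valid], log1m))
    return val


def _update_transition_variances(h, start, stay, gamma_marg, var, K):
    """Bounded 1-D maximization of the expected transition log likelihood per state.

    No closed form exists for the distance-decay parameterization; the new
    value is kept only when it improves the objective, preserving the EM
    ascent property.
    """
    idx = np.where(~start)[0]
    if idx.size == 0 or K < 2:
        return
    lh2 = np.log(h[idx]) ** 2
    for j in range(var.shape[0]):
        s = stay[idx, j]
        mv = np.clip(gamma_marg[idx - 1, j] - s, 0.0, None)
        if s.sum() + mv.sum() < 5.0:
            # a state with almost no expected transitions carries no usable
            # evidence about its decay rate; keep the current (slow) value
            # rather than collapsing it from a handful of stray visits
            continue
        lo, hi = np.log(SIGMA2_BOUNDS[0]), np.log(SIGMA2_BOUNDS[1])
        res = minimize_scalar(
            lambda x: -_transition_objective(np.exp(x), lh2, s, mv, K),
            bounds=(lo, hi), method="bounded", options={"xatol": 1e-2},
        )
        new = float(np.exp(res.x))
        if (_transition_objective(new, lh2, s, mv, K)
                > _transition_objective(float(var[j]), lh2, s, mv, K)):
            var[j] = new


def _update_priors(start, gamma_marg, prior):
    counts = gamma_marg[start].sum(axis=0)
    counts = np.maximum(counts, 1e-12)
    prior[:] = counts / counts.sum()


def em_fit(
    sites: SiteData,
    init_params: ModelParams,
    prev: PrevalenceConfig,
    genotypes: Optional[Sequence[Genotype]] = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    estimate_transitions: bool = True,
) -> tuple[ModelParams, list[float]]:
    """EM estimation of variances and start priors at fixed prevalence levels.

    Emission variances have closed-form weighted-residual updates; the
    transition-decay variances use a bounded numeric search; the start priors
    are normalized expected start-frame counts.  Stops when the log
    likelihood improves by less than ``tol`` or after ``max_iter`` rounds.
    The returned trace is non-decreasing up to numerical tolerance.
    """
    genotypes = list(genotypes) if genotypes is not None else enumerate_genotypes(5)
    params = init_params.copy()
    trace: list[float] = []
    for it in range(max_iter):
        fb = forward_backward(sites, params, prev, genotypes)
        if not np.isfinite(fb.loglik):
            raise RuntimeError(f"EM diverged (non-finite log likelihood) at iteration {it}")
        trace.append(fb.loglik)
        if it > 0 and trace[-1] - trace[-2] < tol:
            break
        _update_emission_variances(sites, genotypes, params, prev, fb.gamma)
        if estimate_transitions:
            gG = fb.gamma.sum(axis=2)
            gZ = fb.gamma.sum(axis=1)
            _update_transition_variances(
                sites.h, sites.start, fb.stay_G, gG, params.var_G, len(genotypes))
            _update_transition_variances(
                sites.h, sites.start, fb.stay_Z, gZ, params.var_Z, prev.n_clones)
        gG = fb.gamma.sum(axis=2)
        gZ = fb.gamma.sum(axis=1)
        _update_priors(sites.start, gG, params.prior_G)
        _update_priors(sites.start, gZ, params.prior_Z)
    return params, trace


# ---------------------------------------------------------------------------
# Prevalence estimation

def _prevalence_objective(sites, genotypes, params, levels, objective="viterbi"):
    """Score of one prevalence configuration, including its grid prior.

    The default scores the jointly most probable path (consistent with the
    decoding rule, which maximizes over all hidden variables at once); the
    marginal likelihood is available but rewards degenerate low-prevalence
    configurations whose genotype block collapses onto the null state.
    """
    prev = PrevalenceConfig(levels=levels, grid=params.grid_P, ordered=False)
    if objective == "viterbi":
        ll = viterbi_decode(sites, params, prev, genotypes).loglik
    else:
        ll = chain_loglik(sites, params, prev, genotypes)
    idx = prev.level_indices(params.grid_P)
    ll += float(np.log(np.maximum(params.prior_P[idx], 1e-300)).sum())
    return ll


def _initial_level_indices(n_levels, n_clones, gap=1):
    idx = []
    for z in range(n_clones):
        target = (n_clones - z) / (n_clones + 1.0)
        idx.append(int(round(target * n_levels)) - 1)
    idx = np.clip(idx, 0, n_levels - 1)
    for z in range(1, n_clones):  # enforce the minimum separation
        if idx[z] > idx[z - 1] - gap:
            idx[z] = idx[z - 1] - gap
    if idx[-1] < 0:
        raise ValueError("prevalence grid too small for the requested clone count")
    return idx


def estimate_prevalence(
    sites: SiteData,
    params: ModelParams,
    n_clones: int,
    mode: str = "auto",
    genotypes: Optional[Sequence[Genotype]] = None,
    init: Optional[PrevalenceConfig] = None,
    max_sweeps: int = 10,
    min_gap_steps: int = 2,
) -> tuple[PrevalenceConfig, float]:
    """Maximum-likelihood prevalence levels on the grid, strictly ordered.

    ``exhaustive`` scores every ordered configuration (feasible for small
    clone counts and one biopsy); ``icm`` updates one level at a time until a
    full sweep changes nothing.  ``auto`` picks exhaustive when the
    configuration count is modest.

    Levels within a biopsy must be separated by at least ``min_gap_steps``
    grid steps: clones closer than two grid steps are declared indiscernible
    by the model, so configurations that place two clones on adjacent levels
    are excluded rather than allowed to soak up residual noise.
    """
    genotypes = list(genotypes) if genotypes is not None else enumerate_genotypes(5)
    grid = params.grid_P
    nP = grid.shape[0]
    M = sites.n_biopsies
    gap = max(int(min_gap_steps), 1)
    if (n_clones - 1) * gap >= nP:
        raise ValueError(f"grid of {nP} levels cannot host {n_clones} clones "
                         f"separated by {gap} steps")
    from math import comb

    n_configs = comb(nP, n_clones) ** M
    if mode == "auto":
        mode = "exhaustive" if n_configs <= 250 else "icm"
    if mode == "exhaustive":
        if n_configs > 20000:
            raise ValueError(f"{n_configs} configurations is too many for exhaustive search")
        per_biopsy = [c[::-1] for c in itertools.combinations(range(nP), n_clones)
                      if all(b - a >= gap for a, b in zip(c, c[1:]))]
        best, best_ll = None, -np.inf
        for combo in itertools.product(per_biopsy, repeat=M):
            levels = grid[np.array(combo)]
            ll = _prevalence_objective(sites, genotypes, params, levels)
            if ll > best_ll:
                best, best_ll = levels, ll
        return PrevalenceConfig(levels=best, grid=grid), float(best_ll)
    if mode != "icm":
        raise ValueError(f"unknown prevalence mode {mode!r}")
    # multi-start ICM: deterministic starting points spread over the ordered
    # simplex guard against local optima of the grid search
    starts = []
    if init is not None:
        cand = init.level_indices(grid).copy()
        for z in range(1, n_clones):  # repair gap violations in the warm start
            cand[:, z] = np.minimum(cand[:, z], cand[:, z - 1] - gap)
        if np.all(cand >= 0):
            starts.append(cand)
    base = np.tile(_initial_level_indices(nP, n_clones, gap), (M, 1))
    top = np.tile(np.arange(nP - 1, nP - 1 - n_clones * gap, -gap), (M, 1))
    wide = np.tile(np.linspace(nP - 1, 0, n_clones).round().astype(int), (M, 1))
    for z in range(1, n_clones):
        wide[:, z] = np.minimum(wide[:, z], wide[:, z - 1] - gap)
    for cand in (base, top, wide):
        if np.all(cand >= 0) and not any(np.array_equal(cand, s) for s in starts):
            starts.append(cand)
    best_idx, best_ll = None, -np.inf
    for start_idx in starts:
        idx = start_idx.copy()
        ll0 = _prevalence_objective(sites, genotypes, params, grid[idx])
        for _ in range(max_sweeps):
            changed = False
            for m in range(M):
                for z in range(n_clones):
                    hi = (idx[m, z - 1] - gap if z > 0 else nP - 1)
                    lo = (idx[m, z + 1] + gap if z < n_clones - 1 else 0)
                    for cand in range(lo, hi + 1):
                        if cand == idx[m, z]:
                            continue
                        old = idx[m, z]
                        idx[m, z] = cand
                        ll = _prevalence_objective(sites, genotypes, params, grid[idx])
                        if ll > ll0 + 1e-12:
                            ll0 = ll
                            changed = True
                        else:
                            idx[m, z] = old
            if not changed:
                break
        if ll0 > best_ll:
            best_idx, best_ll = idx, ll0
    return PrevalenceConfig(levels=grid[best_idx], grid=grid), float(best_ll)


# ---------------------------------------------------------------------------
# Log-ratio offset calibration

def estimate_cm(
    sites: SiteData,
    path: HiddenPath,
    genotypes: Sequence[Genotype],
    current: np.ndarray,
) -> np.ndarray:
    """Re-estimate the per-biopsy log-ratio offset from decoded no-CNA sites.

    The offset is the mean observed log ratio over sites decoded as the AB
    genotype; the driver reruns the model with the refined value.  If no site
    decodes to AB the current offset is kept with a warning.
    """
    null_idx = null_genotype_index(genotypes)
    mask = path.genotype_path == null_idx
    if not mask.any():
        warnings.warn("no sites decoded as AB; keeping the current log-ratio offsets")
        return np.asarray(current, dtype=float).copy()
    return sites.L[:, mask].mean(axis=1)


def initial_cm(sites: SiteData) -> np.ndarray:
    """Data-driven starting offset: the median log ratio over the putative
    normal cluster (germline sites with near-balanced allelic ratio)."""
    out = np.empty(sites.n_biopsies)
    germ = sites.site_type == 0
    for m in range(sites.n_biopsies):
        mask = germ & (np.abs(sites.A[m] - 0.5) <= 0.1)
        out[m] = np.median(sites.L[m][mask]) if mask.any() else np.median(sites.L[m])
    return out


# ---------------------------------------------------------------------------
# Segments and status

def decode_status(sites, path: HiddenPath, genotypes) -> np.ndarray:
    """Per-site clonality call: normal (no event), clonal (top cluster) or subclonal.

    A site hosts an event when its genotype is non-AB at a germline site, or
    carries at least one alternative copy at a somatic-SNV site.
    """
    null_idx = null_genotype_index(genotypes)
    alt = np.array([genotypes[g].alt_copies for g in path.genotype_path])
    is_event = np.where(
        sites.site_type == 1, alt >= 1, path.genotype_path != null_idx
    )
    status = np.where(is_event,
                      np.where(path.clone_path == 0, "clonal", "subclonal"),
                      "normal")
    return status


def segments_from_path(sites: SiteData, path: HiddenPath, genotypes) -> pd.DataFrame:
    """Maximal runs of constant (genotype, clone), 1-based closed coordinates."""
    g, z = path.genotype_path, path.clone_path
    brk = np.zeros(sites.n_sites, dtype=bool)
    brk[0] = True
    brk[1:] = (g[1:] != g[:-1]) | (z[1:] != z[:-1]) | sites.start[1:]
    starts = np.where(brk)[0]
    ends = np.append(starts[1:], sites.n_sites) - 1
    status = decode_status(sites, path, genotypes)
    rows = []
    for s, e in zip(starts, ends):
        gt = genotypes[int(g[s])]
        rows.append({
            "chrom": sites.chrom[s],
            "start": int(sites.pos[s]),
            "end": int(sites.pos[e]),
            "n_sites": int(e - s + 1),
            "genotype": gt.label,
            "total_copies": gt.total_copies,
            "alt_copies": gt.alt_copies,
            "clone": int(z[s]) + 1,
            "status": "normal" if gt.is_null else str(status[s]),
        })
    return pd.DataFrame(rows)


def degrees_of_freedom(params: ModelParams) -> int:
    """Free-parameter count used by BIC: 3M variances + per-state transition
    variances + the three priors' free entries."""
    M = params.n_biopsies
    G = params.n_genotypes
    Z = params.n_clones
    P = params.prior_P.shape[0]
    return 3 * M + G + Z + (G - 1) + (Z - 1) + (P - 1)


# ---------------------------------------------------------------------------
# End-to-end single-run driver

def run_themis(sites: SiteData, config: Optional[RunConfig] = None, **overrides) -> ClonalDecomposition:
    """Full single-model run: initialize, train, calibrate, decode.

    Orchestrates initialization, EM training, grid prevalence estimation, the
    two-pass log-ratio offset calibration (the offset is re-estimated from
    decoded AB sites and the model rerun when it moved materially), Viterbi
    decoding and segment extraction.  Deterministic given inputs and
    configuration.
    """
    cfg = (config or RunConfig()).replace(**overrides)
    if not isinstance(cfg.n_clones, (int, np.integer)):
        raise ValueError("run_themis needs a fixed clone count; use the model "
                         "class or select_num_clones for automatic selection")
    nZ = int(cfg.n_clones)
    work = sites if cfg.include_somatic else sites.select_sites(sites.site_type == 0)
    genotypes = enumerate_genotypes(cfg.c_max)
    offsets = np.asarray(cfg.offsets, float) if cfg.offsets is not None else initial_cm(work)
    params = ModelParams.initial(
        work.n_biopsies, len(genotypes), nZ,
        n_levels=cfg.n_prevalence_levels, offsets=offsets,
        min_effect=cfg.min_effect,
    )
    cm_history = [offsets.copy()]
    trace_all: list[float] = []

    def one_pass(params):
        prev, _ = estimate_prevalence(
            work, params, nZ, mode=cfg.prevalence_mode, genotypes=genotypes,
            max_sweeps=cfg.icm_sweeps, min_gap_steps=cfg.min_level_gap)
        params, trace = em_fit(
            work, params, prev, genotypes=genotypes,
            max_iter=cfg.max_iter, tol=cfg.tol,
            estimate_transitions=cfg.estimate_transitions)
        prev2, _ = estimate_prevalence(
            work, params, nZ, mode=cfg.prevalence_mode, genotypes=genotypes,
            init=prev, min_gap_steps=cfg.min_level_gap)
        if not np.allclose(prev2.levels, prev.levels):
            params, trace2 = em_fit(
                work, params, prev2, genotypes=genotypes,
                max_iter=min(cfg.max_iter, cfg.refresh_iter), tol=cfg.tol,
                estimate_transitions=cfg.estimate_transitions)
            trace = trace + trace2
        return params, prev2, trace

    params, prev, trace = one_pass(params)
    trace_all += trace
    path = viterbi_decode(work, params, prev, genotypes)
    new_cm = estimate_cm(work, path, genotypes, params.offsets)
    cm_history.append(new_cm.copy())
    if np.max(np.abs(new_cm - params.offsets)) > cfg.cm_refit_threshold:
        logger.info("log-ratio offset moved %.4f; running second pass",
                    float(np.max(np.abs(new_cm - params.offsets))))
        params.offsets = new_cm
        params, prev, trace = one_pass(params)
        trace_all += trace
        path = viterbi_decode(work, params, prev, genotypes)
        cm_history.append(estimate_cm(work, path, genotypes, params.offsets))

    # Train the prevalence-level prior on the hard-assigned levels (+1 smoothing).
    idx = prev.level_indices(params.grid_P)
    counts = np.ones(params.grid_P.shape[0])
    for i in idx.ravel():
        counts[i] += 1.0
    params.prior_P = counts / counts.sum()

    chain_ll = chain_loglik(work, params, prev, genotypes)
    total_ll = chain_ll + float(
        np.log(params.prior_P[prev.level_indices(params.grid_P)]).sum())
    segments = segments_from_path(work, path, genotypes)
    return ClonalDecomposition(
        path=path, prevalence=prev, segments=segments, params=params,
        loglik=total_ll, chain_loglik=chain_ll, genotypes=genotypes,
        trace=trace_all, cm_history=cm_history, config=cfg, sites=work,
    )
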