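"""Gaussian observation likelihoods and distance-dependent transition kernels.

Observations are modeled as Gaussians around the deterministic expected
signals from :mod:`themis.genotypes`: the allelic ratio A with a per-biopsy,
per-site-type variance, and the log depth ratio L with a per-biopsy variance.

Transitions between hidden states are distance dependent.  The probability
of staying in state j over a gap of h base pairs is a Gaussian-density ratio
of log h that simplifies to

    rho_j(h) = exp(-(log h)^2 / (2 sigma_j^2)) * (K-1)/K + 1/K,

so rho -> 1 as h -> 1 and rho -> 1/K (the uniform rate) as h -> infinity.
The per-state variance sigma_j^2 sets how slowly the stay probability decays
with distance and is estimated from data.  The remaining mass is spread
uniformly over the other K-1 states.  The natural log is used; the base only
rescales sigma and is absorbed by estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .data import SiteData, SiteRecord
from .genotypes import (
    Genotype,
    allelic_ratio_means,
    genotype_arrays,
    log_ratio_means,
)

LOG_2PI = float(np.log(2.0 * np.pi))


def prevalence_grid(n_levels: int = 20) -> np.ndarray:
    """``n_levels`` equally spaced prevalence levels 1/n .. 1.0 (default 0.05..1.00)."""
    if n_levels < 1:
        raise ValueError("need at least one prevalence level")
    return np.arange(1, n_levels + 1, dtype=float) / n_levels


@dataclass
class ModelParams:
    """The trainable parameter set plus user-fixed configuration.

    var_A : (M, 2) allelic-ratio variances per biopsy and site type
    var_L : (M,)   log-ratio variances per biopsy
    var_G : (|G|,) transition-decay variances per genotype
    var_Z : (|Z|,) transition-decay variances per clone
    prior_G / prior_Z / prior_P : chromosome-start priors
    offsets : (M,) per-biopsy log-ratio offsets c_m
    grid_P : the discrete prevalence grid
    """

    var_A: np.ndarray
    var_L: np.ndarray
    var_G: np.ndarray
    var_Z: np.ndarray
    prior_G: np.ndarray
    prior_Z: np.ndarray
    prior_P: np.ndarray
    offsets: np.ndarray
    grid_P: np.ndarray = field(default_factory=prevalence_grid)
    #: identifiability guard (reference sigma_A, reference sigma_L, squared
    #: effect threshold): a non-null (genotype, clone) state is excluded when
    #: its expected germline signals in every biopsy differ from the no-CNA
    #: state by less than the threshold in combined squared noise units,
    #: (dA/sigma_A)^2 + (dL/sigma_L)^2 < threshold — at very low prevalence
    #: whole genotype blocks otherwise collapse onto the null state and soak
    #: up likelihood without representing any real event
    min_effect: np.ndarray = field(default_factory=lambda: np.array([0.05, 0.2, 1.0]))

    @classmethod
    def initial(
        cls,
        n_biopsies: int,
        n_genotypes: int,
        n_clones: int,
        n_levels: int = 20,
        offsets: Union[Sequence[float], None] = None,
        min_effect: Union[Sequence[float], None] = None,
    ) -> "ModelParams":
        """Default initialization: moderate emission variances, slow transition
        decay (sigma^2 = 25) and uniform priors."""
        off = np.zeros(n_biopsies) if offsets is None else np.asarray(offsets, float)
        if min_effect is not None:
            return cls(
                var_A=np.full((n_biopsies, 2), 0.01),
                var_L=np.full(n_biopsies, 0.04),
                var_G=np.full(n_genotypes, 25.0),
                var_Z=np.full(n_clones, 25.0),
                prior_G=np.full(n_genotypes, 1.0 / n_genotypes),
                prior_Z=np.full(n_clones, 1.0 / n_clones),
                prior_P=np.full(n_levels, 1.0 / n_levels),
                offsets=off,
                grid_P=prevalence_grid(n_levels),
                min_effect=np.asarray(min_effect, dtype=float),
            )
        return cls(
            var_A=np.full((n_biopsies, 2), 0.01),
            var_L=np.full(n_biopsies, 0.04),
            var_G=np.full(n_genotypes, 25.0),
            var_Z=np.full(n_clones, 25.0),
            prior_G=np.full(n_genotypes, 1.0 / n_genotypes),
            prior_Z=np.full(n_clones, 1.0 / n_clones),
            prior_P=np.full(n_levels, 1.0 / n_levels),
            offsets=off,
            grid_P=prevalence_grid(n_levels),
        )

    def validate(self) -> None:
        for name in ("var_A", "var_L", "var_G", "var_Z"):
            v = getattr(self, name)
            if np.any(np.asarray(v) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        for name in ("prior_G", "prior_Z", "prior_P"):
            p = np.asarray(getattr(self, name))
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{name} must be a probability vector")

    _FIELDS = ("var_A", "var_L", "var_G", "var_Z", "prior_G", "prior_Z",
               "prior_P", "offsets", "grid_P", "min_effect")

    def copy(self) -> "ModelParams":
        return ModelParams(**{k: np.array(getattr(self, k)) for k in self._FIELDS})

    @property
    def n_biopsies(self) -> int:
        return self.var_L.shape[0]

    @property
    def n_genotypes(self) -> int:
        return self.var_G.shape[0]

    @property
    def n_clones(self) -> int:
        return self.var_Z.shape[0]

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist() for k in self._FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Emissions

def _gauss_logpdf(x: float, mu: float, var: float) -> float:
    return -0.5 * ((x - mu) ** 2 / var + np.log(var) + LOG_2PI)


def emission_loglik(
    site: SiteRecord,
    g: Genotype,
    z: int,
    prevalences: Sequence[float],
    params: ModelParams,
    m: int,
) -> float:
    """Log density of one biopsy's (A, L) observation given hidden state (g, z).

    ``prevalences`` holds the per-clone carrier prevalences; clone ``z`` is an
    index into it.  The two Gaussian log densities (allelic ratio with the
    site-type-specific variance, log ratio) are summed.
    """
    from .genotypes import expected_allelic_ratio, expected_log_ratio

    var_a = float(params.var_A[m, site.site_type])
    var_l = float(params.var_L[m])
    if var_a <= 0 or var_l <= 0:
        raise ValueError("emission variances must be strictly positive")
    p = float(prevalences[z])
    mu_a = expected_allelic_ratio(g, p, site.site_type)
    mu_l = expected_log_ratio(g, p, float(params.offsets[m]))
    return (_gauss_logpdf(site.obs_allelic[m], mu_a, var_a)
            + _gauss_logpdf(site.obs_logratio[m], mu_l, var_l))


def emission_means(
    genotypes: Sequence[Genotype], params: ModelParams, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Expected (A, L) per biopsy on the (genotype, clone) grid.

    phi : (M, Z) per-biopsy, per-clone carrier prevalences.
    Returns mu_A with shape (M, 2, G, Z) indexed by site type, and mu_L with
    shape (M, G, Z).
    """
    n, a = genotype_arrays(genotypes)
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    M = phi.shape[0]
    G, Z = len(n), phi.shape[1]
    mu_A = np.empty((M, 2, G, Z))
    mu_L = np.empty((M, G, Z))
    for m in range(M):
        mu_A[m, 0] = allelic_ratio_means(n, a, phi[m], "germline")
        mu_A[m, 1] = allelic_ratio_means(n, a, phi[m], "somatic")
        mu_L[m] = log_ratio_means(n, phi[m], float(params.offsets[m]))
    return mu_A, mu_L


def redundant_states(
    genotypes: Sequence[Genotype], params: ModelParams, phi: np.ndarray
) -> np.ndarray:
    """Non-null (genotype, clone) states indistinguishable from the null state.

    A state is redundant when, in every biopsy, its expected germline signals
    are within ``min_effect[2]`` combined squared noise units of the no-CNA
    state (allelic-ratio and log-ratio deviations scaled by the reference
    noise levels ``min_effect[0]`` and ``min_effect[1]``).  Such states arise
    at very low prevalence levels and are excluded so they cannot impersonate
    the no-CNA state.  Shape (G, Z).
    """
    mu_A, mu_L = emission_means(genotypes, params, phi)
    sA, sL, thr = (float(params.min_effect[0]), float(params.min_effect[1]),
                   float(params.min_effect[2]))
    offsets = np.asarray(params.offsets, dtype=float)
    d2 = (((mu_A[:, 0] - 0.5) / sA) ** 2
          + ((mu_L - offsets[:, None, None]) / sL) ** 2)
    near_null = (d2 < thr).all(axis=0)
    for i, g in enumerate(genotypes):
        if g.is_null:
            near_null[i] = False
    return near_null


def emission_loglik_matrix(
    sites: SiteData,
    genotypes: Sequence[Genotype],
    params: ModelParams,
    phi: np.ndarray,
) -> np.ndarray:
    """Per-frame joint-state emission log likelihoods, shape (T, G, Z).

    Sums the A and L Gaussian log densities over all biopsies; redundant
    near-null states (see :func:`redundant_states`) are assigned a large
    negative log likelihood so inference never visits them.
    """
    mu_A, mu_L = emission_means(genotypes, params, phi)
    T = sites.n_sites
    d = sites.site_type.astype(np.int64)
    logE = np.zeros((T, mu_L.shape[1], mu_L.shape[2]))
    for m in range(sites.n_biopsies):
        var_a = params.var_A[m, d]                      # (T,)
        mu_a = mu_A[m, d]                               # (T, G, Z)
        resid = sites.A[m][:, None, None] - mu_a
        logE += -0.5 * (resid ** 2 / var_a[:, None, None]
                        + (np.log(var_a) + LOG_2PI)[:, None, None])
        var_l = float(params.var_L[m])
        resid = sites.L[m][:, None, None] - mu_L[m][None]
        logE += -0.5 * (resid ** 2 / var_l + np.log(var_l) + LOG_2PI)
    logE[:, redundant_states(genotypes, params, phi)] = -1e9
    return logE


# ---------------------------------------------------------------------------
# Transitions

def stay_probability(h, sigma2: float, K: int):
    """Probability of remaining in the same state over a gap of ``h`` bp.

    Closed form of the Gaussian-density ratio: at h=1 the ratio is 1 and the
    stay probability is exactly 1; as h grows it decays toward the uniform
    rate 1/K, with larger sigma2 giving slower decay.  ``h`` may be a scalar
    or array; entries below 1 bp are rejected.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 1):
        raise ValueError("inter-site distance must be >= 1 bp")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be strictly positive")
    if K < 2:
        raise ValueError("state space must have K >= 2 for a stay probability")
    ratio = np.exp(-np.log(h) ** 2 / (2.0 * sigma2))
    out = ratio * (K - 1) / K + 1.0 / K
    return float(out) if out.ndim == 0 else out


def stay_probability_matrix(h: np.ndarray, sigma2: np.ndarray, K: int) -> np.ndarray:
    """Per-frame, per-state stay probabilities, shape (T, K); allows K=1."""
    h = np.asarray(h, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if K == 1:
        return np.ones((h.shape[0], 1))
    logh2 = np.log(np.maximum(h, 1.0)) ** 2
    ratio = np.exp(-logh2[:, None] / (2.0 * sigma2[None, :]))
    return ratio * (K - 1) / K + 1.0 / K


def transition_matrix(h: float, sigmas: Sequence[float], K: int) -> np.ndarray:
    """Row-stochastic K x K transition matrix at distance ``h``.

    Row j has the stay probability rho_j(h) on the diagonal and splits the
    rest uniformly.  The same kernel is applied to the genotype chain (over
    |G| states) and the clone chain (over |Z| states).
    """
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.shape[0] != K:
        raise ValueError("need one sigma^2 per state")
    rho = np.array([stay_probability(h, float(s), K) for s in sigmas])
    Q = np.tile(((1.0 - rho) / (K - 1))[:, None], (1, K))
    np.fill_diagonal(Q, rho)
    return Q
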