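"""Shared fixtures: small simulated patients, a fitted mid-size model, and
brute-force chain oracles used to validate the recursions."""

import itertools
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from themis import RunConfig, run_themis, simulate_patient, two_clone_spec
from themis.data import SiteData
from themis.emissions import emission_loglik_matrix, stay_probability_matrix

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the kernel implementations)

def _transition_prob(rho, K, i, j):
    if i == j:
        return rho[i]
    return (1.0 - rho[i]) / (K - 1)


def brute_force_scores(sites, genotypes, params, prev):
    """Log probability of every joint hidden path by direct enumeration."""
    logE = emission_loglik_matrix(sites, genotypes, params, prev.levels)
    KG, KZ = len(genotypes), prev.n_clones
    rhoG = stay_probability_matrix(sites.h, params.var_G, KG)
    rhoZ = stay_probability_matrix(sites.h, params.var_Z, KZ)
    states = list(itertools.product(range(KG), range(KZ)))
    scores, paths = [], []
    for seq in itertools.product(states, repeat=sites.n_sites):
        lp = 0.0
        for t, (g, z) in enumerate(seq):
            if sites.start[t]:
                lp += np.log(params.prior_G[g] * params.prior_Z[z])
            else:
                gp, zp = seq[t - 1]
                lp += np.log(_transition_prob(rhoG[t], KG, gp, g))
                lp += np.log(_transition_prob(rhoZ[t], KZ, zp, z))
            lp += logE[t, g, z]
        scores.append(lp)
        paths.append(seq)
    return np.array(scores), paths


@pytest.fixture(scope="session")
def oracle():
    return SimpleNamespace(scores=brute_force_scores)


# ---------------------------------------------------------------------------
# Small data helpers

def tiny_sites(rng, T=4, n_chrom=2, M=1):
    """A small random site table spanning up to two chromosomes."""
    split = int(rng.integers(1, T + 1))
    chrom = np.where(np.arange(T) < split, "c1", "c2")[:T]
    if n_chrom == 1:
        chrom = np.full(T, "c1")
    pos = np.cumsum(rng.integers(2, 5000, T))
    d = rng.integers(0, 2, T)
    A = rng.uniform(0, 1, (M, T))
    L = rng.normal(0, 1, (M, T))
    return SiteData(chrom, pos, d, A, L)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_patient():
    """Quick two-clone patient used by several unit tests."""
    spec = two_clone_spec(seed=3, het_per_chrom=800, som_per_chrom=10)
    sites, truth = simulate_patient(spec)
    return SimpleNamespace(spec=spec, sites=sites, truth=truth)


@pytest.fixture(scope="session")
def small_fit(small_patient):
    """Fitted two-clone decomposition on the small patient (shared, ~5 s)."""
    dec = run_themis(small_patient.sites, RunConfig(n_clones=2))
    return SimpleNamespace(**vars(small_patient), decomposition=dec)
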