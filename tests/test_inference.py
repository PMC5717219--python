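"""Forward-backward, Viterbi, EM and the end-to-end single-run pipeline."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.special import logsumexp

from themis import (
    ModelParams,
    PrevalenceConfig,
    RunConfig,
    em_fit,
    enumerate_genotypes,
    estimate_cm,
    estimate_prevalence,
    forward_backward,
    run_themis,
    simulate_patient,
    two_clone_spec,
    viterbi_decode,
)
from themis.data import SiteData
from themis.inference import HiddenPath, chain_loglik, segments_from_path

from conftest import tiny_sites


def random_tiny_instance(rng, c_max=1, nZ=2, M=1):
    genos = enumerate_genotypes(c_max)
    sites = tiny_sites(rng, T=int(rng.integers(2, 6)), M=M)
    params = ModelParams.initial(M, len(genos), nZ)
    params.var_G = rng.uniform(0.5, 30, len(genos))
    params.var_Z = rng.uniform(0.5, 30, nZ)
    pg = rng.uniform(0.1, 1, len(genos))
    params.prior_G = pg / pg.sum()
    pz = rng.uniform(0.1, 1, nZ)
    params.prior_Z = pz / pz.sum()
    levels = np.sort(rng.choice(params.grid_P, size=nZ, replace=False))[::-1]
    prev = PrevalenceConfig(np.tile(levels, (M, 1)))
    return sites, genos, params, prev


class TestForwardBackward:
    def test_single_frame_posterior_is_normalized_prior_times_emission(self, rng):
        sites, genos, params, prev = random_tiny_instance(rng)
        sites = sites.select_sites(np.arange(sites.n_sites) == 0)
        fb = forward_backward(sites, params, prev, genos)
        from themis.emissions import emission_loglik_matrix

        logE = emission_loglik_matrix(sites, genos, params, prev.levels)
        w = params.prior_G[:, None] * params.prior_Z[None, :] * np.exp(logE[0])
        assert np.allclose(fb.gamma[0], w / w.sum(), atol=1e-12)
        assert fb.loglik == pytest.approx(np.log(w.sum()), abs=1e-10)

    def test_constant_emissions_reproduce_prior_chain(self, rng):
        sites, genos, params, prev = random_tiny_instance(rng)
        prev = PrevalenceConfig(np.tile([0.75, 0.35], (sites.n_biopsies, 1)))
        params.var_A[:] = 1e6  # flatten the emissions
        params.var_L[:] = 1e6
        fb = forward_backward(sites, params, prev, genos)
        # with (near-)flat emissions the frame posterior equals the
        # prior-propagated chain marginal; at start frames that is the prior
        start_post = fb.gamma[sites.start]
        expect = params.prior_G[:, None] * params.prior_Z[None, :]
        assert np.allclose(start_post, expect[None], atol=1e-4)

    def test_matches_brute_force_enumeration(self, rng, oracle):
        for _ in range(15):
            sites, genos, params, prev = random_tiny_instance(rng)
            scores, _ = oracle.scores(sites, genos, params, prev)
            fb = forward_backward(sites, params, prev, genos)
            assert fb.loglik == pytest.approx(logsumexp(scores), abs=1e-10)
            assert np.allclose(fb.gamma.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_loglik_invariant_to_chromosome_order(self, rng):
        sites, genos, params, prev = random_tiny_instance(rng)
        ll = forward_backward(sites, params, prev, genos).loglik
        chroms = sites.chromosomes
        if len(chroms) == 2:
            swapped = SiteData(
                np.concatenate([sites.chrom[sites.chrom == chroms[1]],
                                sites.chrom[sites.chrom == chroms[0]]]),
                np.concatenate([sites.pos[sites.chrom == chroms[1]],
                                sites.pos[sites.chrom == chroms[0]]]),
                np.concatenate([sites.site_type[sites.chrom == chroms[1]],
                                sites.site_type[sites.chrom == chroms[0]]]),
                np.concatenate([sites.A[:, sites.chrom == chroms[1]],
                                sites.A[:, sites.chrom == chroms[0]]], axis=1),
                np.concatenate([sites.L[:, sites.chrom == chroms[1]],
                                sites.L[:, sites.chrom == chroms[0]]], axis=1),
                validate=False)
            ll2 = forward_backward(swapped, params, prev, genos).loglik
            assert ll2 == pytest.approx(ll, abs=1e-9)

    def test_empty_input_rejected(self):
        genos = enumerate_genotypes(1)
        params = ModelParams.initial(1, 3, 1)
        with pytest.raises((ValueError, Exception)):
            forward_backward(
                SiteData(["c1"], [1], [0], [[0.5]], [[0.0]]).select_sites(
                    np.array([False])),
                params, PrevalenceConfig([[0.6]]), genos)


class TestViterbi:
    def test_matches_brute_force_maximum(self, rng, oracle):
        for _ in range(15):
            sites, genos, params, prev = random_tiny_instance(rng)
            scores, paths = oracle.scores(sites, genos, params, prev)
            hp = viterbi_decode(sites, params, prev, genos)
            assert hp.loglik == pytest.approx(scores.max(), abs=1e-10)
            decoded = list(zip(hp.genotype_path, hp.clone_path))
            assert scores[paths.index(tuple(decoded))] == pytest.approx(
                scores.max(), abs=1e-10)

    def test_path_score_never_exceeds_marginal(self, rng):
        for _ in range(10):
            sites, genos, params, prev = random_tiny_instance(rng, c_max=2)
            hp = viterbi_decode(sites, params, prev, genos)
            fb = forward_backward(sites, params, prev, genos)
            assert hp.loglik <= fb.loglik + 1e-9

    def test_clone_tie_at_null_sites_breaks_to_lowest_state(self):
        # the null genotype's emissions are identical for every clone, the
        # priors are uniform and the transition kernel is symmetric, so all
        # clone paths tie exactly and the lowest index must win
        genos = enumerate_genotypes(2)
        T = 4
        sites = SiteData(np.full(T, "c1"), np.arange(1, T + 1) * 10,
                         np.zeros(T, dtype=int), np.full((1, T), 0.5),
                         np.zeros((1, T)))
        params = ModelParams.initial(1, len(genos), 3)
        prev = PrevalenceConfig([[0.75, 0.50, 0.25]])
        hp = viterbi_decode(sites, params, prev, genos)
        assert [genos[i].label for i in hp.genotype_path] == ["AB"] * T
        assert np.all(hp.clone_path == 0)

    def test_near_deterministic_emissions_recover_generating_path(self, rng):
        spec = two_clone_spec(seed=9, het_per_chrom=120, som_per_chrom=2,
                              n_chrom=1, sigma_A=(1e-4, 1e-4), sigma_L=1e-3)
        sites, truth = simulate_patient(spec)
        dec = run_themis(sites, RunConfig(n_clones=2, max_iter=15))
        from themis import score_recovery

        errs = score_recovery(dec, truth)
        assert errs["either_error_pct"] == 0.0


class TestEM:
    def test_loglik_trace_non_decreasing(self, rng):
        genos = enumerate_genotypes(3)
        for seed in range(3):
            spec = two_clone_spec(seed=seed, het_per_chrom=60, som_per_chrom=2,
                                  n_chrom=2)
            sites, _ = simulate_patient(spec)
            params = ModelParams.initial(1, len(genos), 2)
            _, trace = em_fit(sites, params, PrevalenceConfig([[0.75, 0.35]]),
                              genotypes=genos, max_iter=8, tol=0.0)
            assert np.all(np.diff(trace) >= -1e-8)

    def test_zero_noise_fixed_point(self):
        # data generated at vanishing noise: the first M-step keeps the
        # emission variances at (floored) minimal values and the loglik stays
        # essentially unchanged afterwards
        spec = two_clone_spec(seed=2, het_per_chrom=100, som_per_chrom=2,
                              n_chrom=1, sigma_A=(1e-6, 1e-6), sigma_L=1e-6,
                              offset=0.0)
        sites, _ = simulate_patient(spec)
        genos = enumerate_genotypes(5)
        params = ModelParams.initial(1, len(genos), 2)
        params.var_A[:] = 1e-8
        params.var_L[:] = 1e-8
        fitted, trace = em_fit(sites, params, PrevalenceConfig([[0.75, 0.35]]),
                               genotypes=genos, max_iter=3, tol=0.0)
        assert fitted.var_A.max() < 1e-6 and fitted.var_L.max() < 1e-6

    def test_recovers_emission_variance(self):
        # single-genotype (all-normal) data: the variance update is the
        # plain sample variance, consistent at moderate T
        rng = np.random.default_rng(5)
        T = 5000
        true_var = 0.0025
        sites = SiteData(np.full(T, "c1"), np.cumsum(rng.integers(100, 5000, T)),
                         np.zeros(T, dtype=int),
                         np.clip(rng.normal(0.5, np.sqrt(true_var), (1, T)), 0, 1),
                         rng.normal(0.0, 0.2, (1, T)))
        genos = enumerate_genotypes(2)
        params = ModelParams.initial(1, len(genos), 1)
        fitted, _ = em_fit(sites, params, PrevalenceConfig([[0.6]]),
                           genotypes=genos, max_iter=25)
        assert fitted.var_A[0, 0] == pytest.approx(true_var, rel=0.2)


class TestPrevalence:
    def test_exhaustive_configuration_count(self):
        from math import comb

        assert comb(20, 2) == 190  # ordered two-clone configurations on the grid

    def test_recovers_single_clone_prevalence(self):
        spec = two_clone_spec(seed=4, het_per_chrom=150, som_per_chrom=2,
                              n_chrom=1, prevalences=(0.60, 0.0),
                              sigma_A=(0.02, 0.02), sigma_L=0.08)
        # a single tumor clone at 60% prevalence (second clone absent)
        spec.biopsies = [{"clone1": 0.60}]
        sites, _ = simulate_patient(spec)
        genos = enumerate_genotypes(5)
        params = ModelParams.initial(1, len(genos), 1, offsets=[0.25])
        params.var_A[:] = 0.02 ** 2
        params.var_L[:] = 0.08 ** 2
        prev, _ = estimate_prevalence(sites, params, 1, mode="exhaustive",
                                      genotypes=genos)
        assert prev.levels[0, 0] == pytest.approx(0.60)

    def test_exhaustive_and_icm_agree_on_small_instance(self):
        spec = two_clone_spec(seed=6, het_per_chrom=200, som_per_chrom=2,
                              n_chrom=1, sigma_A=(0.02, 0.02), sigma_L=0.08)
        sites, _ = simulate_patient(spec)
        genos = enumerate_genotypes(5)
        params = ModelParams.initial(1, len(genos), 2, offsets=[0.25])
        params.var_A[:] = 0.02 ** 2
        params.var_L[:] = 0.08 ** 2
        pe, lle = estimate_prevalence(sites, params, 2, mode="exhaustive",
                                      genotypes=genos)
        pi, lli = estimate_prevalence(sites, params, 2, mode="icm",
                                      genotypes=genos)
        assert np.allclose(pe.levels, pi.levels)
        assert lle == pytest.approx(lli, abs=1e-9)

    def test_grid_too_small_rejected(self, rng):
        sites = tiny_sites(rng)
        genos = enumerate_genotypes(2)
        params = ModelParams.initial(1, len(genos), 3, n_levels=2)
        with pytest.raises(ValueError):
            estimate_prevalence(sites, params, 3, genotypes=genos)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            PrevalenceConfig([[0.4, 0.4]])
        cfg = PrevalenceConfig([[0.75, 0.35]])
        assert np.allclose(cfg.cell_fractions, [[0.40, 0.35]])


class TestOffsetCalibration:
    def test_mean_over_null_sites(self):
        sites = SiteData(["c1", "c1"], [10, 20], [0, 0],
                         [[0.5, 0.5]], [[0.1, 0.3]])
        genos = enumerate_genotypes(2)
        null_idx = 4  # AB in the c_max=2 enumeration
        path = HiddenPath(np.array([null_idx, null_idx]), np.array([0, 0]), 0.0)
        cm = estimate_cm(sites, path, genos, np.array([0.0]))
        assert cm[0] == pytest.approx(0.2)

    def test_no_null_sites_keeps_offset_and_warns(self):
        sites = SiteData(["c1", "c1"], [10, 20], [0, 0],
                         [[0.2, 0.2]], [[0.1, 0.3]])
        genos = enumerate_genotypes(2)
        path = HiddenPath(np.array([1, 1]), np.array([0, 0]), 0.0)
        with pytest.warns(UserWarning):
            cm = estimate_cm(sites, path, genos, np.array([0.7]))
        assert cm[0] == 0.7

    def test_two_pass_recovers_true_offset(self, small_fit):
        # the simulated patient uses a log-ratio offset of 0.25
        assert small_fit.decomposition.params.offsets[0] == pytest.approx(0.25, abs=0.05)


class TestPipeline:
    def test_two_clone_patient_recovery(self, small_fit):
        dec = small_fit.decomposition
        assert dec.n_clones == 2
        assert np.allclose(dec.prevalence.cell_fractions, [[0.40, 0.35]], atol=0.05)

    def test_all_normal_input_gives_single_null_segment_per_chromosome(self):
        rng = np.random.default_rng(8)
        T = 600
        chrom = np.repeat(["c1", "c2", "c3"], T // 3)
        sites = SiteData(chrom,
                         np.concatenate([np.cumsum(rng.integers(100, 3000, T // 3))] * 3),
                         np.zeros(T, dtype=int),
                         np.clip(rng.normal(0.5, 0.04, (1, T)), 0, 1),
                         rng.normal(0.25, 0.15, (1, T)))
        dec = run_themis(sites, RunConfig(n_clones=2, max_iter=20))
        seg = dec.segments
        assert len(seg) == 3
        assert (seg["genotype"] == "AB").all()

    def test_deterministic_across_reruns(self):
        spec = two_clone_spec(seed=12, het_per_chrom=120, som_per_chrom=2, n_chrom=2)
        sites, _ = simulate_patient(spec)
        cfg = RunConfig(n_clones=2, max_iter=15)
        a = run_themis(sites, cfg)
        b = run_themis(sites, cfg)
        assert a.segments.equals(b.segments)
        assert np.array_equal(a.path.genotype_path, b.path.genotype_path)
        assert a.loglik == b.loglik

    def test_isolated_somatic_disagreement_does_not_propagate(self):
        # a single somatic site whose observations contradict the flanking
        # LOH state must not perturb the flanking germline decodes
        rng = np.random.default_rng(3)
        T = 61
        pos = np.cumsum(rng.integers(500, 2000, T))
        site_type = np.zeros(T, dtype=int)
        site_type[30] = 1
        phi = 0.75
        A = np.clip(rng.normal((1 - phi) / (2 - phi), 0.02, T), 0, 1)  # LOH (1,0)
        L = rng.normal(np.log2((2 - phi) / 2), 0.05, T)
        A[30] = 0.30   # SNV-like signal at odds with the deletion state
        L[30] = 0.0
        sites = SiteData(np.full(T, "c1"), pos, site_type, A[None, :], L[None, :])
        genos = enumerate_genotypes(5)
        params = ModelParams.initial(1, len(genos), 2, offsets=[0.0])
        params.var_A[:] = 0.02 ** 2
        params.var_L[:] = 0.05 ** 2
        hp = viterbi_decode(sites, params, PrevalenceConfig([[0.75, 0.35]]), genos)
        flank = np.r_[hp.genotype_path[:30], hp.genotype_path[31:]]
        assert len(np.unique(flank)) == 1
        assert [genos[i].label for i in np.unique(flank)] == ["A"]

    def test_segments_partition_chromosomes(self, small_fit):
        dec = small_fit.decomposition
        sites = dec.sites
        seg = dec.segments
        assert seg["n_sites"].sum() == sites.n_sites
        # adjacent segments on one chromosome differ in (genotype, clone)
        for chrom, g in seg.groupby("chrom", sort=False):
            pairs = zip(g.itertuples(), list(g.itertuples())[1:])
            for a, b in pairs:
                assert (a.genotype, a.clone) != (b.genotype, b.clone)
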