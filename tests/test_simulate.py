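"""The synthetic-patient generator and recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from themis import RunConfig, run_themis, score_recovery
from themis.simulate import (
    ROOT,
    CNAEvent,
    CloneSpec,
    TruthSpec,
    multi_biopsy_spec,
    simulate_patient,
    three_clone_spec,
    two_clone_spec,
)


class TestSpecValidation:
    def test_prevalence_sum_above_one_rejected(self):
        spec = two_clone_spec(seed=0, het_per_chrom=50, som_per_chrom=1, n_chrom=1)
        with pytest.raises(ValueError):
            TruthSpec(chroms=spec.chroms, positions=spec.positions,
                      site_types=spec.site_types, clones=spec.clones,
                      biopsies=[{"clone1": 0.7, "clone2": 0.5}],
                      offsets=(0.0,))

    def test_unknown_parent_rejected(self):
        spec = two_clone_spec(seed=0, het_per_chrom=50, som_per_chrom=1, n_chrom=1)
        clones = [CloneSpec("x", "ghost")]
        with pytest.raises(ValueError):
            TruthSpec(chroms=spec.chroms, positions=spec.positions,
                      site_types=spec.site_types, clones=clones,
                      biopsies=[{"x": 0.5}], offsets=(0.0,))

    def test_overlapping_events_between_clones_rejected(self):
        spec = two_clone_spec(seed=0, het_per_chrom=50, som_per_chrom=1, n_chrom=1)
        chrom = spec.chroms[0]
        lo, hi = int(spec.positions[chrom][0]), int(spec.positions[chrom][-1])
        for c in spec.clones:
            c.cnas = [CNAEvent(chrom, lo, hi, 1, 0)]  # same span in both clones
        with pytest.raises(ValueError):
            simulate_patient(spec)

    def test_subtree_prevalence_sums_descendants(self):
        spec = multi_biopsy_spec(seed=0, het_per_chrom=40, som_per_chrom=2)
        # ancestral clone carries every tumor cell in each biopsy
        assert spec.subtree_prevalence("A", 0) == pytest.approx(0.80)
        assert spec.subtree_prevalence("B", 0) == pytest.approx(0.30)
        assert spec.subtree_prevalence("CD", 1) == pytest.approx(0.35)
        assert spec.subtree_prevalence("D", 0) == 0.0


class TestGeneration:
    def test_noise_free_limit_equals_expected_means(self):
        spec = two_clone_spec(seed=1, het_per_chrom=100, som_per_chrom=4,
                              n_chrom=1, sigma_A=(0.0, 0.0), sigma_L=0.0)
        sites, truth = simulate_patient(spec)
        from themis.genotypes import Genotype, expected_allelic_ratio, expected_log_ratio

        for t in range(sites.n_sites):
            phi = truth["phi_1"].iloc[t]
            if phi > 0:
                g = Genotype(int(truth["total_copies"].iloc[t]),
                             int(truth["alt_copies"].iloc[t]))
            else:
                g = Genotype(2, 1)
                phi = 0.0
            st = "som" if truth["type"].iloc[t] == "som" else "het"
            assert sites.A[0, t] == pytest.approx(
                expected_allelic_ratio(g, phi, st), abs=1e-12)
            assert sites.L[0, t] == pytest.approx(
                expected_log_ratio(g, phi, 0.25), abs=1e-12)

    def test_same_seed_bit_identical(self):
        a_sites, a_truth = simulate_patient(two_clone_spec(seed=9, het_per_chrom=60,
                                                           som_per_chrom=2, n_chrom=2))
        b_sites, b_truth = simulate_patient(two_clone_spec(seed=9, het_per_chrom=60,
                                                           som_per_chrom=2, n_chrom=2))
        assert np.array_equal(a_sites.A, b_sites.A)
        assert np.array_equal(a_sites.L, b_sites.L)
        assert a_truth.equals(b_truth)

    def test_monte_carlo_mean_of_allelic_ratio(self):
        # one fixed site replicated many times: the empirical mean must sit
        # within 3 standard errors of the model mean
        spec = two_clone_spec(seed=2, het_per_chrom=40, som_per_chrom=1, n_chrom=1)
        draws = []
        t_idx = 0
        for rep in range(300):
            spec.seed = 10_000 + rep
            sites, truth = simulate_patient(spec)
            draws.append(sites.A[0, t_idx])
        assert truth["phi_1"].iloc[t_idx] == 0  # site 0 is neutral in this layout
        se = 0.05 / np.sqrt(len(draws))         # model mean 0.5, sigma 0.05
        assert abs(np.mean(draws) - 0.5) < 3 * se

    def test_pure_normal_spec_centers_on_normal_signal(self):
        spec = two_clone_spec(seed=3, het_per_chrom=300, som_per_chrom=10, n_chrom=1)
        spec.biopsies = [{}]  # no tumor cells at all
        sites, truth = simulate_patient(spec)
        het = sites.site_type == 0
        assert abs(sites.A[0, het].mean() - 0.5) < 0.01
        # somatic draws are clipped to [0, 1], so the mean sits slightly
        # above zero (half-normal bias ~ sigma * sqrt(2/pi) / 2)
        assert abs(sites.A[0, ~het].mean() - 0.0) < 0.035
        assert (truth["status_1"] == "normal").all()

    def test_yaml_round_trip(self, tmp_path):
        spec = two_clone_spec(seed=4, het_per_chrom=30, som_per_chrom=2, n_chrom=2)
        p = tmp_path / "spec.yaml"
        spec.to_yaml(p)
        back = TruthSpec.from_yaml(p)
        s1, t1 = simulate_patient(spec)
        s2, t2 = simulate_patient(back)
        assert np.array_equal(s1.A, s2.A) and t1.equals(t2)


class TestScoring:
    def _perfect_assignments(self, truth):
        status = truth["status_1"].to_numpy().copy()
        return pd.DataFrame({
            "chrom": truth["chrom"], "pos": truth["pos"], "type": truth["type"],
            "genotype": "x",
            "total_copies": np.where(truth["phi_1"] > 0, truth["total_copies"], 2),
            "alt_copies": np.where(
                truth["phi_1"] > 0, truth["alt_copies"],
                np.where(truth["type"] == "som", 0, 1)),
            "clone": 1, "status": status,
        })

    def _decomp_stub(self, frame):
        import types

        return types.SimpleNamespace(site_assignments=lambda: frame)

    def test_perfect_decode_scores_zero(self):
        _, truth = simulate_patient(two_clone_spec(seed=5, het_per_chrom=50,
                                                   som_per_chrom=2, n_chrom=1))
        scores = score_recovery(self._decomp_stub(self._perfect_assignments(truth)),
                                truth)
        assert scores == {"genotype_error_pct": 0.0, "clonality_error_pct": 0.0,
                          "either_error_pct": 0.0}

    def test_single_wrong_genotype_counted(self):
        _, truth = simulate_patient(two_clone_spec(seed=5, het_per_chrom=98,
                                                   som_per_chrom=2, n_chrom=1))
        frame = self._perfect_assignments(truth)
        het_idx = frame.index[frame["type"] == "het"][0]
        frame.loc[het_idx, "total_copies"] = 5
        scores = score_recovery(self._decomp_stub(frame), truth)
        T = len(truth)
        assert scores["genotype_error_pct"] == pytest.approx(100 / T)
        assert scores["clonality_error_pct"] == 0.0
        assert scores["either_error_pct"] == pytest.approx(100 / T)

    def test_either_error_at_least_each_component(self, small_fit):
        scores = score_recovery(small_fit.decomposition, small_fit.truth)
        assert scores["either_error_pct"] >= scores["genotype_error_pct"] - 1e-12
        assert scores["either_error_pct"] >= scores["clonality_error_pct"] - 1e-12

    def test_site_mismatch_rejected(self, small_fit):
        truth = small_fit.truth.iloc[:-1]
        with pytest.raises(ValueError):
            score_recovery(small_fit.decomposition, truth)


class TestPrevalenceLadder:
    def test_higher_prevalence_recovers_better(self):
        # single-clone patients with event prevalence 0.2 .. 0.8 at fixed
        # noise: recovery error decreases as prevalence rises
        errors = []
        for p in (0.2, 0.4, 0.6, 0.8):
            spec = two_clone_spec(seed=31, het_per_chrom=400, som_per_chrom=4,
                                  n_chrom=2, sigma_A=(0.04, 0.04), sigma_L=0.15)
            spec.biopsies = [{"clone1": p}]
            sites, truth = simulate_patient(spec)
            dec = run_themis(sites, RunConfig(n_clones=1, max_iter=25))
            errors.append(score_recovery(dec, truth)["either_error_pct"])
        assert errors[-1] < errors[0]
        assert errors[2] < errors[0]
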