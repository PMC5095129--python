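"""Map functions, BC2S3 genotype model, Haley-Knott scan, thresholds, intervals."""

import numpy as np
import pandas as pd
import pytest

from samshape import (
    QtlEffect,
    SimulationConfig,
    bayes_interval,
    bc2s3_joint,
    bc2s3_priors,
    bc2s3_transitions,
    genotype_expectations,
    kosambi_to_cm,
    kosambi_to_recfrac,
    permutation_threshold,
    scanone_hk,
    simulate_cross,
)
from samshape.qtl import AA, AB, BB, MISSING


class TestKosambi:
    def test_zero_maps_to_zero(self):
        assert kosambi_to_cm(0.0) == 0.0
        assert kosambi_to_recfrac(0.0) == 0.0

    def test_quarter_recombination_closed_form(self):
        assert kosambi_to_cm(0.25) == pytest.approx(25 * np.log(3), rel=1e-12)

    @pytest.mark.parametrize("r", np.arange(0.01, 0.50, 0.04))
    def test_round_trip(self, r):
        assert kosambi_to_recfrac(kosambi_to_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_invalid_rec_fraction_rejected(self):
        with pytest.raises(ValueError):
            kosambi_to_cm(0.5)
        with pytest.raises(ValueError):
            kosambi_to_recfrac(-1.0)


class TestBc2s3Model:
    def test_priors_are_breeding_design_frequencies(self):
        assert np.allclose(bc2s3_priors() * 64, [55, 2, 7])

    @pytest.mark.parametrize("r", [0.01, 0.1, 0.3, 0.49])
    def test_joint_marginals_equal_priors_at_any_distance(self, r):
        J = bc2s3_joint(r)
        assert J.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(J.sum(axis=1), bc2s3_priors(), atol=1e-12)
        assert np.allclose(J.sum(axis=0), bc2s3_priors(), atol=1e-12)

    def test_complete_linkage_keeps_genotypes_identical(self):
        J = bc2s3_joint(0.0)
        assert np.trace(J) == pytest.approx(1.0, abs=1e-12)

    def test_transitions_are_stochastic_matrices(self):
        T = bc2s3_transitions(np.array([0.05, 0.2]))
        assert T.shape == (2, 3, 3)
        assert np.allclose(T.sum(axis=2), 1.0, atol=1e-12)
        assert np.all(T >= 0)

    def test_one_marker_chain_matches_direct_enumeration(self):
        # forward-backward on a single-marker chromosome reduces to Bayes rule
        # with the stationary prior; enumerate it directly
        eps = 0.002
        prior = bc2s3_priors()
        for obs in (AA, AB, BB):
            emis = np.full(3, eps / 2)
            emis[obs] = 1 - eps
            expected = prior * emis / np.sum(prior * emis)
            cross = _single_marker_cross([obs])
            probs = genotype_expectations(cross, step=100.0, error_prob=eps)
            assert np.allclose(probs.probs["1"][0, 0], expected, atol=1e-12)


def _single_marker_cross(observed):
    from samshape.qtl import CrossPopulation, GeneticMap

    n = len(observed)
    gmap = GeneticMap(chromosomes=["1"], marker_names={"1": ["m1"]},
                      positions={"1": np.array([0.0])})
    pheno = pd.DataFrame({"y": np.zeros(n)},
                         index=[f"L{i}" for i in range(n)])
    return CrossPopulation(map=gmap, genotypes=np.array(observed, dtype=np.int8)[:, None],
                           phenotypes=pheno)


@pytest.fixture(scope="module")
def qtl_cross():
    cfg = SimulationConfig(seed=11, n_lines=200,
                           qtl=[QtlEffect("3", 50.0, effect_height=12.0)])
    return simulate_cross(cfg)


@pytest.fixture(scope="module")
def null_cross():
    return simulate_cross(SimulationConfig(seed=13, n_lines=150))


class TestGenotypeExpectations:
    def test_observed_marker_dominates_posterior(self, null_cross):
        # exact limit: a lone observed marker with vanishing error rate
        for obs in (AA, AB, BB):
            cross = _single_marker_cross([obs])
            probs = genotype_expectations(cross, step=100.0, error_prob=1e-12)
            assert probs.dosage("1")[0, 0] == pytest.approx(obs / 2.0, abs=1e-9)
        # on a dense map the marker posterior stays close to the observation;
        # isolated double-recombinant genotypes are discounted slightly
        probs = genotype_expectations(null_cross, step=1.0, error_prob=1e-6)
        X, grid = probs.stacked_dosage()
        at_markers = grid["is_marker"].to_numpy()
        obs = null_cross.genotypes.astype(float) / 2.0
        assert np.abs(X[:, at_markers] - obs).max() < 5e-3

    def test_missing_between_maize_homozygotes_is_maize(self):
        from samshape.qtl import CrossPopulation, GeneticMap

        gmap = GeneticMap(chromosomes=["1"], marker_names={"1": ["a", "b", "c"]},
                          positions={"1": np.array([0.0, 0.0, 0.0])})
        geno = np.array([[AA, MISSING, AA]], dtype=np.int8)
        cross = CrossPopulation(map=gmap, genotypes=geno,
                                phenotypes=pd.DataFrame({"y": [0.0]}, index=["L0"]))
        probs = genotype_expectations(cross, step=5.0, error_prob=0.002)
        dosage = probs.dosage("1")[0]
        assert np.all(dosage < 1e-2)

    def test_uninformative_chromosome_returns_prior_mean_dosage(self):
        cross = _single_marker_cross([MISSING])
        probs = genotype_expectations(cross, step=100.0, error_prob=0.002)
        # prior mean dosage/2 = (2/64 + 2*7/64)/2 = 0.125
        assert probs.dosage("1")[0, 0] == pytest.approx(0.125, abs=1e-12)

    def test_stationarity_of_marginals_along_grid(self, null_cross):
        # averaged over many lines, dosage at pseudomarkers matches the prior
        probs = genotype_expectations(null_cross, step=1.0)
        X, _ = probs.stacked_dosage()
        assert X.mean() == pytest.approx(0.125, abs=0.02)


class TestScanone:
    def test_perfect_signal_peaks_at_causal_marker(self, null_cross):
        cross = null_cross
        m_idx = 60  # a marker on chromosome 2
        cross.phenotypes["fake"] = cross.genotypes[:, m_idx].astype(float)
        scan = scanone_hk(cross, "fake")
        names = [n for ch in cross.map.chromosomes for n in cross.map.marker_names[ch]]
        peak_chr, peak_pos = scan.peak()
        target_chr = "2"
        target_pos = cross.map.positions["2"][m_idx - 50]
        assert peak_chr == target_chr
        assert peak_pos == pytest.approx(target_pos, abs=1e-6)
        assert scan.max_lod() > 50  # capped but numerically large

    def test_affine_invariance_of_lod(self, qtl_cross):
        scan1 = scanone_hk(qtl_cross, "height")
        qtl_cross.phenotypes["height2"] = 3.0 * qtl_cross.phenotypes["height"] - 40.0
        scan2 = scanone_hk(qtl_cross, "height2")
        assert np.allclose(scan1.table["lod"], scan2.table["lod"], atol=1e-9)

    def test_constant_phenotype_warns_zero_lod(self, null_cross):
        null_cross.phenotypes["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            scan = scanone_hk(null_cross, "const")
        assert np.allclose(scan.table["lod"], 0.0)

    def test_simulated_qtl_detected_at_position(self, qtl_cross):
        scan = scanone_hk(qtl_cross, "height")
        ch, pos = scan.peak()
        assert ch == "3"
        assert abs(pos - 50.0) < 15.0


class TestPermutationThreshold:
    def test_alpha_one_returns_minimum(self, qtl_cross):
        thr, maxima = permutation_threshold(qtl_cross, "height", n_perm=50, alpha=1.0,
                                            seed=4, return_maxima=True)
        assert thr == pytest.approx(maxima.min())

    def test_reproducible_and_monotone_in_alpha(self, qtl_cross):
        t1 = permutation_threshold(qtl_cross, "height", n_perm=100, alpha=0.05, seed=5)
        t2 = permutation_threshold(qtl_cross, "height", n_perm=100, alpha=0.05, seed=5)
        t3 = permutation_threshold(qtl_cross, "height", n_perm=100, alpha=0.20, seed=5)
        assert t1 == t2
        assert t3 <= t1

    def test_threshold_stable_under_doubling(self, qtl_cross):
        t1 = permutation_threshold(qtl_cross, "height", n_perm=500, seed=6)
        t2 = permutation_threshold(qtl_cross, "height", n_perm=1000, seed=6)
        assert abs(t2 - t1) / t1 < 0.05


class TestBayesInterval:
    def _scan_with_lod(self, lod, pos=None, markers=None):
        from samshape.qtl import QtlScanResult

        lod = np.asarray(lod, dtype=float)
        pos = np.arange(len(lod), dtype=float) if pos is None else np.asarray(pos)
        is_marker = np.ones(len(lod), bool) if markers is None else np.asarray(markers)
        table = pd.DataFrame({"chr": "1", "pos_cM": pos,
                              "marker": [f"m{i}" for i in range(len(lod))],
                              "is_marker": is_marker, "lod": lod})
        return QtlScanResult(table=table, trait="y")

    def test_sharp_spike_collapses_to_flanking_markers(self):
        lod = np.zeros(21)
        lod[10] = 30.0
        markers = np.zeros(21, bool)
        markers[[0, 8, 12, 20]] = True
        iv = bayes_interval(self._scan_with_lod(lod, markers=markers), "1")
        assert iv.lower == 8.0 and iv.upper == 12.0 and iv.peak == 10.0

    def test_symmetric_profile_gives_symmetric_interval(self):
        pos = np.arange(41, dtype=float)
        lod = 5.0 * np.exp(-((pos - 20) ** 2) / 30.0)
        iv = bayes_interval(self._scan_with_lod(lod, pos=pos), "1")
        assert iv.peak == 20.0
        assert (iv.peak - iv.lower) == pytest.approx(iv.upper - iv.peak, abs=1.0)

    def test_flat_lod_covers_whole_chromosome_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            iv = bayes_interval(self._scan_with_lod(np.ones(11)), "1")
        assert iv.lower == 0.0 and iv.upper == 10.0

    def test_simulated_interval_contains_truth(self, qtl_cross):
        scan = scanone_hk(qtl_cross, "height")
        iv = bayes_interval(scan, "3")
        assert iv.lower <= 50.0 <= iv.upper

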