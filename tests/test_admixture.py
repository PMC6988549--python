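"""NMF admixture estimator, K selection, Evanno DeltaK, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popstruct import (AdmixtureFit, SampleTable, aligned_q_rmse,
                       align_clusters, assign_individuals, cluster_summaries,
                       evanno_delta_k, project_rows_to_simplex,
                       regional_assignment_summary, select_K, snmf_fit,
                       allele_freq)

from conftest import make_gm


@pytest.fixture(scope="module")
def recovery_sim():
    """Full-scale structured simulation (K=3, F=0.05, n=300, m=1000)."""
    from popstruct import SimConfig, simulate_dataset
    cfg = SimConfig(fst_target=0.05, seed=101)
    gm, vt, st_, truth = simulate_dataset(cfg)
    return gm, truth


class TestSimplexProjection:
    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.lists(st.floats(-5, 5), min_size=2, max_size=6),
                    min_size=1, max_size=5).filter(
                        lambda r: len({len(x) for x in r}) == 1))
    def test_projection_lands_on_simplex(self, rows):
        P = project_rows_to_simplex(np.array(rows, dtype=float))
        assert (P >= 0).all()
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-8)

    def test_points_on_simplex_are_fixed(self):
        Q = np.array([[0.2, 0.3, 0.5], [1.0, 0.0, 0.0]])
        np.testing.assert_allclose(project_rows_to_simplex(Q), Q, atol=1e-12)


class TestSnmfFit:
    def test_k1_degeneracy_recovers_allele_frequencies(self):
        rng = np.random.default_rng(0)
        codes = rng.choice([0, 1, 2], size=(40, 60), p=[0.5, 0.3, 0.2])
        gm = make_gm(codes)
        fit = snmf_fit(gm, K=1, seed=1, mask_fraction=0.0)
        np.testing.assert_allclose(fit.Q, 1.0, atol=1e-8)
        freq, _ = allele_freq(gm)
        np.testing.assert_allclose(fit.F[0], freq, atol=0.02)

    def test_two_fixed_populations_membership_recovered(self):
        codes = np.zeros((40, 50), dtype=np.int8)
        codes[20:, :] = 2
        gm = make_gm(codes)
        fit = snmf_fit(gm, K=2, seed=3)
        truth = np.zeros((40, 2))
        truth[:20, 0] = 1
        truth[20:, 1] = 1
        assert aligned_q_rmse(fit.Q, truth) < 0.05
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)
        assert ((fit.F >= 0) & (fit.F <= 1)).all()

    def test_three_population_parameter_recovery(self, recovery_sim):
        """Balding-Nichols admixed data, K=3, F=0.05, n=300, m=1000: aligned
        ancestry proportions recovered to RMSE < 0.10."""
        gm, truth = recovery_sim
        fit = snmf_fit(gm, K=3, seed=11)
        assert aligned_q_rmse(fit.Q, truth.q) < 0.10

    def test_loss_nonincreasing(self, small_sim):
        cfg, (gm, *_rest) = small_sim
        fit = snmf_fit(gm, K=3, seed=5)
        diffs = np.diff(fit.loss_history)
        assert (diffs <= 1e-9 * fit.loss_history[:-1] + 1e-9).all()

    def test_k_above_n_rejected(self):
        gm = make_gm(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            snmf_fit(gm, K=4)


class TestSelectK:
    def test_recovers_true_k(self, recovery_sim):
        gm, truth = recovery_sim
        ksel = select_K(gm, range(1, 5), replicates=2, seed=4)
        assert ksel.best_k == 3

    def test_singleton_range(self):
        rng = np.random.default_rng(0)
        gm = make_gm(rng.choice([0, 1, 2], size=(20, 30)))
        ksel = select_K(gm, [1], replicates=2, seed=0)
        assert ksel.best_k == 1 and ksel.delta_k == {}

    def test_empty_range_rejected(self):
        gm = make_gm(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="empty"):
            select_K(gm, [], replicates=2)


class TestEvannoDeltaK:
    def test_peak_at_elbow_of_synthetic_curve(self):
        rng = np.random.default_rng(1)
        crit = {k: list(-(-abs(k - 3)) + rng.normal(0, 0.1, size=8))
                for k in range(1, 7)}
        # criterion = |K-3| + noise: kink (max curvature) at K=3
        dk = evanno_delta_k(crit)
        assert max(dk, key=dk.get) == 3

    def test_linear_curve_gives_zero(self):
        rng = np.random.default_rng(2)
        crit = {k: [2.0 * k + rng.normal(0, 0.05) for _ in range(6)]
                for k in range(1, 6)}
        dk = evanno_delta_k(crit)
        # second difference of a line is ~0 relative to replicate sd
        assert all(v < 25 for v in dk.values())
        crit_exact = {k: [2.0 * k, 2.0 * k + 0.1] for k in range(1, 6)}
        # constant second difference per replicate: |L(K-1)-2L(K)+L(K+1)| = 0
        dk_exact = evanno_delta_k(crit_exact)
        assert all(v == pytest.approx(0.0) for v in dk_exact.values())

    def test_zero_spread_is_undefined_not_infinite(self):
        crit = {k: [10.0, 10.0] for k in range(1, 5)}
        with pytest.warns(UserWarning, match="undefined"):
            dk = evanno_delta_k(crit)
        assert all(np.isnan(v) for v in dk.values())

    def test_needs_three_ks_and_two_replicates(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [1, 2], 2: [1, 2]})
        with pytest.raises(ValueError):
            evanno_delta_k({1: [1], 2: [1], 3: [1]})


def _fit_from_q(Q, F=None):
    K = Q.shape[1]
    m = 4 if F is None else F.shape[1]
    F = F if F is not None else np.full((K, m), 0.5)
    return AdmixtureFit(K=K, Q=Q, F=F, G=np.zeros((K, m, 3)), cross_entropy=0.1,
                        seed=0, n_iter=1, converged=True)


class TestAssignment:
    def test_argmax_and_tie_rule(self):
        Q = np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0]])
        with pytest.warns(UserWarning, match="tied"):
            labels = assign_individuals(_fit_from_q(Q))
        np.testing.assert_array_equal(labels, [0, 0])

    def test_simulation_agreement(self, small_sim):
        cfg, (gm, vt, st_, truth) = small_sim
        fit = snmf_fit(gm, K=3, seed=21)
        labels = assign_individuals(fit)
        perm = align_clusters(fit.Q, truth.q)
        relabel = np.empty(3, dtype=int)
        for ref_col in range(3):
            relabel[perm[ref_col]] = ref_col
        agree = (relabel[labels] == truth.q.argmax(axis=1)).mean()
        assert agree >= 0.95


class TestRegionalSummary:
    def _st(self, regions):
        n = len(regions)
        return SampleTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "locality_id": "L1", "latitude": 45.0, "longitude": -70.0,
            "region": regions}))

    def test_single_region_single_cluster(self):
        st_ = self._st(["central"] * 5)
        pct, counts = regional_assignment_summary(np.zeros(5, dtype=int), st_)
        assert pct.loc["central", 0] == pytest.approx(100.0)

    def test_two_of_29_is_6p9_percent(self):
        """2/29 central-region individuals assigned to the eastern cluster."""
        st_ = self._st(["central"] * 29)
        labels = np.array([1] * 2 + [0] * 27)
        pct, counts = regional_assignment_summary(labels, st_)
        assert pct.loc["central", 1] == pytest.approx(100 * 2 / 29)  # 6.9%
        assert round(pct.loc["central", 1], 1) == 6.9
        np.testing.assert_allclose(pct.sum(axis=1), 100.0)

    def test_planted_foreign_assignment_recovered(self):
        rng = np.random.default_rng(3)
        n = 400
        labels = (rng.random(n) < 0.25).astype(int)
        st_ = self._st(["eastern"] * n)
        pct, _ = regional_assignment_summary(labels, st_)
        assert pct.loc["eastern", 1] == pytest.approx(25.0, abs=3 * 100 * 0.0217)


class TestClusterSummaries:
    def test_identical_rows_zero_distance(self):
        F = np.tile(np.array([0.3, 0.6, 0.1]), (2, 1))
        cs = cluster_summaries(_fit_from_q(np.ones((4, 2)) / 2, F))
        np.testing.assert_allclose(cs.net_nucleotide_distance, 0.0, atol=1e-12)

    def test_fixed_difference_extreme(self):
        F = np.array([[1.0], [0.0]])
        cs = cluster_summaries(_fit_from_q(np.ones((4, 2)) / 2, F))
        assert cs.net_nucleotide_distance[0, 1] == pytest.approx(1.0)

    def test_hand_computed_two_cluster_one_locus(self):
        """p=(0.2, 0.8): D=0.68, self terms 0.32 -> net 0.36."""
        F = np.array([[0.2], [0.8]])
        cs = cluster_summaries(_fit_from_q(np.ones((4, 2)) / 2, F))
        assert cs.net_nucleotide_distance[0, 1] == pytest.approx(0.36)
        np.testing.assert_allclose(cs.expected_heterozygosity, [0.32, 0.32])
        # ancestral mean p=0.5 -> H_anc=0.5; Fst = 1 - 0.32/0.5 = 0.36
        np.testing.assert_allclose(cs.within_cluster_fst, [0.36, 0.36])

    def test_symmetry_and_nonnegativity_on_fit(self, small_sim):
        cfg, (gm, *_rest) = small_sim
        cs = cluster_summaries(snmf_fit(gm, K=3, seed=2))
        D = cs.net_nucleotide_distance
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert (np.diag(D) == 0).all()
        assert (D >= -1e-12).all()
        assert ((cs.expected_heterozygosity >= 0)
                & (cs.expected_heterozygosity <= 1)).all()
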