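import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mtgvar.genome_data import DRPTable, GenotypePanel, drp_weights
from mtgvar.mt_gblup import (
    build_grm,
    gebv_from_components,
    reml_bivariate,
)
from mtgvar.synthetic_data import SimulationConfig, simulate_genotypes

from conftest import make_map


def toy_grm(rng, n1=6, n2=6, n_markers=40):
    cfg = SimulationConfig(n_animals=(n1, n2), markers_per_chromosome=n_markers,
                           window=20, merge_threshold=10,
                           seed=int(rng.integers(1 << 30)))
    panels = simulate_genotypes(cfg)
    return build_grm(panels), panels


def toy_tables(rng, grm, g0, ve, rel=0.8):
    n1 = grm.n_pop1
    n = grm.n_animals
    L = np.linalg.cholesky(grm.values + 1e-8 * np.eye(n))
    a = L @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(g0).T
    rel1 = np.full(n1, rel)
    rel2 = np.full(n - n1, rel)
    d1, d2 = drp_weights(rel1), drp_weights(rel2)
    y1 = a[:n1, 0] + rng.standard_normal(n1) * np.sqrt(d1 * ve[0])
    y2 = a[n1:, 1] + rng.standard_normal(n - n1) * np.sqrt(d2 * ve[1])
    t1 = DRPTable("pop1", grm.animal_id[:n1], y1, rel1, weight=d1)
    t2 = DRPTable("pop2", grm.animal_id[n1:], y2, rel2, weight=d2)
    return (t1, t2), a


class TestBuildGrm:
    def test_single_marker_hand_computation(self):
        # genotypes (0,1,2), p=0.5 -> Z=(-1,0,1), scaling 0.5
        m = make_map(1)
        p1 = GenotypePanel("a", np.array([[0], [1]]), m)
        p2 = GenotypePanel("b", np.array([[2]]), m)
        grm = build_grm((p1, p2))
        assert grm.scaling == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(grm.values), [2.0, 0.0, 2.0])
        assert grm.values[0, 2] == pytest.approx(-2.0)

    def test_mean_diagonal_near_one_under_hwe(self, rng):
        grm, _ = toy_grm(rng, n1=300, n2=300, n_markers=1000)
        assert np.diag(grm.values).mean() == pytest.approx(1.0, abs=0.05)

    def test_duplicated_animals_give_identical_rows(self, rng):
        cfg = SimulationConfig(n_animals=(5, 5), markers_per_chromosome=30,
                               window=15, merge_threshold=5, seed=3)
        p1, p2 = simulate_genotypes(cfg)
        g = p1.genotypes.copy()
        g[1] = g[0]
        p1dup = GenotypePanel("a", g, p1.map)
        grm = build_grm((p1dup, p2))
        np.testing.assert_allclose(grm.values[0], grm.values[1])

    def test_monomorphic_error(self):
        m = make_map(1)
        p1 = GenotypePanel("a", np.zeros((3, 1), dtype=int), m)
        p2 = GenotypePanel("b", np.zeros((3, 1), dtype=int), m)
        with pytest.raises(ValueError, match="monomorphic"):
            build_grm((p1, p2))

    def test_psd_up_to_noise(self, rng):
        grm, _ = toy_grm(rng, n1=40, n2=40, n_markers=100)
        assert np.linalg.eigvalsh(grm.values).min() >= -1e-8

    def test_hdf5_round_trip(self, rng, tmp_path):
        from mtgvar.mt_gblup import grm_from_hdf5, grm_to_hdf5

        grm, _ = toy_grm(rng, n1=8, n2=8, n_markers=40)
        grm_to_hdf5(tmp_path / "g.h5", grm)
        back = grm_from_hdf5(tmp_path / "g.h5")
        np.testing.assert_array_equal(back.values, grm.values)
        assert list(back.animal_id) == list(grm.animal_id)
        assert back.n_pop1 == grm.n_pop1
        assert back.scaling == grm.scaling


class TestRemlBivariate:
    def test_loglik_matches_dense_mvn_oracle(self, rng):
        # 12-animal toy: REML logL == log density of y under
        # N(X b_gls, V) plus the fixed-effects REML adjustment
        grm, _ = toy_grm(rng, n1=6, n2=6, n_markers=50)
        g0 = np.array([[1.0, 0.4], [0.4, 0.8]])
        tables, _ = toy_tables(rng, grm, g0, ve=(0.5, 0.5))
        comps = reml_bivariate(grm, tables)
        # rebuild V at the estimates and evaluate the restricted likelihood
        # from its textbook definition via dense matrices
        n1 = grm.n_pop1
        G11, G12, G22 = grm.blocks()
        y = np.concatenate([tables[0].drp, tables[1].drp])
        d1, d2 = tables[0].weight, tables[1].weight
        va1, cov = comps.g0[0, 0], comps.g0[0, 1]
        va2 = comps.g0[1, 1]
        ve1, ve2 = comps.residual_var
        V = np.block([[va1 * G11, cov * G12], [cov * G12.T, va2 * G22]])
        V[np.arange(6), np.arange(6)] += ve1 * d1
        V[np.arange(6, 12), np.arange(6, 12)] += ve2 * d2
        X = np.zeros((12, 2))
        X[:6, 0] = 1.0
        X[6:, 1] = 1.0
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        ll_full = multivariate_normal(mean=X @ beta, cov=V).logpdf(y)
        sign, logdet_x = np.linalg.slogdet(X.T @ Vinv @ X)
        # fitted logL drops the -(n/2) log 2pi constant, so add it back to
        # the dense oracle before comparing
        expected = ll_full - 0.5 * logdet_x + 6.0 * np.log(2 * np.pi)
        assert comps.loglik == pytest.approx(expected, abs=1e-6)

    def test_loglik_nondecreasing(self, rng):
        grm, _ = toy_grm(rng, n1=40, n2=40, n_markers=150)
        g0 = np.array([[1.0, 0.6], [0.6, 1.0]])
        tables, _ = toy_tables(rng, grm, g0, ve=(1.0, 1.0))
        comps = reml_bivariate(grm, tables)
        path = np.asarray(comps.loglik_path)
        assert np.all(np.diff(path) >= -1e-8)

    def test_null_covariance_recovery(self, rng):
        grm, _ = toy_grm(rng, n1=150, n2=150, n_markers=400)
        g0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        tables, _ = toy_tables(rng, grm, g0, ve=(1.0, 1.0))
        comps = reml_bivariate(grm, tables)
        assert abs(comps.corr) < 2 * comps.corr_se + 1e-8

    def test_moderate_recovery_within_2se(self):
        rng = np.random.default_rng(42)
        grm, _ = toy_grm(rng, n1=200, n2=200, n_markers=500)
        g0 = np.array([[1.0, 0.6], [0.6, 1.0]])
        tables, _ = toy_tables(rng, grm, g0, ve=(1.0, 1.0))
        comps = reml_bivariate(grm, tables)
        est = np.array([comps.g0[0, 0], comps.g0[0, 1], comps.g0[1, 1],
                        comps.residual_var[0], comps.residual_var[1]])
        truth = np.array([1.0, 0.6, 1.0, 1.0, 1.0])
        assert np.all(np.abs(est - truth) <= 2.5 * comps.se)


class TestGebv:
    def test_matches_dense_mme_oracle(self, rng):
        grm, _ = toy_grm(rng, n1=6, n2=6, n_markers=60)
        g0 = np.array([[1.0, 0.5], [0.5, 1.0]])
        tables, _ = toy_tables(rng, grm, g0, ve=(0.7, 0.7))
        # fixed, known components: the oracle compares the BLUP algebra
        from mtgvar.mt_gblup import VarianceComponents

        comps = VarianceComponents(
            g0=g0, residual_var=np.array([0.7, 0.7]), se=np.zeros(5),
            corr=0.5, corr_se=0.0, loglik=0.0, loglik_path=[0.0],
            n_iter=0, converged=True, ai_inverse=np.eye(5),
        )
        gebv = gebv_from_components(grm, comps, tables)

        # oracle: Henderson mixed-model equations with full 2q-dim effects
        q = grm.n_animals
        n1 = grm.n_pop1
        y = np.concatenate([tables[0].drp, tables[1].drp])
        R = np.concatenate([tables[0].weight * comps.residual_var[0],
                            tables[1].weight * comps.residual_var[1]])
        X = np.zeros((q, 2))
        X[:n1, 0] = 1.0
        X[n1:, 1] = 1.0
        Z = np.zeros((q, 2 * q))
        for i in range(n1):
            Z[i, i] = 1.0                 # trait-1 effect of animal i
        for i in range(n1, q):
            Z[i, q + i] = 1.0             # trait-2 effect of animal i
        Ginv = np.linalg.inv(
            np.kron(comps.g0, grm.values + 1e-8 * np.eye(q))
        )
        Rinv = np.diag(1.0 / R)
        C = np.block([
            [X.T @ Rinv @ X, X.T @ Rinv @ Z],
            [Z.T @ Rinv @ X, Z.T @ Rinv @ Z + Ginv],
        ])
        rhs = np.concatenate([X.T @ Rinv @ y, Z.T @ Rinv @ y])
        sol = np.linalg.solve(C, rhs)
        a_hat = sol[2:]
        oracle = np.column_stack([a_hat[:q], a_hat[q:]])
        np.testing.assert_allclose(gebv, oracle, atol=1e-5)

    def test_block_separation_with_diagonal_g0(self, rng):
        grm, _ = toy_grm(rng, n1=20, n2=20, n_markers=80)
        g0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        tables, _ = toy_tables(rng, grm, g0, ve=(1.0, 1.0))
        # force exactly diagonal components to isolate the block structure
        from mtgvar.mt_gblup import VarianceComponents

        comps = VarianceComponents(
            g0=g0, residual_var=np.array([1.0, 1.0]), se=np.zeros(5),
            corr=0.0, corr_se=0.0, loglik=0.0, loglik_path=[0.0],
            n_iter=0, converged=True, ai_inverse=np.eye(5),
        )
        gebv = gebv_from_components(grm, comps, tables)
        # trait-1 GEBV must not change when trait-2 records change
        t2_mod = DRPTable("pop2", tables[1].animal_id, tables[1].drp + 5.0,
                          tables[1].reliability, weight=tables[1].weight)
        gebv2 = gebv_from_components(grm, comps, (tables[0], t2_mod))
        np.testing.assert_allclose(gebv[:, 0], gebv2[:, 0], atol=1e-10)

    def test_unrelated_animal_gets_near_zero(self, rng):
        grm, _ = toy_grm(rng, n1=15, n2=15, n_markers=100)
        G = grm.values.copy()
        G[0, 1:] = 0.0
        G[1:, 0] = 0.0
        G[0, 0] = 1.0
        grm.values = G
        g0 = np.array([[1.0, 0.5], [0.5, 1.0]])
        tables, _ = toy_tables(rng, grm, g0, ve=(1.0, 1.0))
        # remove animal 0's own record signal by zeroing its phenotype
        # deviation: its GEBV must then be driven only by relatives (none)
        t1 = tables[0]
        y = t1.drp.copy()
        y[0] = float(np.average(y[1:]))  # uninformative own record
        from mtgvar.mt_gblup import VarianceComponents

        comps = VarianceComponents(
            g0=g0, residual_var=np.array([1.0, 1.0]), se=np.zeros(5),
            corr=0.5, corr_se=0.0, loglik=0.0, loglik_path=[0.0],
            n_iter=0, converged=True, ai_inverse=np.eye(5),
        )
        gebv = gebv_from_components(
            grm, comps,
            (DRPTable("pop1", t1.animal_id, y, t1.reliability,
                      weight=t1.weight), tables[1]),
        )
        # trait-2 GEBV of the unrelated animal comes only through g0 and its
        # own trait-1 record, which was made uninformative
        assert abs(gebv[0, 1]) < 0.35 * np.abs(gebv[:, 1]).max()
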