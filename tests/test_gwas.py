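"""Association scans: OLS/GLS estimators, invariance theorems, MME/BLUP
equivalences, corrected variances, PC adjustment, SMV."""

import numpy as np
import pytest
import scipy.linalg

from grmscan import (
    GenotypeMatrix,
    PhenotypeVector,
    SimConfig,
    VarComp,
    PhenoCov,
    blup_strongarm,
    build_grm,
    center_markers,
    drop_markers_grm,
    eigen_grm,
    gls_scan,
    lowrank_downdate_inv,
    markerout_variance,
    mme_solve,
    mmr_gls,
    ols_scan,
    pc_adjusted_scan,
    rank1_downdate_inv,
    simulate_dataset,
    smv,
    whiten_gls,
)

from conftest import phenocov_from_matrix, random_pd


def _panel(values, ploidy="diploid012", centered=True):
    arr = np.asarray(values, dtype=float)
    n, p = arr.shape
    g = GenotypeMatrix(arr, [f"s{i}" for i in range(n)], [f"m{j}" for j in range(p)], ploidy)
    return center_markers(g) if centered else g


def _pheno(values):
    return PhenotypeVector(values, [f"s{i}" for i in range(len(values))])


def _sim_instance(seed, n=50, p=200, h2=0.5, scaling="mean_diag"):
    cfg = SimConfig(n=n, p=p, h2_true=h2, seed=seed)
    raw, centered, grm, y, vc = simulate_dataset(cfg, scaling=scaling)
    pc = PhenoCov.from_grm(grm, vc.sigma_g2, vc.sigma_e2)
    return centered, grm, y, vc, pc


class TestOlsScan:
    def test_perfect_fit_marker(self):
        g = _panel([[0.0], [1.0], [2.0]])  # centers to -1,0,1
        y = _pheno([-2.0, 0.0, 2.0])
        t = ols_scan(g, y)
        row = t.table.iloc[0]
        assert row["beta"] == pytest.approx(2.0)
        assert row["r2"] == pytest.approx(1.0)

    def test_orthogonal_marker_has_zero_slope(self):
        g = _panel([[0.0], [2.0], [0.0], [2.0]])
        y = _pheno([-1.0, -1.0, 1.0, 1.0])
        row = ols_scan(g, y).table.iloc[0]
        assert row["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_on_random_panel(self, small_dataset):
        _, g, _, y, _ = small_dataset
        t = ols_scan(g, y).table
        yc = y.values - y.values.mean()
        j = 7
        x = g.values[:, j]
        beta = float(x @ yc) / float(x @ x)
        assert t["beta"].iloc[j] == pytest.approx(beta, rel=1e-12)
        assert 0.0 <= t["r2"].iloc[j] <= 1.0
        assert ((t["p_value"].dropna() >= 0) & (t["p_value"].dropna() <= 1)).all()

    def test_monomorphic_marker_row_is_undefined(self):
        g = _panel([[0.0, 1.0], [2.0, 1.0], [1.0, 1.0]])
        y = _pheno([0.0, 1.0, -1.0])
        t = ols_scan(g, y)
        assert np.isnan(t.table["beta"].iloc[1])
        assert not t.table["significant"].iloc[1]
        assert t.n_tested == 1


class TestGlsScan:
    def test_identity_covariance_reduces_to_ols(self, small_dataset):
        _, g, _, y, _ = small_dataset
        yc = PhenotypeVector(y.values - y.values.mean(), y.sample_ids)
        pc = phenocov_from_matrix(np.eye(g.n))
        gls = gls_scan(g, yc, pc).table
        ols = ols_scan(g, yc).table
        np.testing.assert_allclose(gls["beta"], ols["beta"], atol=1e-10)

    def test_marker_removed_from_G_same_estimate(self, small_dataset):
        """Removing the tested marker's own term from V leaves β̂ unchanged."""
        _, g, grm, y, vc = small_dataset
        pc = PhenoCov.from_grm(grm, vc.sigma_g2, vc.sigma_e2)
        base = gls_scan(g, y, pc).table
        for j in [0, 5, 33]:
            xj = g.values[:, j]
            pc_mj = rank1_downdate_inv(pc, xj, pc.marker_c)
            beta_out = float(xj @ pc_mj.solve(y.values)) / float(xj @ pc_mj.solve(xj))
            assert beta_out == pytest.approx(base["beta"].iloc[j], abs=1e-8)

    def test_markerout_se_is_smaller_than_naive(self, small_dataset):
        _, g, grm, y, vc = small_dataset
        pc = PhenoCov.from_grm(grm, vc.sigma_g2, vc.sigma_e2)
        t = gls_scan(g, y, pc).table.dropna(subset=["se"])
        assert (t["se_markerout"] <= t["se"] + 1e-12).all()


class TestMarkeroutVariance:
    @pytest.mark.parametrize("seed", range(15))
    def test_equals_naive_minus_marker_share(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=9)
        G_rest = random_pd(rng, 9, jitter=0.2)
        c_sigma = 0.3
        V = G_rest + c_sigma * np.outer(x, x) + np.eye(9)
        pc = phenocov_from_matrix(V)
        var = markerout_variance(pc, x, c_sigma)
        naive = 1.0 / float(x @ pc.solve(x))
        assert var == pytest.approx(naive - c_sigma, abs=1e-10)
        assert var > 0

    def test_zero_share_recovers_naive_variance(self):
        rng = np.random.default_rng(2)
        V = random_pd(rng, 6)
        x = rng.normal(size=6)
        pc = phenocov_from_matrix(V)
        naive = 1.0 / float(x @ pc.solve(x))
        assert markerout_variance(pc, x, 0.0) == pytest.approx(naive, rel=1e-12)

    def test_degenerate_marker_rejected(self):
        pc = phenocov_from_matrix(np.eye(4))
        with pytest.raises(ValueError, match="degenerate"):
            markerout_variance(pc, np.zeros(4), 0.1)


class TestMmrGls:
    def test_single_column_matches_scan(self, small_dataset):
        _, g, grm, y, vc = small_dataset
        pc = PhenoCov.from_grm(grm, vc.sigma_g2, vc.sigma_e2)
        scan = gls_scan(g, y, pc).table
        j = 11
        res = mmr_gls(g.values[:, j], y, pc, c_sigma=pc.marker_c)
        assert res.beta[0] == pytest.approx(scan["beta"].iloc[j], rel=1e-10)
        assert np.sqrt(res.cov_naive[0, 0]) == pytest.approx(scan["se"].iloc[j], rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_corrected_covariance_equals_sandwich_form(self, seed):
        rng = np.random.default_rng(500 + seed)
        n, m = 12, 3
        Xm = rng.normal(size=(n, m))
        c_sigma = 0.2
        V = random_pd(rng, n, jitter=0.3) + c_sigma * Xm @ Xm.T
        pc = phenocov_from_matrix(V)
        res = mmr_gls(Xm, rng.normal(size=n), pc, c_sigma=c_sigma)
        Vinv = pc.Vinv
        V_out = V - c_sigma * Xm @ Xm.T
        A_inv = scipy.linalg.inv(Xm.T @ Vinv @ Xm)
        sandwich = A_inv @ Xm.T @ Vinv @ V_out @ Vinv @ Xm @ A_inv
        np.testing.assert_allclose(res.cov_corrected, sandwich, atol=1e-9)

    def test_joint_estimate_invariant_to_removing_markers_from_V(self, small_dataset):
        """m-marker analogue of the marker-out invariance."""
        _, g, grm, y, vc = small_dataset
        pc = PhenoCov.from_grm(grm, vc.sigma_g2, vc.sigma_e2)
        idx = [2, 10, 20]
        Xm = g.values[:, idx]
        res_in = mmr_gls(Xm, y, pc)
        pc_out = lowrank_downdate_inv(pc, Xm, pc.marker_c)
        res_out = mmr_gls(Xm, y, pc_out)
        np.testing.assert_allclose(res_in.beta, res_out.beta, atol=1e-8)

    def test_collinear_columns_named(self):
        pc = phenocov_from_matrix(np.eye(5))
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="collinear"):
            mmr_gls(X, np.zeros(5), pc)

    def test_identity_V_is_ols_multiple_regression(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        pc = phenocov_from_matrix(np.eye(20))
        res = mmr_gls(X, y, pc)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.beta, beta_ols, atol=1e-10)


class TestMmeSolve:
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_gls_plus_strongarm_blup(self, seed):
        rng = np.random.default_rng(600 + seed)
        n = 15
        G = random_pd(rng, n, jitter=0.5)  # invertible G
        from grmscan import GRM

        grm = GRM(G, 1.0, [f"s{i}" for i in range(n)], ())
        sigma_g2, sigma_e2 = 0.8, 1.2
        pc = PhenoCov.from_grm(grm, sigma_g2, sigma_e2)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        res = mme_solve(x, y, scipy.linalg.inv(G), sigma_e2 / sigma_g2, sigma_e2=sigma_e2)
        beta_gls = float(x @ pc.solve(y)) / float(x @ pc.solve(x))
        assert res.beta[0] == pytest.approx(beta_gls, abs=1e-8)
        blup = blup_strongarm(grm, pc, y, x * beta_gls)
        np.testing.assert_allclose(res.blup.g_hat, blup.g_hat, atol=1e-8)
        # cββ σe² equals the GLS sampling variance (x'V⁻¹x)⁻¹
        assert res.c_beta_beta[0, 0] * sigma_e2 == pytest.approx(
            1.0 / float(x @ pc.solve(x)), rel=1e-8
        )

    def test_two_observation_ridge_closed_form(self):
        # G = I, one covariate, n = 2: MME reduce to a hand-solvable system
        x = np.array([1.0, -1.0])
        y = np.array([2.0, 0.0])
        lam = 3.0
        res = mme_solve(x, y, np.eye(2), lam)
        # solve [x'x x'; x I+λI][β;g]=[x'y;y] by hand: g = (y - xβ)/(1+λ)
        # then x'xβ + x'(y-xβ)/(1+λ) = x'y → β = x'y/x'x
        assert res.beta[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.blup.g_hat, (y - x) / (1 + lam), atol=1e-12)

    def test_infinite_ratio_limit_kills_blup(self):
        rng = np.random.default_rng(8)
        n = 10
        G = random_pd(rng, n)
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = mme_solve(x, y, scipy.linalg.inv(G), 1e10)
        beta_ols = float(x @ y) / float(x @ x)
        assert res.beta[0] == pytest.approx(beta_ols, abs=1e-6)
        assert np.abs(res.blup.g_hat).max() < 1e-6


class TestBlup:
    def test_zero_genomic_variance_zero_blup(self, small_dataset):
        _, g, grm, y, _ = small_dataset
        pc = PhenoCov.from_grm(grm, 0.0, 1.0)
        blup = blup_strongarm(grm, pc, y, np.zeros(g.n))
        np.testing.assert_allclose(blup.g_hat, 0.0, atol=1e-14)

    @pytest.mark.parametrize("seed", range(10))
    def test_invariant_to_removing_tested_marker(self, seed):
        g, grm, y, vc, pc = _sim_instance(700 + seed, n=40, p=120)
        j = seed % g.p
        xj = g.values[:, j]
        beta = float(xj @ pc.solve(y.values)) / float(xj @ pc.solve(xj))
        fitted = xj * beta
        blup_full = blup_strongarm(grm, pc, y, fitted)
        grm_mj = drop_markers_grm(grm, g, [j])
        pc_mj = rank1_downdate_inv(pc, xj, pc.marker_c)
        blup_out = blup_strongarm(grm_mj, pc_mj, y, fitted)
        np.testing.assert_allclose(blup_full.g_hat, blup_out.g_hat, atol=1e-8)


class TestPcAdjustedScan:
    def test_zero_pcs_equals_plain_gls(self, small_dataset):
        _, g, grm, y, vc = small_dataset
        pc = PhenoCov.from_grm(grm, vc.sigma_g2, vc.sigma_e2)
        e = eigen_grm(grm)
        adj = pc_adjusted_scan(g, y, e, 0, vc, mode="keep_G").table
        plain = gls_scan(g, y, pc).table
        np.testing.assert_allclose(adj["beta"], plain["beta"], atol=1e-8)

    def test_marker_estimate_invariant_when_components_frozen(self):
        # with variance components held fixed, stripping the fitted
        # eigenvectors from V only perturbs the PC-coefficient block of the
        # information matrix: the tested marker's estimate is unchanged
        # (the same cancellation as the marker-removal theorem)
        g, grm, y, vc, _ = _sim_instance(31, n=60, p=200)
        e = eigen_grm(grm)
        keep = pc_adjusted_scan(g, y, e, 2, vc, mode="keep_G").table
        remove = pc_adjusted_scan(g, y, e, 2, vc, mode="remove_from_G").table
        diff = np.abs(keep["beta"].to_numpy() - remove["beta"].to_numpy())
        assert np.nanmax(diff) < 1e-8

    def test_modes_differ_once_components_are_reestimated(self):
        # the workflow the removal mode implies: refit (sigma_g2, sigma_e2)
        # on the eigenvector-depleted G; estimates then genuinely move
        from grmscan import drop_eigvecs_grm, fit_ml

        g, grm, y, _, _ = _sim_instance(31, n=60, p=200)
        e = eigen_grm(grm)
        vc_full = fit_ml(e, y, se=False)
        keep = pc_adjusted_scan(g, y, e, 2, vc_full, mode="keep_G").table
        vc_dep = fit_ml(eigen_grm(drop_eigvecs_grm(e, [0, 1])), y, se=False)
        remove = pc_adjusted_scan(g, y, e, 2, vc_dep, mode="remove_from_G").table
        diff = np.abs(keep["beta"].to_numpy() - remove["beta"].to_numpy())
        assert np.nanmax(diff) > 1e-6

    def test_too_many_pcs_rejected(self, small_dataset):
        _, g, grm, y, vc = small_dataset
        e = eigen_grm(grm)
        with pytest.raises(ValueError):
            pc_adjusted_scan(g, y, e, g.n, vc)


class TestWhiten:
    def test_identity_covariance_is_identity_transform(self, small_dataset):
        _, g, _, y, _ = small_dataset
        pc = phenocov_from_matrix(np.eye(g.n))
        ystar, Xstar = whiten_gls(g, y, pc)
        np.testing.assert_allclose(ystar, y.values, atol=1e-10)
        np.testing.assert_allclose(Xstar, g.values, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_ols_on_whitened_data_reproduces_gls(self, seed):
        g, grm, y, vc, pc = _sim_instance(800 + seed, n=30, p=80)
        scan = gls_scan(g, y, pc).table
        ystar, Xstar = whiten_gls(g, y, pc)
        for j in [0, 10, 40]:
            xs = Xstar[:, j]
            beta_w = float(xs @ ystar) / float(xs @ xs)
            se_w = np.sqrt(1.0 / float(xs @ xs))  # unit residual variance by design
            assert beta_w == pytest.approx(scan["beta"].iloc[j], abs=1e-10)
            assert se_w == pytest.approx(scan["se"].iloc[j], abs=1e-10)


class TestSmv:
    @pytest.mark.parametrize(
        "q,beta,inbred,expected",
        [
            (0.0, 3.0, False, 0.0),
            (0.5, 1.0, False, 0.5),
            (0.5, 1.0, True, 0.25),
            (0.2, 2.0, False, 2 * 0.2 * 0.8 * 4.0),
        ],
    )
    def test_closed_form(self, q, beta, inbred, expected):
        assert smv(q, beta, inbred=inbred) == pytest.approx(expected)

    def test_scan_tables_carry_smv(self, small_dataset):
        _, g, _, y, _ = small_dataset
        t = ols_scan(g, y).table
        finite = t["smv"].dropna()
        assert (finite >= 0).all()
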