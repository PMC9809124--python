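"""Mixed-model equations, PQL links, AI-REML and the scale transform."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import norm

from pigsurv.mme_engine import (
    VarianceComponents,
    aireml,
    estimate_varcomps_aireml,
    fit_glmm,
    fit_linear,
    liability_to_observed_h2,
    make_model_data,
    observed_to_liability_h2,
)
from pigsurv.relmatrices import build_A, build_A_inverse

from conftest import pedigree_frame


def vc(vl=0.1, va=0.3, vm=0.2, cam=0.05, ve=1.0, scale="observed"):
    return VarianceComponents(vl, va, vm, cam, ve, scale)


def random_fixture(seed, n_founders=3, n_off=5, n_litters=2):
    """Small random pedigree + binary data for oracle comparisons."""
    rng = np.random.default_rng(seed)
    rows = [(i, 0, 0, "M" if i % 2 else "F", 0, 0, 1) for i in range(1, n_founders + 1)]
    next_id = n_founders + 1
    sires = [i for i in range(1, n_founders + 1) if i % 2 == 1]
    dams = [i for i in range(1, n_founders + 1) if i % 2 == 0]
    data_rows = []
    for k in range(n_off):
        s = int(rng.choice(sires))
        d = int(rng.choice(dams))
        lit = int(rng.integers(1, n_litters + 1))
        rows.append((next_id, s, d, "M", 1, lit, 1))
        data_rows.append((next_id, lit, int(rng.integers(0, 2))))
        next_id += 1
    ped = pedigree_frame(rows)
    data = pd.DataFrame(data_rows, columns=["id", "litter", "y"])
    return ped, data


def gls_oracle(ped, data, vcomp):
    """Dense BLUP/GLS from the full joint covariance (independent route).

    Treats mu as the GLS fixed effect and returns (mu, ebv_a, ebv_m) with
    EBVs as conditional means Cov(u, y) V^-1 (y - X mu).
    """
    A = build_A(ped).values
    n_p = len(ped)
    idx = pd.Index(ped["id"])
    ind = idx.get_indexer(data["id"])
    dam = idx.get_indexer(ped["dam"].to_numpy()[ind])
    labels, lit = np.unique(data["litter"], return_inverse=True)
    n = len(data)
    B = np.zeros((n, labels.size))
    B[np.arange(n), lit] = 1.0
    Za = np.zeros((n, n_p))
    Za[np.arange(n), ind] = 1.0
    Zm = np.zeros((n, n_p))
    Zm[np.arange(n), dam] = 1.0
    V = (
        vcomp.var_litter * B @ B.T
        + vcomp.var_direct * Za @ A @ Za.T
        + vcomp.var_maternal * Zm @ A @ Zm.T
        + vcomp.cov_am * (Za @ A @ Zm.T + Zm @ A @ Za.T)
        + vcomp.var_residual * np.eye(n)
    )
    y = data["y"].to_numpy(dtype=float)
    X = np.ones((n, 1))
    Vinv = np.linalg.inv(V)
    mu = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y).item()
    resid = y - mu
    cov_a_y = vcomp.var_direct * A @ Za.T + vcomp.cov_am * A @ Zm.T
    cov_m_y = vcomp.cov_am * A @ Za.T + vcomp.var_maternal * A @ Zm.T
    ebv_a = cov_a_y @ Vinv @ resid
    ebv_m = cov_m_y @ Vinv @ resid
    return mu, ebv_a, ebv_m


class TestMMEvsGLS:
    @pytest.mark.parametrize("seed", range(8))
    def test_solutions_equal_dense_gls_oracle(self, seed):
        ped, data = random_fixture(seed)
        v = vc()
        mmd = make_model_data(ped, data)
        fit = fit_linear(mmd, build_A_inverse(ped), v)
        mu, ebv_a, ebv_m = gls_oracle(ped, data, v)
        assert fit.mu == pytest.approx(mu, abs=1e-8)
        assert np.allclose(fit.ebv_a.to_numpy(), ebv_a, atol=1e-8)
        assert np.allclose(fit.ebv_m.to_numpy(), ebv_m, atol=1e-8)

    def test_doubling_all_components_leaves_ebvs_unchanged(self):
        ped, data = random_fixture(3)
        mmd = make_model_data(ped, data)
        Ainv = build_A_inverse(ped)
        f1 = fit_linear(mmd, Ainv, vc())
        f2 = fit_linear(
            mmd, Ainv, vc(0.2, 0.6, 0.4, 0.1, 2.0)
        )
        assert np.allclose(f1.ebv_a.to_numpy(), f2.ebv_a.to_numpy(), atol=1e-9)
        assert f1.mu == pytest.approx(f2.mu, abs=1e-9)

    def test_vanishing_genetic_variance_shrinks_to_zero_and_mean(self):
        ped, data = random_fixture(4, n_off=6)
        mmd = make_model_data(ped, data)
        f = fit_linear(
            mmd, build_A_inverse(ped), vc(1e-12, 1e-12, 1e-12, 0.0, 1.0)
        )
        assert np.allclose(f.ebv_a.to_numpy(), 0.0, atol=1e-6)
        assert np.allclose(f.ebv_m.to_numpy(), 0.0, atol=1e-6)
        assert f.mu == pytest.approx(data["y"].mean(), abs=1e-6)

    def test_maternal_variance_to_zero_decouples_maternal_solutions(self):
        ped, data = random_fixture(5)
        mmd = make_model_data(ped, data)
        f = fit_linear(mmd, build_A_inverse(ped), vc(0.1, 0.3, 1e-12, 0.0))
        assert np.allclose(f.ebv_m.to_numpy(), 0.0, atol=1e-6)
        assert np.abs(f.ebv_a.to_numpy()).max() > 1e-6

    def test_pedigree_reordering_invariance(self):
        ped, data = random_fixture(6)
        v = vc()
        f1 = fit_linear(make_model_data(ped, data), build_A_inverse(ped), v)
        perm = ped.iloc[[0, 2, 1] + list(range(3, len(ped)))].reset_index(drop=True)
        data2 = data.iloc[::-1].reset_index(drop=True)
        f2 = fit_linear(make_model_data(perm, data2), build_A_inverse(perm), v)
        for i in ped["id"]:
            assert f1.ebv_a.loc[i] == pytest.approx(f2.ebv_a.loc[i], abs=1e-9)


class TestGlmm:
    @pytest.mark.parametrize(
        "link,expected",
        [("logit", np.log(0.8 / 0.2)), ("probit", norm.ppf(0.8))],
    )
    def test_intercept_matches_closed_form_glm(self, link, expected):
        # random effects shrunk to ~0: PQL reduces to the intercept-only GLM
        ped, data = random_fixture(7, n_off=10)
        data["y"] = [1, 1, 1, 1, 0, 1, 1, 1, 1, 0]  # survival fraction 0.8
        mmd = make_model_data(ped, data)
        f = fit_glmm(
            mmd, build_A_inverse(ped), vc(1e-12, 1e-12, 1e-12, 0.0, 1.0, link),
            link,
        )
        assert f.mu == pytest.approx(expected, abs=1e-4)

    def test_identity_link_degenerates_to_fit_linear(self):
        ped, data = random_fixture(8)
        mmd = make_model_data(ped, data)
        Ainv = build_A_inverse(ped)
        v = vc()
        f_lin = fit_linear(mmd, Ainv, v)
        f_id = fit_glmm(mmd, Ainv, v, "identity")
        assert np.allclose(f_lin.ebv_a.to_numpy(), f_id.ebv_a.to_numpy())

    def test_separation_flagged(self):
        ped, data = random_fixture(9, n_off=6)
        data["y"] = 1
        mmd = make_model_data(ped, data)
        f = fit_glmm(mmd, build_A_inverse(ped), vc(scale="logit"), "logit")
        assert any("separation" in fl for fl in f.flags)
        assert np.isfinite(f.mu)


class TestAireml:
    def test_balanced_one_way_equals_anova(self):
        rng = np.random.default_rng(3)
        q, r = 40, 8
        g = rng.normal(0, np.sqrt(2.0), q)
        y = np.repeat(g, r) + rng.normal(0, np.sqrt(5.0), q * r)
        n = q * r
        B = np.zeros((n, q))
        B[np.arange(n), np.repeat(np.arange(q), r)] = 1
        res = aireml(y, np.ones((n, 1)), [B @ B.T, np.eye(n)], np.array([1.0, 1.0]))
        ym = y.reshape(q, r)
        msb = r * np.sum((ym.mean(1) - y.mean()) ** 2) / (q - 1)
        msw = np.sum((ym - ym.mean(1, keepdims=True)) ** 2) / (q * (r - 1))
        assert res["converged"]
        assert res["theta"][0] == pytest.approx((msb - msw) / r, rel=1e-8)
        assert res["theta"][1] == pytest.approx(msw, rel=1e-8)
        assert res["se"][0] > 0

    def test_loglik_trajectory_monotone(self):
        rng = np.random.default_rng(4)
        n = 80
        B = np.zeros((n, 10))
        B[np.arange(n), np.repeat(np.arange(10), 8)] = 1
        y = rng.normal(size=n)
        res = aireml(y, np.ones((n, 1)), [B @ B.T, np.eye(n)], np.array([0.5, 0.5]))
        assert np.all(np.diff(res["trajectory"]) >= -1e-8)

    def test_null_component_recovered_near_boundary(self):
        # data simulated WITHOUT a litter effect: its estimate ~ 0
        rng = np.random.default_rng(12)
        n, q = 240, 30
        B = np.zeros((n, q))
        B[np.arange(n), np.repeat(np.arange(q), n // q)] = 1
        y = rng.normal(0, 1.0, n)
        res = aireml(y, np.ones((n, 1)), [B @ B.T, np.eye(n)], np.array([0.3, 0.7]))
        assert res["theta"][0] < 0.05
        assert res["theta"][1] == pytest.approx(1.0, abs=0.15)


class TestVarcompsWrapper:
    def test_recovers_components_of_gaussian_animal_model(self):
        # Gaussian phenotype on a design where each dam raises two litters
        # by different sires (separating maternal from litter variance);
        # single-dataset REML spread is large, so estimates are averaged
        # over four independent datasets.
        ests = [self._one_dataset(seed) for seed in range(4)]
        mean = {k: np.mean([getattr(e, k) for e in ests]) for k in
                ("var_litter", "var_direct", "var_maternal", "var_residual")}
        assert all(e.converged for e in ests)
        assert mean["var_direct"] == pytest.approx(0.5, abs=0.25)
        assert mean["var_maternal"] == pytest.approx(0.4, abs=0.2)
        assert mean["var_litter"] == pytest.approx(0.3, abs=0.15)
        assert mean["var_residual"] == pytest.approx(1.0, abs=0.2)

    @staticmethod
    def _one_dataset(seed):
        rng = np.random.default_rng(seed)
        n_sires, n_dams = 10, 30
        rows = [
            (i, 0, 0, "M" if i <= n_sires else "F", 0, 0, 1)
            for i in range(1, n_sires + n_dams + 1)
        ]
        true = dict(vl=0.3, va=0.5, vm=0.4, cam=0.1, ve=1.0)
        Sig = np.array([[true["va"], true["cam"]], [true["cam"], true["vm"]]])
        u = rng.multivariate_normal([0, 0], Sig, n_sires + n_dams)
        a = {i: u[i - 1, 0] for i in range(1, n_sires + n_dams + 1)}
        m = {i: u[i - 1, 1] for i in range(1, n_sires + n_dams + 1)}
        next_id = n_sires + n_dams + 1
        data_rows = []
        lit_no = 0
        for rnd in range(2):  # two litters per dam, rotating sires
            for k in range(n_dams):
                d = n_sires + k + 1
                s = (k + rnd * 3) % n_sires + 1
                lit_no += 1
                l_eff = rng.normal(0, np.sqrt(true["vl"]))
                for _ in range(10):
                    ms = rng.multivariate_normal([0, 0], 0.5 * Sig)
                    a[next_id] = 0.5 * (a[s] + a[d]) + ms[0]
                    m[next_id] = 0.5 * (m[s] + m[d]) + ms[1]
                    yv = a[next_id] + m[d] + l_eff + rng.normal(0, np.sqrt(true["ve"]))
                    rows.append((next_id, s, d, "M", 1, lit_no, 1))
                    data_rows.append((next_id, lit_no, yv))
                    next_id += 1
        ped = pedigree_frame(rows)
        data = pd.DataFrame(data_rows, columns=["id", "litter", "y"])
        mmd = make_model_data(ped, data)
        return estimate_varcomps_aireml(mmd, build_A(ped).values)


class TestScaleTransform:
    def test_dempster_lerner_at_80_percent_survival(self):
        # z = phi(Phi^-1(0.8)) = 0.2800 -> factor 0.49: 0.04 -> 0.0196
        h2_obs = liability_to_observed_h2(0.04, 0.8)
        assert h2_obs == pytest.approx(0.0196, abs=2e-4)

    def test_factor_at_half_survival(self):
        assert liability_to_observed_h2(1.0, 0.5) == pytest.approx(0.6366, abs=1e-4)

    def test_round_trip_identity(self):
        for p in (0.2, 0.5, 0.8, 0.95):
            h = 0.37
            assert observed_to_liability_h2(
                liability_to_observed_h2(h, p), p
            ) == pytest.approx(h, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_fraction_rejected(self, p):
        with pytest.raises(ValueError):
            liability_to_observed_h2(0.1, p)
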