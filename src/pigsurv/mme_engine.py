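"""Mixed-model machinery for the maternal-effects animal model.

The model for survival (0/1) of piglet i is

    y = 1 mu + W_l l + Z_a a + Z_m m + e,

with litter effects l ~ N(0, I sigma_l^2), residuals e ~ N(0, I sigma_e^2)
and correlated direct and maternal breeding values

    [a; m] ~ N(0, [[sigma_a^2, sigma_am], [sigma_am, sigma_m^2]] (x) K),

where K is a pedigree (A), genomic (G_omega) or single-step (H)
relationship matrix.  Three links are supported: identity (LM), logit (LG)
and probit (PM); the binary links are fitted by penalised quasi-likelihood
(working-variate iteration).  Variance components are estimated by AI-REML
at observation level (dense phenotypic covariance), which is exact and
fast at the problem sizes this package runs at.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import cg
from scipy.stats import norm

__all__ = [
    "VarianceComponents",
    "MixedModelData",
    "ModelFit",
    "make_model_data",
    "assemble_mme",
    "solve_mme",
    "fit_linear",
    "fit_glmm",
    "aireml",
    "estimate_varcomps_aireml",
    "observed_to_liability_h2",
    "liability_to_observed_h2",
]

LINKS = ("identity", "logit", "probit")
#: fixed residual variance used when reporting link-scale proportions
LINK_RESIDUAL_VARIANCE = {"identity": None, "logit": math.pi**2 / 3.0, "probit": 1.0}


@dataclass
class VarianceComponents:
    """Variance components of the survival model on one scale."""

    var_litter: float
    var_direct: float
    var_maternal: float
    cov_am: float
    var_residual: float
    scale: str = "observed"
    se: dict | None = None
    loglik: float | None = None
    converged: bool | None = None
    n_iter: int | None = None

    def __post_init__(self) -> None:
        for name in ("var_litter", "var_direct", "var_maternal", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        bound = math.sqrt(self.var_direct * self.var_maternal)
        if abs(self.cov_am) > bound + 1e-12:
            raise ValueError("cov_am violates PSD of the genetic covariance")

    @property
    def genetic_covariance(self) -> np.ndarray:
        return np.array(
            [[self.var_direct, self.cov_am], [self.cov_am, self.var_maternal]]
        )

    @property
    def r_am(self) -> float:
        d = math.sqrt(self.var_direct * self.var_maternal)
        return self.cov_am / d if d > 0 else float("nan")

    def proportions(self) -> dict:
        """lit^2, direct and maternal h^2 and r_am, with the denominator
        sigma_l^2 + sigma_a^2 + sigma_m^2 + sigma_e^2 (no covariance)."""
        tot = (
            self.var_litter + self.var_direct + self.var_maternal + self.var_residual
        )
        return {
            "lit2": self.var_litter / tot,
            "h2_direct": self.var_direct / tot,
            "h2_maternal": self.var_maternal / tot,
            "r_am": self.r_am,
        }


@dataclass
class MixedModelData:
    """Phenotypes linked to a (pruned) pedigree, ready for the MME.

    ``obs_ind``/``obs_dam`` are row indices into the pedigree for each
    observation's own and dam's genetic effect; litters are coded densely.
    """

    ped: pd.DataFrame
    y: np.ndarray
    obs_ind: np.ndarray
    obs_dam: np.ndarray
    litter_codes: np.ndarray
    litter_labels: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_ped(self) -> int:
        return len(self.ped)

    @property
    def n_litter(self) -> int:
        return self.litter_labels.size

    def subset(self, mask: np.ndarray) -> "MixedModelData":
        """Restrict observations (litters are re-coded); pedigree unchanged."""
        labels, codes = np.unique(
            self.litter_labels[self.litter_codes[mask]], return_inverse=True
        )
        return MixedModelData(
            ped=self.ped,
            y=self.y[mask],
            obs_ind=self.obs_ind[mask],
            obs_dam=self.obs_dam[mask],
            litter_codes=codes,
            litter_labels=labels,
        )


def make_model_data(pedigree: pd.DataFrame, data: pd.DataFrame) -> MixedModelData:
    """Bundle a phenotype table (id, litter, y) with its pedigree."""
    idx = pd.Index(pedigree["id"].to_numpy())
    obs_ind = idx.get_indexer(data["id"].to_numpy())
    if (obs_ind < 0).any():
        raise ValueError("phenotyped individual missing from pedigree")
    dams = pedigree["dam"].to_numpy()[obs_ind]
    if (dams == 0).any():
        raise ValueError("phenotyped individual has unknown dam")
    obs_dam = idx.get_indexer(dams)
    labels, codes = np.unique(data["litter"].to_numpy(), return_inverse=True)
    return MixedModelData(
        ped=pedigree,
        y=data["y"].to_numpy(dtype=float),
        obs_ind=obs_ind,
        obs_dam=obs_dam,
        litter_codes=codes,
        litter_labels=labels,
    )


# ---------------------------------------------------------------------------
# MME assembly and solving
# ---------------------------------------------------------------------------


def _design(mmd: MixedModelData) -> sp.csr_matrix:
    """T = [1 | W_l | Z_a | Z_m], observations by effects."""
    n, q, p = mmd.n_obs, mmd.n_litter, mmd.n_ped
    rows = np.arange(n)
    ones = np.ones(n)
    blocks = [
        sp.coo_matrix((ones, (rows, np.zeros(n, int))), shape=(n, 1)),
        sp.coo_matrix((ones, (rows, mmd.litter_codes)), shape=(n, q)),
        sp.coo_matrix((ones, (rows, mmd.obs_ind)), shape=(n, p)),
        sp.coo_matrix((ones, (rows, mmd.obs_dam)), shape=(n, p)),
    ]
    return sp.hstack(blocks).tocsr()


def assemble_mme(
    y: np.ndarray,
    mmd: MixedModelData,
    K_inv: sp.spmatrix,
    vc: VarianceComponents,
    resid_inv_diag: np.ndarray,
) -> tuple[sp.csr_matrix, np.ndarray, dict]:
    """Henderson's mixed-model equations.

    ``resid_inv_diag`` is the diagonal of R^-1 (1/sigma_e^2 for the linear
    model, the PQL weights for binary links).  The genetic block carries the
    2x2 (co)variance structure expanded over K^-1 (Kronecker form), the
    litter block the ridge I/sigma_l^2.
    """
    Sigma = vc.genetic_covariance
    if np.linalg.eigvalsh(Sigma).min() <= 0:
        # guard against exactly-singular genetic priors (components may be
        # floored near zero, shrinking the corresponding solutions to 0)
        Sigma = Sigma + 1e-10 * np.eye(2)
    Sigma_inv = np.linalg.inv(Sigma)
    T = _design(mmd)
    Rinv = sp.diags(resid_inv_diag)
    C = (T.T @ Rinv @ T).tolil()
    q, p = mmd.n_litter, mmd.n_ped
    ridge = sp.block_diag(
        [
            sp.coo_matrix((1, 1)),
            sp.identity(q) / max(vc.var_litter, 1e-10),
            sp.kron(Sigma_inv, K_inv),
        ]
    )
    C = (C.tocsr() + ridge).tocsr()
    rhs = T.T @ (resid_inv_diag * y)
    layout = {"mu": 0, "litter": (1, 1 + q), "a": (1 + q, 1 + q + p),
              "m": (1 + q + p, 1 + q + 2 * p)}
    return C, rhs, layout


def solve_mme(
    C: sp.csr_matrix,
    rhs: np.ndarray,
    dense_cutoff: int = 6000,
    cg_tol: float = 1e-10,
) -> np.ndarray:
    """Direct (Cholesky) solve below ``dense_cutoff`` equations, otherwise
    Jacobi-preconditioned conjugate gradients on the sparse system."""
    n = C.shape[0]
    if n <= dense_cutoff:
        return cho_solve(cho_factor(C.toarray(), lower=True), rhs)
    M = sp.diags(1.0 / C.diagonal())
    sol, info = cg(C, rhs, rtol=cg_tol, maxiter=20 * n, M=M)
    if info != 0:
        raise RuntimeError(
            f"CG failed to converge (info={info}, residual="
            f"{np.linalg.norm(C @ sol - rhs):.3e})"
        )
    return sol


@dataclass
class ModelFit:
    """Solutions of one model fit: fixed mean, litter effects and EBVs."""

    mu: float
    litter_effects: pd.Series
    ebv_a: pd.Series
    ebv_m: pd.Series
    link: str
    vc: VarianceComponents
    n_iter: int = 1
    converged: bool = True
    flags: list = field(default_factory=list)

    @property
    def ebv_total(self) -> pd.Series:
        return self.ebv_a + self.ebv_m


def _fit_from_solution(
    sol: np.ndarray, layout: dict, mmd: MixedModelData, link: str,
    vc: VarianceComponents, n_iter: int, converged: bool, flags: list,
) -> ModelFit:
    a0, a1 = layout["a"]
    m0, m1 = layout["m"]
    l0, l1 = layout["litter"]
    ids = mmd.ped["id"].to_numpy()
    return ModelFit(
        mu=float(sol[layout["mu"]]),
        litter_effects=pd.Series(sol[l0:l1], index=mmd.litter_labels),
        ebv_a=pd.Series(sol[a0:a1], index=ids),
        ebv_m=pd.Series(sol[m0:m1], index=ids),
        link=link,
        vc=vc,
        n_iter=n_iter,
        converged=converged,
        flags=flags,
    )


def fit_linear(
    mmd: MixedModelData, K_inv: sp.spmatrix, vc: VarianceComponents,
    dense_cutoff: int = 6000,
) -> ModelFit:
    """BLUP on the observed 0/1 scale (identity link)."""
    resid_inv = np.full(mmd.n_obs, 1.0 / vc.var_residual)
    C, rhs, layout = assemble_mme(mmd.y, mmd, K_inv, vc, resid_inv)
    sol = solve_mme(C, rhs, dense_cutoff)
    return _fit_from_solution(sol, layout, mmd, "identity", vc, 1, True, [])


def _link_funcs(link: str):
    if link == "logit":
        inv = lambda eta: 1.0 / (1.0 + np.exp(-eta))
        # dmu/deta = mu(1-mu); canonical => weight w = mu(1-mu)
        dmu = lambda eta, mu: mu * (1.0 - mu)
        var = lambda mu: mu * (1.0 - mu)
        fwd = lambda p: np.log(p / (1.0 - p))
    elif link == "probit":
        inv = lambda eta: norm.cdf(eta)
        dmu = lambda eta, mu: norm.pdf(eta)
        var = lambda mu: mu * (1.0 - mu)
        fwd = lambda p: norm.ppf(p)
    else:
        raise ValueError(f"unknown binary link {link!r}")
    return inv, dmu, var, fwd


def fit_glmm(
    mmd: MixedModelData,
    K_inv: sp.spmatrix,
    vc: VarianceComponents,
    link: str,
    max_iter: int = 50,
    tol: float = 1e-8,
    dense_cutoff: int = 6000,
    return_working: bool = False,
):
    """Penalised quasi-likelihood fit for the logit/probit model.

    Iterates working response z = eta + (y - mu)/mu'(eta) and weights
    w = mu'(eta)^2 / var(mu) through the weighted MME until the relative
    change in the solution vector drops below ``tol``.  EBVs are on the
    link scale.  With ``return_working`` the converged working response
    and weights are returned as well (used for link-scale AI-REML).
    """
    if link == "identity":
        fit = fit_linear(mmd, K_inv, vc, dense_cutoff)
        return (fit, mmd.y.copy(), np.full(mmd.n_obs, 1.0)) if return_working else fit
    inv, dmu, var, fwd = _link_funcs(link)
    y = mmd.y
    flags = []
    pbar = float(np.clip(y.mean(), 1.0 / (y.size + 1), y.size / (y.size + 1.0)))
    if y.min() == y.max():
        flags.append("separation: all responses equal; mean capped")
    eta = np.full(mmd.n_obs, fwd(pbar))
    sol = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = np.clip(inv(eta), 1e-10, 1.0 - 1e-10)
        d = dmu(eta, mu)
        w = d * d / var(mu)
        z = eta + (y - mu) / d
        C, rhs, layout = assemble_mme(z, mmd, K_inv, vc, w)
        new_sol = solve_mme(C, rhs, dense_cutoff)
        T = _design(mmd)
        eta = T @ new_sol
        if sol is not None:
            denom = np.max(np.abs(new_sol)) + 1e-12
            if np.max(np.abs(new_sol - sol)) / denom < tol:
                sol = new_sol
                converged = True
                break
        sol = new_sol
    fit = _fit_from_solution(
        sol, layout, mmd, link, vc, it, converged, flags
    )
    if return_working:
        mu = np.clip(inv(eta), 1e-10, 1.0 - 1e-10)
        d = dmu(eta, mu)
        w = d * d / var(mu)
        z = eta + (y - mu) / d
        return fit, z, w
    return fit


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------


def _chol_loglik(y, X, V):
    """Cholesky factor of V and the restricted log-likelihood (no inverse)."""
    cho = cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Viy = cho_solve(cho, y)
    ViX = cho_solve(cho, X)
    XtVX = X.T @ ViX
    sign, logdet_X = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    XtViy = X.T @ Viy
    yPy = float(y @ Viy) - float(XtViy @ np.linalg.solve(XtVX, XtViy))
    ll = -0.5 * (logdet_V + logdet_X + yPy)
    return cho, ll


def _projection_pieces(y, X, cho):
    """Full P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1 and Py from a factor."""
    n = y.size
    Vinv = cho_solve(cho, np.eye(n))
    VX = Vinv @ X
    XtVX = X.T @ VX
    P = Vinv - VX @ np.linalg.solve(XtVX, VX.T)
    return P, P @ y


def _reml_pieces(y, X, V):
    cho, ll = _chol_loglik(y, X, V)
    P, Py = _projection_pieces(y, X, cho)
    return P, Py, ll


def aireml(
    y: np.ndarray,
    X: np.ndarray,
    Qs: list,
    init: np.ndarray,
    R_fixed: np.ndarray | None = None,
    cov_triples: list | None = None,
    max_iter: int = 50,
    tol_ll: float = 1e-6,
    tol_par: float = 1e-6,
    damping: float = 0.7,
    n_damped: int = 3,
) -> dict:
    """Average-information REML for V(theta) = sum_k theta_k Q_k + R_fixed.

    ``cov_triples`` lists (k_cov, k_var1, k_var2) constraints keeping
    |theta_cov| <= sqrt(theta_var1 * theta_var2); all other parameters are
    variances bounded below by a small floor.  Newton steps use the average
    information matrix, damped on the first ``n_damped`` iterations and
    halved when the restricted log-likelihood would decrease; if halving
    fails, a gradient-EM step is taken instead (parameter-space safe).
    Returns theta, AI-based standard errors, the log-likelihood trajectory
    and convergence status.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n = y.size
    K = len(Qs)
    cov_idx = {t[0] for t in (cov_triples or [])}
    floor = 1e-8 * max(float(np.var(y)), 1e-12)
    theta = np.asarray(init, dtype=float).copy()

    def project(th):
        th = th.copy()
        for k in range(K):
            if k not in cov_idx:
                th[k] = max(th[k], floor)
        for k_c, k_1, k_2 in cov_triples or []:
            bound = 0.99 * math.sqrt(th[k_1] * th[k_2])
            th[k_c] = float(np.clip(th[k_c], -bound, bound))
        return th

    def build_V(th):
        V = sum(th[k] * Qs[k] for k in range(K))
        if R_fixed is not None:
            V = V + R_fixed
        return V

    theta = project(theta)
    cho, ll = _chol_loglik(y, X, build_V(theta))
    trajectory = [ll]
    converged = False
    AI = np.eye(K)
    it = 0
    scale0 = max(float(np.var(y)), 1e-12)
    for it in range(1, max_iter + 1):
        P, Py = _projection_pieces(y, X, cho)
        QPy = np.column_stack([Q @ Py for Q in Qs])
        grad = np.array(
            [
                -0.5 * (float(np.sum(P * Qs[k])) - float(Py @ QPy[:, k]))
                for k in range(K)
            ]
        )
        PQPy = P @ QPy
        AI = 0.5 * (QPy.T @ PQPy)
        base_step = damping if it <= n_damped else 1.0
        # Newton (AI) step first; progressively Levenberg-Marquardt-damped
        # retries interpolate towards a (scaled) gradient step — the EM
        # flavour of fallback — whenever a step leaves the likelihood ridge
        # or the parameter space.
        accepted = False
        diag_ai = np.abs(np.diag(AI)) + 1e-12
        for lam in (0.0, 1.0, 10.0, 100.0, 1e4):
            try:
                delta = np.linalg.solve(AI + lam * np.diag(diag_ai), grad)
            except np.linalg.LinAlgError:
                delta = grad / diag_ai
            step = base_step
            for _ in range(6):
                cand = project(theta + step * delta)
                if np.max(np.abs(cand - theta)) <= 1e-14 * scale0:
                    break  # projection cancelled the step entirely
                try:
                    cho_new, ll_new = _chol_loglik(y, X, build_V(cand))
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if ll_new >= ll - 1e-10:
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                break
        if not accepted:
            # no uphill move in any damped direction: we are at a (possibly
            # boundary) maximum to numerical precision
            converged = True
            break
        d_par = np.max(np.abs(cand - theta) / (np.abs(theta) + 1e-6))
        d_ll = abs(ll_new - ll)
        theta, cho, ll = cand, cho_new, ll_new
        trajectory.append(ll)
        if d_ll < tol_ll and d_par < tol_par:
            converged = True
            break
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(K, np.nan)
    return {
        "theta": theta,
        "se": se,
        "loglik": ll,
        "trajectory": trajectory,
        "converged": converged,
        "n_iter": it,
    }


def _genetic_blocks(mmd: MixedModelData, K: np.ndarray):
    """K sub-blocks mapping observations to own/dam genetic effects."""
    Kaa = K[np.ix_(mmd.obs_ind, mmd.obs_ind)]
    Kdd = K[np.ix_(mmd.obs_dam, mmd.obs_dam)]
    Kad = K[np.ix_(mmd.obs_ind, mmd.obs_dam)]
    return Kaa, Kdd, Kad + Kad.T


def estimate_varcomps_aireml(
    mmd: MixedModelData,
    K: np.ndarray,
    link: str = "identity",
    K_inv: sp.spmatrix | None = None,
    include_maternal: bool = True,
    glmm_rounds: int = 2,
    init: VarianceComponents | None = None,
    max_iter: int = 50,
) -> VarianceComponents:
    """AI-REML variance components for the survival model.

    For the linear model all five components (litter, direct, maternal,
    their covariance, residual) are free.  For logit/probit the components
    are estimated on the link scale from the converged PQL working variates,
    with the residual structure diag(1/w_i) held fixed (canonical PQL);
    ``glmm_rounds`` alternates PQL fitting and REML updating.
    ``include_maternal=False`` drops the maternal effect and its covariance
    (a reduced direct-effects model).
    """
    n = mmd.n_obs
    X = np.ones((n, 1))
    B = sp.coo_matrix(
        (np.ones(n), (np.arange(n), mmd.litter_codes)),
        shape=(n, mmd.n_litter),
    ).tocsr()
    Q_litter = (B @ B.T).toarray()
    Kaa, Kdd, Kad_sym = _genetic_blocks(mmd, K)
    vy = float(np.var(mmd.y))

    if include_maternal:
        Qs = [Q_litter, Kaa, Kdd, Kad_sym]
        cov_triples = [(3, 1, 2)]
    else:
        Qs = [Q_litter, Kaa]
        cov_triples = []

    def run(y_work, w, vc_scale):
        R_fixed = None
        Q_list = list(Qs)
        if link == "identity":
            Q_list = Q_list + [np.eye(n)]
        else:
            R_fixed = np.diag(1.0 / w)
        vyw = float(np.var(y_work))
        if include_maternal:
            th0 = np.array([0.05, 0.05, 0.05, 0.05 * 0.3, 0.85]) * vyw
            if link != "identity":
                th0 = th0[:4]
        else:
            th0 = np.array([0.05, 0.05, 0.90]) * vyw
            if link != "identity":
                th0 = th0[:2]
        res = aireml(
            y_work, X, Q_list, th0, R_fixed=R_fixed,
            cov_triples=cov_triples, max_iter=max_iter,
        )
        th = res["theta"]
        se = res["se"]
        if include_maternal:
            vl, va, vm, cam = th[0], th[1], th[2], th[3]
            ve = th[4] if link == "identity" else LINK_RESIDUAL_VARIANCE[link]
            se_d = {
                "var_litter": se[0], "var_direct": se[1],
                "var_maternal": se[2], "cov_am": se[3],
            }
            if link == "identity":
                se_d["var_residual"] = se[4]
        else:
            vl, va, vm, cam = th[0], th[1], 0.0, 0.0
            ve = th[2] if link == "identity" else LINK_RESIDUAL_VARIANCE[link]
            se_d = {"var_litter": se[0], "var_direct": se[1]}
            if link == "identity":
                se_d["var_residual"] = se[2]
        cam = float(np.clip(cam, -0.999 * math.sqrt(va * vm), 0.999 * math.sqrt(va * vm))) if va * vm > 0 else 0.0
        return VarianceComponents(
            var_litter=float(vl), var_direct=float(va),
            var_maternal=float(vm), cov_am=cam, var_residual=float(ve),
            scale=vc_scale, se=se_d, loglik=res["loglik"],
            converged=res["converged"], n_iter=res["n_iter"],
        )

    if link == "identity":
        return run(mmd.y, None, "observed")

    if K_inv is None:
        raise ValueError("K_inv is required for binary-link REML (PQL fits)")
    # initial link-scale guess: modest proportions of the canonical total
    tot = LINK_RESIDUAL_VARIANCE[link] / 0.85
    vc = init or VarianceComponents(
        var_litter=0.05 * tot, var_direct=0.05 * tot,
        var_maternal=0.05 * tot,
        cov_am=0.3 * 0.05 * tot,
        var_residual=LINK_RESIDUAL_VARIANCE[link], scale=link,
    )
    for _ in range(max(1, glmm_rounds)):
        _, z, w = fit_glmm(mmd, K_inv, vc, link, return_working=True)
        vc = run(z, w, link)
    return vc


# ---------------------------------------------------------------------------
# observed <-> liability scale heritability
# ---------------------------------------------------------------------------


def liability_to_observed_h2(h2_liab: float, survival_fraction: float) -> float:
    """Dempster-Lerner transform: h2_obs = h2_liab * z^2 / (p (1-p)),
    with z the standard normal density at the threshold Phi^-1(p)."""
    p = survival_fraction
    if not 0.0 < p < 1.0:
        raise ValueError("survival fraction must be in (0,1)")
    z = norm.pdf(norm.ppf(p))
    return h2_liab * z * z / (p * (1.0 - p))


def observed_to_liability_h2(h2_obs: float, survival_fraction: float) -> float:
    """Exact inverse of `liability_to_observed_h2`."""
    p = survival_fraction
    if not 0.0 < p < 1.0:
        raise ValueError("survival fraction must be in (0,1)")
    z = norm.pdf(norm.ppf(p))
    return h2_obs * p * (1.0 - p) / (z * z)
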