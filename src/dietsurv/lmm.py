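"""Maximum-likelihood estimation of the spline linear mixed model.

The longitudinal submodel: for child i at age t,

    y_i(t) = (beta_0 + b_0i) + sum_k (beta_k + b_ki) B_k(t) + eps_i(t),

with independent N(0, sigma^2) errors and a *diagonal* covariance D for
the subject-level random effects (intercept + 5 spline coefficients).
Estimation is by maximum likelihood (not REML): the joint models built on
top require an ML likelihood, and BIC comparisons across fixed-effect
structures are only valid under ML.  The fixed effects are profiled out
(GLS at each variance-parameter value) and the variance parameters are
optimized on the log scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._num import fd_hessian, safe_cov_from_hessian
from .splines import SplineSpec, bspline_basis

LOG_VAR_FLOOR = -12.0  # log-variance lower bound; hitting it flags a zero


@dataclass
class LongData:
    """Per-subject longitudinal data in padded batched arrays.

    ``Z`` is (n_subjects, max_obs, n_coef) with zero rows past each
    subject's observation count; padded entries contribute exactly
    -0.5*log(2*pi*sigma^2) each to the batched likelihood, which is
    corrected analytically.
    """

    subjects: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    counts: np.ndarray
    spec: SplineSpec

    @classmethod
    def from_frame(
        cls,
        long_table: pd.DataFrame,
        spec: SplineSpec,
        value_col: str = "food_g_day",
        age_col: str = "age_years",
        subject_col: str = "subject",
        subjects: np.ndarray | None = None,
    ) -> "LongData":
        df = long_table.sort_values([subject_col, age_col])
        if subjects is None:
            subjects = df[subject_col].unique()
        idx = pd.Index(subjects)
        groups = {k: g for k, g in df.groupby(subject_col)}
        counts = np.array(
            [len(groups[s]) if s in groups else 0 for s in idx], dtype=int
        )
        jmax = max(int(counts.max()), 1)
        n = len(idx)
        p = spec.n_coef
        Z = np.zeros((n, jmax, p))
        y = np.zeros((n, jmax))
        mask = np.zeros((n, jmax), dtype=bool)
        for i, s in enumerate(idx):
            if s not in groups:
                continue
            g = groups[s]
            j = len(g)
            Z[i, :j] = bspline_basis(g[age_col].to_numpy(), spec)
            y[i, :j] = g[value_col].to_numpy()
            mask[i, :j] = True
        return cls(np.asarray(idx), Z, y, mask, counts, spec)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_pad(self) -> int:
        return self.mask.size - self.n_obs


@dataclass
class LmmParams:
    """Fixed effects, log random-effect variances (diagonal D) and log
    residual variance, all on the g/day scale of the response."""

    beta: np.ndarray
    log_d: np.ndarray
    log_sigma2: float

    @property
    def d(self) -> np.ndarray:
        return np.exp(self.log_d)

    @property
    def sigma2(self) -> float:
        return float(np.exp(self.log_sigma2))

    @property
    def n_free(self) -> int:
        return 2 * len(self.beta) + 1

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.log_d, [self.log_sigma2]])

    @classmethod
    def unpack(cls, x: np.ndarray, p: int) -> "LmmParams":
        return cls(x[:p].copy(), x[p:2 * p].copy(), float(x[2 * p]))

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "log_d": self.log_d.tolist(),
            "log_sigma2": self.log_sigma2,
        }


def _marginal_chol(data: LongData, d: np.ndarray, sigma2: float):
    """Cholesky of Sigma_i = Z_i D Z_i' + sigma^2 I for all subjects."""
    S = np.einsum("ijp,p,ikp->ijk", data.Z, d, data.Z)
    jmax = S.shape[1]
    S[:, np.arange(jmax), np.arange(jmax)] += sigma2
    return np.linalg.cholesky(S)


def lmm_loglik(
    params: LmmParams, data: LongData | pd.DataFrame,
    spec: SplineSpec | None = None, **from_frame_kwargs,
) -> float:
    """Exact marginal Gaussian log-likelihood
    sum_i log N(y_i; Z_i beta, Z_i D Z_i' + sigma^2 I)."""
    if isinstance(data, pd.DataFrame):
        if spec is None:
            raise ValueError("spec required when passing a DataFrame")
        data = LongData.from_frame(data, spec, **from_frame_kwargs)
    L = _marginal_chol(data, params.d, params.sigma2)
    r = np.where(data.mask, data.y - data.Z @ params.beta, 0.0)
    u = np.linalg.solve(L, r[..., None])[..., 0]
    jmax = L.shape[1]
    logdet = 2 * np.log(L[:, np.arange(jmax), np.arange(jmax)]).sum()
    quad = float((u * u).sum())
    ll = -0.5 * (data.mask.size * np.log(2 * np.pi) + logdet + quad)
    # remove the padded rows' contribution (-0.5*log(2*pi*sigma^2) each)
    ll += 0.5 * data.n_pad * (np.log(2 * np.pi) + np.log(params.sigma2))
    return float(ll)


def _profile_beta(data: LongData, d: np.ndarray, sigma2: float):
    """GLS fixed effects and the profile log-likelihood pieces."""
    L = _marginal_chol(data, d, sigma2)
    Zt = np.linalg.solve(L, data.Z)          # L^{-1} Z, batched
    yt = np.linalg.solve(L, np.where(data.mask, data.y, 0.0)[..., None])[..., 0]
    A = np.einsum("ijp,ijq->pq", Zt, Zt)
    b = np.einsum("ijp,ij->p", Zt, yt)
    beta = np.linalg.solve(A, b)
    resid = yt - Zt @ beta
    jmax = L.shape[1]
    logdet = 2 * np.log(L[:, np.arange(jmax), np.arange(jmax)]).sum()
    ll = -0.5 * (data.mask.size * np.log(2 * np.pi) + logdet
                 + float((resid * resid).sum()))
    ll += 0.5 * data.n_pad * (np.log(2 * np.pi) + np.log(sigma2))
    return beta, float(ll)


@dataclass
class LmmFit:
    params: LmmParams
    loglik: float
    bic: float
    converged: bool
    n_subjects: int
    spec: SplineSpec
    cov: np.ndarray | None = None
    param_names: list[str] = field(default_factory=list)
    boundary_variances: np.ndarray | None = None
    message: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "loglik": self.loglik,
                "bic": self.bic,
                "converged": self.converged,
                "n_subjects": self.n_subjects,
                "spline": json.loads(self.spec.to_json()),
                "cov": None if self.cov is None else self.cov.tolist(),
                "param_names": self.param_names,
            }
        )


def fit_lmm(
    long_table: pd.DataFrame | LongData,
    spec: SplineSpec | None = None,
    value_col: str = "food_g_day",
    start: LmmParams | None = None,
    compute_se: bool = False,
    max_iter: int = 400,
) -> LmmFit:
    """ML fit of the spline mixed model.

    Fixed effects are profiled; the 7 log-variance parameters are
    optimized by L-BFGS-B with a lower bound of -12 on each log variance
    (a bound hit is reported as a variance estimated at zero).
    """
    if isinstance(long_table, LongData):
        data = long_table
        spec = data.spec
    else:
        if spec is None:
            raise ValueError("spec required")
        data = LongData.from_frame(long_table, spec, value_col=value_col)
    p = spec.n_coef

    ybar = data.y[data.mask]
    v0 = max(float(np.var(ybar)), 1e-3) if ybar.size else 1.0
    if start is not None:
        th0 = np.concatenate([start.log_d, [start.log_sigma2]])
    else:
        th0 = np.full(p + 1, np.log(v0 / 2))

    def nll(th):
        d = np.exp(th[:p])
        s2 = float(np.exp(th[p]))
        _, ll = _profile_beta(data, d, s2)
        return -ll

    res = minimize(
        nll, th0, method="L-BFGS-B",
        bounds=[(LOG_VAR_FLOOR, 25.0)] * (p + 1),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
    )
    th = res.x
    d = np.exp(th[:p])
    s2 = float(np.exp(th[p]))
    beta, ll = _profile_beta(data, d, s2)
    params = LmmParams(beta, th[:p].copy(), float(th[p]))
    bic = -2 * ll + params.n_free * np.log(data.n_subjects)
    names = ([f"beta{k}" for k in range(p)]
             + [f"log_d{k}" for k in range(p)] + ["log_sigma2"])
    fit = LmmFit(
        params=params, loglik=ll, bic=float(bic),
        converged=bool(res.success), n_subjects=data.n_subjects,
        spec=spec, param_names=names,
        boundary_variances=th[:p] <= LOG_VAR_FLOOR + 1e-6,
        message=str(res.message),
    )
    if compute_se:
        def full_nll(x):
            return -lmm_loglik(LmmParams.unpack(x, p), data)

        H = fd_hessian(full_nll, params.pack())
        fit.cov, _ = safe_cov_from_hessian(H)
    return fit


def empirical_bayes_modes(
    params: LmmParams, data: LongData
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior modes b_hat_i and posterior precisions of the random
    effects given the data — closed form in the linear Gaussian model:

        P_i = Z_i'Z_i / sigma^2 + D^{-1},   b_hat_i = P_i^{-1} Z_i'r_i / sigma^2.

    A subject with no observations gets mode 0 and precision D^{-1}.
    Returns (modes (n,p), precisions (n,p,p)).
    """
    d = params.d
    s2 = params.sigma2
    ZtZ = np.einsum("ijp,ijq->ipq", data.Z, data.Z)
    P = ZtZ / s2
    pdim = d.size
    P[:, np.arange(pdim), np.arange(pdim)] += 1.0 / d
    r = np.where(data.mask, data.y - data.Z @ params.beta, 0.0)
    rhs = np.einsum("ijp,ij->ip", data.Z, r) / s2
    modes = np.linalg.solve(P, rhs[..., None])[..., 0]
    return modes, P
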