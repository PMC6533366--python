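"""The comparison analysis: Cox regression with the longitudinal exposure
as a piecewise-constant step function (last value carried forward).

The counting-process table carries one row per (subject, exposure
interval]; the partial likelihood is the standard time-dependent-covariate
one, with Breslow (default) or Efron handling of tied event times.  The
hazard ratio for food consumption is reported per 10 g/day increment, or
per 1 g/MJ after energy adjustment.

``impute_3day_mean`` is a simplified stand-in for multiple imputation of
incomplete 3-day food records; it is not the original registry procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from ._num import fd_hessian_from_grad, safe_cov_from_hessian
from .dataprep import endpoint_times

CP_COLUMNS = ["subject", "start", "stop", "event", "exposure"]


def build_counting_process(
    long_table: pd.DataFrame,
    endpoints: pd.DataFrame,
    baseline: pd.DataFrame | None = None,
    followup_max: float = 6.0,
    exposure_col: str = "food_g_day",
) -> pd.DataFrame:
    """Counting-process rows with the exposure carried forward from each
    food record to the next (last value carried to the event/censoring
    time), events at interval midpoints, administrative censoring at
    ``followup_max``.

    Children whose endpoint precedes their first food record are excluded;
    exclusions are listed in the frame's ``attrs['excluded']``.
    """
    t_end, ev = endpoint_times(endpoints, followup_max)
    end_map = dict(zip(endpoints["subject"], zip(t_end, ev)))
    rows = []
    excluded = []
    for subj, g in long_table.groupby("subject"):
        if subj not in end_map:
            excluded.append((subj, "no endpoint record"))
            continue
        t_i, ev_i = end_map[subj]
        g = g.sort_values("age_years")
        ages = g["age_years"].to_numpy(float)
        vals = g[exposure_col].to_numpy(float)
        keep = ages < t_i
        if not keep.any():
            excluded.append((subj, "no food record before endpoint"))
            continue
        ages, vals = ages[keep], vals[keep]
        stops = np.append(ages[1:], t_i)
        for a, s, v in zip(ages, stops, vals):
            if s <= a:  # zero-length final row when censored at a record age
                continue
            rows.append((subj, a, s, False, v))
        if rows and rows[-1][0] == subj:
            last = rows[-1]
            rows[-1] = (subj, last[1], last[2], bool(ev_i), last[4])
    cp = pd.DataFrame(rows, columns=CP_COLUMNS)
    if baseline is not None:
        cp = cp.merge(
            baseline[["subject", "sex", "genetic_risk", "familial_diabetes"]],
            on="subject", how="left",
        )
    cp.attrs["excluded"] = excluded
    return cp


def energy_adjust(long_table: pd.DataFrame,
                  exposure_col: str = "food_g_day") -> pd.DataFrame:
    """Replace the exposure by food/energy (g/MJ); the reporting increment
    then switches from 10 g/day to 1 g/MJ."""
    energy = long_table["energy_mj_day"].to_numpy(float)
    bad = energy <= 0
    if bad.any():
        subjects = sorted(long_table.loc[bad, "subject"].unique().tolist())
        raise ValueError(f"non-positive energy intake for subjects {subjects}")
    out = long_table.copy()
    out["food_g_mj"] = out[exposure_col] / energy
    out = out.drop(columns=[exposure_col])
    return out


# ---------------------------------------------------------------------------
# partial likelihood


def _risk_structure(cp: pd.DataFrame):
    start = cp["start"].to_numpy(float)
    stop = cp["stop"].to_numpy(float)
    event = cp["event"].to_numpy(bool)
    etimes = np.unique(stop[event])
    deaths = [np.flatnonzero(event & (stop == t)) for t in etimes]
    risks = [np.flatnonzero((start < t) & (stop >= t)) for t in etimes]
    return etimes, deaths, risks


def cox_partial_loglik(
    beta: np.ndarray, X: np.ndarray, structure, ties: str = "breslow"
) -> tuple[float, np.ndarray]:
    """Log partial likelihood and its gradient over counting-process rows."""
    _, deaths, risks = structure
    eta = X @ beta
    ll = 0.0
    grad = np.zeros_like(beta)
    for D, R in zip(deaths, risks):
        xd = X[D]
        ll += eta[D].sum()
        grad += xd.sum(axis=0)
        eR = np.exp(eta[R])
        sR = eR.sum()
        mR = eR @ X[R]
        if ties == "breslow" or len(D) == 1:
            d = len(D)
            ll -= d * np.log(sR)
            grad -= d * mR / sR
        elif ties == "efron":
            eD = np.exp(eta[D])
            sD = eD.sum()
            mD = eD @ xd
            d = len(D)
            for l in range(d):
                f = l / d
                denom = sR - f * sD
                ll -= np.log(denom)
                grad -= (mR - f * mD) / denom
        else:
            raise ValueError(f"unknown ties method {ties!r}")
    return float(ll), grad


@dataclass
class CoxFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    names: list[str]
    ties: str
    n_events: int
    converged: bool
    diverged: bool = False
    unidentifiable: np.ndarray | None = None
    increment: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0, None))

    def hr_table(self, increments: dict | None = None) -> pd.DataFrame:
        """Hazard ratios with 95% Wald CIs on each covariate's reporting
        increment (default 1)."""
        inc = {**{n: 1.0 for n in self.names}, **self.increment,
               **(increments or {})}
        rows = []
        for j, n in enumerate(self.names):
            c = inc[n]
            est, s = c * self.coef[j], c * self.se[j]
            def _safe_exp(v):
                if v > 700:
                    return np.inf
                return float(np.exp(max(v, -700.0)))

            if np.isfinite(s) and s > 0:
                lo, hi = _safe_exp(est - 1.96 * s), _safe_exp(est + 1.96 * s)
                p = 2 * norm.sf(abs(est / s))
            else:  # unidentified term: no finite Wald interval
                lo, hi, p = 0.0, np.inf, np.nan
            rows.append({"term": n, "hr": np.exp(est), "lo": lo,
                         "hi": hi, "p": p})
        return pd.DataFrame(rows)


def fit_cox_td(
    cp_table: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    ties: str = "breslow",
    exposure_increment: float = 10.0,
) -> CoxFit:
    """Maximize the time-dependent-covariate partial likelihood.

    ``covariate_cols`` defaults to the exposure only; pass e.g.
    ``["exposure", "sex_girl", ...]`` after dummy-coding confounders with
    :func:`add_baseline_dummies`.
    """
    covariate_cols = covariate_cols or ["exposure"]
    X = cp_table[covariate_cols].to_numpy(float)
    structure = _risk_structure(cp_table)
    n_events = int(cp_table["event"].sum())
    if n_events == 0:
        raise ValueError("no events in the counting-process table")

    # covariates with no variation anywhere carry no information
    flat = np.array([np.ptp(X[:, j]) == 0 for j in range(X.shape[1])])

    def nll(b):
        ll, g = cox_partial_loglik(b, X, structure, ties)
        return -ll, -g

    res = minimize(nll, np.zeros(X.shape[1]), jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 200})
    coef = res.x
    # a monotone partial likelihood (perfect separation) walks the
    # coefficient out indefinitely; no realistic log-HR approaches 10
    diverged = bool(np.abs(coef[~flat]).max(initial=0) > 10)
    H = fd_hessian_from_grad(lambda b: nll(b)[1], coef)
    if flat.any():
        cov = np.full((X.shape[1], X.shape[1]), np.nan)
        live = ~flat
        if live.any():
            sub, _ = safe_cov_from_hessian(H[np.ix_(live, live)])
            cov[np.ix_(live, live)] = sub
        cov[flat, flat] = np.inf
        coef = np.where(flat, 0.0, coef)
    else:
        cov, _ = safe_cov_from_hessian(H)
    ll, _ = cox_partial_loglik(coef, X, structure, ties)
    inc = {covariate_cols[0]: exposure_increment}
    return CoxFit(
        coef=coef, cov=cov, loglik=ll, names=list(covariate_cols),
        ties=ties, n_events=n_events,
        converged=bool(res.success) and not diverged, diverged=diverged,
        unidentifiable=flat if flat.any() else None, increment=inc,
    )


def add_baseline_dummies(cp: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code the merged baseline columns of a counting-process table."""
    out = cp.copy()
    out["sex_girl"] = (out["sex"] == "girl").astype(float)
    out["risk_high"] = (out["genetic_risk"] == "high").astype(float)
    out["familial_yes"] = (out["familial_diabetes"] == "yes").astype(float)
    out["familial_missing"] = (
        out["familial_diabetes"] == "missing"
    ).astype(float)
    return out, ["sex_girl", "risk_high", "familial_yes", "familial_missing"]


# ---------------------------------------------------------------------------
# multiple imputation


def rubin_pool(
    estimates: np.ndarray, variances: np.ndarray
) -> dict:
    """Rubin's rules: pooled point estimate, total variance
    (within + (1 + 1/m) between) and a normal-reference 95% CI."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = est.size
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    qbar = est.mean()
    within = var.mean()
    between = est.var(ddof=1)
    total = within + (1 + 1 / m) * between
    se = np.sqrt(total)
    return {
        "estimate": float(qbar), "se": float(se),
        "lo": float(qbar - 1.96 * se), "hi": float(qbar + 1.96 * se),
        "within": float(within), "between": float(between), "m": m,
    }


def impute_3day_mean(
    daily_records: pd.DataFrame, m: int, seed: int
) -> list[pd.DataFrame]:
    """Complete incomplete 3-day recording occasions by multiple imputation.

    Simplified stand-in for the registry imputation procedure: missing
    daily values at an occasion are drawn from a normal centred on the
    occasion's observed-day mean, with the day-to-day SD estimated at the
    same nominal age across children.  Input columns: subject, age_years,
    day (1..3), food_g_day [, energy_mj_day]; returns ``m`` long tables
    whose ``food_g_day`` is the completed 3-day mean.
    """
    df = daily_records.copy()
    counts = df.groupby(["subject", "age_years"])["food_g_day"].count()
    if (counts == 0).any():
        raise ValueError("recording occasion with zero observed days")
    # day-to-day residual SD around occasion means, pooled within age
    occ_mean = df.groupby(["subject", "age_years"])["food_g_day"].transform(
        "mean"
    )
    df["_resid"] = df["food_g_day"] - occ_mean
    sd_by_age = df.groupby("age_years")["_resid"].std().fillna(0.0)
    rng = np.random.default_rng(seed)
    extra = [c for c in df.columns
             if c not in ("subject", "age_years", "day", "food_g_day",
                          "_resid")]
    base = (
        df.groupby(["subject", "age_years"])
        .agg(obs_mean=("food_g_day", "mean"), n_days=("food_g_day", "count"),
             **{c: (c, "mean") for c in extra})
        .reset_index()
    )
    out = []
    for _ in range(m):
        comp = base.copy()
        n_miss = 3 - comp["n_days"].to_numpy()
        sd = comp["age_years"].map(sd_by_age).to_numpy()
        draws_sum = np.zeros(len(comp))
        for k in range(3):
            need = n_miss > k
            draws_sum[need] += rng.normal(
                comp.loc[need, "obs_mean"], sd[need]
            )
        comp["food_g_day"] = (
            comp["obs_mean"] * comp["n_days"] + draws_sum
        ) / 3.0
        out.append(
            comp[["subject", "age_years", "food_g_day"] + extra]
        )
    return out
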