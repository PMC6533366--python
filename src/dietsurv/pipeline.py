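"""Analysis orchestration: run the three models over foods and adjustment
variants, produce report tables, and run the sensitivity analyses
(multiple imputation for interval censoring, baseline-hazard knot
perturbation, delete-5 jackknife lives in :mod:`dietsurv.jlcmm`).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import fisher_exact as _scipy_fisher

from .cox import (add_baseline_dummies, build_counting_process, fit_cox_td,
                  energy_adjust, rubin_pool)
from .dataprep import endpoint_times
from .hazard import HazardSpec, equal_event_knots
from .jlcmm import JLCMM_HAZARD, JlcmmConfig, fit_jlcmm, overall_hr_proportional, piecewise_hr
from .jm import JmFit, QuadConfig, fit_jm
from .splines import SplineSpec


# ---------------------------------------------------------------------------
# small exact/nonparametric pieces


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for the 2x2 table [[a, b], [c, d]]
    (sum of hypergeometric probabilities no larger than the observed
    table's)."""
    vals = [a, b, c, d]
    if any(v < 0 or int(v) != v for v in vals):
        raise ValueError("cell counts must be nonnegative integers")
    tab = np.array([[a, b], [c, d]])
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a margin is zero")
    return float(_scipy_fisher(tab, alternative="two-sided")[1])


def km_estimate(
    endpoints: pd.DataFrame,
    groups: pd.Series | None = None,
    followup_max: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves (midpoint event times) with Greenwood
    standard errors, one per group level."""
    t, ev = endpoint_times(endpoints, followup_max)
    if groups is None:
        groups = pd.Series("all", index=range(len(t)))
    out = {}
    garr = np.asarray(groups)
    for lev in pd.unique(garr):
        sel = garr == lev
        if not sel.any():
            raise ValueError(f"empty group {lev!r}")
        tt, dd = t[sel], ev[sel]
        order = np.argsort(tt)
        tt, dd = tt[order], dd[order]
        utimes = np.unique(tt[dd])
        n = len(tt)
        surv, var_sum = 1.0, 0.0
        rows = [(0.0, 1.0, 0.0, n)]
        for u in utimes:
            at_risk = int((tt >= u).sum())
            d_u = int(((tt == u) & dd).sum())
            surv *= 1 - d_u / at_risk
            if at_risk > d_u:
                var_sum += d_u / (at_risk * (at_risk - d_u))
            rows.append((u, surv, surv * np.sqrt(var_sum), at_risk))
        out[str(lev)] = pd.DataFrame(
            rows, columns=["time", "survival", "se", "at_risk"]
        )
    return out


def plot_km(curves: dict[str, pd.DataFrame], path,
            title: str = "Kaplan-Meier survival") -> None:
    """Write the product-limit curves from :func:`km_estimate` as an SVG
    step plot, one line per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        ax.step(curve["time"], curve["survival"], where="post",
                label=label)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("event-free probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    if len(curves) > 1:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def baseline_cox_table(
    baseline: pd.DataFrame,
    endpoints: pd.DataFrame,
    followup_max: float | None = None,
) -> pd.DataFrame:
    """Single Cox fit on all baseline factors jointly; one row per factor
    level with HR (reference level displayed as 1), 95% CI and Wald P."""
    t, ev = endpoint_times(endpoints, followup_max)
    cp = pd.DataFrame({
        "subject": endpoints["subject"], "start": 0.0, "stop": t,
        "event": ev,
    }).merge(baseline, on="subject")
    if (cp["stop"] <= 0).any():
        raise ValueError("nonpositive follow-up time")
    cp, dummies = add_baseline_dummies(cp)
    for col in dummies:
        if cp[col].sum() == 0:
            raise ValueError(f"empty level for {col}")
    fit = fit_cox_td(cp, dummies, exposure_increment=1.0)
    hrs = fit.hr_table().set_index("term")
    rows = []
    layout = [
        ("sex", "boy", None), ("sex", "girl", "sex_girl"),
        ("genetic_risk", "moderate", None),
        ("genetic_risk", "high", "risk_high"),
        ("familial_diabetes", "no", None),
        ("familial_diabetes", "yes", "familial_yes"),
        ("familial_diabetes", "missing", "familial_missing"),
    ]
    for factor, level, term in layout:
        n_level = int((baseline[factor] == level).sum())
        if term is None:
            rows.append({"factor": factor, "level": level, "n": n_level,
                         "hr": 1.0, "lo": np.nan, "hi": np.nan,
                         "p": np.nan})
        else:
            r = hrs.loc[term]
            rows.append({"factor": factor, "level": level, "n": n_level,
                         "hr": r["hr"], "lo": r["lo"], "hi": r["hi"],
                         "p": r["p"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity machinery


def mi_interval_censored(
    endpoints: pd.DataFrame,
    model_fitter,
    m: int = 5,
    seed: int = 0,
    hazard: HazardSpec = HazardSpec(),
) -> dict:
    """Multiple imputation for the interval-censored event times.

    Event times are drawn from a marginal piecewise-exponential survival
    model conditioned to each (L, R] interval; the hazard is first
    estimated from the midpoint data, then refined once from the first
    round of draws.  ``model_fitter(endpoints) -> (estimate, variance)``
    is applied to each completed table and results pooled by Rubin's
    rules; the midpoint analysis is reported alongside.
    """
    from .hazard import occurrence_exposure_heights

    rng = np.random.default_rng(seed)
    mid_est, mid_var = model_fitter(endpoints)
    ev = endpoints["event"].to_numpy().astype(bool)
    L = endpoints["last_negative_age"].to_numpy(float)
    R = endpoints["first_positive_age"].to_numpy(float)

    def draw(log_h):
        edges = hazard.edges
        H_edges = np.concatenate(
            [[0.0], np.cumsum(np.diff(edges) * np.exp(log_h))]
        )

        def Hfun(x):
            return np.interp(x, edges, H_edges)

        def Hinv(hval):
            return np.interp(hval, H_edges, edges)

        out = endpoints.copy()
        T = np.where(ev, 0.5 * (L + R), np.nan)
        for i in np.flatnonzero(ev):
            lo, hi = L[i], min(R[i], hazard.followup_max)
            if hi <= lo:
                T[i] = lo
                continue
            Flo = 1 - np.exp(-Hfun(lo))
            Fhi = 1 - np.exp(-Hfun(hi))
            u = rng.uniform(Flo, Fhi)
            T[i] = np.clip(Hinv(-np.log1p(-u)), lo, hi)
        out.loc[ev, "last_negative_age"] = T[ev]
        out.loc[ev, "first_positive_age"] = T[ev]
        return out

    t_mid, ev_mid = endpoint_times(endpoints, hazard.followup_max)
    log_h = occurrence_exposure_heights(hazard, t_mid, ev_mid)
    # one refinement round: re-estimate the hazard from a first draw
    first = draw(log_h)
    t1, ev1 = endpoint_times(first, hazard.followup_max)
    log_h = occurrence_exposure_heights(hazard, t1, ev1)

    ests, vars_ = [], []
    for _ in range(m):
        est, var = model_fitter(draw(log_h))
        ests.append(est)
        vars_.append(var)
    pooled = rubin_pool(np.array(ests), np.array(vars_))
    return {"pooled": pooled,
            "midpoint": {"estimate": float(mid_est),
                         "se": float(np.sqrt(mid_var))}}


def knot_sensitivity(
    long_table: pd.DataFrame,
    endpoints: pd.DataFrame,
    baseline: pd.DataFrame | None,
    spec: SplineSpec,
    base_fit: JmFit,
    mode: str = "remove_one",
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit the joint model with one baseline-hazard knot removed or
    added, new knots placed at event-time quantiles so every interval
    holds the same number of events; tabulates the food HR against the
    base fit."""
    if mode not in ("remove_one", "add_one"):
        raise ValueError("mode must be 'remove_one' or 'add_one'")
    n_int = base_fit.hazard.n_intervals + (1 if mode == "add_one" else -1)
    if n_int < 1:
        raise ValueError("cannot remove a knot from a 1-interval hazard")
    t, ev = endpoint_times(endpoints, base_fit.hazard.followup_max)
    if n_int == 1:
        new_hazard = HazardSpec(knots=(),
                                followup_max=base_fit.hazard.followup_max)
    else:
        new_hazard = equal_event_knots(
            t[ev], n_int, base_fit.hazard.followup_max
        )
    refit = fit_jm(long_table, endpoints, baseline, spec,
                   hazard=new_hazard, config=base_fit.config,
                   lmm_fit=base_fit.lmm_fit, **fit_kwargs)
    rows = []
    for label, f in (("base", base_fit), (mode, refit)):
        hr = f.hr_table().iloc[0]
        rows.append({"variant": label,
                     "knots": tuple(np.round(f.hazard.knots, 3)),
                     "hr": hr["hr"], "lo": hr["lo"], "hi": hr["hi"],
                     "p": hr["p"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full-run orchestration


@dataclass
class AnalysisConfig:
    """Which foods, models and adjustment variants to run."""

    foods: dict = dc_field(default_factory=lambda: {"food": "long.csv"})
    models: tuple = ("CRM", "JM")
    adjustments: tuple = ("unadjusted", "adjusted", "energy")
    jlcmm_foods: tuple = ()
    crm_followup: float = 6.0
    jm_hazard: HazardSpec = dc_field(default_factory=HazardSpec)
    jlcmm_hazard: HazardSpec = dc_field(default_factory=lambda: JLCMM_HAZARD)
    quad: QuadConfig = dc_field(default_factory=QuadConfig)
    jlcmm_config: JlcmmConfig = dc_field(default_factory=JlcmmConfig)
    spline: SplineSpec = dc_field(default_factory=SplineSpec)
    endpoints_files: dict = dc_field(
        default_factory=lambda: {"primary": "endpoints.csv"}
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("foods", "endpoints_files"):
            if key in raw:
                kwargs[key] = dict(raw[key])
        for key in ("models", "adjustments", "jlcmm_foods"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("crm_followup", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "spline_knots" in raw:
            kwargs["spline"] = SplineSpec(
                interior_knots=tuple(raw["spline_knots"])
            )
        if "quad_nodes" in raw:
            kwargs["quad"] = QuadConfig(nodes=int(raw["quad_nodes"]))
        if "jlcmm_starts" in raw or "jlcmm_seed" in raw:
            kwargs["jlcmm_config"] = JlcmmConfig(
                starts=int(raw.get("jlcmm_starts", 10)),
                seed=int(raw.get("jlcmm_seed", raw.get("seed", 0))),
            )
        return cls(**kwargs)


class _StageLog:
    def __init__(self):
        self.records: list[dict] = []

    def add(self, **kw):
        kw.setdefault("wall_s", None)
        self.records.append(kw)

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r) for r in self.records)


def _crm_cell(long, endpoints, baseline, adjustment, followup):
    if adjustment == "energy":
        long = energy_adjust(long)
        exposure_col, inc = "food_g_mj", 1.0
    else:
        exposure_col, inc = "food_g_day", 10.0
    cp = build_counting_process(
        long, endpoints,
        baseline if adjustment in ("adjusted", "energy") else None,
        followup_max=followup, exposure_col=exposure_col,
    )
    cols = ["exposure"]
    if adjustment == "adjusted":
        cp, dummies = add_baseline_dummies(cp)
        cols += dummies
    fit = fit_cox_td(cp, cols, exposure_increment=inc)
    row = fit.hr_table().iloc[0]
    return {"hr": row["hr"], "lo": row["lo"], "hi": row["hi"],
            "p": row["p"], "n_events": fit.n_events,
            "excluded": len(cp.attrs.get("excluded", []))}


def _jm_cell(long, endpoints, baseline, adjustment, cfg: AnalysisConfig):
    if adjustment == "energy":
        long = energy_adjust(long)
        value_col, inc = "food_g_mj", 1.0
    else:
        value_col, inc = "food_g_day", 10.0
    fit = fit_jm(
        long, endpoints,
        baseline if adjustment in ("adjusted", "energy") else None,
        cfg.spline, hazard=cfg.jm_hazard, config=cfg.quad,
        value_col=value_col,
    )
    row = fit.hr_table(food_increment=inc).iloc[0]
    return {"hr": row["hr"], "lo": row["lo"], "hi": row["hi"],
            "p": row["p"], "n_events": fit.n_events,
            "converged": fit.converged}


def run_full_analysis(config: AnalysisConfig, data_dir,
                      out_dir=None) -> dict:
    """Execute every requested (food, model, adjustment) fit plus the
    latent-class analyses and the baseline-covariate Cox table.

    Returns a bundle of report tables; failures are recorded per cell and
    the run continues.  With ``out_dir`` the reports are also written as
    CSV and Markdown, plus a JSON-lines stage log.
    """
    data_dir = Path(data_dir)
    log = _StageLog()
    baseline = pd.read_csv(data_dir / "baseline.csv")
    endpoints_sets = {
        name: pd.read_csv(data_dir / fname)
        for name, fname in config.endpoints_files.items()
    }
    bundle: dict = {"main": {}, "jlcmm": {}, "accounting": {}}

    primary = endpoints_sets["primary"]
    for ep_name, endpoints in endpoints_sets.items():
        rows = []
        for food, fname in config.foods.items():
            long = pd.read_csv(data_dir / fname)
            total = long["subject"].nunique()
            for model in config.models:
                for adj in config.adjustments:
                    t0 = time.perf_counter()
                    cell = {"food": food, "model": model,
                            "adjustment": adj, "endpoint": ep_name}
                    try:
                        if model == "CRM":
                            cell.update(_crm_cell(
                                long, endpoints, baseline, adj,
                                config.crm_followup,
                            ))
                        elif model == "JM":
                            cell.update(_jm_cell(
                                long, endpoints, baseline, adj, config,
                            ))
                        else:
                            raise ValueError(f"unknown model {model}")
                        status = "ok"
                    except Exception as exc:  # noqa: BLE001
                        cell["failure"] = str(exc)
                        status = "failed"
                    log.add(stage=f"{ep_name}/{food}/{model}/{adj}",
                            status=status, seed=config.seed, n=total,
                            wall_s=round(time.perf_counter() - t0, 3))
                    rows.append(cell)
            bundle["accounting"][f"{ep_name}/{food}"] = {
                "subjects_total": int(total),
            }
        bundle["main"][ep_name] = pd.DataFrame(rows)

    for food in config.jlcmm_foods:
        long = pd.read_csv(data_dir / config.foods[food])
        t0 = time.perf_counter()
        try:
            fit = fit_jlcmm(long, primary, baseline, config.spline, G=2,
                            hazard=config.jlcmm_hazard,
                            config=config.jlcmm_config)
            pw_tab = piecewise_hr(fit)
            overall = overall_hr_proportional(
                long, primary, baseline, config.spline,
                hazard=config.jlcmm_hazard, config=config.jlcmm_config,
                init_fit=fit,
            )
            ev = primary["event"].to_numpy().astype(bool)
            counts = pd.crosstab(fit.modal, ev)
            bundle["jlcmm"][food] = {
                "fit": fit, "piecewise": pw_tab,
                "overall": {"hr": overall.hr, "lo": overall.lo,
                            "hi": overall.hi, "p": overall.p},
                "class_sizes": fit.class_sizes.tolist(),
                "fisher_p": fisher_exact_2x2(
                    int(counts.loc[0].get(True, 0)),
                    int(counts.loc[0].get(False, 0)),
                    int(counts.loc[1].get(True, 0)) if 1 in counts.index else 0,
                    int(counts.loc[1].get(False, 0)) if 1 in counts.index else 0,
                ),
            }
            status = "ok"
        except Exception as exc:  # noqa: BLE001
            bundle["jlcmm"][food] = {"failure": str(exc)}
            status = "failed"
        log.add(stage=f"jlcmm/{food}", status=status, seed=config.seed,
                n=len(baseline), wall_s=round(time.perf_counter() - t0, 3))

    bundle["baseline_cox"] = baseline_cox_table(baseline, primary)
    bundle["log"] = log.records
    if out_dir is not None:
        _write_reports(bundle, out_dir, log)
    return bundle


def _fmt_hr(row) -> str:
    if not np.isfinite(row.get("hr", np.nan)):
        return row.get("failure", "failed")
    return f"{row['hr']:.2f} ({row['lo']:.2f}, {row['hi']:.2f})"


def _write_reports(bundle: dict, out_dir, log: _StageLog) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ep_name, table in bundle["main"].items():
        table.to_csv(out / f"table_main_{ep_name}.csv", index=False)
        md = ["| Food | Model | Adjustment | HR (95% CI) | P |",
              "|---|---|---|---|---|"]
        for _, r in table.iterrows():
            p = f"{r['p']:.3f}" if np.isfinite(r.get("p", np.nan)) else "-"
            md.append(f"| {r['food']} | {r['model']} | {r['adjustment']} "
                      f"| {_fmt_hr(r)} | {p} |")
        (out / f"table_main_{ep_name}.md").write_text("\n".join(md) + "\n")
    for food, res in bundle["jlcmm"].items():
        if "piecewise" in res:
            res["piecewise"].to_csv(out / f"table_jlcmm_{food}.csv",
                                    index=False)
    bundle["baseline_cox"].to_csv(out / "table_baseline_cox.csv",
                                  index=False)
    (out / "stages.jsonl").write_text(log.to_jsonl() + "\n")
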