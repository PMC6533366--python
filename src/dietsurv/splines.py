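"""Cubic B-spline trajectory basis and the BIC-driven interior-knot search.

The longitudinal submodel of both joint models represents a child's food
consumption trajectory as an intercept plus five cubic B-spline basis
functions on the age range of the food records.  The basis has two interior
knots (q = 2); their location is chosen by fitting the mixed model at every
admissible candidate pair and minimizing BIC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SplineSpec:
    """Cubic B-spline space on a fixed age range with q=2 interior knots.

    The full clamped cubic basis with two interior knots spans a space of
    dimension 6.  The design matrix returned by :func:`bspline_basis`
    reparameterizes it as an explicit intercept plus 5 basis columns by
    dropping the first full-basis function (absorbed into the intercept);
    the fitted trajectory m_i(t) is invariant to this choice.
    """

    interior_knots: tuple[float, ...] = (1.6, 3.8)
    boundary: tuple[float, float] = (0.25, 6.0)
    degree: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.boundary
        ks = tuple(float(k) for k in self.interior_knots)
        if not all(a < b for a, b in zip((lo,) + ks, ks + (hi,))):
            raise ValueError(
                f"knots must satisfy {lo} < k_1 < ... < {hi}, got {ks}"
            )
        object.__setattr__(self, "interior_knots", ks)

    @property
    def n_full(self) -> int:
        """Dimension of the full spline space (q + degree + 1)."""
        return len(self.interior_knots) + self.degree + 1

    @property
    def n_basis(self) -> int:
        """Number of basis columns excluding the intercept."""
        return self.n_full - 1

    @property
    def n_coef(self) -> int:
        """Columns of the design matrix (intercept + basis)."""
        return self.n_full

    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        return np.concatenate(
            [
                np.repeat(lo, self.degree + 1),
                np.asarray(self.interior_knots, dtype=float),
                np.repeat(hi, self.degree + 1),
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "degree": self.degree,
                "interior_knots": list(self.interior_knots),
                "boundary": list(self.boundary),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplineSpec":
        d = json.loads(text)
        return cls(
            interior_knots=tuple(d["interior_knots"]),
            boundary=tuple(d["boundary"]),
            degree=d.get("degree", 3),
        )


def full_basis(ages: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Full clamped B-spline basis (partition of unity), one column per
    basis function.  Raises on ages outside the boundary — no silent
    clamping or extrapolation."""
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    lo, hi = spec.boundary
    if ages.size and (ages.min() < lo or ages.max() > hi):
        bad = ages[(ages < lo) | (ages > hi)]
        raise ValueError(
            f"ages outside spline boundary [{lo}, {hi}]: {bad[:5]}"
        )
    t = spec.knot_vector()
    # design_matrix treats the right boundary as exclusive; nudge exact
    # right-endpoint evaluations into the last span (limit from the left).
    x = np.where(ages == hi, np.nextafter(hi, lo), ages)
    dm = BSpline.design_matrix(x, t, spec.degree).toarray()
    # restore exact endpoint values (last basis function is 1 at hi)
    at_hi = ages == hi
    if at_hi.any():
        dm[at_hi] = 0.0
        dm[at_hi, -1] = 1.0
    return dm


def bspline_basis(ages: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Design matrix: intercept column followed by ``spec.n_basis`` spline
    columns (first full-basis function dropped and absorbed into the
    intercept)."""
    full = full_basis(ages, spec)
    out = np.empty((full.shape[0], spec.n_coef))
    out[:, 0] = 1.0
    out[:, 1:] = full[:, 1:]
    return out


@dataclass(frozen=True)
class KnotCandidateSet:
    measurement_ages: tuple[float, ...]
    candidates: tuple[float, ...]
    admissible_pairs: tuple[tuple[float, float], ...] = field(default=())


def candidate_knots(measurement_ages: Sequence[float]) -> KnotCandidateSet:
    """Four equispaced candidate knot positions inside each gap between
    adjacent measurement ages."""
    ages = sorted(set(float(a) for a in measurement_ages))
    if len(ages) < 3:
        raise ValueError("need at least 3 distinct measurement ages")
    cands: list[float] = []
    for a, b in zip(ages[:-1], ages[1:]):
        for j in range(1, 5):
            cands.append(a + j * (b - a) / 5.0)
    return KnotCandidateSet(tuple(ages), tuple(cands))


def admissible_knot_pairs(
    cands: KnotCandidateSet,
) -> list[tuple[float, float]]:
    """Ordered pairs (k1, k2) leaving at least 2 measurement ages before
    k1, strictly between k1 and k2, and after k2."""
    ages = np.asarray(cands.measurement_ages)
    pairs = []
    for i, k1 in enumerate(cands.candidates):
        for k2 in cands.candidates[i + 1:]:
            if (
                (ages < k1).sum() >= 2
                and ((ages > k1) & (ages < k2)).sum() >= 2
                and (ages > k2).sum() >= 2
            ):
                pairs.append((k1, k2))
    if not pairs:
        raise ValueError(
            "no admissible knot pair for this measurement schedule; "
            "supply a denser schedule or relax the spacing rule"
        )
    return pairs


def knot_search(
    long_table,
    measurement_ages: Sequence[float] = (0.25, 0.5, 1, 2, 3, 4, 5, 6),
    boundary: tuple[float, float] | None = None,
    **fit_kwargs,
):
    """Fit the spline mixed model at every admissible knot pair and return
    ``(best_spec, bic_table)`` with the minimum-BIC pair.

    Ties (within 1e-9) break toward the smaller first knot, then the
    smaller second knot.  Non-converged fits are recorded and skipped.
    """
    import pandas as pd

    from .lmm import fit_lmm

    if boundary is None:
        boundary = (min(measurement_ages), max(measurement_ages))
    pairs = admissible_knot_pairs(candidate_knots(measurement_ages))
    rows = []
    start = None  # variance estimates carry over well between knot pairs
    for k1, k2 in pairs:
        spec = SplineSpec(interior_knots=(k1, k2), boundary=boundary)
        try:
            fit = fit_lmm(long_table, spec, start=start, **fit_kwargs)
            if fit.converged:
                start = fit.params
        except Exception as exc:  # noqa: BLE001 - record and move on
            rows.append({"k1": k1, "k2": k2, "bic": np.nan,
                         "loglik": np.nan, "status": f"failed: {exc}"})
            continue
        rows.append({"k1": k1, "k2": k2, "bic": fit.bic,
                     "loglik": fit.loglik,
                     "status": "ok" if fit.converged else "not converged"})
    table = pd.DataFrame(rows)
    ok = table[table["status"] == "ok"]
    if ok.empty:
        raise RuntimeError("all knot-search fits failed")
    best_bic = ok["bic"].min()
    best = ok[ok["bic"] <= best_bic + 1e-9].sort_values(["k1", "k2"]).iloc[0]
    best_spec = SplineSpec(
        interior_knots=(best["k1"], best["k2"]), boundary=boundary
    )
    return best_spec, table
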