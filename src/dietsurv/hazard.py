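"""Piecewise-constant baseline hazard h0(t).

The baseline hazard of the relative-risk submodels is constant on the
intervals between a small set of knot ages (defaults: knots at 1.99 and
3.99 years for the 6-year joint model; an extra knot at 5.99 years for the
15-year latent-class model).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HazardSpec:
    """Knot ages partitioning [0, followup_max] into hazard segments."""

    knots: tuple[float, ...] = (1.99, 3.99)
    followup_max: float = 6.0

    def __post_init__(self) -> None:
        ks = tuple(float(k) for k in self.knots)
        if any(b <= a for a, b in zip(ks[:-1], ks[1:])):
            raise ValueError(f"hazard knots must be increasing: {ks}")
        if ks and (ks[0] <= 0 or ks[-1] >= self.followup_max):
            raise ValueError(
                f"hazard knots must lie inside (0, {self.followup_max})"
            )
        object.__setattr__(self, "knots", ks)

    @property
    def n_intervals(self) -> int:
        return len(self.knots) + 1

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], self.knots, [self.followup_max]])

    def segment_of(self, t) -> np.ndarray:
        """Index of the segment containing each time (events at a knot age
        belong to the segment ending there)."""
        t = np.asarray(t, dtype=float)
        return np.clip(
            np.searchsorted(self.edges[1:-1], t, side="left"),
            0,
            self.n_intervals - 1,
        )

    def exposure(self, t) -> np.ndarray:
        """Time at risk accumulated in each segment up to ``t``;
        shape (..., n_intervals)."""
        t = np.asarray(t, dtype=float)
        lo = self.edges[:-1]
        hi = self.edges[1:]
        return np.clip(t[..., None], lo, hi) - lo


def hazard_value(spec: HazardSpec, log_heights: np.ndarray, t) -> np.ndarray:
    """h0(t) for piecewise-constant heights exp(log_heights)."""
    return np.exp(np.asarray(log_heights))[spec.segment_of(t)]


def cumulative_baseline(
    spec: HazardSpec, log_heights: np.ndarray, t
) -> np.ndarray:
    """H0(t) = integral of the step hazard, piecewise linear in t."""
    return spec.exposure(t) @ np.exp(np.asarray(log_heights))


def occurrence_exposure_heights(
    spec: HazardSpec, times: np.ndarray, events: np.ndarray
) -> np.ndarray:
    """Nelson-Aalen style log occurrence/exposure rate per segment,
    used to initialize baseline-hazard heights."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    expo = spec.exposure(times).sum(axis=0)
    seg = spec.segment_of(times[events])
    occ = np.bincount(seg, minlength=spec.n_intervals).astype(float)
    rate = np.where(expo > 0, np.maximum(occ, 0.5) / np.maximum(expo, 1e-12), 1e-8)
    return np.log(rate)


def equal_event_knots(
    event_times: np.ndarray, n_intervals: int, followup_max: float
) -> HazardSpec:
    """Hazard knots at event-time quantiles so each interval holds (close
    to) the same number of events — the knot-robustness construction."""
    et = np.sort(np.asarray(event_times, dtype=float))
    if et.size < n_intervals + 1:
        raise ValueError(
            f"need at least {n_intervals + 1} events for {n_intervals} "
            f"equal-event intervals, got {et.size}"
        )
    qs = np.arange(1, n_intervals) / n_intervals
    knots = np.quantile(et, qs)
    # guard against duplicate quantiles from heavily tied event times
    knots = np.unique(np.round(knots, 10))
    if len(knots) != n_intervals - 1:
        raise ValueError("tied event times collapse the quantile knots")
    return HazardSpec(knots=tuple(knots), followup_max=followup_max)
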