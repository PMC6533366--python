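"""Shared table schemas and design-matrix coding.

Input tables (delimited text, header row):

* ``long``      — subject, age_years, food_g_day, energy_mj_day
* ``baseline``  — subject, sex {boy,girl}, genetic_risk {moderate,high},
                  familial_diabetes {no,yes,missing}
* ``endpoints`` — subject, last_negative_age, first_positive_age, event,
                  censor_age

For a child reaching the endpoint the event time is interval-censored
between the last negative and first positive visit; the working event time
is the interval midpoint.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEX_LEVELS = ("boy", "girl")
RISK_LEVELS = ("moderate", "high")
FAMILIAL_LEVELS = ("no", "yes", "missing")

BASELINE_CONTRASTS = ["sex_girl", "risk_high", "familial_yes",
                      "familial_missing"]


def endpoint_times(
    endpoints: pd.DataFrame, followup_max: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Working event/censoring times: interval midpoint for events,
    last attended visit for censored children; optionally administratively
    censored at ``followup_max``."""
    ev = endpoints["event"].to_numpy().astype(bool)
    mid = 0.5 * (
        endpoints["last_negative_age"].to_numpy()
        + endpoints["first_positive_age"].to_numpy()
    )
    t = np.where(ev, mid, endpoints["censor_age"].to_numpy(float))
    if followup_max is not None:
        ev = ev & (t <= followup_max)
        t = np.minimum(t, followup_max)
    return t, ev


def baseline_design(
    baseline: pd.DataFrame, subjects: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Dummy coding of the confounder set (reference levels: boy,
    moderate risk, no familial diabetes; missing familial information kept
    as its own category)."""
    b = baseline.set_index("subject").loc[subjects]
    for col, levels in (
        ("sex", SEX_LEVELS),
        ("genetic_risk", RISK_LEVELS),
        ("familial_diabetes", FAMILIAL_LEVELS),
    ):
        bad = set(b[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} levels: {sorted(bad)}")
    W = np.column_stack(
        [
            (b["sex"] == "girl").to_numpy(float),
            (b["genetic_risk"] == "high").to_numpy(float),
            (b["familial_diabetes"] == "yes").to_numpy(float),
            (b["familial_diabetes"] == "missing").to_numpy(float),
        ]
    )
    return W, list(BASELINE_CONTRASTS)
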