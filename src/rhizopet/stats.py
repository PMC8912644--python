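"""Treatment statistics on per-session nodule tracer fractions.

For each plant the six nodule-ROI mean fractions of a session are summed to
one number (percent of belowground allocation).  Across the eight sessions
(two per day, four consecutive days) an ordinary least-squares line gives
the slope in % per day with its standard error and a two-sided t-test of
slope = 0 (n - 2 degrees of freedom), and the relative change from the
first to the last measurement day summarizes the treatment effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class MeasurementRecord:
    """One labelling session of one plant."""

    plant_id: str
    dat: int  # days after transfer
    session_index: int  # 1-based, 1..8 by default
    session_time_days: float  # fractional days since the first session
    fractions: dict  # roi_id -> (mean fraction, sd), dimensionless
    group: str = "control"


@dataclass
class SlopeReport:
    plant_id: str
    group: str
    slope: float  # % day^-1
    se: float  # % day^-1
    p_value: float
    relative_change_pct: float

    def __post_init__(self):
        if self.se < 0:
            raise StatsError("SE must be >= 0")
        if not 0 <= self.p_value <= 1:
            raise StatsError("p-value must lie in [0, 1]")


def sum_nodule_fractions(record: MeasurementRecord) -> float:
    """Summed nodule tracer fraction of one session, in percent."""
    vals = [m for roi, (m, _sd) in record.fractions.items() if roi.startswith("nodule")]
    if not vals:
        raise StatsError(f"record {record.plant_id}/{record.session_index}: no nodule ROIs")
    return 100.0 * float(np.sum(vals))


def fit_slope(times_days, values) -> tuple:
    """OLS slope, its standard error, and the two-sided p-value of the
    t-test against zero slope (n - 2 df).

    Degenerate perfect fits (zero residual variance) report SE 0 and a
    p-value capped at 0 (flat data give slope 0, p 1).
    """
    t = np.asarray(times_days, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 3:
        raise StatsError("need at least 3 points")
    if np.ptp(t) == 0:
        raise StatsError("times must not all be equal")
    res = sps.linregress(t, y)
    slope, se = float(res.slope), float(res.stderr)
    p = float(res.pvalue)
    if se == 0.0 or not np.isfinite(p):
        se = 0.0 if not np.isfinite(se) else se
        p = 1.0 if slope == 0.0 else 0.0
    return slope, se, p


def relative_change(records: list, method: str = "day-mean") -> float:
    """Percent change of the summed nodule fraction from the first to the
    last measurement day.

    ``day-mean`` (default): 100 * (mean over last-day sessions - mean over
    first-day sessions) / first-day mean.  ``regression`` evaluates the OLS
    line of all sessions at the first/last day-mean times instead, which
    trades within-day noise robustness for consistency with the slope.
    """
    if not records:
        raise StatsError("no records")
    recs = sorted(records, key=lambda r: r.session_index)
    dats = sorted({r.dat for r in recs})
    first = [r for r in recs if r.dat == dats[0]]
    last = [r for r in recs if r.dat == dats[-1]]
    y_first = np.mean([sum_nodule_fractions(r) for r in first])
    y_last = np.mean([sum_nodule_fractions(r) for r in last])
    if method == "day-mean":
        pass
    elif method == "regression":
        t = np.array([r.session_time_days for r in recs])
        y = np.array([sum_nodule_fractions(r) for r in recs])
        slope, _, _ = fit_slope(t, y)
        inter = float(np.mean(y) - slope * np.mean(t))
        t_first = np.mean([r.session_time_days for r in first])
        t_last = np.mean([r.session_time_days for r in last])
        y_first = inter + slope * t_first
        y_last = inter + slope * t_last
    else:
        raise StatsError(f"unknown relative-change method {method!r}")
    if y_first <= 0:
        raise StatsError("first-day mean fraction must be > 0")
    return 100.0 * (y_last - y_first) / y_first


def plant_report(records: list, change_method: str = "day-mean") -> SlopeReport:
    """Slope statistics and relative change for one plant's sessions."""
    recs = sorted(records, key=lambda r: r.session_index)
    t = np.array([r.session_time_days for r in recs])
    y = np.array([sum_nodule_fractions(r) for r in recs])
    slope, se, p = fit_slope(t, y)
    return SlopeReport(
        plant_id=recs[0].plant_id,
        group=recs[0].group,
        slope=slope,
        se=se,
        p_value=p,
        relative_change_pct=relative_change(recs, method=change_method),
    )


TABLE_COLUMNS = ["plant", "group", "slope_pct_per_day", "se_pct_per_day", "p_value", "relative_change_pct", "significant"]


def build_table(reports: list) -> pd.DataFrame:
    """One row per plant: group, slope, SE, p, relative change, and a
    significance flag at p < 0.05."""
    if not reports:
        raise StatsError("no reports")
    rows = [
        {
            "plant": r.plant_id,
            "group": r.group,
            "slope_pct_per_day": r.slope,
            "se_pct_per_day": r.se,
            "p_value": r.p_value,
            "relative_change_pct": r.relative_change_pct,
            "significant": r.p_value < 0.05,
        }
        for r in reports
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# protocol utilities


def plan_experiment(n_control: int, n_treatment: int, days_per_plant: int = 4, sessions_per_day: int = 2) -> dict:
    """Enumerate the measurement plan; each plant occupies the scanner for
    ``days_per_plant`` whole days, so total machine time in days is the
    plant count times the days per plant."""
    if min(n_control, n_treatment, days_per_plant, sessions_per_day) < 0:
        raise StatsError("plan arguments must be >= 0")
    n_plants = n_control + n_treatment
    sessions = []
    for p in range(n_plants):
        group = "control" if p < n_control else "treatment"
        plant = f"{'ctrl' if group == 'control' else 'treat'}_P{(p if group == 'control' else p - n_control) + 1}"
        for d in range(days_per_plant):
            for s in range(sessions_per_day):
                sessions.append({"plant": plant, "group": group, "dat": 13 + d, "session": d * sessions_per_day + s + 1})
    return {"total_measurement_days": n_plants * days_per_plant, "sessions": sessions}


#: nitrate ions released per formula unit of supported salts
NITRATE_STOICHIOMETRY = {
    "KNO3": 1,
    "Ca(NO3)2": 2,
    "NaNO3": 1,
    "Mg(NO3)2": 2,
    "NH4NO3": 1,
}


def nitrate_concentration(salt_additions: list) -> float:
    """Total nitrate concentration (mmol/L) from a list of
    ``(salt, mmol/L)`` additions, via a small built-in stoichiometry table."""
    total = 0.0
    for salt, conc in salt_additions:
        if salt not in NITRATE_STOICHIOMETRY:
            raise StatsError(f"unknown salt {salt!r}")
        total += NITRATE_STOICHIOMETRY[salt] * conc
    return total
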