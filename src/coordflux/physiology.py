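"""Growth rates, specific uptake/secretion rates and culture unit conversions.

Specific rates are estimated from batch time courses by regressing the
extracellular concentration on biomass (X = OD600 · 0.413 g CDW/l) and
multiplying the slope by the growth rate: during balanced exponential growth
C(t) = C₀ + (q/μ)·(X(t) − X₀), so the slope is q/μ. Secretion is positive,
uptake negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

OD_TO_CDW = 0.413        # g CDW per litre per OD unit (= mg CDW/ml)
CELLVOL_PER_CDW = 2.7    # µl cell volume per mg CDW
MINOR_EXCHANGE_THRESHOLD = 0.01  # mmol·gCDW⁻¹·h⁻¹ (10 µmol·gCDW⁻¹·h⁻¹)

#: exchanged species always classified as major
DEFAULT_MAJOR = ("glc", "glucose", "ace", "acetate", "akg", "2-oxoglutarate")


class EstimationError(ValueError):
    pass


@dataclass
class RatePanel:
    """Per-condition growth rates and signed specific exchange rates."""

    growth: pd.DataFrame  # condition_id, mu, mu_stderr
    rates: pd.DataFrame   # condition_id, metabolite, q, q_stderr, class

    def mu(self, condition_id: str) -> float:
        row = self.growth.loc[self.growth["condition_id"] == condition_id, "mu"]
        if row.empty:
            raise KeyError(condition_id)
        return float(row.iloc[0])

    def condition_rates(self, condition_id: str) -> pd.DataFrame:
        return self.rates[self.rates["condition_id"] == condition_id]

    def to_csv(self, path) -> None:
        merged = self.rates.merge(self.growth, on="condition_id", how="left")
        merged.to_csv(path, index=False)


def estimate_growth_rate(
    times_h: np.ndarray, od: np.ndarray, window_h: float | None = None
) -> tuple[float, float]:
    """OLS slope of ln(OD) vs time; optional maximal-rate window mode.

    In window mode the contiguous window of width ``window_h`` (e.g. the
    1.5 h maximal-growth window used for steady-state promoter activities)
    maximizing the fitted slope is used.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(od, dtype=float)
    if len(t) < 3:
        raise EstimationError("need at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise EstimationError("times must be strictly increasing")
    if np.any(y <= 0):
        raise EstimationError("OD values must be positive for log-linear fit")
    ln = np.log(y)
    if window_h is None:
        res = stats.linregress(t, ln)
        return float(res.slope), float(res.stderr)
    best = None
    for i in range(len(t)):
        sel = (t >= t[i]) & (t <= t[i] + window_h)
        if sel.sum() < 3:
            continue
        res = stats.linregress(t[sel], ln[sel])
        if best is None or res.slope > best.slope:
            best = res
    if best is None:
        raise EstimationError("no window contains 3 or more points")
    return float(best.slope), float(best.stderr)


def estimate_exchange_rate(
    conc_mM: np.ndarray, od: np.ndarray, mu: float
) -> tuple[float, float]:
    """q = μ · slope of concentration (mM) on biomass X = OD·0.413 g/l.

    The slope's standard error is propagated: se(q) = μ · se(slope).
    """
    c = np.asarray(conc_mM, dtype=float)
    x = np.asarray(od, dtype=float) * OD_TO_CDW
    if len(c) != len(x):
        raise EstimationError("concentration and OD series must share time points")
    if len(c) < 3:
        raise EstimationError("need at least 3 shared points")
    if mu <= 0:
        raise EstimationError("growth rate must be positive")
    if np.allclose(c, c[0]):
        return 0.0, 0.0
    res = stats.linregress(x, c)
    return float(res.slope * mu), float(res.stderr * mu)


def od_to_biomass(od: float, volume_ml: float) -> float:
    """mg CDW in a sample: od · 0.413 mg·ml⁻¹·OD⁻¹ · volume."""
    if od < 0 or volume_ml <= 0:
        raise EstimationError("od must be >= 0 and volume > 0")
    return od * OD_TO_CDW * volume_ml


def biomass_to_cellvolume(mg_cdw: float) -> float:
    """µl of cell volume: 2.7 µl per mg CDW."""
    if mg_cdw < 0:
        raise EstimationError("biomass must be >= 0")
    return mg_cdw * CELLVOL_PER_CDW


def promoter_activity(
    times_h: np.ndarray, gfp: np.ndarray, od: np.ndarray
) -> np.ndarray:
    """OD-normalized GFP production rate via centered finite differences."""
    t = np.asarray(times_h, dtype=float)
    g = np.asarray(gfp, dtype=float)
    o = np.asarray(od, dtype=float)
    if not (len(t) == len(g) == len(o)):
        raise EstimationError("GFP and OD series must be aligned on time")
    dgdt = np.gradient(g, t)
    return dgdt / o


def steady_state_gfp_concentration(activity: np.ndarray, mu: float) -> np.ndarray:
    """GFP concentration at steady state = promoter activity / μ."""
    if mu <= 0:
        raise EstimationError("growth rate must be positive")
    return np.asarray(activity, dtype=float) / mu


def partition_exchanges(
    rates: pd.DataFrame,
    majors: tuple[str, ...] = DEFAULT_MAJOR,
    threshold: float = MINOR_EXCHANGE_THRESHOLD,
) -> pd.Series:
    """Classify exchanged metabolites as major / minor / trace.

    Named majors stay major regardless of magnitude; other metabolites whose
    maximal |q| across conditions exceeds the 0.01 mmol·gCDW⁻¹·h⁻¹ threshold
    are minor; the rest are trace and excluded from flux-inference
    constraints.
    """
    if rates.empty:
        raise EstimationError("need rates for at least one condition")
    max_abs = rates.groupby("metabolite")["q"].apply(lambda s: s.abs().max())
    out = {}
    for met, mq in max_abs.items():
        if met in majors:
            out[met] = "major"
        elif mq > threshold:
            out[met] = "minor"
        else:
            out[met] = "trace"
    return pd.Series(out, name="class")


def estimate_rate_panel(
    od_timecourses: pd.DataFrame,
    conc_timecourses: pd.DataFrame,
    majors: tuple[str, ...] = DEFAULT_MAJOR,
    window_h: float | None = None,
) -> RatePanel:
    """Run both estimators across all conditions of tidy time-course tables.

    ``od_timecourses``: columns condition_id, time_h, od.
    ``conc_timecourses``: columns condition_id, metabolite, time_h, conc_mM.
    """
    growth_rows = []
    rate_rows = []
    for cid, od_grp in od_timecourses.groupby("condition_id", sort=True):
        od_grp = od_grp.sort_values("time_h")
        mu, mu_se = estimate_growth_rate(
            od_grp["time_h"].values, od_grp["od"].values, window_h=window_h
        )
        growth_rows.append({"condition_id": cid, "mu": mu, "mu_stderr": mu_se})
        conc_grp = conc_timecourses[conc_timecourses["condition_id"] == cid]
        for met, series in conc_grp.groupby("metabolite", sort=True):
            series = series.sort_values("time_h")
            q, q_se = estimate_exchange_rate(
                series["conc_mM"].values, od_grp["od"].values, mu
            )
            rate_rows.append(
                {"condition_id": cid, "metabolite": met, "q": q, "q_stderr": q_se}
            )
    rates = pd.DataFrame(rate_rows)
    classes = partition_exchanges(rates, majors=majors)
    rates["class"] = rates["metabolite"].map(classes)
    return RatePanel(growth=pd.DataFrame(growth_rows), rates=rates)
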