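"""Model-qualification statistics: fold errors, residuals, Wilcoxon, GMR CIs.

The qualification suite compares predicted with observed exposures and
concentration-time points:

* GMFE = 10**(mean |log10(pred/obs)|), a spread measure that is always >= 1;
  AFE = 10**(mean log10(pred/obs)), its signed (bias) counterpart.
* Weighted residuals WRi = (Yo - Yp)/Sp (per-point observed SD) and
  percentage errors PE% = (Yo - Yp)/Yo * 100, with per-study medians/means
  (MWRi, MAWRi, MPE%, MAPE%, MdPE%, MdAPE%).
* A two-sided Wilcoxon signed-rank test of zero median on the residuals
  (exact null for n <= 25); the statistic follows the R convention
  V = sum of positive ranks.
* 90% confidence intervals for the geometric mean ratio (GMR) of predicted
  to observed exposure via the pooled log-scale formula
  GMR * exp(-+ t * sqrt(Vobs/nobs + Vpred/npred)), classified against the
  bioequivalence-style 0.80-1.25 range.
* The two-fold criterion: 0.5 <= pred/obs <= 2, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ObservedSeries",
    "PredictionPair",
    "ValidationReport",
    "fold_errors",
    "residual_metrics",
    "wilcoxon_zero_median",
    "gmr_confidence_interval",
    "two_fold_check",
    "interpolate_predictions",
    "read_observed_csv",
    "write_observed_csv",
]


@dataclass(frozen=True)
class ObservedSeries:
    """One observed concentration-time study after a single IV dose."""

    study_id: str
    dose_per_kg: float  # mg/kg
    route: str  # "bolus" | "infusion"
    times: np.ndarray  # h
    concentrations: np.ndarray  # ug/mL
    sds: np.ndarray | None = None  # ug/mL, per point
    infusion_h: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if self.route not in ("bolus", "infusion"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.route == "infusion" and self.infusion_h <= 0:
            raise ValueError("infusion route requires infusion_h > 0")
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if c.shape != t.shape or np.any(c < 0):
            raise ValueError("concentrations must match times and be >= 0")
        if self.sds is not None:
            s = np.asarray(self.sds, dtype=float)
            object.__setattr__(self, "sds", s)
            if s.shape != t.shape or np.any(s <= 0):
                raise ValueError("sds must match times and be > 0")

    @property
    def infusion_duration(self) -> float:
        return self.infusion_h if self.route == "infusion" else 0.0


@dataclass(frozen=True)
class PredictionPair:
    """One predicted/observed exposure pair (AUClast or Cmax)."""

    study_id: str
    quantity: str  # "auc_last" | "cmax"
    observed: float
    predicted: float
    units: str = "umol*min/L"

    def __post_init__(self) -> None:
        if self.observed <= 0 or self.predicted <= 0:
            raise ValueError("observed and predicted must be > 0")

    @property
    def ratio(self) -> float:
        return self.predicted / self.observed


def fold_errors(pairs: Sequence[PredictionPair]) -> tuple[float, float]:
    """(GMFE, AFE) over prediction pairs.

    GMFE uses |log10(pred/obs)| (>= 1 by construction); AFE keeps the sign
    and measures bias.  Both are invariant to a common unit change.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    logs = np.array([np.log10(p.ratio) for p in pairs])
    if not np.all(np.isfinite(logs)):
        raise ValueError("non-finite log ratio")
    gmfe = float(10 ** np.mean(np.abs(logs)))
    afe = float(10 ** np.mean(logs))
    return gmfe, afe


def residual_metrics(
    points: pd.DataFrame, by: str = "study_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-point residuals and per-study summaries.

    ``points`` needs columns ``study_id``, ``observed``, ``predicted`` and
    optionally ``sd``.  Returns (per-point frame with WRi/AWRi/PE%/APE%,
    per-study frame with MWRi, MAWRi, MPE%, MdPE%, MAPE%, MdAPE%).  WRi is
    only computed where an SD is available; PE% requires observed != 0.
    """
    pts = points.copy()
    obs = pts["observed"].to_numpy(dtype=float)
    pred = pts["predicted"].to_numpy(dtype=float)
    if np.any(obs == 0):
        raise ValueError("observed value of 0 is not allowed for PE%")
    pts["pe_pct"] = (obs - pred) / obs * 100.0
    pts["ape_pct"] = np.abs(pts["pe_pct"])
    if "sd" in pts.columns and pts["sd"].notna().any():
        sd = pts["sd"].to_numpy(dtype=float)
        with_sd = ~np.isnan(sd)
        if np.any(sd[with_sd] == 0):
            raise ValueError("sd of 0 is not allowed for weighted residuals")
        wri = np.full_like(obs, np.nan)
        wri[with_sd] = (obs[with_sd] - pred[with_sd]) / sd[with_sd]
        pts["wri"] = wri
        pts["awri"] = np.abs(wri)
    else:
        pts["wri"] = np.nan
        pts["awri"] = np.nan

    def _summ(g: pd.DataFrame) -> pd.Series:
        has_wri = g["wri"].notna().any()
        return pd.Series(
            {
                "mwri": g["wri"].median() if has_wri else np.nan,
                "mawri": g["awri"].median() if has_wri else np.nan,
                "mpe_pct": g["pe_pct"].mean(),
                "mdpe_pct": g["pe_pct"].median(),
                "mape_pct": g["ape_pct"].mean(),
                "mdape_pct": g["ape_pct"].median(),
            }
        )

    summaries = pts.groupby(by, sort=True).apply(_summ, include_groups=False).reset_index()
    return pts, summaries


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # V = sum of positive ranks (R convention)
    p_value: float
    n: int
    small_sample: bool  # n < 5: exact p exists but has little resolution


def wilcoxon_zero_median(residuals: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test that residuals center on 0.

    Zeros are dropped (signed-rank convention); the exact null distribution
    is used for n <= 25 and the normal approximation above.  Raises on an
    all-zero input; flags n < 5 as a small sample.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[r != 0]
    if r.size == 0:
        raise ValueError("all residuals are zero; the test is degenerate")
    ranks = stats.rankdata(np.abs(r))
    v = float(ranks[r > 0].sum())
    method = "exact" if r.size <= 25 else "approx"
    res = stats.wilcoxon(r, alternative="two-sided", method=method)
    return WilcoxonResult(
        statistic=v, p_value=float(res.pvalue), n=int(r.size), small_sample=r.size < 5
    )


@dataclass(frozen=True)
class GMRInterval:
    gmr: float
    lower: float
    upper: float
    classification: str  # accepted | inconclusive | rejected
    df: float


def gmr_confidence_interval(
    obs_mean_log: float,
    obs_var_log: float,
    n_obs: int,
    pred_mean_log: float,
    pred_var_log: float,
    n_pred: int,
    alpha: float = 0.10,
    acceptance: tuple[float, float] = (0.80, 1.25),
) -> GMRInterval:
    """Pooled CI for the geometric mean ratio predicted/observed.

    Inputs are log-scale summary statistics per arm (mean, variance, n).
    CI = GMR * exp(-+ t_{1-alpha/2, nu} * sqrt(Vobs/nobs + Vpred/npred)) with
    Welch-Satterthwaite degrees of freedom.  Classification: "accepted" when
    the CI lies inside the acceptance range, "rejected" when it is disjoint
    from it, otherwise "inconclusive".
    """
    if n_obs < 2:
        raise ValueError("need n_obs >= 2")
    if n_pred < 1:
        raise ValueError("need n_pred >= 1")
    if obs_var_log < 0 or pred_var_log < 0:
        raise ValueError("variances must be >= 0")
    gmr = float(np.exp(pred_mean_log - obs_mean_log))
    se2 = obs_var_log / n_obs + pred_var_log / n_pred
    if se2 == 0:
        lo = hi = gmr
        df = float("inf")
    else:
        num = se2**2
        den = 0.0
        if obs_var_log > 0:
            den += (obs_var_log / n_obs) ** 2 / (n_obs - 1)
        if pred_var_log > 0 and n_pred > 1:
            den += (pred_var_log / n_pred) ** 2 / (n_pred - 1)
        df = num / den if den > 0 else float(max(n_obs, n_pred) - 1)
        t = stats.t.ppf(1 - alpha / 2, df)
        half = t * np.sqrt(se2)
        lo, hi = float(gmr * np.exp(-half)), float(gmr * np.exp(half))
    a_lo, a_hi = acceptance
    if a_lo <= lo and hi <= a_hi:
        cls = "accepted"
    elif hi < a_lo or lo > a_hi:
        cls = "rejected"
    else:
        cls = "inconclusive"
    return GMRInterval(gmr=gmr, lower=lo, upper=hi, classification=cls, df=float(df))


def two_fold_check(pairs: Sequence[PredictionPair]) -> tuple[float, list[bool]]:
    """Fraction (and per-pair flags) of predictions within 2-fold, inclusive."""
    if not pairs:
        raise ValueError("need at least one pair")
    flags = [0.5 <= p.ratio <= 2.0 for p in pairs]
    return float(np.mean(flags)), flags


def interpolate_predictions(
    pred_times: np.ndarray, pred_conc: np.ndarray, at_times: np.ndarray
) -> np.ndarray:
    """Log-linearly interpolate a simulated profile at observed time points."""
    pt = np.asarray(pred_times, dtype=float)
    pc = np.maximum(np.asarray(pred_conc, dtype=float), 1e-300)
    return np.exp(np.interp(np.asarray(at_times, dtype=float), pt, np.log(pc)))


@dataclass(frozen=True)
class ValidationReport:
    """Bundle of qualification metrics for a set of predicted/observed series."""

    gmfe: float
    afe: float
    per_study: pd.DataFrame
    wilcoxon_wri: WilcoxonResult | None
    wilcoxon_pe: WilcoxonResult
    gmr_intervals: Mapping[str, GMRInterval]
    two_fold_fraction: float

    def to_dict(self) -> dict:
        return {
            "gmfe": self.gmfe,
            "afe": self.afe,
            "two_fold_fraction": self.two_fold_fraction,
            "per_study": self.per_study.to_dict(orient="records"),
            "wilcoxon_wri": None
            if self.wilcoxon_wri is None
            else self.wilcoxon_wri.__dict__,
            "wilcoxon_pe": self.wilcoxon_pe.__dict__,
            "gmr_intervals": {k: v.__dict__ for k, v in self.gmr_intervals.items()},
        }


OBSERVED_CSV_COLUMNS = (
    "study_id",
    "dose_mg_kg",
    "route",
    "infusion_h",
    "time_h",
    "conc_ug_ml",
    "sd_ug_ml",
)


def read_observed_csv(path) -> list[ObservedSeries]:
    """Read the observed-data CSV dialect into series objects."""
    frame = pd.read_csv(path)
    missing = set(OBSERVED_CSV_COLUMNS[:-1]) - set(frame.columns)
    if missing:
        raise ValueError(f"observed CSV lacks columns {sorted(missing)}")
    series = []
    for sid, g in frame.groupby("study_id", sort=True):
        g = g.sort_values("time_h")
        sds = None
        if "sd_ug_ml" in g.columns and g["sd_ug_ml"].notna().all():
            sds = g["sd_ug_ml"].to_numpy(dtype=float)
        series.append(
            ObservedSeries(
                study_id=str(sid),
                dose_per_kg=float(g["dose_mg_kg"].iloc[0]),
                route=str(g["route"].iloc[0]),
                infusion_h=float(g["infusion_h"].iloc[0]),
                times=g["time_h"].to_numpy(dtype=float),
                concentrations=g["conc_ug_ml"].to_numpy(dtype=float),
                sds=sds,
            )
        )
    return series


def write_observed_csv(series: Sequence[ObservedSeries], path) -> None:
    rows = []
    for s in series:
        for i, t in enumerate(s.times):
            rows.append(
                {
                    "study_id": s.study_id,
                    "dose_mg_kg": s.dose_per_kg,
                    "route": s.route,
                    "infusion_h": s.infusion_h,
                    "time_h": float(t),
                    "conc_ug_ml": float(s.concentrations[i]),
                    "sd_ug_ml": float(s.sds[i]) if s.sds is not None else np.nan,
                }
            )
    pd.DataFrame(rows, columns=OBSERVED_CSV_COLUMNS).to_csv(path, index=False)
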