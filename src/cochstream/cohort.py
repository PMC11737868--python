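"""Cohort-level effect-time statistics.

The silence-condition records define a diffusion trend
``tTrend(x) = x^2 / (4 D_eff z^2)`` (z = erfcinv of the threshold fraction);
every record is then normalized to the trend in decibels,
``tE[dB] = 20 log10(tE / tTrend)``, and conditions are compared with Welch
two-tailed t-tests, overall and split at 4.5 kHz into low- and high-CF strata.

The trend is fitted as a model object: build :class:`DiffusionTrend` from the
silence records and call :meth:`~DiffusionTrend.fit` for a results object
carrying the effective diffusion constant, its uncertainty, residuals and a
``summary()`` table.  The fit runs in log-time space (multiplicative errors,
consistent with the dB residual presentation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.special import erfcinv

__all__ = [
    "DiffusionTrend",
    "DiffusionTrendResults",
    "StratumComparison",
    "ComparisonResult",
    "effect_time_db",
    "compare_groups",
    "fit_diffusion_trend",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("animal_id", "cf_hz", "place_m", "condition", "te_min")


def effect_time_db(te_min, t_trend_min):
    """Effect time relative to the trend: 20*log10(tE / tTrend) [dB]."""
    te = np.asarray(te_min, dtype=float)
    tr = np.asarray(t_trend_min, dtype=float)
    if np.any(te <= 0) or np.any(tr <= 0):
        raise ValueError("effect times and trend values must be positive")
    out = 20.0 * np.log10(te / tr)
    return float(out) if np.isscalar(te_min) else out


class DiffusionTrend:
    """Model of effect time versus place under 1-D diffusion from the base.

    Parameters
    ----------
    place_m, te_min : array-like
        Record places (metres from the base) and effect times (minutes).
    threshold_fraction : float
        Concentration fraction defining the effect time (default 1%).
    """

    def __init__(self, place_m, te_min, threshold_fraction: float = 0.01):
        self.place_m = np.asarray(place_m, dtype=float)
        self.te_min = np.asarray(te_min, dtype=float)
        self.threshold_fraction = float(threshold_fraction)
        if self.place_m.shape != self.te_min.shape:
            raise ValueError("place_m and te_min must have the same shape")
        if self.place_m.size < 3:
            raise ValueError("trend fit needs at least 3 records")
        if np.any(self.te_min <= 0) or np.any(self.place_m <= 0):
            raise ValueError("places and effect times must be positive")
        if np.ptp(self.place_m) < 1e-3:
            raise ValueError("records must span more than 1 mm of places")
        self.z = erfcinv(self.threshold_fraction)

    @classmethod
    def from_records(cls, records: pd.DataFrame, condition: str | None = "silence",
                     threshold_fraction: float = 0.01) -> "DiffusionTrend":
        df = records
        if condition is not None:
            df = df[df["condition"] == condition]
        df = df.dropna(subset=["te_min"])
        return cls(df["place_m"].to_numpy(), df["te_min"].to_numpy(),
                   threshold_fraction)

    def fit(self, fix_exponent: bool = True) -> "DiffusionTrendResults":
        """Least squares in log10-time.

        With ``fix_exponent=True`` (the model) only the level -- hence
        D_eff -- is free; with ``fix_exponent=False`` the exponent of
        ``tE ~ x**b`` is estimated too (a diagnostic of the x^2 law).
        """
        logx = np.log10(self.place_m)
        logt = np.log10(self.te_min)
        if fix_exponent:
            y = logt - 2.0 * logx
            X = np.ones((y.size, 1))
            res = sm.OLS(y, X).fit()
            intercept = float(res.params[0])
            intercept_se = float(res.bse[0])
            exponent, exponent_se = 2.0, 0.0
        else:
            X = sm.add_constant(logx)
            res = sm.OLS(logt, X).fit()
            intercept = float(res.params[0])
            intercept_se = float(res.bse[0])
            exponent = float(res.params[1])
            exponent_se = float(res.bse[1])
        # intercept c satisfies tE_min = 10^c * x^b; for b = 2,
        # tE_sec = x^2/(4 D z^2)  =>  10^c * 60 = 1/(4 D z^2)
        d_eff = 1.0 / (4.0 * self.z**2 * 60.0 * 10.0**intercept)
        d_eff_se = d_eff * np.log(10.0) * intercept_se
        return DiffusionTrendResults(
            model=self,
            d_eff_m2_s=d_eff,
            d_eff_se=d_eff_se,
            exponent=exponent,
            exponent_se=exponent_se,
            intercept_log10_min=intercept,
            nobs=self.place_m.size,
            resid_db=20.0 * (logt - (intercept + exponent * logx)),
        )


@dataclass
class DiffusionTrendResults:
    """Fitted effect-time trend."""

    model: DiffusionTrend
    d_eff_m2_s: float
    d_eff_se: float
    exponent: float
    exponent_se: float
    intercept_log10_min: float
    nobs: int
    resid_db: np.ndarray

    def predict(self, place_m) -> np.ndarray:
        """Trend effect time tTrend [minutes] at the given places."""
        x = np.asarray(place_m, dtype=float)
        out = 10.0**self.intercept_log10_min * x**self.exponent
        return float(out) if np.isscalar(place_m) else out

    def conf_int(self, alpha: float = 0.05):
        """(lo, hi) for D_eff, normal on the log scale."""
        zq = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
        se_log10 = self.d_eff_se / (self.d_eff_m2_s * np.log(10.0))
        lo = self.d_eff_m2_s * 10.0 ** (-zq * se_log10)
        hi = self.d_eff_m2_s * 10.0 ** (+zq * se_log10)
        return lo, hi

    @property
    def resid_sd_db(self) -> float:
        return float(np.std(self.resid_db, ddof=1))

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Effect-time diffusion trend (log-space least squares)",
            "-" * 56,
            f"records (n)          : {self.nobs}",
            f"threshold fraction   : {self.model.threshold_fraction:g}",
            f"D_eff [m^2/s]        : {self.d_eff_m2_s:.4g} "
            f"(95% CI {lo:.4g} .. {hi:.4g})",
            f"exponent of tE ~ x^b : {self.exponent:.3f}"
            + ("" if self.exponent_se == 0 else f" +/- {self.exponent_se:.3f}")
            + ("  [fixed]" if self.exponent_se == 0 else ""),
            f"residual SD [dB]     : {self.resid_sd_db:.2f}",
        ]
        return "\n".join(lines)


def fit_diffusion_trend(records: pd.DataFrame, condition: str | None = "silence",
                        threshold_fraction: float = 0.01,
                        fix_exponent: bool = True) -> DiffusionTrendResults:
    """Convenience wrapper: build the model from records and fit it."""
    return DiffusionTrend.from_records(
        records, condition, threshold_fraction
    ).fit(fix_exponent=fix_exponent)


# ---------------------------------------------------------------------------
# grouped comparisons
# ---------------------------------------------------------------------------

@dataclass
class StratumComparison:
    name: str
    n_a: int
    n_b: int
    mean_a_db: float | None = None
    mean_b_db: float | None = None
    ci95_a: tuple | None = None
    ci95_b: tuple | None = None
    t_stat: float | None = None
    p_value: float | None = None
    computable: bool = False


@dataclass
class ComparisonResult:
    """Welch t-test comparison of dB-normalized effect times, per stratum."""

    strata: dict
    cf_split_hz: float
    n_excluded_a: int
    n_excluded_b: int

    def __getitem__(self, key):
        return self.strata[key]

    def summary(self) -> str:
        lines = [
            f"Effect-time comparison (Welch two-tailed t; CF split "
            f"{self.cf_split_hz / 1000:g} kHz)",
            "-" * 72,
            f"{'stratum':10s} {'n_a':>4s} {'n_b':>4s} {'mean_a':>8s} "
            f"{'mean_b':>8s} {'t':>7s} {'p':>10s}",
        ]
        for name, s in self.strata.items():
            if s.computable:
                lines.append(
                    f"{name:10s} {s.n_a:4d} {s.n_b:4d} {s.mean_a_db:8.2f} "
                    f"{s.mean_b_db:8.2f} {s.t_stat:7.2f} {s.p_value:10.3g}"
                )
            else:
                lines.append(f"{name:10s} {s.n_a:4d} {s.n_b:4d}   (not computable)")
        return "\n".join(lines)


def _mean_ci(x: np.ndarray):
    m = float(np.mean(x))
    if x.size < 2:
        return m, (np.nan, np.nan)
    half = scipy.stats.t.ppf(0.975, x.size - 1) * np.std(x, ddof=1) / np.sqrt(x.size)
    return m, (m - half, m + half)


def compare_groups(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    trend: DiffusionTrendResults,
    cf_split_hz: float = 4500.0,
) -> ComparisonResult:
    """Compare two record groups on trend-normalized effect times (dB).

    Strata: the whole CF range, low CF (<= split, the boundary going to the
    low stratum) and high CF (> split).  Records with unreached effect times
    (NaN) are excluded listwise and counted.  A stratum with fewer than two
    records in either group is marked not computable; the others are still
    returned.
    """

    def prep(df):
        n0 = len(df)
        df = df.dropna(subset=["te_min"])
        return df, n0 - len(df)

    a, excl_a = prep(records_a)
    b, excl_b = prep(records_b)
    if excl_a or excl_b:
        logger.info("excluded unreached effect times: %d (a), %d (b)", excl_a, excl_b)

    def db_values(df):
        return effect_time_db(
            df["te_min"].to_numpy(), trend.predict(df["place_m"].to_numpy())
        )

    strata = {}
    masks = {
        "whole": (np.ones(len(a), dtype=bool), np.ones(len(b), dtype=bool)),
        "low_cf": (
            a["cf_hz"].to_numpy() <= cf_split_hz,
            b["cf_hz"].to_numpy() <= cf_split_hz,
        ),
        "high_cf": (
            a["cf_hz"].to_numpy() > cf_split_hz,
            b["cf_hz"].to_numpy() > cf_split_hz,
        ),
    }
    for name, (ma, mb) in masks.items():
        da, db_ = a[ma], b[mb]
        s = StratumComparison(name=name, n_a=len(da), n_b=len(db_))
        if len(da) >= 2 and len(db_) >= 2:
            va, vb = db_values(da), db_values(db_)
            s.mean_a_db, s.ci95_a = _mean_ci(va)
            s.mean_b_db, s.ci95_b = _mean_ci(vb)
            t, p = scipy.stats.ttest_ind(va, vb, equal_var=False)
            s.t_stat, s.p_value = float(t), float(p)
            s.computable = True
        strata[name] = s
    return ComparisonResult(
        strata=strata,
        cf_split_hz=cf_split_hz,
        n_excluded_a=excl_a,
        n_excluded_b=excl_b,
    )
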