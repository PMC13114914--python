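"""Exponential tumor-growth kinetics: simulation, fitting, forecasting.

High-grade gliomas grow approximately exponentially over clinical
horizons, V(t) = V0 * exp(SGR * t), where SGR is the specific growth
rate (fraction per day; the clinically reported glioblastoma figure is
~1.4 %/day, doubling time ln2/SGR ~ 49.5 days).

Fitting is log-linear least squares — ln V = ln V0 + SGR * t — which is
closed-form and numerically stable; goodness-of-fit statistics (SSE,
MSE, RMSE, R^2) are reported on the natural volume scale against the
back-transformed curve, and 95 % prediction intervals come from the
log-scale residual variance with t_{n-2} quantiles, back-transformed.

The module follows the Model/Results idiom: build an
:class:`ExponentialGrowthModel` from data, call :meth:`fit`, and read
estimates, diagnostics, ``summary()``, ``forecast()`` and ``plot()``
from the returned :class:`ExponentialGrowthResults`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DEFAULT_SGR", "predict_volume", "doubling_time",
    "interpolate_two_points", "ExponentialGrowthModel",
    "ExponentialGrowthResults",
]

#: clinically reported glioblastoma specific growth rate (per day)
DEFAULT_SGR = 0.014


class InsufficientDataError(ValueError):
    """Fewer than three observations."""


def predict_volume(v0: float, sgr: float, t) -> np.ndarray | float:
    """V(t) = V0 * exp(SGR * t); exact exponential evaluation."""
    if v0 <= 0:
        raise ValueError("v0 must be > 0")
    t = np.asarray(t, dtype=float)
    out = v0 * np.exp(sgr * t)
    return float(out) if out.ndim == 0 else out


def doubling_time(sgr: float) -> float:
    """ln 2 / SGR in days (inf for a non-growing tumor)."""
    return np.inf if sgr == 0 else float(np.log(2.0) / sgr)


def interpolate_two_points(times, volumes) -> tuple[float, float]:
    """Exact (v0, sgr) of the exponential through two distinct points."""
    (t1, t2), (v1, v2) = np.asarray(times, float), np.asarray(volumes, float)
    if t1 == t2:
        raise ValueError("times must be distinct")
    sgr = float(np.log(v2 / v1) / (t2 - t1))
    v0 = float(v1 * np.exp(-sgr * t1))
    return v0, sgr


class ExponentialGrowthModel:
    """Exponential growth model for a longitudinal volume series.

    Parameters
    ----------
    times : array of days since baseline, strictly increasing
    volumes : array of tumor volumes in cc, all positive (>= 3 points)
    """

    def __init__(self, times, volumes):
        self.times = np.asarray(times, dtype=float)
        self.volumes = np.asarray(volumes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must be equal-length 1-D")
        if self.times.size < 3:
            raise InsufficientDataError(
                f"need >= 3 observations, got {self.times.size}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.volumes <= 0):
            raise ValueError("volumes must be positive")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "day",
                       volume_col: str = "volume_cc"
                       ) -> "ExponentialGrowthModel":
        return cls(df[time_col].to_numpy(), df[volume_col].to_numpy())

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ExponentialGrowthModel":
        return cls.from_dataframe(pd.read_csv(path), **kwargs)

    def fit(self) -> "ExponentialGrowthResults":
        """Log-linear OLS: ln V = ln V0 + SGR * t."""
        exog = sm.add_constant(self.times)
        ols = sm.OLS(np.log(self.volumes), exog).fit()
        return ExponentialGrowthResults(self, ols)


class ExponentialGrowthResults:
    """Estimates, fit statistics, and forecasts of an exponential fit."""

    def __init__(self, model: ExponentialGrowthModel, ols_results):
        self.model = model
        self._ols = ols_results
        self.v0_hat = float(np.exp(ols_results.params[0]))
        self.sgr_hat = float(ols_results.params[1])
        n = model.times.size
        fitted = self.predict(model.times)
        resid = model.volumes - fitted
        self.n = n
        self.sse = float(np.sum(resid ** 2))
        self.mse = self.sse / n
        self.rmse = float(np.sqrt(self.mse))
        ss_tot = float(np.sum((model.volumes - model.volumes.mean()) ** 2))
        self.r2 = 1.0 - self.sse / ss_tot if ss_tot > 0 else 1.0
        # log-scale residual variance, n-2 degrees of freedom
        self._log_sigma2 = float(ols_results.mse_resid) if n > 2 else 0.0

    # ------------------------------------------------------ prediction --
    def predict(self, t) -> np.ndarray | float:
        return predict_volume(self.v0_hat, self.sgr_hat, t)

    def prediction_interval(self, t, alpha: float = 0.05
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Back-transformed (1-alpha) prediction interval at times ``t``.

        Uses the log-scale OLS prediction variance (residual variance
        plus parameter uncertainty) with t_{n-2} quantiles; the band is
        degenerate (zero width) for a noise-free series.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        exog = sm.add_constant(t, has_constant="add")
        pred = self._ols.get_prediction(exog)
        se_obs = np.sqrt(pred.var_pred_mean + self._ols.mse_resid)
        q = stats.t.ppf(1 - alpha / 2.0, df=self._ols.df_resid)
        mean = pred.predicted_mean
        lo = np.exp(mean - q * se_obs)
        hi = np.exp(mean + q * se_obs)
        return lo, hi

    @property
    def doubling_time(self) -> float:
        """Implied volume doubling time ln2 / SGR (days)."""
        return doubling_time(self.sgr_hat)

    def forecast(self, horizon: float, n_points: int = 61,
                 alpha: float = 0.05) -> pd.DataFrame:
        """Extrapolate from the last observation over ``horizon`` days.

        Returns a frame (day, volume_cc, lower_cc, upper_cc); the
        prediction band widens monotonically with the horizon.
        """
        if horizon < 0:
            raise ValueError("horizon must be >= 0")
        t_last = self.model.times[-1]
        t = np.linspace(t_last, t_last + horizon, n_points) \
            if horizon > 0 else np.array([t_last])
        lo, hi = self.prediction_interval(t, alpha=alpha)
        return pd.DataFrame({"day": t, "volume_cc": self.predict(t),
                             "lower_cc": lo, "upper_cc": hi})

    # ------------------------------------------------------- reporting --
    def summary(self) -> str:
        lines = [
            "Exponential tumor-growth fit  V(t) = V0 * exp(SGR t)",
            "-" * 52,
            f"observations        {self.n}",
            f"V0 (cc)             {self.v0_hat:.4f}",
            f"SGR (/day)          {self.sgr_hat:.6f}",
            f"doubling time (d)   {self.doubling_time:.2f}",
            f"SSE (cc^2)          {self.sse:.4f}",
            f"MSE (cc^2)          {self.mse:.4f}",
            f"RMSE (cc)           {self.rmse:.4f}",
            f"R^2                 {self.r2:.6f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"v0_hat": self.v0_hat, "sgr_hat": self.sgr_hat,
                "doubling_time_days": self.doubling_time, "n": self.n,
                "sse": self.sse, "mse": self.mse, "rmse": self.rmse,
                "r2": self.r2}

    def plot(self, horizon: float = 0.0, ax=None):  # pragma: no cover
        """Observed points, fitted curve, and the 95 % prediction band."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        m = self.model
        t = np.linspace(m.times[0], m.times[-1] + horizon, 200)
        lo, hi = self.prediction_interval(t)
        ax.fill_between(t, lo, hi, alpha=0.2, label="95% PI")
        ax.plot(t, self.predict(t), label="fit")
        ax.plot(m.times, m.volumes, "k.", ms=4, label="observed")
        ax.set_xlabel("days"), ax.set_ylabel("volume (cc)")
        ax.legend()
        return ax
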