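"""Spectral EEG features: band powers, spectral balance, and the
Functional Health Vector / Index.

Band powers in the canonical Theta (4-7 Hz), Alpha (8-12 Hz) and Beta
(13-30 Hz) bands are integrated from a Welch power-spectral-density
estimate averaged over the EEG channels.  Two window-level summaries are
derived from them:

* the **spectral balance** FB_t, a logistic squashing of the log-ratio
  difference log(alpha/beta) - log(theta/alpha).  It rises toward 1 when
  the alpha rhythm dominates (relaxed cortical stability) and falls
  toward 0 under beta elevation (stress) or theta elevation (fatigue);

* the **Functional Health Index** FHI_t, a weighted mean of K=5 features
  (relative theta/alpha/beta power plus the two spectral ratios), each
  min-max standardised against a patient-specific baseline and clipped
  to [0, 1].  The default weights give alpha-linked features the largest
  say, reflecting alpha's association with stable cognitive equilibrium.

Both summaries are bounded in [0, 1] by construction and together form
the two-term Functional Health Vector FHV(t) = {FB_t, FHI_t} that feeds
the sequence decoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .eeg_preproc import EEGWindow

__all__ = [
    "BANDS", "BandPowerFeatures", "BaselineStats", "FunctionalHealthVector",
    "band_powers", "spectral_balance", "feature_vector", "normalize", "fhi",
    "fhv_from_windows", "feature_table",
]

BANDS = {"theta": (4.0, 7.0), "alpha": (8.0, 12.0), "beta": (13.0, 30.0)}

#: guard against zero denominators in spectral ratios
_EPS = 1e-12

#: FHI feature order; the spectral ratios enter on the log scale, the
#: standard transform for scale-free, heavy-tailed band-power ratios
FEATURE_NAMES = ("rel_theta", "rel_alpha", "rel_beta",
                 "log_ab_ratio", "log_ta_ratio")

#: default physiological weights; alpha-linked features weighted up
DEFAULT_WEIGHTS = np.array([1.0, 2.0, 1.0, 1.5, 1.0])


@dataclass
class BandPowerFeatures:
    """Integrated band powers (uV^2) and the derived spectral ratios."""

    theta: float
    alpha: float
    beta: float
    degenerate: bool = False

    @property
    def total(self) -> float:
        return self.theta + self.alpha + self.beta

    @property
    def alpha_beta_ratio(self) -> float:
        return self.alpha / (self.beta + _EPS)

    @property
    def theta_alpha_ratio(self) -> float:
        return self.theta / (self.alpha + _EPS)


@dataclass
class FunctionalHealthVector:
    fb: float
    fhi: float
    timestamp: float = 0.0
    degenerate: bool = False


def band_powers(window: EEGWindow | np.ndarray, fs: float | None = None
                ) -> BandPowerFeatures:
    """Welch band powers averaged over EEG channels.

    Accepts an :class:`EEGWindow` or a raw (channels, time) array plus
    ``fs``.  The PSD uses a Hann taper with segment length = half the
    window (two averaged segments), and band power is the rectangle-rule
    integral of the PSD over each band.  Windows shorter than 2 s are
    rejected: the 4-7 Hz band needs <= 0.5 Hz resolution under Welch
    halving to be integrated meaningfully.
    """
    if isinstance(window, EEGWindow):
        x = window.eeg_samples()
        fs = window.fs
    else:
        if fs is None:
            raise ValueError("fs required for raw arrays")
        x = np.atleast_2d(np.asarray(window, dtype=float))
    n = x.shape[1]
    if n < 2 * fs:
        raise ValueError(
            f"window of {n / fs:.2f} s too short for 0.5 Hz resolution")
    nperseg = n // 2
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                              axis=1)
    psd = psd.mean(axis=0)
    df = freqs[1] - freqs[0]
    powers = {}
    for name, (lo, hi) in BANDS.items():
        sel = (freqs >= lo) & (freqs <= hi)
        powers[name] = float(psd[sel].sum() * df)
    degenerate = sum(powers.values()) <= 0.0
    return BandPowerFeatures(theta=powers["theta"], alpha=powers["alpha"],
                             beta=powers["beta"], degenerate=degenerate)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def spectral_balance(features: BandPowerFeatures) -> float:
    """FB_t = logistic(log(alpha/beta) - log(theta/alpha)) in (0, 1).

    Monotonically increasing in the alpha/beta ratio and decreasing in
    the theta/alpha ratio.
    """
    ab = features.alpha_beta_ratio
    ta = features.theta_alpha_ratio
    return float(_logistic(np.log(ab + _EPS) - np.log(ta + _EPS)))


def feature_vector(features: BandPowerFeatures) -> np.ndarray:
    """The K=5 FHI feature vector: relative powers plus log spectral ratios.

    Ratios are log-transformed before baseline standardisation because
    band-power ratios are heavy-tailed; on the raw scale a single
    high-ratio baseline window would dominate the min-max range and
    squash every other window's standardised value toward 0.
    """
    total = features.total + _EPS
    return np.array([
        features.theta / total,
        features.alpha / total,
        features.beta / total,
        np.log(features.alpha_beta_ratio + _EPS),
        np.log(features.theta_alpha_ratio + _EPS),
    ])


@dataclass
class BaselineStats:
    """Patient-baseline statistics for feature standardisation.

    Fit from at least 10 reference windows.  ``weights`` are the
    physiological FHI weights w_i >= 0 with a positive sum.
    """

    mean: np.ndarray
    std: np.ndarray
    min: np.ndarray
    max: np.ndarray
    weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_WEIGHTS.copy())
    n_windows: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")

    @classmethod
    def fit(cls, feature_rows: np.ndarray,
            weights: np.ndarray | None = None) -> "BaselineStats":
        rows = np.atleast_2d(np.asarray(feature_rows, dtype=float))
        if rows.shape[0] < 10:
            raise ValueError(
                f"baseline needs >= 10 windows, got {rows.shape[0]}")
        return cls(mean=rows.mean(axis=0), std=rows.std(axis=0, ddof=1),
                   min=rows.min(axis=0), max=rows.max(axis=0),
                   weights=DEFAULT_WEIGHTS.copy() if weights is None
                   else np.asarray(weights, dtype=float),
                   n_windows=rows.shape[0])


def normalize(features: BandPowerFeatures | np.ndarray,
              baseline: BaselineStats, mode: str = "minmax"
              ) -> tuple[np.ndarray, np.ndarray]:
    """Standardise a feature vector against the baseline.

    ``zscore`` returns (x - mean)/std; ``minmax`` returns
    (x - min)/(max - min) clipped to [0, 1].  Returns the standardised
    vector and a boolean mask of degenerate features (zero baseline
    spread), which are set to 0 (z-score) or 0.5 (min-max).
    """
    x = (feature_vector(features) if isinstance(features, BandPowerFeatures)
         else np.asarray(features, dtype=float))
    if mode == "zscore":
        spread = baseline.std
        degenerate = spread <= 0
        safe = np.where(degenerate, 1.0, spread)
        z = (x - baseline.mean) / safe
        return np.where(degenerate, 0.0, z), degenerate
    if mode == "minmax":
        spread = baseline.max - baseline.min
        degenerate = spread <= 0
        safe = np.where(degenerate, 1.0, spread)
        z = np.clip((x - baseline.min) / safe, 0.0, 1.0)
        return np.where(degenerate, 0.5, z), degenerate
    raise ValueError(f"unknown mode {mode!r}")


def fhi(features: BandPowerFeatures | np.ndarray,
        baseline: BaselineStats) -> float:
    """FHI_t = sum_i w_i phi_i(t) / sum_i w_i, in [0, 1].

    ``features`` may be a :class:`BandPowerFeatures` or a raw K-vector.
    phi_i are the min-max standardised (clipped) features, so the
    weighted mean is bounded; it is invariant to rescaling all weights.
    """
    phi, _ = normalize(features, baseline, mode="minmax")
    w = baseline.weights
    return float(np.dot(w, phi) / w.sum())


def fhv_from_windows(windows, baseline: BaselineStats
                     ) -> list[FunctionalHealthVector]:
    """Compute the two-term FHV for each analysis window."""
    out = []
    for w in windows:
        bp = band_powers(w)
        out.append(FunctionalHealthVector(
            fb=spectral_balance(bp), fhi=fhi(bp, baseline),
            timestamp=w.start_time + w.length / 2.0,
            degenerate=bp.degenerate))
    return out


def feature_table(windows, baseline: BaselineStats | None = None
                  ) -> pd.DataFrame:
    """Per-window feature table (timestamp, band powers, ratios, FB, FHI)."""
    rows = []
    for w in windows:
        bp = band_powers(w)
        row = {
            "timestamp": w.start_time + w.length / 2.0,
            "theta": bp.theta, "alpha": bp.alpha, "beta": bp.beta,
            "ab_ratio": bp.alpha_beta_ratio, "ta_ratio": bp.theta_alpha_ratio,
            "fb": spectral_balance(bp),
            "state": w.state_label,
        }
        if baseline is not None:
            row["fhi"] = fhi(bp, baseline)
        rows.append(row)
    return pd.DataFrame(rows)
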