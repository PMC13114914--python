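"""EEG preprocessing: bandpass/notch filtering, LMS EOG decorrelation,
50 %-overlap windowing, and SNR reporting.

The artifact-removal chain mirrors the standard edge-side EEG pipeline:

1. zero-phase Butterworth bandpass (default 0.5-45 Hz) to remove drift and
   high-frequency noise,
2. zero-phase IIR notch at the power-line frequency (50/60 Hz),
3. a single-tap least-mean-squares (LMS) adaptive filter that subtracts
   the component of each EEG channel that projects linearly onto a shared
   EOG reference r(t):

       e(t)   = y(t) - a(t) * r(t)
       a(t+1) = a(t) + mu * e(t) * r(t)          (plain LMS)

   The normalised variant divides the update by a running estimate of the
   reference power, which keeps the step size stable regardless of EOG
   amplitude; it is the default because the plain recursion's stability
   bound depends on the (unknown) input power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "EEGRecord", "LMSState", "EEGWindow",
    "bandpass", "notch", "lms_denoise", "segment", "snr_db",
    "DataError", "StabilityError",
]

#: cap applied when the residual is exactly zero (dB)
SNR_CAP_DB = 300.0


class DataError(ValueError):
    """Input data violates a precondition (non-finite, too short, ...)."""


class StabilityError(RuntimeError):
    """The adaptive filter diverged."""


@dataclass
class EEGRecord:
    """A multichannel EEG recording in microvolts.

    ``samples`` is (channels, time).  ``eog_channel`` indexes the EOG
    reference row, if present.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list | None = None
    eog_channel: int | None = None

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise DataError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(self.n_channels)]
        if self.eog_channel is not None and not (
                0 <= self.eog_channel < self.n_channels):
            raise DataError(f"eog_channel {self.eog_channel} out of range")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def eeg_channel_indices(self) -> np.ndarray:
        idx = np.arange(self.n_channels)
        if self.eog_channel is not None:
            idx = idx[idx != self.eog_channel]
        return idx

    def copy_with(self, samples: np.ndarray) -> "EEGRecord":
        return EEGRecord(samples=samples, fs=self.fs,
                         channel_labels=list(self.channel_labels),
                         eog_channel=self.eog_channel)


@dataclass
class LMSState:
    """Per-channel scalar LMS coefficients and the learning rate."""

    a_hat: np.ndarray
    mu: float = 0.01
    normalized: bool = True

    def __post_init__(self):
        self.a_hat = np.atleast_1d(np.asarray(self.a_hat, dtype=float))
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if not np.all(np.isfinite(self.a_hat)):
            raise ValueError("a_hat must be finite")


@dataclass
class EEGWindow:
    """A fixed-length analysis window cut from a record."""

    samples: np.ndarray          # (channels, L*fs)
    fs: float
    start_time: float
    length: float                # seconds
    eog_channel: int | None = None
    state_label: str | None = None

    @property
    def step(self) -> float:
        return 0.5 * self.length

    def eeg_samples(self) -> np.ndarray:
        if self.eog_channel is None:
            return self.samples
        keep = np.arange(self.samples.shape[0]) != self.eog_channel
        return self.samples[keep]


def read_edf(path, eog_label: str | None = None) -> EEGRecord:
    """Load a European Data Format recording (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional mne "
                          "dependency (pip install neurotwin[io])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    eog = labels.index(eog_label) if eog_label in labels else None
    return EEGRecord(samples=raw.get_data() * 1e6,  # volts -> microvolts
                     fs=float(raw.info["sfreq"]), channel_labels=labels,
                     eog_channel=eog)


# ------------------------------------------------------------- filters --
def bandpass(record: EEGRecord, low: float = 0.5, high: float = 45.0,
             order: int = 4) -> EEGRecord:
    """Zero-phase Butterworth bandpass applied to every channel."""
    nyq = record.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for fs={record.fs} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass",
                        fs=record.fs, output="sos")
    out = signal.sosfiltfilt(sos, record.samples, axis=1)
    return record.copy_with(out)


def notch(record: EEGRecord, line_freq: float = 50.0,
          quality: float = 30.0) -> EEGRecord:
    """Zero-phase IIR notch at the power-line frequency (50 or 60 Hz)."""
    if line_freq not in (50.0, 60.0, 50, 60):
        raise ValueError("line_freq must be 50 or 60 Hz")
    b, a = signal.iirnotch(line_freq, quality, fs=record.fs)
    out = signal.filtfilt(b, a, record.samples, axis=1)
    return record.copy_with(out)


# ----------------------------------------------------------------- LMS --
#: divergence bound on |a_hat|; EOG projection gains are O(1)
_A_BOUND = 1e6


def lms_denoise(record: EEGRecord, state: LMSState | None = None,
                mu: float = 0.01, normalized: bool = True,
                return_trajectory: bool = False):
    """Sample-by-sample LMS decorrelation of every EEG channel against r(t).

    Returns the denoised record (EOG row passed through unchanged) and the
    adapted filter state.  The recursion per channel c is

        e_c(t)   = y_c(t) - a_c(t) * r(t)
        a_c(t+1) = a_c(t) + mu * e_c(t) * r(t) [/ (p(t) + eps) if normalized]

    where p(t) is an exponential moving average of r(t)^2.  With
    ``return_trajectory`` the per-sample coefficient path (channels x T)
    is returned as a third value; the steady-state coefficient is best
    read as a time average of its tail, since the instantaneous a(t)
    fluctuates around the least-squares projection with variance
    proportional to mu.
    """
    if record.eog_channel is None:
        raise DataError("record has no EOG reference channel")
    eeg_idx = record.eeg_channel_indices()
    y = record.samples[eeg_idx]
    r = record.samples[record.eog_channel]
    if state is None:
        state = LMSState(a_hat=np.zeros(len(eeg_idx)), mu=mu,
                         normalized=normalized)
    a = state.a_hat.astype(float).copy()
    if a.shape != (len(eeg_idx),):
        raise ValueError("a_hat length does not match EEG channel count")

    e = np.empty_like(y)
    traj = np.empty_like(y) if return_trajectory else None
    p = float(np.mean(r[:min(100, len(r))] ** 2))  # power warm start
    eps = 1e-12
    lam = 0.999                                    # power-EMA forgetting
    for t in range(y.shape[1]):
        rt = r[t]
        et = y[:, t] - a * rt
        e[:, t] = et
        if state.normalized:
            p = lam * p + (1 - lam) * rt * rt
            a += state.mu * et * rt / (p + eps)
        else:
            a += state.mu * et * rt
        if traj is not None:
            traj[:, t] = a
        if t % 1000 == 0 and np.max(np.abs(a)) > _A_BOUND:
            raise StabilityError(
                f"LMS diverged (|a|>{_A_BOUND:g}); reduce mu={state.mu}")
    if np.max(np.abs(a)) > _A_BOUND or not np.all(np.isfinite(a)):
        raise StabilityError(
            f"LMS diverged (|a|>{_A_BOUND:g}); reduce mu={state.mu}")

    out = record.samples.copy()
    out[eeg_idx] = e
    final = LMSState(a_hat=a, mu=state.mu, normalized=state.normalized)
    if return_trajectory:
        return record.copy_with(out), final, traj
    return record.copy_with(out), final


def denoise_chain(record: EEGRecord, low: float = 0.5, high: float = 45.0,
                  line_freq: float = 50.0, mu: float = 0.01
                  ) -> tuple[EEGRecord, LMSState]:
    """Bandpass -> notch -> LMS, the full edge-side denoising chain.

    The EOG reference row is bandpass-filtered along with the EEG channels
    (it must share the passband so in-band EOG leakage can be subtracted)
    but the notch is irrelevant to it.
    """
    filtered = notch(bandpass(record, low, high), line_freq)
    return lms_denoise(filtered, mu=mu)


# ----------------------------------------------------------- windowing --
def segment(record: EEGRecord, window_len: float = 2.0,
            state_of_time=None) -> list[EEGWindow]:
    """Cut the record into 50 %-overlap windows of ``window_len`` seconds.

    Windows are anchored at t=0 with step S = 0.5 L; a trailing partial
    window is dropped.  ``state_of_time``, if given, maps the window
    midpoint time to a state label.
    """
    if not (2.0 <= window_len <= 5.0):
        raise ValueError(f"window_len must be in [2, 5] s, got {window_len}")
    n_win = int(round(window_len * record.fs))
    step = n_win // 2
    if record.n_samples < n_win:
        raise DataError(
            f"record ({record.duration:.2f} s) shorter than one window")
    windows = []
    start = 0
    while start + n_win <= record.n_samples:
        t0 = start / record.fs
        label = None
        if state_of_time is not None:
            label = state_of_time(t0 + window_len / 2.0)
        windows.append(EEGWindow(
            samples=record.samples[:, start:start + n_win].copy(),
            fs=record.fs, start_time=t0, length=window_len,
            eog_channel=record.eog_channel, state_label=label))
        start += step
    return windows


# ----------------------------------------------------------------- SNR --
def snr_db(clean: np.ndarray, sig: np.ndarray) -> float:
    """10*log10(P_clean / P_residual) where residual = sig - clean.

    Inputs may be 1-D or (channels, time); power is pooled over everything.
    A zero residual returns the documented cap instead of +inf.
    """
    clean = np.asarray(clean, dtype=float)
    sig = np.asarray(sig, dtype=float)
    if clean.shape != sig.shape:
        raise ValueError(f"shape mismatch {clean.shape} vs {sig.shape}")
    p_clean = float(np.mean(clean ** 2))
    if p_clean == 0.0:
        raise DataError("clean signal has zero power; SNR undefined")
    p_res = float(np.mean((sig - clean) ** 2))
    if p_res == 0.0:
        return SNR_CAP_DB
    return min(10.0 * np.log10(p_clean / p_res), SNR_CAP_DB)
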