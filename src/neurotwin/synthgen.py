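"""Synthetic EEG, MRI phantom, and tumor-volume generators.

These generators provide data with the statistical structure the rest of
the pipeline assumes, so every downstream stage (denoising, spectral
features, state decoding, patch-transformer segmentation, growth-kinetics
fitting) can be exercised and validated without any recorded data.

EEG model
---------
Each cognitive state is expressed as a band-limited oscillation on every
EEG channel: a ~10 Hz alpha rhythm for *Relaxed*, a 13-30 Hz beta rhythm
for *Stress*, and a 4-7 Hz theta rhythm for *Fatigue* — the canonical
spectral signatures of those states.  Channels are contaminated by a
shared electro-oculographic (EOG) reference mixed in with a per-channel
gain, a power-line sinusoid, and white sensor noise:

    x_c(t) = s_c(t) + g_c * r(t) + A * sin(2*pi*f_line*t + phi) + n_c(t)

The clean state signal ``s_c`` and the EOG reference ``r`` are returned
separately so tests can check the denoising chain against ground truth.
The EOG reference is a sub-4 Hz process — smoothed random blink
deflections plus a slow drift — because ocular artifacts live below the
EEG bands of interest and are removed by decorrelation, not by spectral
filtering.

MRI phantom model
-----------------
Grayscale slices with a uniform background, additive Gaussian noise, and
zero or more bright circular "tumor" discs.  A patch is labelled tumor
when the disc covers more than half of the patch's area.

Volume model
------------
Exponential growth V(t) = V0 * exp(SGR * t) with additive Gaussian noise,
truncated to stay positive.  The default specific growth rate of 1.4 %/day
is the clinically reported figure for glioblastoma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eeg_preproc import EEGRecord

__all__ = [
    "STATES", "SynthEEGSpec", "SynthEEG", "generate_eeg",
    "SynthPhantomSpec", "Phantom", "generate_phantom",
    "SynthVolumeSpec", "generate_volume_series",
    "write_eeg_text", "write_volume_csv", "write_phantom_png",
]

STATES = ("Relaxed", "Stress", "Fatigue")

#: per-state frequency band (Hz) from which the dominant rhythm is drawn
_STATE_BANDS = {"Relaxed": (9.0, 11.0), "Stress": (15.0, 25.0),
                "Fatigue": (4.5, 6.5)}

DEFAULT_CHANNELS = ("Fz", "Cz", "C3", "C4", "Pz")


class ScheduleError(ValueError):
    """State intervals overlap or do not cover the recording."""


class ParameterError(ValueError):
    """A generator parameter is outside its valid range."""


# ----------------------------------------------------------------- EEG --
@dataclass
class SynthEEGSpec:
    """Specification for a synthetic multichannel EEG recording.

    Amplitudes are in microvolts.  The default rhythm amplitude (10 uV)
    and sensor-noise SD (2 uV) correspond to a clean laboratory recording;
    the default EOG gain (0.8) and line amplitude (15 uV) give raw traces
    visibly dominated by artifact, as wearable dry-electrode EEG is.
    """

    duration: float
    fs: float = 500.0
    n_eeg_channels: int = 5
    channel_labels: tuple = DEFAULT_CHANNELS
    state_schedule: list | None = None          # [(state, start_s, end_s)]
    rhythm_amplitude: float = 10.0
    line_freq: float = 50.0
    line_amplitude: float = 15.0
    eog_gain: float | np.ndarray = 0.8
    eog_amplitude: float = 60.0
    blink_rate: float = 0.25                    # blinks per second
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.fs < 100:
            raise ParameterError(f"fs={self.fs} Hz; need fs >= 100 Hz")
        if self.line_freq not in (50.0, 60.0, 50, 60):
            raise ParameterError("line_freq must be 50 or 60 Hz")
        if self.state_schedule is None:
            self.state_schedule = [("Relaxed", 0.0, self.duration)]
        gains = np.broadcast_to(np.asarray(self.eog_gain, dtype=float),
                                (self.n_eeg_channels,))
        if not np.all(np.isfinite(gains)):
            raise ParameterError("eog_gain must be finite")
        self._validate_schedule()

    def _validate_schedule(self):
        ivals = sorted(self.state_schedule, key=lambda iv: iv[1])
        cursor = 0.0
        for state, start, end in ivals:
            if state not in STATES:
                raise ScheduleError(f"unknown state {state!r}")
            if start < cursor - 1e-9:
                raise ScheduleError("state intervals overlap")
            if abs(start - cursor) > 1e-9:
                raise ScheduleError("state intervals leave a gap")
            cursor = end
        if abs(cursor - self.duration) > 1e-9:
            raise ScheduleError("state schedule does not cover [0, duration]")

    def state_at(self, t: float) -> str:
        for state, start, end in self.state_schedule:
            if start <= t < end or (t == end == self.duration):
                return state
        raise ScheduleError(f"time {t} outside schedule")


@dataclass
class SynthEEG:
    """A generated recording plus the ground truth behind it."""

    record: EEGRecord               # contaminated channels + EOG reference row
    clean: np.ndarray               # (n_eeg_channels, T) state signal only
    eog: np.ndarray                 # (T,) EOG reference r(t)
    spec: SynthEEGSpec

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.record.n_samples) / self.record.fs

    def state_labels(self, times: np.ndarray) -> np.ndarray:
        return np.array([self.spec.state_at(float(t)) for t in times])


def _eog_reference(rng: np.random.Generator, n: int, fs: float,
                   amplitude: float, blink_rate: float) -> np.ndarray:
    """Smoothed random blink deflections plus slow drift, all < 4 Hz."""
    r = np.zeros(n)
    t = np.arange(n) / fs
    expected = blink_rate * n / fs
    n_blinks = rng.poisson(expected)
    width = 0.15  # blink half-width in seconds
    for _ in range(n_blinks):
        center = rng.uniform(0, n / fs)
        amp = amplitude * rng.uniform(0.6, 1.4)
        r += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    # slow drift: two random low-frequency cosines (< 0.5 Hz)
    for _ in range(2):
        f = rng.uniform(0.05, 0.4)
        r += 0.2 * amplitude * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return r


def generate_eeg(spec: SynthEEGSpec) -> SynthEEG:
    """Generate a contaminated EEG recording with known ground truth.

    Deterministic under a fixed ``spec.seed``.  The returned record has
    ``n_eeg_channels + 1`` rows; the last row is the EOG reference and
    ``record.eog_channel`` points at it.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    C = spec.n_eeg_channels

    clean = np.zeros((C, n))
    for state, start, end in spec.state_schedule:
        lo, hi = _STATE_BANDS[state]
        i0, i1 = int(round(start * spec.fs)), int(round(end * spec.fs))
        for c in range(C):
            f = rng.uniform(lo, hi)
            phase = rng.uniform(0, 2 * np.pi)
            amp = spec.rhythm_amplitude * rng.uniform(0.8, 1.2)
            clean[c, i0:i1] = amp * np.sin(2 * np.pi * f * t[i0:i1] + phase)

    eog = _eog_reference(rng, n, spec.fs, spec.eog_amplitude, spec.blink_rate)
    gains = np.broadcast_to(np.asarray(spec.eog_gain, dtype=float), (C,))
    line = spec.line_amplitude * np.sin(
        2 * np.pi * spec.line_freq * t + rng.uniform(0, 2 * np.pi))
    noise = rng.normal(0.0, spec.noise_sd, size=(C, n)) if spec.noise_sd > 0 \
        else np.zeros((C, n))

    contaminated = clean + gains[:, None] * eog[None, :] + line[None, :] + noise
    samples = np.vstack([contaminated, eog[None, :]])
    record = EEGRecord(samples=samples, fs=spec.fs,
                       channel_labels=list(spec.channel_labels[:C]) + ["EOG"],
                       eog_channel=C)
    return SynthEEG(record=record, clean=clean, eog=eog, spec=spec)


# ------------------------------------------------------------- phantom --
@dataclass
class SynthPhantomSpec:
    """Specification for a grayscale tumor phantom slice.

    Intensities are on a [0, 1] gray scale; the default background of 0.25
    with a +0.35 tumor offset mimics the contrast of an enhancing lesion
    against parenchyma.
    """

    image_size: int = 64
    patch_size: int = 16
    tumor_count: int = 1
    tumor_radius_range: tuple = (12.0, 20.0)
    tumor_intensity_delta: float = 0.35
    background: float = 0.25
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ParameterError(
                f"image_size {self.image_size} not divisible by patch size "
                f"{self.patch_size}")
        if self.tumor_count < 0:
            raise ParameterError("tumor_count must be >= 0")
        rmax = self.tumor_radius_range[1]
        if 2 * rmax > self.image_size:
            raise ParameterError("tumor discs must fit inside the image")


@dataclass
class Phantom:
    image: np.ndarray        # (H, W) float gray levels
    patch_labels: np.ndarray  # (H/P, W/P) int {0,1}
    pixel_mask: np.ndarray   # (H, W) bool, True inside a tumor disc
    spec: SynthPhantomSpec

    @property
    def slice_label(self) -> int:
        return int(self.patch_labels.any())


def patch_overlap_fractions(pixel_mask: np.ndarray, patch_size: int
                            ) -> np.ndarray:
    """Fraction of each P x P patch covered by the mask (row-major grid)."""
    H, W = pixel_mask.shape
    P = patch_size
    return pixel_mask.reshape(H // P, P, W // P, P).mean(axis=(1, 3))


def generate_phantom(spec: SynthPhantomSpec) -> Phantom:
    """Generate a phantom slice; patch label = 1 iff disc overlap > 50 %."""
    rng = np.random.default_rng(spec.seed)
    H = W = spec.image_size
    yy, xx = np.mgrid[0:H, 0:W]
    mask = np.zeros((H, W), dtype=bool)
    for _ in range(spec.tumor_count):
        r = rng.uniform(*spec.tumor_radius_range)
        cy = rng.uniform(r, H - r)
        cx = rng.uniform(r, W - r)
        mask |= (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= r ** 2
    image = np.full((H, W), spec.background)
    image[mask] += spec.tumor_intensity_delta
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(H, W))
    frac = patch_overlap_fractions(mask, spec.patch_size)
    labels = (frac > 0.5).astype(int)
    return Phantom(image=image, patch_labels=labels, pixel_mask=mask, spec=spec)


def generate_phantom_dataset(n: int, tumor_fraction: float = 0.5,
                             seed: int = 0, **spec_kwargs) -> list[Phantom]:
    """A cohort of phantoms, a fixed fraction of which contain tumors."""
    rng = np.random.default_rng(seed)
    phantoms = []
    for i in range(n):
        has_tumor = i < int(round(n * tumor_fraction))
        sub = int(rng.integers(0, 2 ** 31 - 1))
        phantoms.append(generate_phantom(SynthPhantomSpec(
            tumor_count=1 if has_tumor else 0, seed=sub, **spec_kwargs)))
    order = rng.permutation(n)
    return [phantoms[i] for i in order]


# -------------------------------------------------------------- volume --
@dataclass
class SynthVolumeSpec:
    """Specification for a longitudinal tumor-volume series (cc vs days)."""

    v0: float = 50.0
    sgr: float = 0.014            # specific growth rate, per day
    n_points: int = 151
    interval: float = 1.0         # days between measurements
    noise_sd: float = 3.0         # cc
    seed: int = 0

    def __post_init__(self):
        if self.v0 <= 0:
            raise ParameterError("v0 must be > 0")
        if self.sgr < 0:
            raise ParameterError("sgr must be >= 0")
        if self.n_points < 3:
            raise ParameterError("need n_points >= 3")


def generate_volume_series(spec: SynthVolumeSpec) -> pd.DataFrame:
    """V_i = v0*exp(sgr*t_i) + eps_i, eps ~ N(0, noise_sd^2), kept positive.

    Returns a DataFrame with columns ``day`` and ``volume_cc``.  Noise draws
    that would make a volume non-positive are redrawn (truncation).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_points) * spec.interval
    v_true = spec.v0 * np.exp(spec.sgr * t)
    v = v_true.copy()
    if spec.noise_sd > 0:
        eps = rng.normal(0.0, spec.noise_sd, size=spec.n_points)
        v = v_true + eps
        bad = v <= 0
        while bad.any():
            v[bad] = v_true[bad] + rng.normal(0.0, spec.noise_sd, bad.sum())
            bad = v <= 0
    return pd.DataFrame({"day": t, "volume_cc": v})


# ------------------------------------------------------------- writers --
def write_eeg_text(synth: SynthEEG, path) -> None:
    """Columnar text export: time_s then one column per channel (uV)."""
    rec = synth.record
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.insert(0, "time_s", synth.times)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_volume_csv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False, columns=["day", "volume_cc"])


def write_phantom_png(phantom: Phantom, path) -> None:
    """8-bit PNG export (requires imageio)."""
    import imageio.v3 as iio
    img = np.clip(phantom.image, 0.0, 1.0)
    iio.imwrite(path, (img * 255).astype(np.uint8))


def write_phantom_nifti(phantom: Phantom, path,
                        pixel_mm: float = 1.0) -> None:
    """Single-slice NIfTI export (requires nibabel)."""
    import nibabel as nib
    affine = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
    img = nib.Nifti1Image(phantom.image[..., None].astype(np.float32),
                          affine)
    nib.save(img, str(path))


def read_nifti_slices(path) -> np.ndarray:
    """Load a NIfTI volume as a (slices, H, W) stack (requires nibabel)."""
    import nibabel as nib
    data = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim == 2:
        data = data[..., None]
    return np.moveaxis(data, -1, 0)
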