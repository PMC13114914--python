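"""End-to-end helpers wiring the EEG chain into datasets and reports.

The functions here are thin orchestration: generate synthetic recordings,
run the denoising chain, segment into 50 %-overlap windows, extract FHV
features, and package them as labelled sequences for the state decoder.
Splits are subject-disjoint (each recording is one synthetic subject) and
the feature baseline is fitted on training subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import synthgen
from .eeg_preproc import denoise_chain, segment
from .eeg_features import (BaselineStats, band_powers, feature_vector,
                           spectral_balance, fhi)
from .state_bilstm import StateSequence, STATE_ORDER

__all__ = ["StateCohort", "build_state_cohort"]


@dataclass
class StateCohort:
    """Subject-disjoint train/test FHV sequences plus the fitted baseline."""

    train: list[StateSequence]
    test: list[StateSequence]
    baseline: BaselineStats


def _sequence_duration(windows_per_seq: int, window_len: float) -> float:
    # n windows at 50 % overlap need (n + 1) * L / 2 seconds
    return (windows_per_seq + 1) * window_len / 2.0


def build_state_cohort(n_per_class: int = 12, windows_per_seq: int = 30,
                       window_len: float = 2.0, seed: int = 0,
                       test_fraction: float = 0.3, denoise: bool = True,
                       **eeg_overrides) -> StateCohort:
    """Generate a balanced three-state cohort of FHV sequences.

    Each synthetic subject contributes one single-state recording long
    enough for ``windows_per_seq`` windows.  The full chain (bandpass,
    notch, LMS decorrelation) runs before feature extraction unless
    ``denoise`` is disabled.  The min-max feature baseline for the FHI is
    fitted on training windows pooled across states.
    """
    rng = np.random.default_rng(seed)
    duration = _sequence_duration(windows_per_seq, window_len)
    per_subject: list[tuple[str, np.ndarray, np.ndarray]] = []
    for state in STATE_ORDER:
        for _ in range(n_per_class):
            spec = synthgen.SynthEEGSpec(
                duration=duration,
                state_schedule=[(state, 0.0, duration)],
                seed=int(rng.integers(0, 2 ** 31 - 1)),
                **eeg_overrides)
            synth = synthgen.generate_eeg(spec)
            record = synth.record
            if denoise:
                record, _ = denoise_chain(
                    record, line_freq=spec.line_freq)
            windows = segment(record, window_len,
                              state_of_time=spec.state_at)
            bps = [band_powers(w) for w in windows]
            rows = np.array([feature_vector(bp) for bp in bps])
            fbs = np.array([spectral_balance(bp) for bp in bps])
            per_subject.append((state, rows, fbs, bps))

    n_test = max(1, int(round(n_per_class * test_fraction)))
    train_sub, test_sub = [], []
    for ci, state in enumerate(STATE_ORDER):
        block = per_subject[ci * n_per_class:(ci + 1) * n_per_class]
        test_sub.extend(block[:n_test])
        train_sub.extend(block[n_test:])

    baseline = BaselineStats.fit(
        np.vstack([rows for _, rows, _, _ in train_sub]))

    def to_sequences(subjects):
        seqs = []
        for state, _rows, fbs, bps in subjects:
            fhis = np.array([fhi(bp, baseline) for bp in bps])
            inputs = np.column_stack([fbs, fhis])
            seqs.append(StateSequence(
                inputs=inputs, labels=np.full(len(inputs), state)))
        return seqs

    return StateCohort(train=to_sequences(train_sub),
                       test=to_sequences(test_sub), baseline=baseline)
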