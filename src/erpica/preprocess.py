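"""Epoch-level cleaning: re-referencing, artifact rejection, averaging,
and projection-based removal of decomposition components.

Rejection implements three automatic rules on raw epochs, each applied
per channel with a strict threshold (values exactly at threshold are
kept):

* amplitude: max |x| > 100 uV anywhere in the epoch;
* fast activity: max |x| of the 20-35 Hz band-passed trace > 35 uV;
* slow activity: max |x| of the 0-1 Hz low-passed trace > 50 uV.

Band-limited amplitude is measured as the peak absolute value of a
4th-order zero-phase Butterworth filtered trace; an epoch violating any
rule is dropped whole.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .synth import EpochSet

AMPLITUDE_THRESHOLD_UV = 100.0
FAST_BAND_HZ = (20.0, 35.0)
FAST_THRESHOLD_UV = 35.0
SLOW_CUTOFF_HZ = 1.0
SLOW_THRESHOLD_UV = 50.0


def rereference_average(data: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every time point.

    Idempotent and linear; errors on single-channel input, for which an
    average reference would null the signal.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("average reference needs a channels x samples matrix with >= 2 channels")
    return data - data.mean(axis=0, keepdims=True)


def _band_trace(x: np.ndarray, fs: float, band: tuple[float, float] | None, cutoff: float | None) -> np.ndarray:
    if band is not None:
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    else:
        sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def epoch_rejection_reasons(epoch: np.ndarray, fs: float) -> tuple[str, ...]:
    """Reason codes ('amplitude', 'fast', 'slow') violated by one epoch."""
    if fs / 2.0 <= FAST_BAND_HZ[1]:
        raise ValueError(f"sampling rate {fs} Hz cannot resolve the {FAST_BAND_HZ} Hz band")
    reasons = []
    if np.max(np.abs(epoch)) > AMPLITUDE_THRESHOLD_UV:
        reasons.append("amplitude")
    if np.max(np.abs(_band_trace(epoch, fs, FAST_BAND_HZ, None))) > FAST_THRESHOLD_UV:
        reasons.append("fast")
    if np.max(np.abs(_band_trace(epoch, fs, None, SLOW_CUTOFF_HZ))) > SLOW_THRESHOLD_UV:
        reasons.append("slow")
    return tuple(reasons)


def reject_epochs(epochs: EpochSet) -> EpochSet:
    """Mark epochs violating any of the three artifact rules."""
    reasons = [epoch_rejection_reasons(e, epochs.sampling_rate_hz) for e in epochs.epochs]
    rejected = np.array([len(r) > 0 for r in reasons], dtype=bool)
    return dataclasses.replace(epochs, rejected=rejected, reasons=reasons)


def average_epochs(epochs: EpochSet, mask_aware: bool = True) -> np.ndarray:
    """Element-wise mean over the surviving (or all) epochs."""
    if mask_aware:
        kept = [e for e, rej in zip(epochs.epochs, epochs.rejected) if not rej]
    else:
        kept = list(epochs.epochs)
    if not kept:
        raise ValueError("all epochs rejected: subject unusable")
    return np.mean(np.stack(kept), axis=0)


def remove_components(P: np.ndarray, model, indices) -> np.ndarray:
    """Zero the activation of selected components: (I - sum F_i) P.

    The equivalent of eyeblink correction by zeroing activation curves,
    for any supplied decomposition.
    """
    P = np.asarray(P, dtype=float)
    indices = list(indices)
    for i in indices:
        if not (0 <= i < model.n_components):
            raise IndexError(f"component index {i} out of range 0..{model.n_components - 1}")
    out = P.copy()
    for i in indices:
        out -= model.spatial_filter(i) @ P
    return out
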