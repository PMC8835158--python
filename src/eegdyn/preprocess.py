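"""Continuous-recording containers and the preprocessing chain.

A raw multichannel recording is band-pass filtered (zero-phase FIR),
notch filtered, cut into fixed-length non-overlapping epochs,
re-referenced to the common average, and screened for high-amplitude
artifacts.  Eye/muscle artifact removal by manual independent-component
inspection is deliberately not offered; a deterministic peak-amplitude
epoch rejection stands in its place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .montage import ChannelMontage

__all__ = [
    "Recording",
    "EpochSet",
    "bandpass_filter",
    "notch_filter",
    "epoch",
    "rereference_average",
    "reject_artifacts",
    "preprocess",
]


@dataclass(frozen=True)
class Recording:
    """Continuous multichannel EEG.

    ``data`` is a ``(n_samples, n_channels)`` array in microvolts.
    """

    data: np.ndarray
    fs_hz: float
    montage: ChannelMontage

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"data has {data.shape[1]} channels, montage has {self.montage.n_channels}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length epochs: ``(n_epochs, n_times, n_channels)`` in microvolts."""

    epochs: np.ndarray
    fs_hz: float
    montage: ChannelMontage
    epoch_length_s: float = 2.0
    rejected_count: int = 0

    def __post_init__(self) -> None:
        ep = np.asarray(self.epochs, dtype=float)
        if ep.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch x time x channel)")
        expected = int(round(self.epoch_length_s * self.fs_hz))
        if ep.shape[1] != expected:
            raise ValueError(
                f"epoch length {ep.shape[1]} samples != {self.epoch_length_s} s at {self.fs_hz} Hz"
            )
        if ep.shape[2] != self.montage.n_channels:
            raise ValueError("epoch channel count does not match montage")
        object.__setattr__(self, "epochs", ep)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[2]


def _fir_bandpass(low_hz: float, high_hz: float, fs_hz: float,
                  transition_hz: float = 1.0) -> np.ndarray:
    """Hamming-window FIR band-pass taps with ~1 Hz transition at the low edge."""
    nyq = fs_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyq})"
        )
    # Hamming transition width is ~3.3/N in normalized frequency.
    numtaps = int(np.ceil(3.3 * fs_hz / transition_hz))
    numtaps |= 1  # odd length keeps a type-I linear-phase filter
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False, fs=fs_hz,
                         window="hamming")


def bandpass_filter(rec: Recording, low_hz: float, high_hz: float,
                    transition_hz: float = 1.0) -> Recording:
    """Zero-phase FIR band-pass filter.

    The symmetric (linear-phase) FIR is applied once by FFT convolution
    with its group delay compensated exactly, which is zero-phase;
    reflect padding suppresses edge transients.
    """
    taps = _fir_bandpass(low_hz, high_hz, rec.fs_hz, transition_hz)
    pad = len(taps) // 2
    if pad < rec.n_samples:
        padded = np.pad(rec.data, ((pad, pad), (0, 0)), mode="reflect")
        out = signal.fftconvolve(padded, taps[:, None], mode="valid", axes=0)
    else:  # recording shorter than the filter: accept zero-padded edges
        out = signal.fftconvolve(rec.data, taps[:, None], mode="same", axes=0)
    return replace(rec, data=out)


def notch_filter(rec: Recording, freq_hz: float = 50.0, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at ``freq_hz`` (mains interference)."""
    if not (0 < freq_hz < rec.fs_hz / 2):
        raise ValueError("notch frequency must lie below Nyquist")
    b, a = signal.iirnotch(freq_hz, q, fs=rec.fs_hz)
    out = signal.filtfilt(b, a, rec.data, axis=0)
    return replace(rec, data=out)


def epoch(rec: Recording, length_s: float = 2.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    A trailing partial segment is discarded; a recording shorter than one
    epoch is an error.
    """
    n_per = int(round(length_s * rec.fs_hz))
    n_full = rec.n_samples // n_per
    if n_full < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s is shorter than one {length_s} s epoch"
        )
    cut = rec.data[: n_full * n_per].reshape(n_full, n_per, -1)
    return EpochSet(epochs=cut.copy(), fs_hz=rec.fs_hz, montage=rec.montage,
                    epoch_length_s=length_s)


def rereference_average(ep: EpochSet) -> EpochSet:
    """Subtract the per-sample mean over channels (common average reference)."""
    if ep.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = ep.epochs - ep.epochs.mean(axis=2, keepdims=True)
    return replace(ep, epochs=data)


def reject_artifacts(ep: EpochSet, peak_uV: float = 100.0) -> EpochSet:
    """Drop epochs whose absolute amplitude exceeds ``peak_uV`` on any channel."""
    if peak_uV <= 0:
        raise ValueError("rejection threshold must be positive")
    peaks = np.abs(ep.epochs).max(axis=(1, 2))
    keep = peaks <= peak_uV
    n_rej = int((~keep).sum())
    return replace(ep, epochs=ep.epochs[keep],
                   rejected_count=ep.rejected_count + n_rej)


def preprocess(rec: Recording, low_hz: float = 0.5, high_hz: float = 45.0,
               notch_hz: float | None = 50.0, epoch_length_s: float = 2.0,
               reject_uV: float | None = 100.0) -> EpochSet:
    """Full chain: band-pass, notch, epoch, average reference, artifact rejection.

    ``notch_hz=None`` or ``reject_uV=None`` skips that stage; the notch is
    also skipped when it would sit at or above Nyquist.
    """
    out = bandpass_filter(rec, low_hz, high_hz)
    if notch_hz is not None and notch_hz < rec.fs_hz / 2:
        out = notch_filter(out, notch_hz)
    ep = rereference_average(epoch(out, epoch_length_s))
    if reject_uV is not None:
        ep = reject_artifacts(ep, reject_uV)
    return ep
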