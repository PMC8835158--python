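"""Omega spatial complexity: the spatial-dynamics stage.

Omega complexity quantifies how many independent spatial modes a set of
channels carries in a frequency band.  Per 2-s epoch the channels are
Hann-tapered and Fourier transformed; for each frequency bin f the
cross-spectral matrix

    C(f) = mean over epochs of  u(f) u(f)^H

is estimated from the channel coefficient vectors u(f).  Its eigenvalues
lambda_i are trace-normalized, lambda'_i = lambda_i / sum(lambda), and

    Omega = exp( - sum_i lambda'_i * log(lambda'_i) )

is the exponential of their Shannon entropy.  Omega ranges from 1 (one
mode: all channels perfectly synchronized) to K, the number of channels
(K equal modes: no spatial synchronization).  Band values are the
arithmetic mean of per-bin omega over the bins in the band; scopes are
the full montage ("global", K = 30 by default) and the 7-channel
anterior/posterior regional subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "CrossSpectra",
    "cross_spectra",
    "omega_from_matrix",
    "omega_per_bin",
    "band_omega",
    "omega_pipeline",
    "DEFAULT_SCOPES",
]

DEFAULT_SCOPES = ("global", "anterior", "posterior")


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band; bins are selected half-open, [low, high)."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: low must be < high")


#: The seven analysis bands.  Shared edges (13 Hz) are resolved by the
#: half-open convention, so each bin belongs to exactly one band.
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 3.5),
    BandDefinition("theta", 4.0, 7.5),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 11.0, 13.0),
    BandDefinition("beta1", 13.0, 20.0),
    BandDefinition("beta2", 20.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


@dataclass(frozen=True)
class CrossSpectra:
    """Cross-spectral matrices per frequency bin for one channel scope.

    ``matrices``: (n_bins, K, K) complex Hermitian PSD; ``freqs_hz``:
    (n_bins,).
    """

    freqs_hz: np.ndarray
    matrices: np.ndarray
    scope: str = "global"

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[-1]


def cross_spectra(ep: EpochSet, scope: str = "global",
                  max_freq_hz: float | None = None) -> CrossSpectra:
    """Epoch-averaged cross-spectral matrices for a channel scope.

    Each epoch is Hann-tapered and discrete-Fourier transformed; bins are
    spaced at 1/epoch_length (0.5 Hz for 2-s epochs).  The DC bin is
    dropped.  Averaging the rank-one coefficient outer products over epochs
    is what gives C(f) a meaningful eigenvalue spectrum: any single epoch
    contributes exactly one spatial mode per bin.
    """
    if ep.n_epochs < 2:
        raise ValueError("cross-spectral estimation needs at least 2 epochs")
    idx = ep.montage.scope_indices(scope)
    data = ep.epochs[:, :, idx]
    taper = np.hanning(ep.n_times)
    coef = np.fft.rfft(data * taper[None, :, None], axis=1)
    freqs = np.fft.rfftfreq(ep.n_times, d=1.0 / ep.fs_hz)
    keep = freqs > 0
    if max_freq_hz is not None:
        keep &= freqs <= max_freq_hz
    coef = coef[:, keep, :]
    freqs = freqs[keep]
    mats = np.einsum("efk,efl->fkl", coef, np.conj(coef)) / ep.n_epochs
    return CrossSpectra(freqs_hz=freqs, matrices=mats, scope=scope)


def omega_from_matrix(C: np.ndarray) -> float:
    """Omega of one Hermitian PSD matrix.

    Eigenvalues are trace-normalized and omega is exp of their Shannon
    entropy (natural log, 0*log 0 := 0).  A zero-trace matrix has no
    defined mode distribution and raises.
    """
    C = np.asarray(C)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    herm_err = np.abs(C - C.conj().T).max()
    scale = max(np.abs(C).max(), 1.0)
    if herm_err > 1e-8 * scale:
        raise ValueError("C is not Hermitian")
    lam = np.linalg.eigvalsh((C + C.conj().T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    tr = lam.sum()
    if tr <= 0:
        raise ValueError("zero-trace cross-spectral matrix: omega undefined")
    p = lam / tr
    nz = p > 0
    entropy = -float(p[nz] @ np.log(p[nz]))
    return float(np.exp(entropy))


def omega_per_bin(spectra: CrossSpectra,
                  normalize: str = "trace") -> np.ndarray:
    """Omega for every frequency bin (vectorized eigen-decomposition).

    ``normalize="trace"`` (default) uses the cross-spectral matrices as
    estimated, matching the printed definition; ``"correlation"`` first
    rescales each matrix to unit diagonal (coherence-like), removing
    per-channel power differences from the mode spectrum.
    """
    mats = spectra.matrices
    if normalize == "correlation":
        d = np.sqrt(np.einsum("fkk->fk", mats).real)
        if np.any(d <= 0):
            raise ValueError("zero-power channel: correlation undefined")
        mats = mats / (d[:, :, None] * d[:, None, :])
    elif normalize != "trace":
        raise ValueError(f"unknown normalization {normalize!r}")
    lam = np.linalg.eigvalsh(mats)
    lam = np.clip(lam, 0.0, None)
    tr = lam.sum(axis=1, keepdims=True)
    if np.any(tr <= 0):
        raise ValueError("zero-trace cross-spectral matrix: omega undefined")
    p = lam / tr
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return np.exp(-plogp.sum(axis=1))


def band_omega(spectra: CrossSpectra, band: BandDefinition,
               omegas: np.ndarray | None = None,
               normalize: str = "trace") -> float:
    """Mean per-bin omega over the bins with band.low <= f < band.high."""
    sel = (spectra.freqs_hz >= band.low_hz) & (spectra.freqs_hz < band.high_hz)
    if not sel.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    if omegas is None:
        omegas = omega_per_bin(spectra, normalize=normalize)
    return float(omegas[sel].mean())


def omega_pipeline(ep: EpochSet, bands=DEFAULT_BANDS,
                   scopes=DEFAULT_SCOPES,
                   normalize: str = "trace") -> pd.DataFrame:
    """Tidy omega table for one recording: one row per (band, scope).

    Every value lies in [1, K(scope)].
    """
    rows = []
    for scope in scopes:
        spectra = cross_spectra(ep, scope=scope,
                                max_freq_hz=max(b.high_hz for b in bands))
        omegas = omega_per_bin(spectra)
        for band in bands:
            rows.append({"band": band.name, "scope": scope,
                         "omega": band_omega(spectra, band, omegas=omegas),
                         "n_channels": spectra.n_channels})
    return pd.DataFrame(rows)
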