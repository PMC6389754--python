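"""Normalized EEG power spectra and the alpha-power-shift statistic.

The pipeline: common-average re-reference, segmentation into 1-s epochs
with 90% overlap, per-epoch demeaning, Hann tapering, zero-padding,
FFT, squared modulus averaged over epochs, extraction of the integer
2..20 Hz bins, and per-channel normalization to relative power.

The alpha-power shift is the ratio of mean relative power in the
low-alpha band (6-9 Hz) over the high-alpha band (10-11 Hz), reported on
a binary-log scale: positive values mean the alpha rhythm has slowed
(power shifted downwards in frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .segment import EEGSegment

#: Frequencies (Hz) at which relative power is reported.
ANALYSIS_FREQS = np.arange(2, 21)
#: Inclusive band edges, Hz.
LOW_ALPHA = (6, 9)
HIGH_ALPHA = (10, 11)


@dataclass
class PowerSpectrum:
    """Per-channel relative power at integer frequencies 2..20 Hz."""

    power: np.ndarray  # (n_channels, n_freqs), rows sum to 1
    freqs: np.ndarray  # integer Hz
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs)
        if self.power.shape != (len(self.channel_labels), len(self.freqs)):
            raise ValueError("power must be (n_channels, n_freqs)")
        if np.any(self.power < 0):
            raise ValueError("negative power")
        if not np.allclose(self.power.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows must sum to 1 (relative power)")

    def band_mean(self, band: tuple[float, float]) -> np.ndarray:
        """Per-channel mean power over the inclusive band [lo, hi] Hz."""
        lo, hi = band
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {band} outside analysis frequencies")
        return self.power[:, sel].mean(axis=1)


@dataclass
class AlphaShiftProfile:
    """Log2 low/high alpha power ratios for one subject.

    ``global_log2_shift`` follows the channel-average-first convention:
    spectra are averaged across channels and the ratio is formed on the
    averaged spectrum.  ``mean_channel_log2_shift`` (mean of per-channel
    log ratios) is exposed as an alternative summary.
    """

    per_channel_log2_shift: np.ndarray
    global_log2_shift: float
    mean_channel_log2_shift: float
    channel_labels: tuple[str, ...]
    low_band: tuple[float, float] = LOW_ALPHA
    high_band: tuple[float, float] = HIGH_ALPHA

    def __post_init__(self) -> None:
        self.per_channel_log2_shift = np.asarray(self.per_channel_log2_shift,
                                                 dtype=float)
        if not np.isfinite(self.per_channel_log2_shift).all():
            raise ValueError("non-finite per-channel shift")
        if not np.isfinite(self.global_log2_shift):
            raise ValueError("non-finite global shift")


def rereference_common_average(seg: EEGSegment) -> EEGSegment:
    """Re-express every channel relative to the instantaneous channel mean."""
    if seg.n_channels < 2:
        raise ValueError("common-average reference requires >= 2 channels")
    return seg.copy_with(seg.data - seg.data.mean(axis=0, keepdims=True))


def epoch_segment(seg: EEGSegment, epoch_len: float = 1.0,
                  overlap: float = 0.9) -> np.ndarray:
    """Cut a segment into overlapping epochs.

    Returns an (n_epochs, n_channels, L) view with L = epoch_len * fs and
    integer step round((1 - overlap) * L), at least 1 sample.  At 256 Hz
    with 1-s epochs and 90% overlap the step is 26 samples (89.84%
    effective overlap), giving 188 epochs from a 20-s segment.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    L_float = epoch_len * seg.fs
    L = int(round(L_float))
    if abs(L_float - L) > 1e-9:
        raise ValueError("epoch_len * fs must be an integer number of samples")
    if seg.n_samples < L:
        raise ValueError("segment shorter than one epoch")
    step = max(1, int(round((1 - overlap) * L)))
    windows = sliding_window_view(seg.data, L, axis=1)[:, ::step]
    return np.swapaxes(windows, 0, 1)


def power_spectrum(seg: EEGSegment, pad_factor: int = 2,
                   epoch_len: float = 1.0, overlap: float = 0.9,
                   freqs: np.ndarray = ANALYSIS_FREQS) -> PowerSpectrum:
    """Hann-tapered, zero-padded, epoch-averaged relative power spectrum.

    Each epoch is demeaned per channel, multiplied by a periodic Hann
    taper, zero-padded to ``pad_factor`` times its length, and Fourier
    transformed; squared moduli are averaged over epochs.  Power at the
    integer frequencies ``freqs`` is then normalized per channel by its
    sum over those bins, so each row sums to one.
    """
    freqs = np.asarray(freqs)
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")
    if seg.fs <= 2 * freqs.max():
        raise ValueError(
            f"sampling rate {seg.fs} Hz cannot resolve {freqs.max()} Hz")
    epochs = epoch_segment(seg, epoch_len=epoch_len, overlap=overlap)
    L = epochs.shape[-1]
    nfft = pad_factor * L
    bins = freqs * nfft / seg.fs
    if not np.allclose(bins, np.round(bins)):
        raise ValueError("requested frequencies fall between FFT bins")
    taper = hann(L, sym=False)
    demeaned = epochs - epochs.mean(axis=-1, keepdims=True)
    coefs = np.fft.rfft(demeaned * taper, n=nfft, axis=-1)
    raw = (np.abs(coefs) ** 2).mean(axis=0)  # (channels, nfft//2+1)
    power = raw[:, np.round(bins).astype(int)]
    totals = power.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("zero total power in at least one channel")
    return PowerSpectrum(power=power / totals, freqs=freqs,
                         channel_labels=seg.channel_labels)


def alpha_shift(ps: PowerSpectrum, low_band: tuple[float, float] = LOW_ALPHA,
                high_band: tuple[float, float] = HIGH_ALPHA) -> AlphaShiftProfile:
    """Log2 ratio of mean low-alpha over mean high-alpha relative power."""
    for f in (*low_band, *high_band):
        if f not in ps.freqs:
            raise ValueError(f"spectrum lacks required frequency {f} Hz")
    low = ps.band_mean(low_band)
    high = ps.band_mean(high_band)
    if np.any(high <= 0):
        raise ValueError("zero high-alpha power: shift ratio undefined")
    per_channel = np.log2(low / high)

    # Global shift: average spectra across channels first, then the ratio.
    mean_spec = PowerSpectrum(
        power=ps.power.mean(axis=0, keepdims=True) /
        ps.power.mean(axis=0).sum(),
        freqs=ps.freqs, channel_labels=("global",))
    g_low = mean_spec.band_mean(low_band)[0]
    g_high = mean_spec.band_mean(high_band)[0]
    if g_high <= 0:
        raise ValueError("zero high-alpha power in channel-averaged spectrum")
    return AlphaShiftProfile(
        per_channel_log2_shift=per_channel,
        global_log2_shift=float(np.log2(g_low / g_high)),
        mean_channel_log2_shift=float(per_channel.mean()),
        channel_labels=ps.channel_labels,
        low_band=low_band, high_band=high_band)


def individual_alpha_frequency(ps: PowerSpectrum,
                               search_band: tuple[float, float] = (6, 13)
                               ) -> float:
    """Frequency of maximal channel-averaged power within ``search_band``.

    Ties are broken toward the lower frequency.
    """
    lo, hi = search_band
    sel = (ps.freqs >= lo) & (ps.freqs <= hi)
    if not sel.any():
        raise ValueError(f"empty search band {search_band}")
    mean_spec = ps.power.mean(axis=0)[sel]
    return float(ps.freqs[sel][int(np.argmax(mean_spec))])
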