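"""Morlet wavelet time-frequency decomposition, binning, and ITPC.

The analysis bank holds 40 complex Morlet wavelets with center frequencies
log-spaced from 0.5 to 100 Hz and cycle counts log-spaced from 2 to 10
(paired to the frequencies).  Kernels are unit-energy by default so power is
comparable across frequencies; a unit peak-gain normalization is available
since either convention is defensible.

Event-aligned coefficient stacks feed three derived quantities:

* trial-averaged power, binned into 100 ms intervals;
* baseline normalization (relative change, dB, or z-score against the
  pre-movement baseline);
* inter-trial phase consistency, ITPC = |mean over trials of the unit
  phasor|, computed per sample and then averaged within bins (the
  conservative reading of bin-averaged ITPC).

Low frequencies have wavelets longer than the epoch padding; affected bins
are masked, not NaN-poisoned, and downstream statistics exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import fftconvolve

__all__ = ["WaveletBank", "ComplexTFR", "EventWindows", "BinnedMap",
           "build_bank", "convolve", "align", "power_binned",
           "baseline_normalize", "itpc", "band_window_average"]


@dataclass(frozen=True)
class EventWindows:
    """Analysis windows (ms, relative to the aligning event), as used throughout."""

    baseline: tuple[float, float] = (-550.0, -50.0)
    movement: tuple[float, float] = (-50.0, 950.0)
    disappearance: tuple[float, float] = (-350.0, 950.0)
    reappearance: tuple[float, float] = (-350.0, 450.0)
    norm_baseline: tuple[float, float] = (-500.0, -200.0)  # rel. movement onset

    def items(self):
        return [("baseline", self.baseline), ("movement", self.movement),
                ("disappearance", self.disappearance),
                ("reappearance", self.reappearance)]


@dataclass(frozen=True)
class WaveletBank:
    freqs: np.ndarray       # (n,) Hz, strictly increasing
    cycles: np.ndarray      # (n,)
    kernels: list           # complex arrays, odd length
    half_widths_ms: np.ndarray  # truncation half-support per kernel
    fs: float
    normalization: str = "energy"

    @property
    def n_freqs(self) -> int:
        return len(self.freqs)

    def subset(self, f_lo: float, f_hi: float) -> "WaveletBank":
        """Restrict the bank to center frequencies inside [f_lo, f_hi]."""
        sel = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        if not sel.any():
            raise ValueError("empty frequency selection")
        idx = np.flatnonzero(sel)
        return WaveletBank(self.freqs[sel], self.cycles[sel],
                           [self.kernels[i] for i in idx],
                           self.half_widths_ms[sel], self.fs,
                           self.normalization)


def build_bank(f_min: float = 0.5, f_max: float = 100.0, n: int = 40,
               c_min: float = 2.0, c_max: float = 10.0, fs: float = 1000.0,
               normalization: str = "energy") -> WaveletBank:
    """Log-spaced complex Morlet bank.

    freqs[k] = f_min (f_max/f_min)^(k/(n-1)), cycles likewise from c_min to
    c_max; Gaussian envelope with sigma_t = cycles / (2 pi f), truncated at
    +-3.5 sigma_t.  ``normalization``: "energy" (sum |k|^2 = 1) or "peak"
    (gain 1 at the center frequency).
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if f_max > fs / 2.0:
        raise ValueError("f_max above Nyquist")
    k = np.arange(n)
    expo = k / (n - 1) if n > 1 else np.zeros(1)
    freqs = f_min * (f_max / f_min) ** expo
    cycles = c_min * (c_max / c_min) ** expo
    kernels, half_widths = [], []
    for f, c in zip(freqs, cycles):
        sigma_t = c / (2.0 * np.pi * f)
        half = int(np.ceil(3.5 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        env = np.exp(-(t**2) / (2 * sigma_t**2))
        # admissibility correction: zero-mean kernel even at 2 cycles
        kappa = np.exp(-0.5 * (2 * np.pi * f * sigma_t) ** 2)
        kern = env * (np.exp(2j * np.pi * f * t) - kappa)
        if normalization == "energy":
            kern = kern / np.sqrt(np.sum(np.abs(kern) ** 2))
        elif normalization == "peak":
            kern = kern / np.sum(np.abs(kern))  # |sum k e^{-i2pift}| = 1 at f
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        kernels.append(kern)
        half_widths.append(half * 1000.0 / fs)
    return WaveletBank(freqs, cycles, kernels, np.array(half_widths), fs,
                       normalization)


@dataclass
class ComplexTFR:
    """Event-aligned complex coefficients: (n_trials, n_channels, n_freqs, n_times)."""

    coefficients: np.ndarray
    times_ms: np.ndarray
    freqs: np.ndarray
    valid: np.ndarray  # (n_trials, n_freqs, n_times) bool: wavelet fits the epoch

    @property
    def n_trials(self) -> int:
        return self.coefficients.shape[0]


def convolve(epoch: np.ndarray, bank: WaveletBank) -> tuple[np.ndarray, np.ndarray]:
    """Convolve one epoch (n_channels, n_samples) with the bank.

    Returns (coeffs (n_ch, n_freq, n_samples), valid (n_freq, n_samples));
    a sample is valid at a frequency iff its distance to either epoch edge
    is at least the kernel half-width (FFT-based, center-aligned).
    """
    epoch = np.atleast_2d(np.asarray(epoch, float))
    n_ch, n_s = epoch.shape
    out = np.empty((n_ch, bank.n_freqs, n_s), complex)
    valid = np.zeros((bank.n_freqs, n_s), bool)
    samp = np.arange(n_s)
    for i, kern in enumerate(bank.kernels):
        out[:, i, :] = fftconvolve(epoch, kern[None, :], mode="same", axes=1)
        hw = (len(kern) - 1) // 2
        valid[i] = (samp >= hw) & (samp <= n_s - 1 - hw)
    return out, valid


def align(epoch_tfrs: list[np.ndarray], valids: list[np.ndarray],
          event_samples: list[int], window_ms: tuple[float, float],
          fs: float, freqs: np.ndarray) -> ComplexTFR:
    """Cut event-aligned segments from per-trial TFRs into one stack.

    ``event_samples[i]`` is the aligning event's sample index within epoch i;
    the window is half-open on the sample grid: samples with time in
    [window[0], window[1]) relative to the event.
    """
    lo = int(np.round(window_ms[0] * fs / 1000.0))
    hi = int(np.round(window_ms[1] * fs / 1000.0))
    n_t = hi - lo
    stacks, vstacks = [], []
    for tfr, val, ev in zip(epoch_tfrs, valids, event_samples):
        n_s = tfr.shape[-1]
        i0, i1 = ev + lo, ev + hi
        if i0 < 0 or i1 > n_s:
            raise ValueError("window exceeds epoch bounds; increase padding")
        stacks.append(tfr[:, :, i0:i1])
        vstacks.append(val[:, i0:i1])
    times = (np.arange(lo, hi)) * 1000.0 / fs
    return ComplexTFR(np.stack(stacks), times, np.asarray(freqs),
                      np.stack(vstacks))


@dataclass
class BinnedMap:
    """channel x frequency x 100-ms-bin map of power, normalized power, or ITPC."""

    values: np.ndarray
    bin_centers_ms: np.ndarray
    freqs: np.ndarray
    kind: str
    valid: np.ndarray  # (n_freqs, n_bins): no member sample touched an edge

    def to_hdf5(self, path: str, name: str = "map") -> None:
        with h5py.File(path, "a") as fh:
            if name in fh:
                del fh[name]
            g = fh.create_group(name)
            g.create_dataset("values", data=self.values)
            g.create_dataset("bin_centers_ms", data=self.bin_centers_ms)
            g.create_dataset("freqs", data=self.freqs)
            g.create_dataset("valid", data=self.valid)
            g.attrs["kind"] = self.kind

    @classmethod
    def from_hdf5(cls, path: str, name: str = "map") -> "BinnedMap":
        with h5py.File(path, "r") as fh:
            g = fh[name]
            return cls(g["values"][()], g["bin_centers_ms"][()],
                       g["freqs"][()], str(g.attrs["kind"]), g["valid"][()])


def _bin_index(times_ms: np.ndarray, bin_ms: float):
    """Half-open [left, right) bins anchored at the window start.

    Centers sit at left + bin/2; a trailing fragment bin (window width not a
    multiple of the bin width) is dropped.
    """
    left = times_ms[0]
    idx = np.floor((times_ms - left) / bin_ms + 1e-9).astype(int)
    n_bins = idx.max() + 1
    per_bin = np.bincount(idx, minlength=n_bins)
    full = int(round(bin_ms / np.median(np.diff(times_ms))))
    keep = per_bin >= full
    centers = left + (np.arange(n_bins) + 0.5) * bin_ms
    return idx, keep, centers


def power_binned(tfr: ComplexTFR, bin_ms: float = 100.0) -> BinnedMap:
    """Trial-averaged power |coef|^2, mean within each 100 ms bin."""
    if tfr.n_trials < 1:
        raise ValueError("no trials")
    pw = (np.abs(tfr.coefficients) ** 2).mean(axis=0)  # (ch, f, t)
    idx, keep, centers = _bin_index(tfr.times_ms, bin_ms)
    return _binned(pw, tfr, idx, keep, centers, "power")


def itpc(tfr: ComplexTFR, bin_ms: float = 100.0) -> BinnedMap:
    """Inter-trial phase consistency per sample, then bin-averaged; in [0, 1]."""
    if tfr.n_trials < 2:
        raise ValueError("ITPC needs at least 2 trials")
    mag = np.abs(tfr.coefficients)
    mag[mag == 0] = 1.0
    R = np.minimum(np.abs((tfr.coefficients / mag).mean(axis=0)), 1.0)  # (ch, f, t)
    idx, keep, centers = _bin_index(tfr.times_ms, bin_ms)
    return _binned(R, tfr, idx, keep, centers, "itpc")


def _binned(values: np.ndarray, tfr: ComplexTFR, idx, keep, centers,
            kind: str) -> BinnedMap:
    n_ch, n_f, _ = values.shape
    n_bins = len(centers)
    out = np.zeros((n_ch, n_f, n_bins))
    ok = np.zeros((n_f, n_bins), bool)
    all_valid = tfr.valid.all(axis=0)  # (f, t)
    for b in range(n_bins):
        sel = idx == b
        if not keep[b] or not sel.any():
            continue
        out[:, :, b] = values[:, :, sel].mean(axis=2)
        ok[:, b] = all_valid[:, sel].all(axis=1)
    return BinnedMap(out[:, :, keep], centers[keep], tfr.freqs, kind,
                     ok[:, keep])


def baseline_normalize(mp: BinnedMap, baseline: BinnedMap,
                       mode: str = "relative") -> BinnedMap:
    """Normalize a power map against the pre-movement baseline map.

    relative: (P - mu_b)/mu_b; db: 10 log10(P/mu_b); zscore: (P - mu_b)/sd_b,
    with mu_b, sd_b over valid baseline bins per channel x frequency.
    """
    bvals = baseline.values  # (ch, f, bins)
    bvalid = baseline.valid  # (f, bins)
    mu = np.empty(bvals.shape[:2])
    sd = np.empty(bvals.shape[:2])
    for f in range(bvals.shape[1]):
        sel = bvalid[f]
        if not sel.any():
            mu[:, f] = np.nan
            sd[:, f] = np.nan
            continue
        mu[:, f] = bvals[:, f, sel].mean(axis=1)
        sd[:, f] = bvals[:, f, sel].std(axis=1)
    if mode in ("relative", "db") and np.nanmin(mu) <= 0:
        raise ValueError("baseline mean power must be positive")
    P = mp.values
    if mode == "relative":
        out = (P - mu[..., None]) / mu[..., None]
    elif mode == "db":
        out = 10.0 * np.log10(P / mu[..., None])
    elif mode == "zscore":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (P - mu[..., None]) / sd[..., None]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    valid = mp.valid & ~np.isnan(mu[0])[:, None] if mp.valid.ndim == 2 else mp.valid
    return BinnedMap(out, mp.bin_centers_ms, mp.freqs, f"{mp.kind}_{mode}", valid)


def band_window_average(mp: BinnedMap, band_hz: tuple[float, float],
                        window_ms: tuple[float, float],
                        require_valid: bool = True) -> np.ndarray:
    """Mean over frequency bins in the band and time bins in the window.

    Returns one value per channel (or per voxel for source-level maps).
    """
    fsel = (mp.freqs >= band_hz[0]) & (mp.freqs <= band_hz[1])
    tsel = (mp.bin_centers_ms >= window_ms[0]) & (mp.bin_centers_ms <= window_ms[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band/window selection")
    sub = mp.values[:, fsel][:, :, tsel]
    if require_valid:
        ok = mp.valid[np.ix_(fsel, tsel)]
        if not ok.any():
            raise ValueError("no valid bins in selection")
        return sub[:, ok].mean(axis=1)
    return sub.mean(axis=(1, 2))
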