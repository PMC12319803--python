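"""Spectral estimation: ISF detection, sliding-window TFRs, ISF alignment.

The individual stimulation frequency (ISF) is the participant's alpha peak:
the frequency of maximal Hanning-tapered FFT power on the baseline
recording, searched on a 1 Hz grid restricted to the broad alpha range
7-14 Hz.  Time-frequency decomposition uses a Hanning taper on sliding
windows — 7 cycles per window for the main analysis, a fixed 400 ms window
for the modulatory analysis — stepped every 100 ms.  Frequency axes are
then re-indexed relative to each participant's ISF ("ISF-2" ... "ISF+26")
so that power maps are comparable across participants; a harmonic variant
aligns on 2*ISF instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.signal

from .data_core import TrialSet

logger = logging.getLogger(__name__)

SPECTRUM_FREQS = np.arange(4.0, 41.0)
TFR_FREQS = np.arange(5.0, 41.0)
ALPHA_RANGE = (7.0, 14.0)
TFR_STEP = 0.1
FUNDAMENTAL_OFFSETS = np.arange(-2, 27)  # "ISF-2" .. "ISF+26", 29 bins
HARMONIC_OFFSETS = np.arange(-4, 17)  # around 2*ISF, stays within 5-40 Hz


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    isf: float


@dataclass
class TFR:
    """Per-trial sliding-window power, shape (trial, unit, freq, time).

    Time points whose window does not fit inside the epoch are NaN
    (missing), never zero-filled.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    variant: str
    sampling_rate: float
    rejected_trials: np.ndarray

    def good_trials(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected_trials)


@dataclass
class AlignedTFR:
    """TFR with the frequency axis re-indexed as offsets from the ISF."""

    power: np.ndarray  # (trial, unit, offset, time)
    offsets: np.ndarray
    times: np.ndarray
    isf_used: float
    alignment_mode: str
    rejected_trials: np.ndarray

    def absolute_freqs(self) -> np.ndarray:
        centre = self.isf_used if self.alignment_mode == "fundamental" \
            else 2.0 * self.isf_used
        return centre + self.offsets

    def good_trials(self) -> np.ndarray:
        return np.flatnonzero(~self.rejected_trials)


def _detrend(x: np.ndarray) -> np.ndarray:
    """Remove per-epoch mean and linear trend (last axis), dtype-preserving."""
    n = x.shape[-1]
    dtype = x.dtype.type if np.issubdtype(x.dtype, np.floating) \
        else np.float64
    t = (np.arange(n) - (n - 1) / 2.0).astype(dtype)
    denom = dtype(np.sum(t.astype(np.float64) ** 2))
    mean = x.mean(axis=-1, keepdims=True)
    slope = (x @ t)[..., None] / denom
    return x - mean - slope * t


def _hann_power(x: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Single-Hanning-taper power of ``x`` (last axis) at given frequencies.

    Normalised so a sinusoid of amplitude A at a grid frequency yields
    power A^2/2 (its variance), independent of segment length.  Uses an FFT
    when every requested frequency falls on the segment's DFT grid, direct
    inner products otherwise.
    """
    n = x.shape[-1]
    dtype = x.dtype.type if np.issubdtype(x.dtype, np.floating) \
        else np.float64
    w = scipy.signal.get_window("hann", n, fftbins=False).astype(dtype)
    xw = x * w
    bins = np.asarray(freqs) * n / fs
    on_grid = np.allclose(bins, np.round(bins), atol=1e-9) and np.all(
        np.round(bins) <= n // 2
    )
    if on_grid:
        spec = scipy.fft.rfft(xw, axis=-1)
        sel = spec[..., np.round(bins).astype(int)]
        power = np.abs(sel) ** 2
    else:
        t = np.arange(n) / fs
        phase = 2 * np.pi * np.outer(freqs, t)
        re = xw @ np.cos(phase).T.astype(dtype)
        im = xw @ np.sin(phase).T.astype(dtype)
        power = re.astype(np.float64) ** 2 + im.astype(np.float64) ** 2
    return 2.0 * power.astype(np.float64) / (float(w.sum()) ** 2)


def estimate_isf(
    baseline: TrialSet,
    units: np.ndarray | None = None,
    mode: str = "concatenate",
    freqs: np.ndarray = SPECTRUM_FREQS,
    detrend: bool = True,
) -> PowerSpectrum:
    """Estimate the individual stimulation frequency from baseline data.

    ``mode='concatenate'`` (default) tapers one single Hanning window over
    the trial-concatenated baseline; ``mode='per_trial'`` tapers each epoch
    separately and averages power over epochs.  Power is averaged over the
    declared unit subset, and the ISF is the argmax on the 1 Hz grid within
    7-14 Hz; exact ties resolve to the lower frequency (logged).
    """
    good = baseline.good_trials()
    if len(good) == 0:
        raise ValueError("no usable baseline trials")
    data = baseline.data[:, good, :]
    if units is not None:
        units = np.asarray(units)
        if units.size == 0:
            raise ValueError("unit subset is empty")
        data = data[units]
    if detrend:
        data = _detrend(data)
    fs = baseline.sampling_rate
    if mode == "concatenate":
        series = data.reshape(data.shape[0], -1)
        power = _hann_power(series, freqs, fs).mean(axis=0)
    elif mode == "per_trial":
        power = _hann_power(data, freqs, fs).mean(axis=(0, 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    isf = pick_alpha_peak(freqs, power)
    return PowerSpectrum(freqs=freqs, power=power, isf=isf)


def pick_alpha_peak(freqs: np.ndarray, power: np.ndarray) -> float:
    """Frequency of maximal power within the broad alpha range 7-14 Hz.

    Exact ties resolve to the lower frequency (logged); an all-zero alpha
    band is an error.
    """
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    in_alpha = (freqs >= ALPHA_RANGE[0]) & (freqs <= ALPHA_RANGE[1])
    alpha_power = power[in_alpha]
    if not np.any(alpha_power > 0):
        raise ValueError("no alpha peak: spectrum is zero within 7-14 Hz")
    alpha_freqs = freqs[in_alpha]
    best = np.flatnonzero(alpha_power == alpha_power.max())
    if len(best) > 1:
        logger.info(
            "ISF tie between %s Hz; choosing the lower frequency",
            alpha_freqs[best].tolist(),
        )
    return float(alpha_freqs[best[0]])


def _window_length(freq: float, variant: str, fs: float) -> int:
    if variant == "cycles7":
        return int(round(7.0 / freq * fs))
    if variant == "win400ms":
        return int(round(0.4 * fs))
    raise ValueError(f"unknown TFR variant {variant!r}")


def compute_tfr(
    trials: TrialSet,
    variant: str = "cycles7",
    freqs: np.ndarray | None = None,
    detrend: bool = True,
) -> TFR:
    """Hanning-taper sliding-window power, 100 ms steps, trial dim retained.

    For ``variant='cycles7'`` the window at frequency f spans 7/f seconds;
    ``variant='win400ms'`` uses a fixed 400 ms window (coarser spectral,
    finer temporal resolution, used by the modulatory analysis).
    """
    freqs = TFR_FREQS if freqs is None else np.atleast_1d(
        np.asarray(freqs, dtype=float)
    )
    fs = trials.sampling_rate
    step = int(round(TFR_STEP * fs))
    if abs(step - TFR_STEP * fs) > 1e-9:
        raise ValueError("sampling rate incompatible with the 100 ms step")
    data = trials.data
    if detrend:
        data = _detrend(data)
    nu, nt, ns = data.shape
    sig = np.ascontiguousarray(data.reshape(nu * nt, ns))
    n_times = (ns - 1) // step + 1
    times = trials.time_axis[0] + TFR_STEP * np.arange(n_times)
    power = np.full((nt, nu, len(freqs), n_times), np.nan)
    lengths = [_window_length(f, variant, fs) for f in freqs]
    for L in sorted(set(lengths)):
        if L > ns:
            f_bad = freqs[int(np.argmax(np.asarray(lengths) == L))]
            raise ValueError(
                f"epoch of {ns / fs:g} s too short for the "
                f"{L / fs:g} s window at {f_bad:g} Hz"
            )
        f_idx = [i for i, li in enumerate(lengths) if li == L]
        centres = step * np.arange(n_times)
        starts = centres - L // 2
        valid = (starts >= 0) & (starts + L <= ns)
        w = scipy.signal.get_window("hann", L, fftbins=False)
        ph = 2 * np.pi * np.outer(freqs[f_idx], np.arange(L) / fs)
        # one (L, 2*n_freq) kernel: frequencies sharing a window length
        # cost a single window gather + one GEMM
        kern = np.ascontiguousarray(
            np.concatenate([(w * np.cos(ph)).T, (w * np.sin(ph)).T], axis=1)
        ).astype(sig.dtype)
        win = np.lib.stride_tricks.sliding_window_view(sig, L, axis=-1)
        seg = win[:, starts[valid], :]
        quad = (seg @ kern).astype(np.float64)
        nf = len(f_idx)
        p = 2.0 * (quad[..., :nf] ** 2 + quad[..., nf:] ** 2) \
            / (w.sum() ** 2)
        p = p.reshape(nu, nt, -1, nf).transpose(1, 0, 3, 2)
        power[np.ix_(np.arange(nt), np.arange(nu), np.array(f_idx),
                     np.flatnonzero(valid))] = p
    return TFR(
        power=power, freqs=freqs, times=times, variant=variant,
        sampling_rate=fs, rejected_trials=trials.rejected_trials.copy(),
    )


def align_tfr(tfr: TFR, isf: float, mode: str = "fundamental") -> AlignedTFR:
    """Re-index the TFR frequency axis as offsets relative to the ISF.

    ``fundamental``: offset k maps to absolute frequency ISF + k for
    k = -2..26.  ``harmonic``: offsets -4..16 around the first harmonic
    2*ISF, so the harmonic lands in a common bin across participants.
    Offsets whose absolute frequency is outside the computed TFR range are
    left missing (NaN), never extrapolated.
    """
    if mode == "fundamental":
        offsets = FUNDAMENTAL_OFFSETS
        centre = isf
    elif mode == "harmonic":
        offsets = HARMONIC_OFFSETS
        centre = 2.0 * isf
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    nt, nu, _, nti = tfr.power.shape
    out = np.full((nt, nu, len(offsets), nti), np.nan)
    for k, off in enumerate(offsets):
        target = centre + off
        hit = np.flatnonzero(np.isclose(tfr.freqs, target))
        if len(hit):
            out[:, :, k, :] = tfr.power[:, :, hit[0], :]
    return AlignedTFR(
        power=out, offsets=offsets.copy(), times=tfr.times.copy(),
        isf_used=float(isf), alignment_mode=mode,
        rejected_trials=tfr.rejected_trials.copy(),
    )
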