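"""Rhythmic power-modulation analysis (filter bank + Hilbert envelope).

Alpha power fluctuates slowly (~0.1-2 Hz) over time.  To quantify whether
stimulation changes this rhythmicity, per-trial power time courses (400 ms
TFR windows, 100 ms steps -> 10 Hz power sampling) are first referenced to
the preceding trial,

    power_difference(n, t) = power(n, t) - mean_t power(n-1, t),   n >= 2,

averaged over the significant-cluster units.  The per-trial difference
courses are concatenated in trial order, band-pass filtered in a bank of
slow bands (centres 0.1-0.5 Hz in 0.1 Hz steps, then 0.75-2 Hz in 0.25 Hz
steps), Hilbert-transformed, and the time-averaged analytic-signal
magnitude per trial is the "modulatory power" at that (modulation
frequency, carrier frequency) pair.

Filtering sub-Hz components in a single 5.5 s trial is ill-posed, so the
session-level concatenated series is filtered once (with mirror padding of
one series length at both ends to suppress edge transients) and then
segmented back into trials for time-averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .cluster_stats import (
    ClusterTestResult,
    ClusterTestSpec,
    cluster_permutation_test,
    grid_adjacency,
)

#: filter-bank centres, Hz: 0.1..0.5 by 0.1, then 0.75..2.0 by 0.25
MOD_CENTRES = np.array(
    [0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0]
)
POWER_FS = 10.0  # Hz; one TFR estimate per 100 ms


@dataclass
class TrialPowerDifference:
    """Power-difference time courses, shape (n_trials-1, n_carriers, n_times).

    ``trial_numbers`` are the 1-based indices of the retained trials (the
    first trial has no predecessor and is excluded).
    """

    values: np.ndarray
    trial_numbers: np.ndarray
    carrier_offsets: np.ndarray
    sampling_rate: float = POWER_FS


@dataclass
class ModulatorySpectrum:
    """Modulatory power per trial, shape (n_trials, n_mod, n_carriers)."""

    values: np.ndarray
    mod_freqs: np.ndarray
    carrier_offsets: np.ndarray

    def trial_average(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)


def trial_power_difference(
    power: np.ndarray,
    cluster_units: np.ndarray,
    carrier_offsets: np.ndarray | None = None,
) -> TrialPowerDifference:
    """Trial-to-trial power difference, unit-averaged over the cluster.

    ``power``: per-trial power from the 400 ms-window TFR, shape
    (n_trials, n_units, n_carriers, n_times).  Time bins that are missing
    (NaN, window does not fit) in any trial are dropped so every trial
    contributes an equal-length course.
    """
    power = np.asarray(power, dtype=float)
    if power.ndim != 4:
        raise ValueError("power must be (trial, unit, carrier, time)")
    n_trials = power.shape[0]
    if n_trials < 2:
        raise ValueError("need at least 2 trials (trial 1 has no predecessor)")
    p = power[:, np.asarray(cluster_units)].mean(axis=1)  # (trial, carr, time)
    valid = np.isfinite(p).all(axis=(0, 1))
    p = p[..., valid]
    prev_avg = p[:-1].mean(axis=-1, keepdims=True)
    diffs = p[1:] - prev_avg
    return TrialPowerDifference(
        values=diffs,
        trial_numbers=np.arange(2, n_trials + 1),
        carrier_offsets=np.asarray(carrier_offsets)
        if carrier_offsets is not None
        else np.arange(p.shape[1]),
    )


def band_filter(centre: float, fs: float = POWER_FS) -> np.ndarray:
    """Butterworth band-pass SOS for one filter-bank centre.

    Bandwidth is max(0.1 Hz, centre/2); the order is chosen (via buttord)
    for at least 20 dB stop-band attenuation at twice the centre frequency.
    Applied forward-backward, so the realised attenuation is doubled and
    the phase response is zero.
    """
    bw = max(0.1, 0.5 * centre)
    lo, hi = centre - bw / 2.0, centre + bw / 2.0
    nyq = fs / 2.0
    if lo <= 0 or hi >= nyq:
        raise ValueError(
            f"band edges [{lo:g}, {hi:g}] Hz of centre {centre:g} Hz are "
            f"outside (0, {nyq:g})"
        )
    ws = (max(lo / 2.0, 1e-3), min(2.0 * centre, nyq * 0.999))
    order, wn = scipy.signal.buttord((lo, hi), ws, gpass=1.0, gstop=20.0,
                                     fs=fs)
    order = max(order, 2)
    return scipy.signal.butter(order, wn, btype="bandpass", output="sos",
                               fs=fs)


def bandwidth(centre: float) -> float:
    return max(0.1, 0.5 * centre)


def modulatory_power(
    diff: TrialPowerDifference,
    centres: np.ndarray = MOD_CENTRES,
    normalize_bandwidth: bool = False,
) -> ModulatorySpectrum:
    """Filter-Hilbert modulatory power per (trial, modulation, carrier).

    The per-trial courses are concatenated in trial order, mirror-padded by
    one series length at each end, zero-phase band-pass filtered per
    centre, Hilbert-transformed, and the envelope magnitude is time-
    averaged within each trial segment.  ``normalize_bandwidth`` divides by
    sqrt(bandwidth / 0.1 Hz) to make centres with unequal bandwidths
    comparable (white noise then gives a roughly flat spectrum).
    """
    vals = diff.values  # (n_trials, n_carriers, n_times)
    n_trials, n_carr, n_times = vals.shape
    series = np.moveaxis(vals, 0, 1).reshape(n_carr, n_trials * n_times)
    total = series.shape[-1]
    padded = np.concatenate(
        [series[..., ::-1], series, series[..., ::-1]], axis=-1
    )
    out = np.empty((n_trials, len(centres), n_carr))
    for ci, centre in enumerate(np.asarray(centres, dtype=float)):
        sos = band_filter(centre, diff.sampling_rate)
        filt = scipy.signal.sosfiltfilt(sos, padded, axis=-1, padlen=0)
        env = np.abs(scipy.signal.hilbert(filt, axis=-1))
        env = env[..., total:2 * total]
        env = env.reshape(n_carr, n_trials, n_times)
        if normalize_bandwidth:
            env = env / np.sqrt(bandwidth(centre) / 0.1)
        out[:, ci, :] = env.mean(axis=-1).T
    return ModulatorySpectrum(
        values=out, mod_freqs=np.asarray(centres, dtype=float),
        carrier_offsets=diff.carrier_offsets,
    )


def modulatory_contrast(
    tacs_spectra: np.ndarray,
    control_spectra: np.ndarray,
    spec: ClusterTestSpec,
) -> ClusterTestResult:
    """Cluster permutation test over the modulation x carrier plane.

    Inputs are per-participant trial-averaged modulatory spectra, shape
    (n_participants, n_mod, n_carriers); adjacency is the 4-neighbour grid
    on that plane.
    """
    tacs_spectra = np.asarray(tacs_spectra, dtype=float)
    adj = grid_adjacency(tacs_spectra.shape[1:])
    return cluster_permutation_test(tacs_spectra, control_spectra, spec, adj)
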