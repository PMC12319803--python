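"""Synthetic multi-unit recordings with known oscillatory ground truth.

Each unit carries an alpha oscillation at the participant's individual
stimulation frequency (ISF), slowly amplitude-modulated at ``mod_freq``
(default 0.4 Hz, the slow power fluctuation seen in real recordings),
superimposed on 1/f-like broadband noise.  In the tACS session the alpha
amplitude of the effect units is scaled by ``sqrt(1 + tacs_gain)`` in
post-stimulation epochs only, so the injected *power* gain at ISF equals
``tacs_gain`` exactly; the control session carries no effect.

Defaults are chosen to emulate a realistic MEG-like regime: with
``alpha_amp = 1`` and ``noise_amp = 1.9`` the alpha peak stands roughly an
order of magnitude above the 1/f background in a 1 Hz-resolution spectrum,
so spectral peak detection is reliable while per-trial power estimates keep
realistic variability.  Trial-to-trial amplitude jitter is log-normal and
shared across units within a trial (global excitability fluctuation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft

from .data_core import (
    POST_TRIM,
    BASELINE_DISCARD,
    BASELINE_EPOCH,
    StudyDesign,
    TrialSet,
    UnitLayout,
    grid_layout,
    segment_recording,
    write_container,
)

DEFAULT_ISF_CHOICES = (8, 9, 10, 11, 12, 13)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth parameters of one synthetic participant.

    isf : alpha peak / stimulation frequency, Hz, within 7-14.
    alpha_amp : baseline alpha oscillation amplitude (arbitrary units).
    tacs_gain : fractional power increase at ISF in tACS post epochs
        (0.30 means +30 % power on the effect units).
    effect_units : indices of units carrying the tACS effect.
    mod_freq / mod_depth : slow sinusoidal amplitude modulation (Hz, 0-1).
    mod_depth_tacs : optional modulation depth used in tACS post epochs
        (condition-dependent rhythmicity); ``None`` means same as control.
    noise_exponent : spectral slope of the background (power ~ f^-exponent).
    noise_amp : standard deviation of the broadband noise.
    amp_jitter_sd : sd of the log-normal per-trial amplitude jitter.
    """

    isf: float = 10.0
    alpha_amp: float = 1.0
    tacs_gain: float = 0.30
    effect_units: tuple[int, ...] = ()
    mod_freq: float = 0.4
    mod_depth: float = 0.3
    mod_depth_tacs: float | None = None
    noise_exponent: float = 1.0
    noise_amp: float = 1.9
    amp_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (7.0 <= self.isf <= 14.0):
            raise ValueError("isf must lie within 7-14 Hz")
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError("mod_depth must lie in [0, 1]")
        if self.mod_depth_tacs is not None and not (
            0.0 <= self.mod_depth_tacs <= 1.0
        ):
            raise ValueError("mod_depth_tacs must lie in [0, 1]")
        if self.tacs_gain <= -1.0:
            raise ValueError("tacs_gain must be > -1")


def colored_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_samples: int,
    fs: float,
    exponent: float,
    amp: float,
    dtype=np.float32,
) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ~ max(f, 1 Hz)^(-exponent/2).

    Synthesised in the frequency domain with random phases; the spectrum is
    flattened below 1 Hz to avoid unbounded low-frequency drift.  Output
    sample standard deviation equals ``amp`` in expectation.  Synthesis runs
    at an FFT-friendly length and is truncated to ``n_samples``.
    """
    n_fast = scipy.fft.next_fast_len(n_samples, real=True)
    freqs = np.fft.rfftfreq(n_fast, d=1.0 / fs)
    s = np.zeros(len(freqs), dtype=dtype)
    s[1:] = np.maximum(freqs[1:], 1.0) ** (-exponent / 2.0)
    # amp is the std of the nominal full-band process; components above
    # 150 Hz are omitted (invisible to every 4-40 Hz analysis stage)
    sigma = dtype(amp * n_fast
                  / np.sqrt(2.0 * np.sum(s.astype(np.float64) ** 2)))
    keep = int(np.searchsorted(freqs, min(150.0, fs / 2.0), side="right"))
    z = rng.standard_normal(shape + (2 * keep,), dtype=np.float32)
    coeff = np.zeros(shape + (len(freqs),), dtype=np.complex64)
    coeff[..., :keep] = z.view(np.complex64) * (
        sigma * s[:keep] / np.sqrt(2.0, dtype=dtype)
    )
    out = scipy.fft.irfft(coeff, n=n_fast, axis=-1)
    return np.ascontiguousarray(out[..., :n_samples]).astype(dtype, copy=False)


@dataclass
class ParticipantRecording:
    """In-memory container: all trial sets of one synthetic participant."""

    design: StudyDesign
    layout: UnitLayout
    spec: EffectSpec
    trialsets: dict[tuple[str, str, str], TrialSet]

    def save(self, path, metadata: dict | None = None) -> str:
        meta = {"isf": self.spec.isf, "tacs_gain": self.spec.tacs_gain}
        meta.update(metadata or {})
        return write_container(
            path, self.design, self.layout, self.trialsets,
            seed=self.spec.seed, metadata=meta,
        )


def _oscillation(
    spec: EffectSpec,
    t_abs: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    gain_mask: np.ndarray | None,
    mod_depth: float,
    dtype=np.float32,
) -> np.ndarray:
    """Deterministic oscillatory component, shape (unit, *t_abs.shape).

    signal_u(t) = amp_u * (1 + m sin(2 pi f_mod t + phi_u))
                        * sin(2 pi isf t + theta_u)

    evaluated via angle-addition so the expensive sin/cos run once over the
    time base instead of once per unit.
    """
    shape1 = (-1,) + (1,) * t_abs.ndim
    wm = 2 * np.pi * spec.mod_freq * t_abs
    wc = 2 * np.pi * spec.isf * t_abs
    sin_m, cos_m = np.sin(wm).astype(dtype), np.cos(wm).astype(dtype)
    sin_c, cos_c = np.sin(wc).astype(dtype), np.cos(wc).astype(dtype)
    sp, cp = np.sin(phi).astype(dtype), np.cos(phi).astype(dtype)
    st, ct = np.sin(theta).astype(dtype), np.cos(theta).astype(dtype)
    env = 1.0 + dtype(mod_depth) * (
        sin_m * cp.reshape(shape1) + cos_m * sp.reshape(shape1)
    )
    carrier = sin_c * ct.reshape(shape1) + cos_c * st.reshape(shape1)
    amp = np.full(len(theta), spec.alpha_amp, dtype=dtype)
    if gain_mask is not None:
        amp = amp * np.where(gain_mask, np.sqrt(1.0 + spec.tacs_gain), 1.0
                             ).astype(dtype)
    env *= carrier
    env *= amp.reshape(shape1)
    return env


def generate_participant(
    design: StudyDesign,
    layout: UnitLayout,
    spec: EffectSpec,
    sessions: tuple[str, ...] | None = None,
    blocks: tuple[str, ...] | None = None,
    mode: str = "epochs",
) -> ParticipantRecording:
    """Simulate all sessions/blocks of one participant.

    mode="continuous" synthesises the full continuous block recording
    (baseline, trains, intervals) and runs the standard segmentation on it;
    mode="epochs" synthesises only the analysis epochs directly (identical
    signal model evaluated at the epochs' absolute session times, with
    epoch-wise independent noise), which is much cheaper and is the default
    for cohort-scale simulation.
    """
    if spec.tacs_gain != 0.0 and len(spec.effect_units) == 0:
        raise ValueError("effect_units is empty but tacs_gain is nonzero")
    if any(u < 0 or u >= layout.n_units for u in spec.effect_units):
        raise ValueError("effect_units outside layout")
    if mode not in ("epochs", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    sessions = sessions or design.sessions
    blocks = blocks or design.blocks
    rng = np.random.default_rng(spec.seed)
    nu = layout.n_units
    theta = rng.uniform(0, 2 * np.pi, nu)
    # one slow modulator drives all units coherently (a bodily-rhythm-like
    # source); carrier phases stay unit-specific
    phi = np.full(nu, rng.uniform(0, 2 * np.pi))
    fs = design.sampling_rate
    gain_mask = np.zeros(nu, dtype=bool)
    gain_mask[list(spec.effect_units)] = True

    trialsets: dict[tuple[str, str, str], TrialSet] = {}
    for session in sessions:
        for block in blocks:
            onsets = design.train_onsets(block)
            dur = design.train_durations[block]
            in_tacs = session == "tacs"
            mod_post = (
                spec.mod_depth_tacs
                if (in_tacs and spec.mod_depth_tacs is not None)
                else spec.mod_depth
            )
            if mode == "continuous":
                n = int(round(design.block_duration(block) * fs))
                t = np.arange(n) / fs
                sig = _oscillation(spec, t, theta, phi, None, spec.mod_depth)
                sig += colored_noise(
                    rng, (nu,), n, fs, spec.noise_exponent, spec.noise_amp
                )
                # per-train effect & modulation depth inside usable windows
                for onset in onsets:
                    off = onset + dur
                    i0 = int(round((off + POST_TRIM[0]) * fs))
                    i1 = int(round((off + POST_TRIM[1]) * fs))
                    seg_t = t[i0:i1]
                    base_osc = _oscillation(
                        spec, seg_t, theta, phi, None, spec.mod_depth
                    )
                    eff_osc = _oscillation(
                        spec, seg_t, theta, phi,
                        gain_mask if in_tacs else None, mod_post,
                    )
                    jit = np.exp(spec.amp_jitter_sd * rng.standard_normal())
                    sig[:, i0:i1] += jit * eff_osc - base_osc
                # baseline trial jitter: rescale oscillation per 5.5 s epoch
                n_base = int(
                    round((design.baseline_duration - BASELINE_DISCARD)
                          / BASELINE_EPOCH)
                )
                for k in range(n_base):
                    i0 = int(round(k * BASELINE_EPOCH * fs))
                    i1 = int(round((k + 1) * BASELINE_EPOCH * fs))
                    jit = np.exp(spec.amp_jitter_sd * rng.standard_normal())
                    sig[:, i0:i1] += (jit - 1.0) * _oscillation(
                        spec, t[i0:i1], theta, phi, None, spec.mod_depth
                    )
                baseline, post = segment_recording(sig, design, onsets, block)
            else:
                n_ep = int(round(BASELINE_EPOCH * fs))
                n_base = int(
                    round((design.baseline_duration - BASELINE_DISCARD)
                          / BASELINE_EPOCH)
                )
                # baseline epochs at absolute times k*5.5 .. k*5.5+5.5
                t0 = np.arange(n_base) * BASELINE_EPOCH
                t_abs = t0[:, None] + np.arange(n_ep) / fs
                osc = _oscillation(spec, t_abs, theta, phi, None,
                                   spec.mod_depth)
                jit = np.exp(
                    spec.amp_jitter_sd * rng.standard_normal(n_base)
                ).astype(np.float32)
                data = jit[None, :, None] * osc + colored_noise(
                    rng, (nu, n_base), n_ep, fs,
                    spec.noise_exponent, spec.noise_amp,
                )
                baseline = TrialSet(
                    data, np.arange(n_ep) / fs, "baseline", fs
                )
                # post epochs at absolute times offset+4.2 .. offset+9.7
                t0 = onsets + dur + POST_TRIM[0]
                t_abs = t0[:, None] + np.arange(n_ep) / fs
                osc = _oscillation(
                    spec, t_abs, theta, phi,
                    gain_mask if in_tacs else None, mod_post,
                )
                jit = np.exp(
                    spec.amp_jitter_sd
                    * rng.standard_normal(design.trains_per_block)
                ).astype(np.float32)
                data = jit[None, :, None] * osc + colored_noise(
                    rng, (nu, design.trains_per_block), n_ep, fs,
                    spec.noise_exponent, spec.noise_amp,
                )
                post = TrialSet(
                    data, POST_TRIM[0] + np.arange(n_ep) / fs, "post", fs
                )
            trialsets[(session, block, "baseline")] = baseline
            trialsets[(session, block, "post")] = post
    return ParticipantRecording(design, layout, spec, trialsets)


def participant_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic, collision-free per-participant seeds.

    Seeds are the first words of ``SeedSequence(master_seed).spawn(n)``
    child states; distinctness is checked explicitly.
    """
    children = np.random.SeedSequence(master_seed).spawn(n)
    seeds = [int(c.generate_state(1)[0]) for c in children]
    if len(set(seeds)) != n:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("seed collision in cohort derivation")
    return seeds


def draw_cohort_specs(
    n: int,
    template: EffectSpec,
    master_seed: int,
    isf_choices: tuple[int, ...] = DEFAULT_ISF_CHOICES,
) -> list[EffectSpec]:
    """Per-participant EffectSpecs: ISF drawn uniformly from ``isf_choices``,
    seeds derived deterministically from ``master_seed``."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 participants")
    rng = np.random.default_rng(master_seed)
    isfs = rng.choice(isf_choices, size=n, replace=True)
    seeds = participant_seeds(master_seed, n)
    return [
        replace(template, isf=float(isf), seed=seed)
        for isf, seed in zip(isfs, seeds)
    ]


def generate_cohort(
    n: int,
    design: StudyDesign,
    layout: UnitLayout,
    template: EffectSpec,
    master_seed: int,
    isf_choices: tuple[int, ...] = DEFAULT_ISF_CHOICES,
    sessions: tuple[str, ...] | None = None,
    blocks: tuple[str, ...] | None = None,
    mode: str = "epochs",
):
    """Yield one :class:`ParticipantRecording` per cohort member (lazy)."""
    for spec in draw_cohort_specs(n, template, master_seed, isf_choices):
        yield generate_participant(design, layout, spec, sessions, blocks, mode)


def default_layout(
    n_rows: int = 8, n_cols: int = 8, with_frontal: bool = False
) -> tuple[UnitLayout, tuple[int, ...]]:
    """Default lattice: a contiguous 3x3 'somatosensory' patch (plus an
    optional second 'frontal' patch) on an ``n_rows x n_cols`` grid.

    Returns the layout and the indices of all labelled (effect) units.
    """
    # the frontal patch sits directly below the somatosensory one so that,
    # when both carry the effect, they form one contiguous cluster spanning
    # the two regions (the configuration the region split dissects)
    soma = (slice(1, 4), slice(1, 4))
    frontal = (slice(n_rows - 4, n_rows - 1), slice(1, 4))
    layout = grid_layout(
        n_rows, n_cols, somatosensory=soma,
        frontal=frontal if with_frontal else None,
    )
    effect = np.flatnonzero(
        np.isin(np.asarray(layout.region_labels), ("somatosensory", "frontal"))
    )
    return layout, tuple(int(i) for i in effect)
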