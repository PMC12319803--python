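"""Monte-Carlo validation experiments run against known synthetic truth.

Each experiment regenerates cohorts from scratch under the study's design
constants and measures an operating characteristic of the analysis chain:
the false-positive rate of the spatial cluster test on null cohorts, the
detection rate and recovered effect size under an injected 30 % power gain,
exact ISF recovery, and recovery of the injected slow power modulation.
Every function takes a master seed and derives all cohort seeds from it.
"""

from __future__ import annotations

import numpy as np

from .modulatory import MOD_CENTRES, modulatory_contrast, modulatory_power, \
    trial_power_difference
from .cluster_stats import ClusterTestSpec
from .data_core import StudyDesign, grid_layout
from .pipeline import PipelineConfig, run_pipeline
from .spectral import FUNDAMENTAL_OFFSETS, compute_tfr, estimate_isf
from .synthgen import EffectSpec, generate_participant


def _cohort_seed(master_seed: int, k: int) -> int:
    return int(np.random.SeedSequence([master_seed, k]).generate_state(1)[0]
               % (2**31))


def null_calibration(
    n_cohorts: int = 200,
    master_seed: int = 0,
    n_participants: int = 8,
    grid: int = 4,
    n_permutations: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the spatial cluster test on effect-free cohorts.

    Each cohort is a full simulated experiment with ``tacs_gain = 0`` — the
    two sessions differ only in noise — and counts as a false positive when
    any spatial cluster reaches p < alpha.
    """
    config = PipelineConfig(
        n_participants=n_participants, layout_rows=grid, layout_cols=grid,
        blocks=("train10",), effect={"tacs_gain": 0.0},
        n_permutations=n_permutations, stages=("spatial",),
    )
    hits = 0
    for k in range(n_cohorts):
        _, report = run_pipeline(config, _cohort_seed(master_seed, k))
        if any(c["p"] < alpha for c in report["spatial_clusters"]):
            hits += 1
    return {"type1_rate": hits / n_cohorts, "n_cohorts": n_cohorts,
            "n_participants": n_participants}


def effect_recovery(
    n_cohorts: int = 50,
    master_seed: int = 0,
    n_participants: int = 12,
    grid: int = 5,
    tacs_gain: float = 0.30,
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Detection rate and recovered power change under an injected gain.

    The effect sits on the 3x3 'somatosensory' patch of a ``grid x grid``
    layout.  A cohort counts as detected when a significant positive
    spatial cluster overlaps the patch; the recovered effect size is the
    report's tACS-session mean power change (%) at ISF within the cluster.
    """
    config = PipelineConfig(
        n_participants=n_participants, layout_rows=grid, layout_cols=grid,
        blocks=("train10",), effect={"tacs_gain": tacs_gain},
        n_permutations=n_permutations, stages=("spatial",),
    )
    layout, patch = config.layout()
    patch = set(patch)
    detected = 0
    changes_tacs: list[float] = []
    changes_control: list[float] = []
    for k in range(n_cohorts):
        _, report = run_pipeline(config, _cohort_seed(master_seed, k))
        sig = [c for c in report["spatial_clusters"]
               if c["p"] < alpha and c["sign"] > 0
               and patch & set(c["units"])]
        if sig:
            detected += 1
        if "power_change_pct" in report:
            changes_tacs.append(report["power_change_pct"]["tacs"]["mean"])
            changes_control.append(
                report["power_change_pct"]["control"]["mean"]
            )
    return {
        "detection_rate": detected / n_cohorts,
        "mean_power_change_tacs_pct": float(np.mean(changes_tacs))
        if changes_tacs else float("nan"),
        "mean_power_change_control_pct": float(np.mean(changes_control))
        if changes_control else float("nan"),
        "n_cohorts": n_cohorts,
    }


def _single_participant(isf: float, seed: int, grid: int = 3,
                        **spec_kwargs):
    """One participant on an all-effect 3x3 patch, tACS session only."""
    layout = grid_layout(grid, grid,
                         somatosensory=(slice(0, grid), slice(0, grid)))
    design = StudyDesign(blocks=("train10",))
    spec = EffectSpec(isf=isf, seed=seed,
                      effect_units=tuple(range(layout.n_units)),
                      **spec_kwargs)
    return generate_participant(design, layout, spec,
                                sessions=("tacs",)), layout


def isf_recovery(n_seeds: int = 50, master_seed: int = 0) -> dict:
    """Fraction of runs in which the baseline alpha peak is recovered
    exactly on the 1 Hz grid, cycling the injected ISF through 8-13 Hz."""
    exact = 0
    for k in range(n_seeds):
        isf = float(8 + k % 6)
        rec, layout = _single_participant(isf, _cohort_seed(master_seed, k))
        base = rec.trialsets[("tacs", "train10", "baseline")]
        est = estimate_isf(base, units=np.arange(layout.n_units)).isf
        exact += est == isf
    return {"isf_exact_rate": exact / n_seeds, "n_seeds": n_seeds}


def _participant_mod_spectrum(rec, layout, isf: float) -> np.ndarray:
    """Trial-averaged modulatory spectrum of one session's post trials."""
    post = rec.trialsets[("tacs", "train10", "post")] \
        if ("tacs", "train10", "post") in rec.trialsets \
        else rec.trialsets[("control", "train10", "post")]
    carriers = isf + FUNDAMENTAL_OFFSETS.astype(float)
    tfr = compute_tfr(post, "win400ms", freqs=carriers)
    diff = trial_power_difference(tfr.power, np.arange(layout.n_units),
                                  carrier_offsets=FUNDAMENTAL_OFFSETS)
    return modulatory_power(diff).trial_average()


def modulatory_argmax(
    n_seeds: int = 50,
    master_seed: int = 0,
    mod_depth: float = 0.3,
    mod_freq: float = 0.4,
) -> dict:
    """How often the modulatory spectrum peaks at the injected slow
    frequency, read at the ISF carrier (offset 0)."""
    k0 = int(np.flatnonzero(FUNDAMENTAL_OFFSETS == 0)[0])
    target = int(np.argmin(np.abs(MOD_CENTRES - mod_freq)))
    hits = 0
    for k in range(n_seeds):
        isf = float(8 + k % 6)
        rec, layout = _single_participant(
            isf, _cohort_seed(master_seed, 1000 + k),
            mod_depth=mod_depth, mod_freq=mod_freq,
        )
        spec = _participant_mod_spectrum(rec, layout, isf)
        hits += int(np.argmax(spec[:, k0])) == target
    return {"argmax_rate": hits / n_seeds, "n_seeds": n_seeds,
            "target_centre": float(MOD_CENTRES[target])}


def modulatory_contrast_recovery(
    n_cohorts: int = 25,
    master_seed: int = 0,
    n_participants: int = 6,
    control_depth: float = 0.3,
    tacs_depth: float = 0.6,
    n_permutations: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Detection of a condition difference in modulation depth.

    Participants carry a stronger 0.4 Hz amplitude modulation in tACS post
    epochs than in control; the group modulatory contrast should yield a
    significant positive cluster whose rows include the 0.4 Hz centre.
    The known effect patch stands in for the significant spatial cluster.
    """
    grid = 3
    layout = grid_layout(grid, grid,
                         somatosensory=(slice(0, grid), slice(0, grid)))
    design = StudyDesign(blocks=("train10",))
    units = np.arange(layout.n_units)
    carriers_row = int(np.argmin(np.abs(MOD_CENTRES - 0.4)))
    n_carr = len(FUNDAMENTAL_OFFSETS)
    hits = 0
    for k in range(n_cohorts):
        rng = np.random.default_rng(_cohort_seed(master_seed, 2000 + k))
        tacs_specs, ctrl_specs = [], []
        for i in range(n_participants):
            isf = float(rng.integers(8, 14))
            seed = int(rng.integers(0, 2**31))
            spec = EffectSpec(
                isf=isf, seed=seed, effect_units=tuple(units),
                mod_depth=control_depth, mod_depth_tacs=tacs_depth,
                tacs_gain=0.0,
            )
            rec = generate_participant(design, layout, spec)
            carriers = isf + FUNDAMENTAL_OFFSETS.astype(float)
            per_cond = {}
            for cond in ("tacs", "control"):
                post = rec.trialsets[(cond, "train10", "post")]
                tfr = compute_tfr(post, "win400ms", freqs=carriers)
                diff = trial_power_difference(
                    tfr.power, units, carrier_offsets=FUNDAMENTAL_OFFSETS
                )
                per_cond[cond] = modulatory_power(diff).trial_average()
            tacs_specs.append(per_cond["tacs"])
            ctrl_specs.append(per_cond["control"])
        test_spec = ClusterTestSpec(
            n_permutations=n_permutations,
            seed=_cohort_seed(master_seed, 3000 + k),
            adjacency_domain="modfreq_carrierfreq",
        )
        result = modulatory_contrast(
            np.stack(tacs_specs), np.stack(ctrl_specs), test_spec
        )
        for c in result.clusters:
            if c.p < alpha and c.sign > 0 and np.any(
                c.members // n_carr == carriers_row
            ):
                hits += 1
                break
    return {"contrast_rate": hits / n_cohorts, "n_cohorts": n_cohorts}
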