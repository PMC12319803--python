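"""End-to-end orchestration: simulate -> ISF -> TFR -> align -> delta power
-> cluster tests -> binning -> modulatory spectrum, from one config.

The pipeline analyses a synthetic cohort exactly as the MEG analysis would
treat real recordings: every participant gets an estimated ISF (from the
baseline of the first block), ISF-aligned delta-power maps per session and
block, pooled maps, and the battery of group statistics.  All randomness
derives from one master seed; re-running an unchanged config reproduces
identical derived arrays and an identical report.

Participants are processed one at a time and regenerated deterministically
from their per-participant seeds where a later stage (the modulatory
analysis, which needs the significant-cluster units) has to revisit the raw
data, so cohort-scale memory stays bounded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import binning as binning_mod
from . import modulatory as modulatory_mod
from .cluster_stats import (
    ClusterTestResult,
    ClusterTestSpec,
    block_contrast,
    cluster_permutation_test,
    delta_power_from_aligned,
    grid_adjacency,
    region_split_test,
)
from .data_core import StudyDesign, UnitLayout
from .spectral import (
    FUNDAMENTAL_OFFSETS,
    TFR_FREQS,
    align_tfr,
    compute_tfr,
    estimate_isf,
)
from .synthgen import (
    DEFAULT_ISF_CHOICES,
    EffectSpec,
    ParticipantRecording,
    default_layout,
    draw_cohort_specs,
    generate_participant,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

ALL_STAGES = ("spatial", "tf", "regions", "block_contrast", "binning",
              "modulatory")


@dataclass(frozen=True)
class PipelineConfig:
    """One self-contained description of a cohort simulation + analysis."""

    n_participants: int = 24
    layout_rows: int = 8
    layout_cols: int = 8
    with_frontal: bool = False
    blocks: tuple[str, ...] = ("train10", "train30")
    trains_per_block: int = 20
    baseline_duration: float = 120.0
    sampling_rate: float = 1000.0
    effect: dict = field(default_factory=dict)  # EffectSpec overrides
    isf_choices: tuple[int, ...] = DEFAULT_ISF_CHOICES
    alpha: float = 0.05
    n_permutations: int = 1000
    simulate_mode: str = "epochs"
    stages: tuple[str, ...] = ALL_STAGES
    isf_units_region: str = "somatosensory"

    def design(self) -> StudyDesign:
        return StudyDesign(
            n_participants=self.n_participants,
            blocks=self.blocks,
            trains_per_block=self.trains_per_block,
            baseline_duration=self.baseline_duration,
            sampling_rate=self.sampling_rate,
        )

    def layout(self) -> tuple[UnitLayout, tuple[int, ...]]:
        return default_layout(self.layout_rows, self.layout_cols,
                              self.with_frontal)

    def template(self, effect_units: tuple[int, ...]) -> EffectSpec:
        kwargs: dict = {"effect_units": effect_units}
        kwargs.update(self.effect)
        if "effect_units" in self.effect:
            kwargs["effect_units"] = tuple(self.effect["effect_units"])
        return EffectSpec(**kwargs)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("blocks", "isf_choices", "stages"):
            d[key] = list(d[key])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        d = json.loads(s)
        for key in ("blocks", "isf_choices", "stages"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    version: str = __version__
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, **params) -> None:
        self.stages.append(
            {"stage": name, "params": params, "timestamp": time.time()}
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _stage_seed(master_seed: int, label: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ParticipantDerived:
    """Per-participant products of the first analysis pass."""

    isf: float
    # (condition, block) -> delta map (unit, offset, time)
    delta: dict[tuple[str, str], np.ndarray]
    # (condition, block) -> per-trial time-avg power at ISF (trial, unit)
    post_isf_power: dict[tuple[str, str], np.ndarray]
    # (condition, block) -> baseline per-trial time-avg power (trial, unit)
    base_isf_power: dict[tuple[str, str], np.ndarray]


def analyse_participant(
    rec: ParticipantRecording,
    config: PipelineConfig,
    restrict_to_isf: bool = False,
) -> ParticipantDerived:
    """First pass: ISF, aligned TFRs and delta-power maps for one
    participant.

    ``restrict_to_isf=True`` decomposes only at the participant's estimated
    ISF instead of the full 5-40 Hz axis — much cheaper when only the
    spatial/ISF-level stages are enabled; the other aligned offsets are
    then simply missing (NaN).
    """
    layout = rec.layout
    isf_units = layout.units_in_region(config.isf_units_region)
    first = (rec.design.sessions[0], rec.design.blocks[0])
    spectrum = estimate_isf(rec.trialsets[first + ("baseline",)],
                            units=isf_units)
    isf = spectrum.isf
    use_freqs = np.array([isf]) if restrict_to_isf else TFR_FREQS
    delta, post_pow, base_pow = {}, {}, {}
    for session in rec.design.sessions:
        for block in rec.design.blocks:
            post = rec.trialsets[(session, block, "post")]
            base = rec.trialsets[(session, block, "baseline")]
            a_post = align_tfr(compute_tfr(post, "cycles7", use_freqs), isf)
            a_base = align_tfr(compute_tfr(base, "cycles7", use_freqs), isf)
            dmap = delta_power_from_aligned(
                a_post, a_base, participant=rec.spec.seed,
                condition=session, block=block,
            )
            delta[(session, block)] = dmap.values
            k0 = int(np.flatnonzero(FUNDAMENTAL_OFFSETS == 0)[0])
            post_pow[(session, block)] = np.nanmean(
                a_post.power[:, :, k0, :], axis=-1
            )
            base_pow[(session, block)] = np.nanmean(
                a_base.power[:, :, k0, :], axis=-1
            )
    return ParticipantDerived(
        isf=isf, delta=delta, post_isf_power=post_pow,
        base_isf_power=base_pow,
    )


def _offset0(maps: np.ndarray) -> np.ndarray:
    """Spatial view: offset-0 bin, time-averaged -> (participants, units)."""
    k0 = int(np.flatnonzero(FUNDAMENTAL_OFFSETS == 0)[0])
    return np.nanmean(maps[:, :, k0, :], axis=-1)


def run_pipeline(
    config: PipelineConfig,
    master_seed: int,
    store: dict | None = None,
) -> tuple[RunManifest, dict]:
    """Run the configured stage chain; returns (manifest, report).

    ``store`` is an optional stage cache: stage outputs already present are
    reused instead of recomputed, which implements skip/resume; passing the
    same populated store reproduces identical downstream results.
    """
    store = {} if store is None else store
    manifest = RunManifest(config.config_hash(), master_seed)
    report: dict = {"config_hash": config.config_hash(),
                    "master_seed": master_seed}
    design = config.design()
    layout, effect_units = config.layout()
    template = config.template(effect_units)
    specs = draw_cohort_specs(
        config.n_participants, template, master_seed, config.isf_choices
    )
    need_full_tfr = bool({"tf", "regions"} & set(config.stages))

    if "derived" not in store:
        logger.info("pass 1: simulating and analysing %d participants",
                    len(specs))
        derived = []
        for i, spec in enumerate(specs):
            rec = generate_participant(design, layout, spec,
                                       mode=config.simulate_mode)
            der = analyse_participant(
                rec, config, restrict_to_isf=not need_full_tfr
            )
            derived.append(der)
            logger.info("participant %d/%d: ISF=%g", i + 1, len(specs),
                        der.isf)
        store["derived"] = derived
    derived = store["derived"]
    manifest.record("simulate_analyse", n=len(derived),
                    mode=config.simulate_mode)
    report["isf_estimates"] = [d.isf for d in derived]
    report["isf_true"] = [s.isf for s in specs]

    # pooled per-participant maps per condition
    def pooled_maps(condition: str) -> np.ndarray:
        out = []
        for d in derived:
            vals = [d.delta[(condition, b)] for b in design.blocks]
            m = vals[0]
            for v in vals[1:]:
                m = 0.5 * (m + v)
            out.append(m)
        return np.stack(out)

    if "pooled" not in store:
        store["pooled"] = {c: pooled_maps(c) for c in design.sessions}
    pooled = store["pooled"]

    cluster_units = np.array([], dtype=int)
    spatial_result: ClusterTestResult | None = None
    if "spatial" in config.stages:
        if "spatial" not in store:
            spec = ClusterTestSpec(
                alpha_form=config.alpha,
                n_permutations=config.n_permutations,
                seed=_stage_seed(master_seed, "spatial"),
                adjacency_domain="space",
            )
            store["spatial"] = cluster_permutation_test(
                _offset0(pooled["tacs"]), _offset0(pooled["control"]),
                spec, layout.adjacency,
            )
        spatial_result = store["spatial"]
        manifest.record("spatial", n_permutations=config.n_permutations,
                        seed=spatial_result.seed)
        report["spatial_clusters"] = [
            {"size": len(c.members), "sum_t": c.sum_t, "sign": c.sign,
             "p": c.p, "units": c.members.tolist()}
            for c in spatial_result.clusters
        ]
        sig_pos = [c for c in spatial_result.significant(config.alpha)
                   if c.sign > 0]
        if sig_pos:
            cluster_units = max(sig_pos, key=lambda c: abs(c.sum_t)).members
        report["significant_cluster_units"] = cluster_units.tolist()

    # mean power change (%) at ISF within the significant cluster
    if len(cluster_units):
        report["power_change_pct"] = {}
        for condition in design.sessions:
            per_part = []
            for d in derived:
                vals = []
                for block in design.blocks:
                    post = d.post_isf_power[(condition, block)]
                    base = d.base_isf_power[(condition, block)]
                    avg_base = base[:, cluster_units].mean(axis=0)
                    pd = (post[:, cluster_units] - avg_base) / avg_base
                    vals.append(pd.mean())
                per_part.append(100.0 * float(np.mean(vals)))
            report["power_change_pct"][condition] = {
                "mean": float(np.mean(per_part)),
                "sd": float(np.std(per_part, ddof=1)),
                "per_participant": per_part,
            }

    if "tf" in config.stages and len(cluster_units):
        if "tf" not in store:
            spec = ClusterTestSpec(
                alpha_form=config.alpha,
                n_permutations=config.n_permutations,
                seed=_stage_seed(master_seed, "tf"),
                adjacency_domain="time_frequency",
            )
            t_maps = pooled["tacs"][:, cluster_units].mean(axis=1)
            c_maps = pooled["control"][:, cluster_units].mean(axis=1)
            store["tf"] = cluster_permutation_test(
                t_maps, c_maps, spec, grid_adjacency(t_maps.shape[1:])
            )
        tf_result = store["tf"]
        manifest.record("tf", seed=tf_result.seed)
        report["tf_clusters"] = [
            {"size": len(c.members), "sum_t": c.sum_t, "sign": c.sign,
             "p": c.p}
            for c in tf_result.clusters
        ]

    if "regions" in config.stages and len(cluster_units) \
            and layout.region_labels is not None:
        try:
            spec = ClusterTestSpec(
                alpha_form=config.alpha,
                n_permutations=config.n_permutations,
                seed=_stage_seed(master_seed, "regions"),
                adjacency_domain="time_frequency",
            )
            if "regions" not in store:
                store["regions"] = region_split_test(
                    pooled["tacs"], pooled["control"], cluster_units,
                    layout, spec,
                )
            report["region_clusters"] = {
                region: [{"size": len(c.members), "sum_t": c.sum_t,
                          "sign": c.sign, "p": c.p}
                         for c in res.clusters]
                for region, res in store["regions"].items()
            }
            manifest.record("regions")
        except ValueError as exc:
            report["region_clusters"] = {"error": str(exc)}

    if "block_contrast" in config.stages and len(cluster_units) >= 2 \
            and len(design.blocks) == 2:
        if "block_contrast" not in store:
            k0 = int(np.flatnonzero(FUNDAMENTAL_OFFSETS == 0)[0])
            by_block = {
                cond: {
                    blk: np.stack([
                        np.nanmean(d.delta[(cond, blk)][:, k0, :], axis=-1)
                        for d in derived
                    ])
                    for blk in design.blocks
                }
                for cond in design.sessions
            }
            store["block_contrast"] = block_contrast(
                by_block["tacs"], by_block["control"], cluster_units
            )
        bc = store["block_contrast"]
        manifest.record("block_contrast")
        report["block_contrast"] = {
            "u": bc.u_stat, "p": bc.p,
            "t_values": {k: v.tolist() for k, v in bc.t_values.items()},
        }

    if "binning" in config.stages and len(cluster_units) \
            and design.trains_per_block == binning_mod.N_BINS \
            * binning_mod.TRIALS_PER_BIN:
        if "binning" not in store:
            tables: dict = {}
            for cond in design.sessions:
                for blk in design.blocks:
                    rows = []
                    for d in derived:
                        post = d.post_isf_power[(cond, blk)][:, :, None]
                        base = d.base_isf_power[(cond, blk)][:, :, None]
                        bs = binning_mod.compute_bin_series(
                            post, base, cluster_units,
                            condition=cond, block=blk,
                        )
                        rows.append(bs.bin_means)
                    tables[(cond, blk)] = np.stack(rows)
            store["binning"] = {
                key: (tbl, binning_mod.friedman_bins(tbl))
                for key, tbl in tables.items()
            }
        manifest.record("binning")
        report["binning"] = {
            f"{cond}_{blk}": {
                "chi2": res.chi2, "df": res.df, "p": res.p,
                "bin_means_pct": (100.0 * tbl.mean(axis=0)).tolist(),
                "posthoc_p": None if res.posthoc is None
                else res.posthoc.tolist(),
            }
            for (cond, blk), (tbl, res) in store["binning"].items()
        }

    if "modulatory" in config.stages and len(cluster_units):
        if "modulatory" not in store:
            store["modulatory"] = _modulatory_stage(
                config, design, layout, specs, derived, cluster_units,
                master_seed,
            )
        manifest.record("modulatory")
        report["modulatory"] = {
            blk: [{"size": len(c.members), "sum_t": c.sum_t,
                   "sign": c.sign, "p": c.p,
                   "mod_rows": sorted({int(m) for m in
                                       c.members // len(FUNDAMENTAL_OFFSETS)})}
                  for c in res.clusters]
            for blk, res in store["modulatory"].items()
        }

    report["n_participants"] = len(derived)
    return manifest, report


def _modulatory_stage(
    config: PipelineConfig,
    design: StudyDesign,
    layout: UnitLayout,
    specs: list[EffectSpec],
    derived: list[ParticipantDerived],
    cluster_units: np.ndarray,
    master_seed: int,
) -> dict[str, ClusterTestResult]:
    """Second pass: regenerate participants and run the modulatory contrast
    per block over the significant-cluster units."""
    results = {}
    spectra: dict[tuple[str, str], list[np.ndarray]] = {
        (cond, blk): [] for cond in design.sessions for blk in design.blocks
    }
    for spec, der in zip(specs, derived):
        rec = generate_participant(design, layout, spec,
                                   mode=config.simulate_mode)
        carriers = der.isf + FUNDAMENTAL_OFFSETS.astype(float)
        for cond in design.sessions:
            for blk in design.blocks:
                post = rec.trialsets[(cond, blk, "post")]
                tfr = compute_tfr(post, "win400ms", freqs=carriers)
                diff = modulatory_mod.trial_power_difference(
                    tfr.power, cluster_units,
                    carrier_offsets=FUNDAMENTAL_OFFSETS,
                )
                ms = modulatory_mod.modulatory_power(diff)
                spectra[(cond, blk)].append(ms.trial_average())
    for blk in design.blocks:
        spec = ClusterTestSpec(
            alpha_form=config.alpha,
            n_permutations=config.n_permutations,
            seed=_stage_seed(master_seed, f"modulatory:{blk}"),
            adjacency_domain="modfreq_carrierfreq",
        )
        results[blk] = modulatory_mod.modulatory_contrast(
            np.stack(spectra[("tacs", blk)]),
            np.stack(spectra[("control", blk)]),
            spec,
        )
    return results


def make_fixtures(size: str = "tiny") -> PipelineConfig:
    """Seeded study configurations for testing and demonstration.

    ``tiny``: 4 participants on a 3x3 layout with 6 trains of one block —
    small enough that the group permutation null (2^4 = 16 sign flips) is
    enumerated exhaustively.  ``demo``: the full design — 24 participants,
    8x8 layout, 20 trains in both blocks.
    """
    if size == "tiny":
        return PipelineConfig(
            n_participants=4, layout_rows=3, layout_cols=3,
            blocks=("train10",), trains_per_block=6,
            baseline_duration=6 * 5.5 + 10.0,
            effect={"tacs_gain": 0.0},
            n_permutations=1000,
            stages=("spatial",),
        )
    if size == "demo":
        return PipelineConfig()
    raise ValueError(f"unknown fixture size {size!r}")
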