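# tacsalpha

Detecting after-effects of short-period transcranial alternating current
stimulation (tACS) on somatosensory alpha oscillations.

## The problem

Short (10–30 s) trains of tACS, applied over the somatosensory cortex at
each participant's individual alpha peak frequency (the *individual
stimulation frequency*, ISF, 7–14 Hz), may leave an elevation of alpha
power in the intervals after each train. Detecting that after-effect from
trial-structured MEG/EEG-like recordings requires a chain of estimators —
and a way to know the chain works before pointing it at real data. This
package provides both: the full analysis pipeline, and a synthetic
multi-unit generator with every effect parameter known, so each stage can
be validated against ground truth.

It is written for electrophysiologists and methods researchers who want a
tested, scriptable implementation of this analysis family: ISF-aligned
power statistics with nonparametric cluster inference.

## The analysis

For each participant, session (tACS / control) and block (10 s / 30 s
trains), recordings are segmented into 20 baseline epochs (5.5 s each,
from the first 110 s of the 2-min baseline) and 20 post-stimulation epochs
(4.2–9.7 s after train offset). Then:

1. **ISF** — argmax of Hanning-tapered FFT power (4–40 Hz, 1 Hz grid)
   within 7–14 Hz on the baseline.
2. **TFR** — sliding-window Hanning power (7 cycles per window, 100 ms
   steps, 5–40 Hz), frequency axis re-indexed as offsets ISF−2 … ISF+26
   so maps are comparable across participants (a harmonic variant aligns
   on 2·ISF).
3. **Δpower** — per element, a two-sample t contrasting per-trial post
   power against per-trial (time-averaged) baseline power:
   `Δpower = (power_post − power_baseline) / SE_pooled`.
4. **Cluster permutation tests** — paired group t of Δpower (tACS vs
   control), clusters of adjacent suprathreshold elements (|t| above the
   two-tailed p < 0.05 threshold, minimum size 2), summed-t cluster
   statistic, null distribution of per-permutation maxima under
   condition-label sign flips (exhaustively enumerated when 2ⁿ ≤
   n_permutations, so small-cohort p values are exact). Run spatially over
   the unit graph, over the time–frequency plane within the significant
   spatial cluster, per region (somatosensory / frontal split), and the
   10 s vs 30 s contrast via Wilcoxon rank-sum on cluster-member t values.
5. **Binning** — per-trial relative power change at ISF grouped into 5
   trial-order bins of 4; Friedman test across participants with pairwise
   Conover post hoc (Bonferroni) when the omnibus is significant.
6. **Modulatory spectrum** — slow (0.1–2 Hz) rhythmicity of alpha power:
   trial-to-trial power differences, a zero-phase band-pass filter bank,
   Hilbert envelopes, and the same cluster machinery on the modulation ×
   carrier plane.

The synthetic generator injects a known power gain (`tacs_gain`, e.g.
+30 %) on a spatial patch in tACS post epochs, a slow coherent amplitude
modulation (default 0.4 Hz), 1/f background noise and per-trial amplitude
jitter — the statistical structure the analysis assumes, with none of the
hardware artifacts it does not model. See `docs/methods.md` for the model
and every default.

## Worked example

Simulate a small cohort with a +30 % injected gain and run the ISF-level
stages:

```python
from tacsalpha import PipelineConfig, run_pipeline

config = PipelineConfig(
    n_participants=6, layout_rows=4, layout_cols=4,
    blocks=("train10", "train30"), n_permutations=300,
    stages=("spatial", "binning", "block_contrast"),
)
manifest, report = run_pipeline(config, master_seed=2024)

sig = [c for c in report["spatial_clusters"] if c["p"] < 0.05]
print("significant spatial clusters:", [(c["size"], round(c["p"], 4)) for c in sig])
print("tACS power change at ISF: %.2f%% (SD %.2f)" % (
    report["power_change_pct"]["tacs"]["mean"],
    report["power_change_pct"]["tacs"]["sd"]))
print("control power change at ISF: %.2f%%" %
      report["power_change_pct"]["control"]["mean"])
print("10s-vs-30s rank-sum p: %.3f" % report["block_contrast"]["p"])
```

prints

```
significant spatial clusters: [(9, 0.0312)]
tACS power change at ISF: 25.13% (SD 5.75)
control power change at ISF: -1.67%
10s-vs-30s rank-sum p: 0.331
```

One cluster of 9 units — the effect patch — is significant (p = 0.031
from 300 permutations); the recovered tACS power change sits just under
the injected +30 % (raw ISF-bin power includes a noise share that does not
scale with the gain), the control session shows none, and with equal gain
in both blocks the train-duration contrast is null, as it should be.

The same chain is scriptable from a shell:

```bash
tacsalpha fixtures --size tiny --out tiny.json
tacsalpha run --config tiny.json --out report.json --seed 11
```

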