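# rgcpipe

Functional classification and projection-target comparison of retinal
ganglion cell (RGC) recordings.

## The problem

Mouse RGCs project to (among other targets) the superior colliculus (SC)
and the dorsal lateral geniculate nucleus (dLGN). Whether these two
retinorecipient structures receive the same retinal information can be
asked quantitatively: retrogradely label RGCs from each target, record
each labelled cell's spiking responses to a standard stimulus battery
(luminance steps, spots of 50–800 μm, bars moving in 8 directions at
800 μm/s, 7–8 speeds from 50–3,200 μm/s, 1/2/4 Hz sinusoidal luminance
modulation), reduce each cell to a handful of functional metrics, assign
it to a functional group, and compare group proportions between the two
projection populations. `rgcpipe` implements that full analysis chain,
plus the spatial analysis of labelled-cell maps on the retina, plus a
synthetic-data generator with known ground truth so every stage is
testable without recordings.

## The metrics at its core

For each cell, from kernel-smoothed spike density functions (SDF,
Gaussian kernel, default bandwidth 25 ms):

- spontaneous rate; response latency (threshold 0.1 of peak above
  baseline sustained ≥ 50 ms);
- **response duration** = ∫SDF over 500 ms from latency ÷ (peak × 0.5 s)
  ∈ [0, 1] — sustained ≈ 1, transient ≈ 0;
- **NVSL** (normalised vector sum length) = |Σ rⱼ e^{iθⱼ}| / Σ rⱼ over 8
  motion directions, with the preferred direction as its argument;
- polarity (ON / OFF / ON_OFF) from baseline-subtracted onset/offset step
  responses via the index (on − off)/(on + off);
- best size and speed, tuning widths (= curve integral / peak), a gamma
  fit of the size curve giving the interpolated best size, and the
  half-maximal ("cutoff") temporal frequency.

Cells are assigned to six groups — On-Off direction-selective
(NVSL > 0.2), sustained/transient Off, sustained/transient On
(duration cutoff 0.4), and small-transient On (width < 500 μm) — and
group proportions are compared between the dLGN- and SC-projecting
populations with Pearson χ² on 2×2 tables (no continuity correction by
default) and Wilcoxon-Mann-Whitney rank tests on metric distributions.
Labelled-cell maps are summarised by 2D Gaussian fits, centroid vectors
from the optic nerve head, angular separations, centroid distances and
two-standard-deviation overlap counts.

See `docs/methods.md` for the full model and every default.

## Worked example

```python
import numpy as np
from rgcpipe import synth, tuning, classify, popstats
from rgcpipe.config import RunConfig

cfg = RunConfig(seed=7)
dataset = synth.simulate_experiment(seed=cfg.seed)   # default composition
metrics = tuning.compute_metrics_table(dataset, cfg)
labels = classify.classify_table(metrics, cfg.thresholds)
labels = labels.merge(dataset.ground_truth[["cell_id", "group"]], on="cell_id")
counts = classify.tabulate(labels)
print(counts)
tab = classify.contingency_2x2(counts, "ON_OFF_DS", ("dLGN", "SC"))
stat, p = popstats.chi2_2x2(tab)
print(f"On-Off DS fraction, dLGN vs SC: chi2 = {stat:.2f}, p = {p:.3f}")
truth = dataset.ground_truth.class_label.to_numpy()
print(f"ground-truth recovery: {(labels.class_label.to_numpy() == truth).mean():.1%}")
```

prints

```
group               SC  dLGN
class_label
ON_OFF_DS           20    10
OFF_SUSTAINED        8    11
OFF_TRANSIENT       15     8
ON_SUSTAINED        12    30
ON_TRANSIENT        16    14
ON_SMALL_TRANSIENT   8     1
UNCLASSIFIED         0     0
On-Off DS fraction, dLGN vs SC: chi2 = 3.38, p = 0.066
ground-truth recovery: 100.0%
```

The simulated population uses the default composition (74 dLGN- and 79
SC-projecting classified cells); every simulated cell is pushed through
spike sampling, SDF estimation, metric extraction and rule-based
classification, and here every cell returns to its generating class. The
χ² line compares the On-Off DS fraction between the two groups on the
simulated counts (20/79 vs 10/74).

The same pipeline is scriptable from the shell:

```
rgcpipe simulate --out data/ --seed 7
rgcpipe metrics  --spikes data/spikes.csv --epochs data/epochs.csv --out metrics.csv
rgcpipe classify --metrics metrics.csv --groups data/ground_truth.csv \
                 --out labels.csv --counts-out counts.csv
rgcpipe compare  --labels labels.csv --metrics metrics.csv --out report.csv
rgcpipe retinomap --positions positions.csv --out retinotopy.csv
```

All output tables carry a comment header with the configuration hash and
master seed; identical seeds give byte-identical outputs.

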