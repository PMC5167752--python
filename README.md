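# bna — spatiotemporal brain network activation analysis for ERPs

`bna` implements a group-level network analysis of event-related potentials
(ERPs) for EEG researchers who want to go beyond per-electrode peak picking.
Scalp activity is treated as a spatiotemporal field: each subject's ERP is
decomposed into frequency bands, interpolated onto a high-resolution scalp
grid, and segmented into **STEPs** (spatiotemporal parcels) — local extrema
of the amplitude in space and time together with their surrounding activity
above half the peak amplitude. STEPs common to most of a cohort are
clustered into **group STEPs**; latency synchronization between group STEPs
defines the edges of a **brain network activation (BNA) model**. Individual
subjects are then scored against the reference model and classified with a
linear SVM, with test-retest repeatability quantified by the intraclass
correlation coefficient. A synthetic oddball-ERP simulator with known
ground truth makes the entire chain testable without real recordings.

## The model in brief

Per band volume `ST(x, y, t)` (left-right × anterior-posterior × time,
33 × 37 grid), a STEP is a strict 26-neighborhood extremum plus the
connected voxels of the same polarity with `|amplitude| ≥ |peak| / 2`; its
*rise time* is the earliest active sample. Group STEPs require coverage
≥ 70 % of subjects inside spatiotemporal clustering windows (±50 ms, 4 px);
two group STEPs are connected when the per-subject latency difference
satisfies `|Δt| ≤ 30 ms` for at least 70 % of the common subjects (peak-peak
and rise-rise variants).

Subject scoring uses the spatiotemporal correlation of a subject STEP
`ST^s` with a group STEP `ST^g` over their voxel overlap,

    STcov(ST^s, ST^g) = Σ_{x,y,t} (ST^s - mean(ST^s)) (ST^g - mean(ST^g))
    TopoCorr          = STcov / sqrt(STvar_s · STvar_g)   ∈ [-1, 1]

(zero when the subject peak violates the windows), plus the STEP's global
field power `GFP = (1/N) Σ amplitude_i²` and, per network edge, the
subject's signed peak and rise-time differences. Features are z-scored with
training-cohort statistics, `x̃ = (x - x̂) / σ_x`, and classified with a
linear SVM (default `C = 10^-3.5`); repeatability uses the one-way
random-effects ICC, `(MSb - MSw) / (MSb + (k-1) MSw)`.

## Worked example

Simulate a 20-subject Target cohort with three planted components
(N100⁻ θ @ 100 ms, P200⁺ θ @ 180 ms, P300⁺ δ @ 375 ms; 10 ms latency
jitter, 2.5 µV ERP noise) and build the group model:

```python
import numpy as np
from bna import (SimConfig, simulate_dataset, GridGeometry, ModelConfig,
                 build_model, cohort_steps)
from bna.pipeline import _three_component_set

config = SimConfig(n_subjects=20, n_trials=60,
                   condition_proportions={"Target": 1.0},
                   noise_sd_uv=2.5 * np.sqrt(60), seed=7)
dataset = simulate_dataset(config, _three_component_set())
geometry = GridGeometry()
steps = cohort_steps(dataset, geometry, bands=("delta", "theta"))
model = build_model([s for ss in steps.values() for s in ss],
                    ModelConfig(), "Target", geometry, dataset.times_ms,
                    n_subjects=20)
for gs in model.group_steps:
    print(f"{gs.id}  band={gs.band:5s} polarity={gs.polarity:+d} "
          f"peak={gs.peak.t_ms:6.1f} ms  amp={gs.peak.amplitude_uv:+5.1f} uV "
          f"coverage={gs.coverage:.2f}")
```

prints

```
s00  band=theta polarity=-1 peak=  96.9 ms  amp= -9.0 uV coverage=1.00
s01  band=theta polarity=+1 peak= 178.9 ms  amp= +8.5 uV coverage=1.00
s02  band=delta polarity=+1 peak= 378.1 ms  amp= +8.4 uV coverage=1.00
```

— exactly the three planted components, each recovered within ~3 ms of its
planted latency and present in every subject (coverage 1.00). No edges
emerge here because the planted inter-component lags (80 ms, 195 ms) exceed
the 30 ms synchronization window.

The same flow is available from the shell:

```sh
bna simulate --out data/ --seed 7
bna segment --in data/ --montage data/montage.sfp --out steps/
bna build-model --steps steps/ --condition Target --visit V1 --out target.json
bna build-model --steps steps/ --condition Novel  --visit V1 --out novel.json
bna score --model-target target.json --model-novel novel.json \
    --steps steps/ --out features.tsv
bna classify --train features_v3.tsv --test features_v1.tsv --out report/
bna icc --visits v1.tsv v2.tsv --out icc.tsv
```

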