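# Methods

This note documents the models, parameters and numerical choices behind
`bna`, and what the packaged simulations do and do not show about real EEG.

## Pipeline overview

1. **Pre-processing.** An averaged ERP (channels × time, µV) is filtered
   into four conventional bands — δ 0.5–4 Hz, θ 3–8 Hz, α 7–13 Hz,
   β 12–30 Hz (edges overlap slightly, as is conventional) — with a
   least-squares linear-phase FIR band-pass applied forward and reversed
   (zero net phase, `scipy.signal.filtfilt`, symmetric padding of one
   filter length). Filter length is 3 cycles of the band's lower edge,
   capped at signal length − 1 and forced odd. Electrode positions are
   projected azimuthally-equidistantly about the vertex (least-squares
   sphere center, so cap-only montages work) and each band is interpolated
   per time sample onto a fixed 33 × 37 scalp grid (left-right ×
   anterior-posterior) with an exact thin-plate spline
   (`scipy.interpolate.RBFInterpolator`, degree-1 polynomial tail, so
   constant and affine fields are reproduced exactly). Pixels outside the
   circular head mask are NaN.

2. **Segmentation.** A STEP is a strict 26-neighborhood spatiotemporal
   extremum plus the 26-connected voxels of the same polarity with
   `|amplitude| ≥ |peak|/2`; rise time is the earliest sample in that set.
   Boundary voxels compare against existing neighbors only; equal-valued
   plateaus are not strict extrema, but a plateau that strictly dominates
   its surroundings contributes its earliest-time, lowest-index voxel. The
   default noise floor is half the volume's robust spread
   (1.4826 × MAD); see "Amplitude floor" below for why the packaged
   experiments override it.

3. **Group model.** Per band and polarity: (a) every STEP seeds a
   candidate cluster that collects, from each other subject, the nearest
   STEP within ±50 ms and 4 px (Chebyshev), nearest by the normalized
   distance `max(|Δt|/50, Δpx/4)`; (b) a greedy pass repeatedly selects the
   candidate with highest coverage (ties: smaller mean normalized spread,
   then earlier seed), removing its members from the remaining candidates,
   until none reaches the 70 % coverage threshold; (c) each cluster becomes
   a group STEP: member-wise median peak location/time (rounded to the
   grid), voxels present in ≥ 50 % of members after peak alignment,
   member-mean amplitudes, rise time = earliest group voxel. Edges connect
   group-STEP pairs when the per-subject latency difference (peak-to-peak,
   or rise-onset-to-onset) satisfies `|Δt| ≤ 30 ms` for ≥ 70 % of the
   common members **and** the common members themselves cover ≥ 70 % of
   the cohort (both gates kept deliberately conservative; each is
   configurable). The group Δt is the median over the in-window subjects,
   which keeps `|Δt| ≤ 30 ms` by construction. The model is invariant to
   subject order.

4. **Scoring.** For each group STEP, the subject's same-band same-polarity
   STEPs inside the clustering windows compete by topographic correlation
   (covariance over the voxel overlap, means per STEP over its own voxels,
   variances over the same overlap — Cauchy–Schwarz bounds the ratio to
   [−1, 1]); the winner contributes its correlation and its GFP (mean of
   squared voxel amplitudes by default; an RMS mode exists because the
   field's conventional GFP takes the root — the printed defining formula
   here is the plain mean square). Unmatched STEPs score (0, 0), and edges
   with an unmatched endpoint contribute (0, 0) — a deliberate zero
   convention rather than imputation, mirroring the out-of-window rule.

5. **Evaluation.** Features are z-scored with *training-cohort* statistics
   (population sd; zero-variance columns are zeroed and flagged). A linear
   SVM (`sklearn.svm.SVC`, kernel="linear", tol 1e-6) with a deliberately
   small default `C = 10^-3.5` guards against overfitting the
   high-dimensional feature set; scores are signed distances from the
   hyperplane, positive = Target. AUC is the rank probability (ties ½).
   Repeatability is the one-way random-effects ICC,
   `(MSb − MSw) / (MSb + (k−1)·MSw)`, with each subject one ANOVA group
   and k visits; the ANOVA is computed directly from the definition,
   negative values are reported as computed, and an all-equal table is
   flagged degenerate with ICC 0.

## The simulator

The generator emulates a 3-stimulus auditory oddball study: 600 trials at
80 % Frequent / 10 % Target / 10 % Novel, 256 Hz, −200…800 ms epochs.
Each component is a separable kernel: temporally a Gaussian-windowed cosine
at the band's center frequency (δ 2 Hz, θ 5.5 Hz, α 10 Hz, β 20 Hz) whose
envelope sd is a quarter carrier period — the ±3 sd support spans 1.5
cycles, giving one dominant extremum per component (a literal 1.5-period
envelope sd would produce a long oscillation train with many comparable
extrema, defeating the purpose of a single planted event); spatially a 2-D
Gaussian over the projected electrode positions. The default component set
mirrors the oddball literature: Target N100⁻ (~100 ms, θ), P200⁺ (~180 ms,
θ), P300⁺ (~375 ms, δ, posterior); Novel N100⁻ (~145 ms, θ) and P300⁺
(~335 ms, δ, central); a small Frequent N100.

Variability structure: latency jitter is drawn per subject and visit
(components may share a jitter group, fixing their lag across the cohort —
used to plant synchronization edges); an amplitude scale is drawn once per
subject (a stable trait, the substrate of test-retest repeatability) with
an additional small per-visit amplitude jitter; topography centers shift
uniformly per subject. In averaged-ERP mode the trial mean is drawn
directly as template + white noise of sd `noise_sd/√n_trials`, which is
distributionally identical to averaging trials and much faster; raw-epoch
mode generates individual trials and supports planted ±150 µV square
artifacts for the rejection stage. The montage is a synthetic 37-electrode
spherical cap generated in code.

What the simulator does **not** emulate: volume conduction and realistic
forward fields, 1/f background spectra, ocular/muscle artifacts beyond the
square excursions, habituation across trials, or between-site recording
differences. Passing tests therefore demonstrate the correctness and
statistical behavior of the algorithm under its own assumptions, not
clinical performance on human EEG.

## Amplitude floor and model specificity

Band-pass ringing (spectral truncation of a wide-band component by the
band filter) and cross-band leakage (a θ-windowed component has real
spectral mass inside δ) produce secondary extrema of 3–5 µV for 10 µV
planted components — and they are *consistent across subjects*, so
coverage alone cannot reject them. The packaged experiments therefore use
a 5 µV peak floor (half the planted amplitude, ~5× the in-band noise of
the simulated averages). More broadly, coverage is not a specificity
guarantee at permissive floors: with the default ±50 ms / 4 px windows and
a floor of half a noise sd, even independent pure-noise cohorts yield
abundant chance-aligned "group" STEPs. Practical use of the method should
set the floor from the amplitude of the events of interest, as the
experiments do; the packaged null check (noise-only cohort at the 5 µV
floor → zero group STEPs) reflects that regime.

## Experiment designs (packaged study conditions)

* **Component recovery** — 20 subjects, three planted components
  (N100⁻/P200⁺ θ, P300⁺ δ, all 10 µV), latency jitter sd 10 ms, topography
  jitter up to 2 px, ERP noise 2.5 µV (25 % of amplitude). Expected: the
  model contains exactly the three planted group STEPs, latencies within
  ±15 ms, coverage ≥ 0.7.
* **Synchronization gate** — two θ components at spatially distinct sites
  whose lag is fixed across subjects via a shared jitter draw; a 20 ms lag
  must produce a peak-sync edge with median Δt within 5 ms, a 60 ms lag no
  edge.
* **Classification** — one cohort (n = 30), three visits with independent
  jitter; Target and Novel share an N100 while the P300 differs by 40 ms
  and a 4 px posterior-to-central shift. Reference networks and classifier
  training use V3; V1/V2 are test visits (per-visit AUC ≥ 0.9 expected).
  The null (identical templates) reports the pooled V1+V2 AUC per seed:
  a single-visit AUC at n = 30 + 30 has a chance sd of ≈ 0.075, so the
  pooled statistic (sd ≈ 0.05) is the right granularity for a
  [0.35, 0.65] band over 10 seeds.
* **Repeatability** — n = 40, k = 2 visits; between-subject amplitude sd
  30 % of the mean, within-subject visit-to-visit sd 5 %, latency jitter
  3 ms. GFP tracks squared amplitude, so the stable subject trait should
  dominate: GFP-feature ICC ≥ 0.7 expected (topography-score ICC is not
  constrained — it measures shape, not gain).

These problem sizes (20–40 subjects, two bands, 256 Hz, 33 × 37 grid) were
chosen as the smallest cohorts at which the statistical claims are stable;
each experiment completes in seconds to a couple of minutes on one CPU.

## Numerical and design choices

* 26-connectivity throughout (isotropic treatment of space and time);
  boundary voxels use existing neighbors only.
* Strict inequality defines extrema; tie plateaus contribute at most one
  representative (earliest time, then lowest index).
* Candidate clusters never mix bands or polarities.
* Matching windows for scoring are the model's own clustering windows,
  stored in the model file, so scoring is self-consistent.
* The SVM's printed regularization default `10^-3.5` is exposed as `--C`.
* All writers are deterministic (sorted keys, fixed float formats); model
  and STEP files store voxel sets run-length-encoded over raveled grid
  indices and are schema-versioned.
* Degenerate inputs: empty models are valid (with a warning); empty STEP
  GFP is 0; ROC and SVM require both classes; ICC requires complete
  tables (no imputation).

## Known limitations

* The greedy clustering is order-deterministic but not globally optimal;
  heavily overlapping event structure can split or merge clusters.
* Scoring zero-fills unmatched STEPs and edges, which compresses feature
  variance for poorly matched subjects (mean imputation is available via
  the scoring mode flag).
* The thin-plate interpolant can overshoot between electrodes; amplitudes
  on the grid are therefore not bounded by the electrode values.
* β-band networks are computed but unexercised by the packaged
  experiments, whose components live in δ and θ.
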