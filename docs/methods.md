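# Methods

This note documents the models implemented in `tempopred`, the assumptions
behind them, the parameters that matter, and what the synthetic-cohort tests
do and do not establish.

## Task model

A trial is a deterministic timing chain: fixation (1500 ms) → visible
movement (uniform 1000–1500 ms, snapped to the sample grid) → occlusion
(1500 ms + Δt, Δt ∈ {±34, ±134, …, ±934} ms) → reappearance display
(500 ms). Sessions hold 480 trials (8 blocks × 60); controls run the
condition twice (960 trials total). Analysis epochs are padded by 1240 ms on
both sides, so epoch durations span exactly 4546–6914 ms. Δt levels are
balanced over the session (counts differ by ≤ 1) and permuted by seed; the
paradigm source does not state whether balancing was per block, so we
balance overall. The movement interval's distribution is not stated either;
continuous-uniform is the least-informative choice.

## Behavioral model and psychometric fit

The simulated observer responds "late" with probability
`lapse/2 + (1−lapse)·σ(b₁(Δt − PSE))`, where σ is the logistic function and
`b₁ = 2 ln 3 · s`. This parameterization puts the ground truth directly on
the reported steepness scale: the fitted reciprocal 75–25 span recovers `s`
exactly in expectation. The fitted model is a plain binomial logistic GLM
(no lapse term — the generator's lapse defaults to 0 so fit and generator
are conjugate; sensitivity to lapse > 0 is a test, not a model term), fitted
by IRLS with convergence at max |Δβ| < 1e−8 or 100 iterations. Complete
separation (ideal synthetic observers) is detected and the fit falls back to
Firth-type penalization (Jeffreys-prior score correction), flagged
non-converged. Trials are "subjectively correct" when the response lies on
the correct side of the fitted PSE; a Δt exactly at the PSE counts correct
(a measure-zero tie, fixed for determinism).

Group statistics follow the clinical conventions: paired t within patients,
independent t against controls (Welch reported first, the pooled-variance
t(n₁+n₂−2) companion alongside, since published work in this area prints
pooled dfs), one-sample t for PSE-vs-zero, Cohen's d, and a comparison-wise
α of 0.05/3 for the three primary contrasts.

Reaction times are generated as truncated-normal positives. This is a
placeholder: nothing downstream infers RT parameters, and the RT summary is
purely descriptive.

## Spectral analysis

The wavelet bank holds 40 complex Morlet kernels with center frequencies
log-spaced 0.5–100 Hz and cycle counts log-spaced 2–10, σ_t = cycles/(2πf),
truncated at ±3.5 σ_t. Two non-obvious choices:

* **Admissibility.** At 2 cycles a plain Gaussian-windowed exponential has a
  ~13% DC leak; kernels therefore include the standard zero-mean correction
  term `env·(e^{2πift} − κ)`, κ = exp(−½(2πfσ_t)²).
* **Normalization.** Kernels are unit-energy by default (power comparable
  across frequencies); unit peak-gain is available, since the convention is
  not dictated by the analysis description.

Convolution is FFT-based and center-aligned; a sample is valid at a
frequency iff its distance to either epoch edge is at least the kernel
half-width. The 0.5 Hz wavelet spans ~4.5 s, longer than the 1240 ms pads:
those bins are masked (not NaN-poisoned) and excluded from statistics.

Power and ITPC are computed on event-aligned windows — baseline (−550, −50),
movement (−50, 950), disappearance (−350, 950), reappearance (−350, 450) ms
— binned into 100 ms half-open intervals anchored at the window start
(centers at left + 50 ms). ITPC is computed per sample and then averaged
within bins (the conservative reading of bin-averaged phase consistency).
Power is normalized to the pre-movement baseline (−500, −200 ms relative to
movement onset); relative change is the sensor-level default, z-scoring the
source-summary default, dB available.

## Cluster-based permutation inference

Element-wise statistic maps (paired/independent/one-sample t, Pearson r
across participants) are thresholded at the two-sided parametric quantile
for cluster-α = 0.05; suprathreshold cells of equal sign are clustered over
neighboring channels (great-circle adjacency, median degree ≈ 6), adjacent
grid frequencies, adjacent 100 ms bins, or 26-connected voxels. The cluster
statistic is the **mass** (sum of the statistic). The permutation null
records, per permutation, the maximum of |mass| over clusters of both
signs; `p = (1 + #{null ≥ |mass|})/(n_perm + 1)`. Using the pooled max-|mass|
null (rather than separate per-sign nulls at α) makes p exactly invariant
under group exchange and is power-equivalent to per-sign nulls with a halved
α. When fewer distinct permutations exist than requested, the scheme is
enumerated exhaustively and p becomes count/n_total.

Correlations are clustered on their t-equivalent scale
`t = r·sqrt(df/(1−r²))`: thresholding is unchanged (the map is monotone),
but mass in r units saturates at |r| = 1 and systematically favors extended
weak effects over strong focal ones; the t scale is the convention of the
major EEG statistics toolboxes.

## Source analysis

The volume conductor is a homogeneous sphere (radius 85 mm, conductivity
0.33 S/m) with an insulating boundary; surface potentials come from the
classical Legendre series, evaluated by recurrence with a term bound that
guarantees ~1e−14 truncation. This replaces an MRI-template single-shell
model: it has a closed form to test against, and the DICS machinery accepts
externally supplied leadfields so a realistic model can be dropped in.
Sources live on a cubic lattice restricted to an inner brain sphere (0.85 R):
cortex lies below the scalp, and the series converges slowly for dipoles
near the surface. A 5003-voxel target grid is reached by bisection on the
spacing (achieved count within 2%).

DICS filters are computed from the real part of a band/window-averaged CSD,
regularized by λ = 5% of mean sensor power (both conventional; the analysis
description is silent). Scalar filters follow the dominant orientation
(largest eigenvalue of the 3×3 source CSD); they are the default for power
and mandatory for ITPC, since the phase of a 3-vector is ill-defined. One
*common* filter set from condition-pooled CSD serves every condition in a
contrast, pooled over exactly the units entering that contrast. Source
power is reported raw, z-scored across voxels (the source-summary
convention), or as the noise-normalized neural activity index
`wCwᵀ/(wwᵀ)` — raw minimum-variance power is depth-biased (small leadfields
inflate it), so localization uses the NAI.

## The synthetic cohort

The generator states an explicit world:

* **Background**: per-channel Gaussian noise shaped to a 1/f^a amplitude
  spectrum (a = 1), RMS 10 µV.
* **Beta generator**: a fronto-central dipole carrying narrowband noise
  (center ± 2.5 Hz) whose envelope drops by the stated fractional power
  change (e.g. −0.4) from movement onset to reappearance, with 100 ms
  cosine ramps.
* **Delta generator**: an occipito-parietal coherent patch of constant
  amplitude whose phase is *reset* at each stimulus disappearance to a von
  Mises draw (concentration κ, preferred phase configurable). A pure phase
  reset produces ITPC without any power change, so power and phase effects
  are independently manipulable.
* Generators are projected through the spherical forward model and scaled so
  each generator's sensor RMS equals `snr` × background RMS. `snr = 0`
  yields pure background, bit-identical to the no-generator stream.

Group defaults state the qualitative clinical pattern: the OFF state has
shallower psychometric curves (s = 0.0015/ms vs 0.003 ON, 0.004 controls),
weaker beta suppression (−0.10 vs −0.35, −0.40) and weaker delta locking
(κ = 0.8 / 0.9 / 2.0). What the generator does **not** emulate: ocular,
muscular, cardiac artifacts (removed by manual ICA in practice — the
pipeline's ICA stage is a pluggable no-op), realistic cortical geometry,
spatially correlated background, head movement, or stimulator artifacts (an
optional harmonic comb exists to exercise the band-stop/low-pass stages).
A green recovery test therefore establishes the correctness of the analysis
arithmetic and its statistical calibration, not robustness to real-world
artifact regimes.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth stages: 0.5 Hz
high-pass, 95 Hz low-pass, 49.5–50.5 Hz band-stop. The filtfilt padding is
set to ~3 periods of each stage's slowest pole — the library default pad is
far too short for a 0.5 Hz high-pass and leaves seconds-long edge
transients. Epochs are cut 1240 ms before movement onset to 1240 ms after
reappearance offset and kept ragged; trials with missing/out-of-range
markers are dropped with a log entry, and the accounting
`epochs + dropped = scheduled` is asserted in tests.

## Determinism

All randomness flows from one root seed through named, crc32-keyed
`SeedSequence` substreams (schedule, responses, noise, oscillators,
permutations, cohort/subject). Identical seeds give bit-identical schedules,
tables, signals, and permutation logs; the pipeline summary JSON is
hash-stable.

## Scaled test sizes

The statistical-calibration and end-to-end suites run at reduced size to
stay within a desk-scale CPU budget: 250 Hz sampling, 16-channel montage,
reduced wavelet counts, coarse source grids (25–35 mm), 60–120 trials, and
10–200 replicates where module-level statements reference up to 100–500.
The detection criteria themselves (rates, directions, subject counts) are
unchanged. The coupled-cohort check (source ITPC vs steepness) uses a
deterministic κ ∝ steepness coupling with steepness spread ~lognormal
(cv 0.7) at snr 5 — a strong-effect world; with weaker coupling the
cluster-mass test correctly loses power (an observation about cluster
inference, not a defect of the implementation).

## Known limitations

* The spherical forward model ignores skull/scalp conductivity layering;
  absolute source amplitudes are not interpretable, only contrasts.
* Beamformer ITPC inherits the usual leakage: phase-locked activity appears
  over an extended region around the generator.
* The Firth fallback returns finite slopes for separated data but its
  standard errors are not specially corrected.
* EDF+ writing quantizes each channel to its own physical range; recordings
  with extreme single-sample outliers lose resolution across that channel.
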