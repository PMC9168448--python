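# Methods

## Signal model and what the metrics see

The quantity of interest is the consistency of the cortical 40 Hz phase
across repeated presentations of an amplitude-modulated tone.  All three
metrics (ITPC, PLV, ciPLV) are functionals of per-trial instantaneous
phases, computed **across trials at each time sample**, never within
trials.  Phases are obtained by a zero-phase (forward–backward)
Hamming-window FIR band-pass at 39–41 Hz followed by the analytic-signal
(Hilbert) angle.

The filter length defaults to ~0.4 s of samples (241 taps at 600 Hz).
This is a deliberate compromise: a steeper filter would need ≥ 1.5 s of
taps, whose zero-phase transient around the stimulus-onset discontinuity
would bleed into both the baseline (−0.5 to −0.2 s) and steady-state
(0.3–0.7 s) windows of a 3 s epoch.  At 241 taps the transient half-width
(~0.2 s) stays clear of both windows, while stop-band attenuation still
rejects out-of-band components: a 10 Hz sinusoid of equal amplitude
perturbs the recovered 40 Hz phase by < 0.05 rad (tested).

Conventions fixed by the implementation (each pinned by a unit test):

- z-scoring uses the baseline **sample** standard deviation (ddof = 1);
  a zero-variance baseline yields z = 0 with a warning rather than an
  error, so one constant vertex cannot abort a cohort run.
- Seed-based connectivity maps average the **moduli** of the per-seed-
  vertex metrics (an option averages the complex mean vectors instead),
  and the self-pair s = w is excluded — PLV of a signal with itself is
  identically 1 and would inflate seed-adjacent values.
- ciPLV at pure zero lag (|Re C| = 1) is defined as 0 with a warning
  (the statistic's own limit is 0/0).
- PLV/ciPLV maps are z-scored and time-averaged exactly like ITPC.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 180
trials per recording, 600 Hz sampling, 3 s epochs (−1.5 to +1.5 s) with
the stimulus in 0–1 s.  Phase locking is modeled **at the level of the
trial's 40 Hz onset phase**, drawn von Mises(0, κ_v) during the stimulus
and uniform during Silence.  The metrics only ever see phase
distributions, so this is the minimal sufficient model; no biophysical
oscillator is simulated.  Key parameters:

| parameter | default | meaning |
|---|---|---|
| `kappa_base` | 2.0 | von Mises concentration at every vertex (ITPC ≈ 0.70 at κ = 2) |
| `effect_slope` | 0 (calibrated when needed) | dκ/d(thickness), 1/mm, inside the effect ROI |
| `thickness_mean_mm` / `sd` | 2.5 / 0.3 | cortical thickness field statistics |
| `thickness_smoothness_mm` | 15 | Gaussian σ of the thickness field's spatial correlation |
| `coupling_lag_rad` | π/2 | phase lag of the coupled target (right A1) behind the seed (left A1) |
| `noise_snr` | 1.0 | 40 Hz signal amplitude / broadband 1/f noise RMS |

Background noise is 1/f-shaped Gaussian (MEG-like spectrum), scaled by
`noise_snr`; after the 2 Hz-wide analysis filter the in-band noise power
is small, so modest SNR values still yield clean phases.

Two generation modes exist.  `mode="trials"` synthesizes full waveforms
so the complete signal path can run.  `mode="maps"` computes each
recording's steady-state ITPC map directly as the resultant length of the
drawn onset phases — the exact noiseless reduction of the signal path —
which keeps Monte-Carlo studies with thousands of recordings tractable.
Ground truth (per-vertex κ, planted ROI, slope, lag) is returned in a
sidecar record, never embedded in the data containers, so pipeline code
cannot cheat.

**Effect-size calibration.**  The generative slope is not an observable;
what the field reports is the observed correlation (ρ ≈ 0.5 at the
strongest vertices).  `calibrate_effect_slope` therefore bisects the
slope until the median across-subject Spearman ρ between thickness and
stimulus ITPC over effect-ROI vertices reaches the target (0.5), using
pilot cohorts of the same size as the main analysis (n = 72).  The
calibrated slope depends on trial count, κ_base and thickness sd, so it
is re-derived per configuration rather than hard-coded.

What the generator does **not** emulate: inverse-solution spatial
leakage (beyond what ciPLV is designed to discount), inter-subject
anatomical variability (all subjects share one mesh, standing in for
template-space registration), trial rejection, head movement, and
non-stationary entrainment build-up.  Passing tests therefore establish
correctness of the estimators and the inference machinery under the
stated phase model — not robustness to every artifact of real MEG data.

## Surface smoothing

Gaussian smoothing on the mesh is iterative neighbor-weighted diffusion:
`x ← (1−λ)x + λ·mean_neighbors(x)`.  Averaging over a ring of radius e
adds (e²/4)·Laplacian, so each step advances heat-equation time by
λ·E[e²]/4 and n steps give a kernel of per-axis variance n·λ·E[e²]/2.
The step count is derived from the mesh's mean squared edge length with
λ ≤ 0.5, then λ is adjusted so the accumulated variance equals
σ² = (FWHM/2.3548)² exactly.  On a regular 1 mm grid the impulse
response's geodesic half-maximum radius matches FWHM/2 within the
discretization (tested at 3, 5 and 8 mm against shortest-path
geodesics).  `fwhm=0` is the identity; the operator is row-stochastic,
so constants are preserved and isolated vertices pass through unchanged
(with a warning).

## Cluster-based permutation inference

Per vertex, Spearman ρ is the Pearson correlation of average ranks (one
shared kernel serves the vertex-wise and thalamic analyses); Fisher
z = atanh ρ and t = ρ√((n−2)/(1−ρ²)) are stored, and clustering operates
on t.  Suprathreshold vertices (|t| above the two-sided parametric
critical value at p = 0.05, df = n−2; threshold exposed in `PermSpec`)
are grouped into connected components on the mesh adjacency, positive
and negative t separately; the cluster statistic is the signed summed t
("maxsum" mass, not extent).  The null distribution records, per
permutation of the subject correspondence between the two map sets (the
only exchangeable unit in a correlation design), the maximum |mass|.
p-values use (1+b)/(1+n_perm), so the smallest attainable p is
1/(n_perm+1) and zero p-values are impossible.  Degenerate cases:
constant-across-subject vertices are flagged and set ρ = 0; |ρ| = 1 maps
to a capped t sentinel (10⁶) so a perfectly monotone vertex cannot
produce infinities; ties get average ranks.

Repeated scans are treated as independent recordings by default; the
`unique_subjects` option keeps each subject's first scan (the
sensitivity analysis).  With `tail="positive"` only positive clusters
are formed and the null uses positive masses only.

## ROI analyses

The inter-A1 contrast computes the pair metric across trials per time
sample for every (left-A1, right-A1) vertex pair, averages moduli over
pairs, and takes raw time-averages over the steady-state window
(stimulus condition) and the baseline window (Silence condition).  The
paired test is the Wilcoxon signed-rank: zeros dropped, average ranks
for ties, Z from the normal approximation with tie-corrected variance
(no continuity correction), signed toward the stimulus condition.  For
n ≤ 20 effective pairs an exact p is computed by dynamic programming
over the signed-rank distribution (ranks doubled to integers, so
average ranks are handled exactly); a test verifies agreement with
exhaustive 2ⁿ sign-flip enumeration to 10⁻¹².  The choice of a
signed-rank test for paired condition contrasts is an inference from the
reporting conventions of the field (paired design, medians/IQR
displayed); a paired-permutation alternative can be obtained by using
the exact p, which *is* the sign-flip permutation p on ranks.

Thalamic nucleus volumes are normalized as volume/TIV ratios (scale
invariance is tested), correlated per nucleus with a subject-level
synchrony summary (default: whole-cortex mean of the steady-state map;
any ROI restriction can be passed instead), and corrected family-wise by
a max-|ρ| permutation across nuclei.

## Problem sizes for the Monte-Carlo studies

The statistical-calibration experiments run on a 500-vertex two-sphere
mesh — large enough for non-trivial cluster topology, small enough that
the full permutation machinery can be replicated hundreds of times:

- type-I error: 200 null cohorts (n = 24 subjects), 500 permutations,
  family-wise false-positive rate checked against the 99% binomial band
  [0.02, 0.09] around α = 0.05;
- planted-effect recovery: 50 cohorts (n = 72 recordings), slope
  calibrated to true ρ ≈ 0.5, 1000 permutations; recovery = significant
  cluster with Dice ≥ 0.5 against the planted ROI; the same cohorts'
  Silence maps drive the control analysis;
- the acceptance script uses slightly smaller replicate counts
  (120 null cohorts, 30 effect cohorts) and reports the measured rates.

Full-waveform simulations (signal path, leakage suppression, inter-A1
contrast) use 12–60 vertices per hemisphere and 60–180 trials.

## Known limitations

- The mesh generator produces jittered spheres, not folded cortical
  geometry; geodesic distances are graph shortest paths, which
  overestimate true geodesics by the mesh's metrication error.
- `mode="maps"` bypasses the filter/Hilbert chain; its equivalence to
  the signal path holds exactly only in the noiseless limit (the signal
  path at the default SNR adds a small ITPC bias that the statistical
  experiments deliberately avoid conflating with estimator error).
- The cluster-forming threshold, tail and cluster statistic are
  conventions, exposed in `PermSpec`; results at very coarse meshes are
  sensitive to the threshold choice, as for any cluster-based method.
- Wilcoxon Z omits the continuity correction; at n = 72 the difference
  is negligible but exact agreement with implementations that apply it
  should not be expected.
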