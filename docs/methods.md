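# Methods

`megfalff` implements a resting-state MEG analysis that asks whether a
subject-level trait score — a 1–7 subjective-happiness composite — predicts
the *fractional amplitude of low-frequency fluctuation* (fALFF) of
source-level band-limited power, and a synthetic cohort generator that plants
exactly that effect so the whole chain can be validated against ground truth.
This note records the model, the parameter choices, and the places where the
design was genuinely open.

## The measurement model

Each subject contributes an eyes-open resting recording (184 s at 1000 Hz by
default; 2 s trimmed from each end, leaving a 180-s analysis window) from a
120-channel radial-magnetometer array on a spherical cap, plus vertical and
horizontal EOG. Processing is a fixed, pure pipeline:

1. **Downsample** to 200 Hz (polyphase FIR anti-aliasing, `scipy.signal.resample_poly`).
2. **Line filter**: a DFT filter zeroes the Fourier bins within ±0.1 Hz of
   60 Hz and its harmonics below Nyquist. With minutes of data the bin
   spacing is a few mHz, so content 1 Hz away is untouched.
3. **ICA artifact removal** (FastICA; the unmixing algorithm is a pluggable
   contract — any linear decomposition maximizing independence will do; the
   tested content is the flagging logic). Components are flagged when
   (a) |Pearson r| with either EOG channel ≥ 0.5, (b) the robust z-score of
   their excess kurtosis (median/scaled-MAD across components) ≥ 5, or
   (c) more than 50% of their spectral power lies above 80 Hz (muscle-like).
   The unmixing is fitted on robustly selected samples — 2-s windows whose
   global RMS violates the scaled-MAD rule are excluded from *fitting* (not
   from the data) — because rare high-amplitude bursts otherwise dominate the
   whitening and the blink component never separates. Flagged components'
   sensor projections are subtracted; the part of the data outside the
   component subspace is retained.
4. **Band filtering** into theta 4–8, alpha 8–12, beta 12–30, gamma 30–60 Hz
   (5th-order Butterworth, forward–backward, so zero phase and double order).
5. **Epoching** into contiguous 2000-ms windows: 180 s → 90 epochs.
6. **Bad-epoch flagging** on the broadband data: epoch *i* is bad iff
   |g_i − median(g)| > 5 · 1.4826 · MAD(g), where g is the per-epoch RMS over
   all channels. The strict inequality with no zero-MAD special case means
   that when most epochs are identical, any deviant is flagged. One mask is
   shared across the four bands so the band pipelines stay aligned.

**Source reconstruction** uses a unit-gain LCMV beamformer on a 10-mm cubic
grid inside an 80-mm sphere: w_j = C⁻¹L_j / (L_jᵀC⁻¹L_j), with C the
good-epoch sensor covariance plus 5% mean-diagonal loading, and L_j the
analytic single-sphere (Sarvas) lead field. The dipole orientation per grid
point maximizes output power (smallest generalized eigenvector of LᵀC⁻¹L,
restricted to the magnetically visible column space — the near-radial
direction is silent in a sphere and grid points with vanishing lead fields
are excluded from maps). Per-epoch mean squared beamformer output gives a
90-point band-limited power series per grid point, which is linearly
resampled onto a 2-mm isotropic MNI-aligned voxel grid and smoothed with an
8-mm-FWHM Gaussian kernel renormalised inside the analysis mask. The
renormalised kernel alone does not preserve the masked mean exactly, so an
explicit masked-mean rescale follows; the maps are positive power images and
are z-scored per subject later, so this global scale carries no information.

Because no individual anatomy exists for synthetic subjects, the sphere is a
single conductor (radius 90 mm) for both simulation and inversion, optionally
with sensor-position jitter between the two to probe robustness. One geometric
subtlety: the MNI origin is the anterior commissure, not the head centre, so
the conductor is centred at (0, −18, 18) MNI mm; the nominal target
coordinate (6, −62, 66) — right precuneus — lies 65 mm from that centre,
comfortably inside the source sphere, whereas its distance from the MNI
origin (91 mm) would put it outside a sphere centred there.

**fALFF.** The 90-point power series is sampled at 0.5 Hz, so its spectrum
covers (0, 0.25] Hz in 1/180-Hz bins. Censored timepoints are repaired by
natural cubic-spline interpolation through the good points (edges take the
nearest good value; a subject with > 50% censored epochs is excluded), then
four nuisance regressors — constant, linear drift, and the per-epoch
band-limited power of each EOG channel in the same band — are removed by OLS
per voxel. fALFF is the sum of Fourier amplitude moduli over 0.01–0.1 Hz
divided by the sum over all positive frequencies; the DC bin is excluded from
both sums (conventions differ; the constant was removed by the nuisance
regression anyway). For N = 90 this is 17 in-band bins of 45, so white noise
has expected fALFF ≈ 0.378 — a useful calibration point. Each subject's map
is z-scored over the analysis mask.

**Group statistics** follow the statsmodels Model/Results idiom:
`FALFFRegression(Y, cohort)` builds the voxel-wise design (intercept,
happiness, sex, age, IQ → residual df = n − 5 = 43 at n = 48) and `fit()`
returns results with t, Z (= Φ⁻¹ of the t tail mass, evaluated in log space),
partial r (|r| = |t|/√(t²+df)), the joint F over all non-intercept columns,
and R². The reported t tests the *negative* association (positive t means
happier → lower fALFF) while the partial correlation keeps the raw sign —
both conventions are emitted and labelled. Family-wise error is controlled by
Freedman–Lane max-|t| permutation: residualize Y on the covariate-only model,
permute residual rows, refit, record the maximum |t| over the search region
— the whole mask, or the region-of-interest mask for small-volume correction
(default ROI: 15-mm spheres at (±6, −62, 66) standing in for the bilateral
precuneus; any NIfTI mask on the output grid is accepted). p = (1 + #{maxima
≥ |t_obs|})/(n_perm + 1), so the smallest attainable p is 1/(n_perm+1).
Leverage diagnostics (hat-matrix diagonal, default flag threshold 0.21) and
26-connected cluster tables (peak MNI coordinate, peak t, extent in voxels
and mm³) round out the results object. Permutation replaces random-field
theory deliberately: it is assumption-light and exactly implementable;
an empirical-Bayes beamformer is likewise replaced by the closed-form LCMV
member of the same family. Both substitutions are scope decisions, not
approximations of the originals.

## The data-generating model

Every cortical source is amplitude-modulated band-limited noise
x_j(t) = e_j(t)·c_j(t): c_j is unit-variance Gaussian noise confined to the
source's carrier band, and e_j(t) = μ + a_j(1 + sin(2πf_slow t + φ_j))/2 +
σ_e η_j(t), clipped at zero, with f_slow inside the fALFF band. The planted
effect acts on the *slow-fluctuation amplitude* of the gamma target source at
the precuneus grid point: a_s = a₀(1 + γ_eff z_s) with γ_eff = −0.5 and z_s
the standardized happiness score ((h − 4.6)/0.8, the population calibration).
Mean power stays trait-independent, so the fluctuation-fraction measure — not
power itself — carries the effect, and specificity is testable. Eight
background sources (fixed locations ≥ 30 mm from the target, round-robin
across the four bands) carry trait-independent envelopes. Sensor data add a
60-Hz sinusoid with per-channel coupling, a frontal-topography blink train
(gamma-function pulses, τ = 150 ms, Poisson onsets at 12/min, also written to
the EOG channels), white sensor noise, and n_bad = 3 injected bursts.

Parameter choices that matter, with rationale:

- **Cohort calibration** (n = 48; happiness ~ N(4.6, 0.8) truncated to [1,7];
  age ~ N(22.3, 4.4) truncated ≥ 18; IQ ~ N(121.7, 8.6); sexes balanced):
  these are the published sample's moments. The published headcount is 51
  volunteers, but every reported degree of freedom (t(46) two-sample,
  T(43) = n−5, T(46) = n−2) implies 48 analysed subjects; the generator
  defaults to 48. Covariates are generated independent of the planted effect.
  Scores are kept continuous: the published observed range 1.8–6.0 is not on
  the quarter-point grid a 4-item mean of integer responses would produce.
- **Carrier band 38–55 Hz** for the target source, not the full 30–60 band.
  The two-pass Butterworth filters attenuate only ~15× at 17% past a cutoff,
  so a carrier flush against the 30-Hz beta/gamma boundary would plant the
  slow fluctuation in *both* bands' filtered power — the band-specificity of
  the ground truth itself, not of the pipeline, would fail. 38–55 Hz keeps
  the planted spectral support inside the gamma analysis band.
- **f_slow = 0.03 Hz** (target; background sources draw from [0.02, 0.08]):
  mid-band for the 0.01–0.1 Hz fALFF numerator.
- **Amplitudes** (μ = 1, a₀ = 0.8, σ_e = 0.2; dipole moment 20 nA·m; sensor
  noise 50 fT per sample; line 0.15 pT; blink 2 pT peak frontal): chosen so
  source deflections at the sensors are a few hundred fT — the scale of real
  cortical MEG — with blinks an order of magnitude larger, as in real
  recordings.
- **Bursts** are ×20 cosine-tapered gain windows aligned to the epoch grid,
  at non-adjacent epochs. The taper keeps burst energy inside its own epoch
  after the anti-alias and band filters spread edges by tens of
  milliseconds, so "the injected epochs and only those are flagged" is a
  well-posed ground-truth statement.

What the generator does *not* emulate: head movement, physiological drift,
1/f background spectra, planar-gradiometer physics, individual anatomy,
eyes-closed states, or spatially distributed (non-dipolar) sources. Passing
the recovery tests therefore shows the pipeline is correct and sensitive
under its own assumptions — not that the published effect would replicate in
new human data.

## Numerical choices and degenerate inputs

- Two-pass filtering is tested against the *squared* magnitude response;
  epoch trailing remainders are dropped (floor semantics).
- A zero-MAD, non-constant global signal flags every deviant from the median
  (with a warning): the rule's strict inequality makes the threshold zero.
- An all-zero power series has fALFF defined as 0 (with a warning); a
  constant map cannot be z-scored and raises.
- Perfect GLM fits (zero residual variance) report a capped t with a
  `perfect_fit` flag; Z values of extreme t are computed from `logsf` so the
  tails do not saturate.
- Rank-deficient nuisance sets drop dependent columns with a warning;
  rank-deficient group designs raise, naming the collinear columns.
- Ties in nearest-grid-point lookups break toward the lexicographically
  smallest coordinate; the exact sphere centre (silent for every dipole
  orientation) is excluded from the source grid.
- Cluster connectivity defaults to 26-neighbour (6 available).

## Problem sizes

The default configuration is the study condition (48 subjects, 120 channels,
1000 Hz, 10-mm source grid, 2-mm output grid, four bands, 1000 permutations).
The `reduced_config()` preset — 48 sensors at 400 Hz, 25-mm source grid,
5-mm output grid, gamma + beta bands, 499 permutations — is the package's
own desk-scale condition for repeated end-to-end runs (about a minute per
cohort); the recovery checks run it across ten seeds and require the
gamma-band SVC-FWE p at the target voxel to fall below .05 in at least eight,
with at most two nominally significant beta replicates (the FWE level's
null expectation). All randomness flows from a single seed through
`numpy.random.SeedSequence`, so every artifact is bit-reproducible.

## Known limitations

- The LCMV + coarse-grid + single-sphere chain localizes the planted source
  to within about one grid spacing; peak *coordinates* in the reduced preset
  are accordingly quantized and can land in the contralateral ROI sphere
  while the target-voxel statistics remain correct.
- fALFF on 90 points has 1/180-Hz resolution; slow-fluctuation frequencies
  below 0.011 Hz alias into the first in-band bins and are not distinguished.
- The ICA contract assumes artifacts are linearly separable and
  EOG-observable; cardiac artifacts are neither simulated nor specifically
  flagged (the kurtosis and spectral criteria would catch gross cases).
- Vendor MEG formats are out of scope; only the package's HDF5 dialect is
  read, behind an adapter seam (`io.read_recording`).
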