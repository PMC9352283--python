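# Methods

This note records the models behind `speckleheart`, the parameters that
matter, and the design decisions taken where the published description of
the measurement principle leaves the implementation open.

## Physical model of the measurement

A coherent laser spot on the skin produces, at the camera, a fully
developed speckle pattern: the field amplitude is circular complex
Gaussian, the intensity negative-exponential, and the speckle contrast
(std/mean) equals 1. Heart-sound pressure waves tilt the skin surface by a
small angle; by the speckle memory effect the far-field pattern then
*translates* without changing shape, proportionally to the tilt. The
forward model is therefore translation-only:

    frame_t = Q( I( A0 shifted by s_t ) + n_t ),
    s_t = g * x_t * u + d * sin(2*pi*f_d*t/fs + phi) * v,

where `A0` is a static complex speckle field, `x_t` the heart-sound
waveform, `g` the gain in px per unit sound amplitude, `(f_d, d)` a
low-frequency (< 20 Hz) sinusoidal drift standing in for macroscopic body
motion, `u`, `v` fixed unit direction vectors, `n_t` Gaussian read noise
and `Q` quantization to the camera bit depth. Translation is applied as a
Fourier phase ramp on the complex amplitude, so sub-pixel shifts are exact
and periodic, and every synthetic video carries its exact shift sequence as
ground truth.

Deliberately not modelled: speckle decorrelation ("boiling"), diffraction
of the physical objective, laser power, defocus and stand-off distance —
the memory-effect regime asserts shape-preserving translation, and the
hardware parameters affect only the gain and grain size, which are free
simulator parameters here.

### Simulator parameters

| parameter | default | meaning |
|---|---|---|
| frame_rate | 1500 Hz | one frame per sound sample |
| height x width | 200 x 208 px | nominal camera crop |
| grain_size | 4 px | speckle correlation width (pupil cut-off 1/(2*grain)) |
| gain | 0.3 px | pattern shift per unit sound amplitude |
| noise_sigma | 2 counts | Gaussian read noise before 8-bit quantization |
| drift | 1.2 Hz, 2 px | macroscopic-motion sinusoid |
| saturation_quantile | 0.995 | intensity mapped to the top level; ~0.5% of pixels clip |

The grain size in pixels of the original camera is not reported anywhere;
4 px is a simulator choice that keeps several pixels per speckle (no
aliasing) and tens of grains even in small frames.

## Sound retrieval (dense optical flow)

Farneback polynomial expansion is implemented directly: each frame is
approximated around every pixel by f(u) ~ c + b'u + u'Au with a Gaussian
applicability (poly_ksize 7, sigma 1.2), computed via separable
correlations; for a pair of frames the translation d solves A d = -(b2 -
b1)/2, averaged over a Gaussian window (win_size 15 at nominal resolution)
before the per-pixel 2x2 solve. Boundary handling is periodic, matching
the simulator; warp-and-refine iterations and a coarse-to-fine pyramid are
available for motions above ~1 px/frame but are unnecessary for
heart-sound amplitudes.

The per-pair displacement maps are averaged to one vector per frame pair;
the vector sequence is projected onto its first principal axis (SVD of the
centred cloud, sign fixed so the largest axis component is positive) to
give the scalar sound trace at the frame rate. The projection preserves
oscillation polarity, unlike the rectifying vector norm; the overall sign
is arbitrary and irrelevant after the modulus in the scattering stage. The
per-pair displacement itself (not its cumulative sum) is treated as the
sound signal; the resulting first-difference weighting of the spectrum is
absorbed by the unit-amplitude rescaling and affects both sessions of an
experiment identically.

Frames whose intensity variance falls below `texture_threshold` (1
count^2) cannot be tracked; the pair is flagged and contributes a zero
vector rather than failing the trace.

Verification: on synthetic videos with known sub-pixel shift sequences the
mean-displacement trace agrees with the exact shifts and with an
independent phase-correlation oracle to well below 0.05 px RMSE, and
injected tones at 30-600 Hz reappear as the dominant spectral peak.

## Phonocardiogram conditioning

A 20-700 Hz Butterworth band-pass with design order N=10 (the common
toolbox convention: the band-pass transformation doubles the pole count to
20) removes the 0-20 Hz motion band. It is applied forward-backward
(`sosfiltfilt`), so timing morphology is preserved and the effective
magnitude is the squared Butterworth response. Because the digital design
is a bilinear transform with frequency pre-warping of the analog
prototype, the implemented magnitude admits a closed form,

    |H(f)| = (1 + Omega(f)^(2N))^(-1/2),
    Omega = |w^2 - W1 W2| / (w (W2 - W1)),  w = 2 fs tan(pi f / fs),

which the audit in `pcg.butterworth_bandpass_gain` checks against the
designed filter to 1e-6 relative error (observed: ~1e-13).

Filtered traces are rescaled to unit peak amplitude and cut into
non-overlapping 2.5 s windows (fixed-length, not beat-synchronous), so a
4.5 min session yields 108 segments and a 30 s session 12. Stethoscope
corpora are handled by the import adapter with 3 s windows and no
re-filtering (digital stethoscopes ship pre-conditioned, [-1, 1]-scaled
WAVs); segment counts follow the actual file lengths.

## Synthetic heart sounds

No morphological model of the original subjects' sounds is available, so
each valve sound is a Gabor atom — a Gaussian-windowed cosine with centre
frequency f, amplitude a and damping d (envelope std 1/d s, spectral std
d/(2*pi) Hz). A cardiac cycle is S1 (10-140 Hz band) followed after the
systolic interval by S2 (10-400 Hz), with optional S4/S3 flanking sounds
and a band-limited systolic murmur (20-1000 Hz), all off by default. Beat
intervals are (60/HR)(1 + jitter), jitter ~ N(0, 0.03) by default. Cohorts
draw (s1, s2) uniformly from [25, 90] x [60, 220] Hz — inside the
physiological bands but above the 20 Hz filter floor — with a minimum
pairwise Euclidean separation of 5 Hz for identifiability; dampings,
amplitudes, heart rate and systolic interval are drawn from ranges typical
of resting adults. Session-to-session variability (the laser spot is not
repositioned identically, physiology changes day to day) is modelled by
multiplying each parameter by (1 + U(-m, m)) with m = 0.05, clipped to the
physiological bands.

What this generator does *not* emulate: real PCG morphology (split S2,
respiratory modulation, within-beat frequency glides), non-stationary body
motion, speckle decorrelation. Passing tests therefore demonstrate that
the *pipeline* recovers and discriminates the information the forward
model encodes; they are not evidence about the difficulty of real
recordings.

## Scattering features

Three layers of Gabor (Gaussian frequency-domain) wavelet filter banks
with M=56, N=30 and P=9 filters per node, centre frequencies geometrically
spaced from 700 Hz down to 20 Hz in every layer, constant-Q spectral stds
0.6*(r-1)*fc (r the spacing ratio, floored at the low-pass bandwidth).
Each bank plus a Gaussian low-pass of invariance scale T = 0.5 s
(time-domain std T/2) is rescaled so the Littlewood-Paley sum stays at
0.999 < 1, making every layer non-expansive. Only frequency-decreasing
paths (l2 < l1, l3 < l2) are retained — 3471 coefficients for the default
configuration — and each path's envelope is averaged over the whole
segment to a single coefficient, so features are independent of segment
alignment. T = 0.5 s is shorter than a cardiac cycle (S1/S2 structure
survives) but long enough for shift stability; the frame-level
representation (`transform_frames`) exposes the T trade-off explicitly and
is used by the stability-vs-T check.

Between layers the filtered analytic signals are resampled by exact
Fourier-domain truncation to the lowest rate that supports the next
layer's filters (all filters fit inside the retained band by
construction; only the far Gaussian tails of the envelopes alias, at the
1e-7 level verified against the single-rate exact mode). This multirate
scheme is what makes the 56/30/9 configuration affordable: ~0.13 s per
2.5 s segment on one CPU.

Feature reduction uses the raw averaged coefficients. A log(eps + .)
compression is available but off by default: with a tiny eps (1e-6) the
logarithm amplifies the near-zero coefficients dominated by the
speckle-realization-specific tracking-noise floor, and in pilot runs this
halved cross-session accuracy (0.50 vs 0.90 raw; same-session 1.00
either way). With log enabled the default eps is 1e-3, which restores
cross-session performance.

## Identification

One-vs-one soft-margin SVMs with an inhomogeneous third-degree polynomial
kernel (hinge loss; C = 1) on per-column mean-centred features; ties in
the pairwise vote resolve to the lowest class index. Identification is
closed-set: every query maps to an enrolled subject, and results are
reported as k x k confusion matrices whose row sums equal the per-class
test counts.

Per-column unit-variance scaling is deliberately **not** applied (a
`scale_features` switch restores it): within a single training session the
variances of scattering coefficients are near zero and noisy, and dividing
by them inflates uninformative columns — in pilot runs full
standardization dropped same-session accuracy to 0.55 and cross-session to
0.35, versus 1.00/0.90 with centring only.

## Experiment design and problem sizes

The synthetic study mirrors the original protocol: 10 subjects, 4.5 min of
recording in session one (108 segments; the first 12, i.e. 30 s, train the
SVM; the remaining 96 per subject are the same-session test), and a 30 s
second session per subject with perturbed profile (m = 0.05) and an
independent speckle realization (12 segments each). A shuffled-label
control retrains on permuted labels. All randomness descends from one
master seed through `numpy.random.SeedSequence` spawning.

Experiment videos are rendered at 24 x 24 px (grain 4 px, ~36 speckle
grains; flow window 7 px). This is the package's desk-scale operating
point: tracking noise at this size is ~0.006 px RMSE per pair against
ground truth — an order of magnitude below the heart-sound signal — while
keeping the 4.05 million frames per full experiment tractable on a single
CPU. The nominal 200 x 208 geometry remains the default everywhere outside
the experiment protocol and is used by the tracking-accuracy checks.

On the shuffled-label control: segments of one subject are strongly
correlated, so the null accuracy has the subject count (10), not the
segment count (960), as its effective sample size; its dispersion around
1/k = 0.1 is correspondingly wide, and the control is checked against the
subject-level binomial band.

## Numerical choices and degenerate inputs

- Flow normal equations are regularized by 1e-6 of the mean determinant;
  flat (low-texture) frames yield flagged zero vectors, not failures.
- Quantization maps the 0.995 intensity quantile of the base field to the
  top level; the exponential intensity tail means ~0.5% of pixels clip.
- `rescale_unit` rejects all-zero signals; `segment` drops the trailing
  remainder and returns an empty list for short inputs.
- Scattering on a signal shorter than the averaging support T*fs is
  rejected; zero signals produce exactly zero coefficients.
- Cohort sampling uses bounded rejection; it aborts with a clear error if
  the requested separation cannot be met in the given ranges.
- The memory-effect guard rejects trajectories beyond 25% of the frame
  size, where a translation-only speckle model stops being meaningful.

## Known limitations

- The translation-only forward model cannot probe robustness to speckle
  decorrelation; real skin at high frame rates partially decorrelates.
- Gabor-atom heart sounds are spectrally compact; classifiers may find
  them easier to separate than real PCGs. Identification accuracies
  measured here characterize the pipeline, not expected field performance.
- The Farneback implementation is single-threaded NumPy/SciPy; it is
  adequate for desk-scale studies, not real-time use.
- The stethoscope adapter resamples to 1500 Hz by default; corpora with
  rates not commensurate with 1500 Hz get exact rational resampling, but
  no anti-rumble filtering beyond what the source applied.
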