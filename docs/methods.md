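# Methods

## Problem setting

A camera on a stable support films a mostly static scene containing one or
more people.  Breathing translates parts of each body by a sub-pixel
amount at 0.2–0.3 Hz (12–18 breaths/min for an adult).  The frame rate
must satisfy the sampling criterion `f_s > 2 f_h` for the highest motion
frequency of interest; both 50 fps recordings and low-cost 20 fps cameras
satisfy it comfortably for breathing.  The toolkit magnifies the motion in
a user-chosen temporal band so it becomes visible, and provides the
measurement machinery to verify — on ground-truthed synthetic scenes —
that the magnification factor achieved is the one requested.

## Intensity pipeline (ELVM)

Per RGB channel and frame, a Laplacian pyramid is built with the separable
binomial kernel `[1,4,6,4,1]/16`, reflect boundary, ceil-halving of odd
dimensions.  Band `H_k = G_k − upsample(G_{k+1})`; the upsampler
zero-inserts and blurs with the doubled kernel, interpolating border
samples against symmetric padding, so the transform is exactly invertible
(max reconstruction error ~1e−16) and a constant image produces exactly
empty bands.

Each band's per-pixel time series is bandpass-filtered and added back
scaled by a per-band factor `α_k`:

- `α_k = α` for bands whose representative wavelength `λ_k` (the level
  diagonal, in px) is at least the cutoff `lambda_c`; below the cutoff
  `α_k = α λ_k / lambda_c` (linear attenuation of high spatial
  frequencies).  `lambda_c = 0` (default) disables attenuation.
- With `enforce_bound=True`, `α_k` is additionally capped at
  `λ_k/(8 δ) − 1`, the first-order-Taylor validity ceiling for an assumed
  motion scale `δ` (`delta_assumed`, default 1 px).  The default pipeline
  leaves enforcement off so the `(1+α)` contract can be measured directly;
  comparisons at large α run the intensity method in this, its published
  valid regime.

The default synthesis is `out = I(x,t) + α B(x,t)` (current frame plus the
amplified bandpassed signal), the numerically stabler form; the literal
first-frame Taylor synthesis `I(x,0) + (1+α) B` is available as
`exact_eq1_mode` and behaves equivalently to first order.  The lowpass
residual (scene DC, illumination) passes through untouched.

## Phase pipeline (PBVM)

The complex steerable pyramid is built in the Fourier domain: a
raised-cosine radial high/low split at the Nyquist ring, then per scale a
one-octave radial bandpass times `cos^(K−1)` angular windows restricted to
the positive-frequency half-plane (doubled in gain), yielding analytic
coefficients with local amplitude and phase.  Scale-s coefficients are
stored decimated by `2^s`; the recursive lowpass fits in the cropped
spectrum, and the crop rescales so decimation preserves amplitude.  The
squared window set tiles the frequency plane, so reconstruction — real
part of each band re-filtered with the both-lobe angular magnitude window,
plus the two residuals — is exact to machine precision for even
dimensions.  Coefficients are held in single precision during video
processing (phase error ~1e−7 rad, far below any motion of interest;
memory is halved on minute-long clips).

Phase differences against frame 0 are computed wrap-safely as
`arg(S_t conj(S_0))`, never by subtracting angle arrays.  The differences
are bandpass-filtered (which also removes the temporal DC component),
multiplied by α and applied as pure rotations `e^{iαB}`; amplitudes and
the two real residuals are never modified.  The sign convention: local
phase at a fixed pixel is `ω(x − d)` for a pattern moved by `+d`, so
deltas are negative for positive motion; rotations inherit the convention
consistently.

Per-band magnification ceilings: `α δ < π/(2ω)` for the 4-orientation
(octave) pyramid and `α δ < π/ω` for the 8-orientation (half-octave)
variant — exactly double.  The literature source prints the two bounds
with an ambiguous constant; this implementation fixes the constant at π/2
(a quarter period of the carrier) and asserts only the 1/ω scaling and the
factor-2 relation, which are unambiguous.

## Temporal filter

Digital Butterworth bandpass, order 1 by default (the classic choice for
Eulerian magnification), applied forward–backward (zero phase) with
odd-reflect padding.  Zero-phase application matters because a one-way IIR
pass would delay the motion signal relative to the unfiltered frames.  The
single-pass gain at the geometric band centre exceeds 0.995; the effective
two-pass gain measured on a 60 s, 0.25 Hz tone is ≈0.94 (edge transients
account for the difference — the residual DC mean of a filtered random
series is ~1e−3 of the input mean and shrinks with series length, not the
1e−6 one would get from the steady-state response alone).  An ideal FFT
brick-wall bandpass is available as an independent cross-check.

## Synthetic scenes

Patterns are closed-form intensity functions — Gaussian blob,
smooth-edged rectangle (error-function profiles, torso aspect ratio 1.6),
and a seeded band-limited sinusoid texture — evaluated at the continuous
per-frame offset `δ(t) = δ0 sin(2π f t)`.  Nothing is resampled, so the
ground truth displacement is exact; interpolation artifacts would
otherwise swamp measurements at δ0 ≈ 0.05 px.  Optional confounds:
i.i.d. Gaussian sensor noise (σ on the [0,1] scale) and global sinusoidal
camera shake.  The texture realization has its own seed so the noiseless
scene does not change with the noise seed.

Default scene: 96×96 px, 10 fps, 60 s, δ0 = 0.05 px at 0.25 Hz.  The
default pattern scale (Gaussian σ = 3 px) is chosen so the pattern's
spatial spectrum lies inside the octaves the pyramids amplify: energy at
wavelengths beyond the deepest band lands in the lowpass residual, which
both published methods pass through unmodified, and no magnification
method could act on it.  What the generator does *not* model: illumination
changes, occlusion, non-rigid deformation, photorealistic bodies, or
codec artifacts — passing tests demonstrate the signal-processing chain,
not field performance on arbitrary footage.

## Measurement oracles

Motion is measured by upsampled phase cross-correlation of each frame
against frame 0 (sub-pixel, 1/100 px grid), independent of both
magnification pipelines; amplitude is read off by least-squares fit of a
sinusoid at the known frequency (robust to phase and offset).  The
breath-rate estimator takes the Hann-tapered periodogram peak restricted
to 0.1–0.5 Hz and reports a rate only when the peak exceeds 4× the median
in-band power *and* an absolute amplitude floor (0.01 trace units) — the
floor prevents a numerically quiet, flat trace from being declared
respiration.

## Verification battery and problem sizes

The reproduction experiments (`vitalmag.experiments`, driven by
`scripts/acceptance.py` and the end-to-end tests) use: 100 random 64×64
images for pyramid fidelity; the standard 60 s scene (600 frames) with
Laplacian depth 6 and steerable depth 4 for amplification measurements at
α = 9, 19 and 50; a two-region 96×128 scene (0.25 Hz vs 2 Hz) for
selectivity; a static noisy scene (σ = 0.02) across the α grid 5–60 in
steps of 5 for the noise law; a noisy torso scene (σ = 0.005) for the
α = 50 quality comparison; and a three-subject 64×192 scene (12 bpm,
15 bpm, non-breathing) read out through the full phase pipeline.

Two regime notes.  First, the α = 50 ELVM/PBVM comparisons run the
intensity method with its linearization bound enforced — its published
operating envelope — which reproduces the characteristic observation that
intensity magnification at large α moves far less than phase
magnification while preserving more of the original image.  Second, the
quality ordering (intensity method degrades the video less at α = 50) is
a property of torso-scale scenes, where the phase method's much larger
synthesized motion dominates its error budget.  On scenes whose moving
content is tiny relative to the frame, amplified background noise
dominates instead and the ordering can invert; the ordering is a statement
about realistic subjects, not a universal inequality.

## Known limitations

- Camera shake inside the passband is magnified like any other in-band
  motion (demonstrated by the shake generator); the toolkit deliberately
  does not attempt stabilization.
- The phase reference is frame 0; very long clips with drift would need a
  sliding reference, which is out of scope.
- Odd frame dimensions reconstruct slightly less precisely in the
  steerable pyramid (spectrum cropping is exact only for even sizes);
  fidelity remains far above the 40 dB requirement.
- MP4/AVI support depends on an ffmpeg-capable imageio plugin; the
  canonical interchange format is the lossless PNG sequence.
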