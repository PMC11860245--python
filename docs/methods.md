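# Methods

## Model

The generator optimizes each frame of a video so that chosen statistics of a
two-stream feature model match those of target videos.

**Spatial stream.** A VGG-19 convolutional hierarchy up to `conv5_1`.  Two
departures from the classification network are deliberate: pooling is
average (not max), the standard choice in texture synthesis because it
produces smoother gradients; and the weights default to seeded He-initialized
random filters, with trained weights loadable from an `.npz` file.  Random
multiscale filter banks are known to support texture synthesis reasonably
well, and every shipped test instead uses a two-layer fixture network
(6 and 8 filters) so that the full pipeline is exercised at desk scale with
no downloads.

**Temporal stream.** An analytic multiscale spacetime-oriented energy (MSOE)
model, built rather than trained: the frame pair is grayscaled
(0.299, 0.587, 0.114), a binomial Gaussian pyramid is computed (3 scales by
default), and at each scale quadrature pairs of even/odd Gabor filters
(7×7, wavelength 4 px, envelope σ = 2 px, zero-mean) are applied to both
frames.  Opponent motion energies are formed by the standard two-frame
quadrature construction — e.g. rightward energy (a_e − b_o)² + (a_o + b_e)²
where a/b index current/previous frame and e/o the even/odd filter — giving
five channels per scale: static, right, left, down, up.  A drifting grating
moving a quarter wavelength per frame maximally excites its direction
channel; a static pattern yields exactly twice as much energy in the static
channel as in any opponent channel.  Channels are divisively normalized
(E_i / (ΣE + 0.01)) and scaled by a gain of 10 so activations are O(1),
which gives the temporal Gram statistics a dynamic range comparable to
typical spatial conv activations; without this the temporal texture loss is
orders of magnitude weaker than the spatial one and motion statistics are
effectively unconstrained at equal term weights.  Because the filters are
zero-mean, the model is exactly invariant to global luminance offsets.  The
per-scale maps are bilinearly upsampled and concatenated into the `concat`
layer used by the texture loss.

**Differentiation.** Both streams run on a minimal reverse-mode autodiff
core over numpy (`stst.autodiff`): broadcasted arithmetic, ReLU, |·|,
reductions, matmul, same-padded convolution via im2col, 2× pooling and
decimation, bilinear resizing, concatenation and slicing.  Analytic
gradients are verified against central finite differences (rtol 1e-3 on 8×8
probes, and much tighter in practice).  Model weights are constants; only
the generated frame receives a gradient.

## Losses

With activations A^ℓ (N_ℓ filters × M_ℓ locations), flattened filters-major
and row-major in space:

- content: 1/(2 N_ℓ M_ℓ) Σ (A − Â)²;
- Gram: G = A Aᵀ/(N_ℓ M_ℓ); texture: 1/(2 N_ℓ²) Σ (G − Ĝ)²;
- total variation (anisotropic): mean over H·W·C of |vertical| + |horizontal|
  neighbor differences, summed over in-bounds pairs only (the printed sum is
  ambiguous at the last row/column; the normalization keeps 1/(HWC));
- total: Σ_ℓ (α·content + β·texture) over spatial layers plus
  Σ_ℓ (θ·content + λ·texture) over temporal layers plus ω·TV, each term
  routed to its own target video.  Zero-weight terms are never computed.
  Texture layers are summed with unit per-layer weights.  Because the Gram
  normalizes by M_ℓ, texture targets transfer across octave resolutions;
  content targets are re-rendered per octave.

## Optimization and preconditioning

Plain gradient descent matching the stated update rule (no momentum), with
the gradient divided per channel by its standard deviation over the octave's
spatial dimensions (ε = 1e-8 guard; channel-wise statistics are a choice —
the source procedure is silent on channels).  Frames are clamped to [0, 1]
after every step, since frames must remain displayable and the color
transfer assumes bounded support.  Octaves run coarse to fine; the estimate
is bilinearly upsampled between octaves (half-pixel-center convention,
no antialias prefilter, also used for all frame resizing).  Octave sizes are
trunc(H σᵒ) — truncation, not rounding, reproduces the documented
160×284 / 240×426 / 360×640 ladder for σ = 1.5.

Per-frame initialization blends the previous *post-processed* frame with
uniform noise, g_t ← φ g_{t−1} + (1−φ) U(0,1); the very first frame is pure
noise.  To let early frames reach stationary statistics, all targets are
mirror-padded with their first ξ frames in reversed order; the first ξ
outputs are discarded.  The first padded frame has no predecessor, so
temporal terms are dropped for it (its output is discarded anyway); running
temporal losses with ξ = 0 is rejected as a configuration error.  On the
generated side the temporal stream receives the previous generated
(post-processed) frame as a constant.

**Color transfer.** After optimization each frame's 3D color distribution is
transferred toward a reference frame by iterative distribution transfer
(seeded random 3D rotations + sorted quantile matching of the rotated
marginals, 20 iterations by default), followed by a regrain step that
re-imposes the generated frame's spatial gradient field via damped Jacobi
relaxation (50 iterations, data weight 1).  This is a standard realization
of "full 3D pdf transfer with grain suppression"; bit-exactness with any
specific published implementation is not claimed.  In factorization mode the
color reference defaults to the spatial-texture target (the spatial stream
owns appearance); it is configurable.

## STPS baseline

Three steps: a single uniform random 2D phase field per channel added to
every frame's 2D spectrum; a random 3D phase field per channel added to the
spatiotemporal spectrum; per-frame color transfer with the original frame as
reference.  Random phases are drawn as the phase spectrum of white Gaussian
noise, which is Hermitian-symmetric by construction, so outputs are real and
the DC bin (hence the mean) is untouched.  Amplitude spectra are preserved
exactly by the phase-only steps; the optional clamp to [0, 1]
(`clip=True`, the default) is display postprocessing and is the only source
of spectral deviation.

## Feature analysis

Per frame: mean intensity over H, W, C; contrast as the population standard
deviation of the grayscale image.  Per frame pair: mean |Δ| pixel change;
dense optical flow summarized by mean magnitude and mean angle.  Flow uses
the TV-L1 solver from scikit-image (an established dense estimator; the
Farnebäck parameter block is retained in `FlowParams` for config
compatibility but no Farnebäck backend ships here).  Angles use
atan2(v_down, v_right) evaluated in (−π, π] before the per-frame arithmetic
mean — keeping rightward motion away from the branch cut — and the series is
reported wrapped to [0, 2π); a circular mean is available
(`FlowParams(circular_mean=True)`) but off by default to match the plain
averaging of the reference procedure.  Flow correctness is asserted against
ground-truth fixture motion (magnitude within 25 %, angle within 0.3 rad),
not against another solver.

Comparison statistics: Pearson correlation and Euclidean distance between
series (zero-variance series yield a flagged NaN correlation); KL divergence
between pooled 16³-bin color histograms with 1e-9 additive smoothing; k-means
palettes (seeded, k = 5 by default).  Representational similarity: linear
CKA in its feature-space form (tested equal to the centered-Gram HSIC form),
a sliding-window variant (window 5, step 1) stacking per-frame samples; SSIM
with an 11×11 Gaussian window (σ = 1.5, K1 = 0.01, K2 = 0.03, unit dynamic
range, grayscale, border crop by the window radius — verified to 1e-6
against scikit-image); and cSSIM = (1 − SSIM(f_{t−1}, f̂_t))·SSIM(f_t, f̂_t).

## Synthetic fixtures

All tests run on seeded generators with analytically known motion: drifting
sinusoidal gratings, smooth noise textures rigidly translating with toroidal
wraparound (exact subpixel Fourier shifts, so per-frame means are conserved
to machine precision; optional per-frame contrast profiles and channel-mean
palettes for factorization experiments), and static color-blob tilings.
These emulate the controlled-motion content the method is evaluated on; they
do not emulate natural videos' scene statistics, occlusions or photometric
variation, so passing tests demonstrate mechanism correctness and the
direction of the documented effects, not effect sizes on natural footage.

## Problem sizes and reproducibility

The shipped tests and the acceptance checks run at desk scale — frames of
12–32 px, 3–9 frames, fixture networks, single-octave schedules of 50–100
iterations, 5–10 seeds per stochastic claim — sizes chosen so the full suite
completes in about a minute on one CPU while every mechanism (multiscale
descent, blending, padding, color transfer, factorization routing) is
exercised.  Full-resolution synthesis (e.g. 360×640×120 with the default
three-octave schedule) is supported by the same code path but is
computationally heavy on CPU.  All randomness is seeded: fixture content,
initialization noise, color-transfer rotations and phase fields; identical
configs reproduce outputs bitwise on CPU, and run manifests record the
config hash alongside an output checksum.

## Known limitations

- The temporal stream is an analytic motion-energy model, not the trained
  optical-flow CNN of the original two-stream setup; its filter bank
  (orientations, wavelength, scales, gain) is exposed in config rather than
  asserted as ground truth.
- Gram matching constrains motion direction statistics well but
  under-reproduces flow *magnitude* at test scales (generated speeds are
  compressed toward zero); the direction ordering against STPS is the robust
  effect.
- Without an ffmpeg plugin only PNG frame directories are readable/writable;
  MP4 support activates automatically when imageio-ffmpeg is present.
- SSIM/cSSIM are computed on grayscale; per-channel variants are out of
  scope.
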