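# Methods

## Model

KomplexNet is a convolutional classifier whose unit activities are complex
numbers `z = m·e^{iθ}`. The amplitude `m` plays the role of an ordinary
activation — feature strength — while the phase `θ` tags which object a
feature belongs to. Features of the same object should end up with aligned
phases, features of different objects with phases far apart on the unit
circle ("binding by synchrony").

### First layer: amplitudes plus a Kuramoto phase dynamic

A rectified, bias-free real convolution (8 channels, 5×5, same padding)
extracts an amplitude field `a ∈ ℝ^{8×32×32}` from the input image, computed
once and held fixed. Each first-layer unit also carries an oscillator phase,
initialized i.i.d. uniform on (−π, π]. One network timestep applies one
explicit Euler step of a Kuramoto dynamic:

    θ̇_cij = η · Σ_k (r_{k,cij} − ε) · sin(θ_k − θ_cij) · tanh(a_k)

The learnable coupling kernel `r ∈ ℝ^{C×C×h×w}` (all channel pairs, odd
spatial support, applied as a centered convolution with zero padding) pulls
each phase toward its neighbors; the global constant ε, subtracted for
*every* oscillator in the population, pushes the phase away from the
population at large. `tanh(a_k)` gates the influence of a unit by its
activity, so silent units neither attract nor repel. The integration step
size is absorbed into the gain η. The net effect is local attraction with
global repulsion: phases inside a compact active region synchronize, and
distinct regions settle at well-separated positions on the circle.

The kernel is initialized as a 2-D Gaussian (peak `scale_l0`, spatial std
`sigma_l0`, identical for every channel pair), which makes the untrained
dynamic already group by proximity; training reshapes it.

### Complex layer operations

Each subsequent layer (one stride-2 complex convolution to 8×16×16, then
dense layers of 50 and 10 complex units) applies three steps:

1. **Linear application** — the same real-valued, bias-free weights act on
   the real and imaginary parts: `z₁ = f(Re z) + i·f(Im z)`.
2. **Synchrony gating** — the "classic" term `χ = f(|z|)` is the response
   the layer would give to perfectly phase-aligned input; the transmitted
   magnitude is the average `m₂ = (|z₁| + χ)/2`. In-phase inputs pass at
   full strength, antiphase inputs are attenuated to half instead of acting
   like inhibition from negative weights.
3. **Normalized rectification** — `m₂` is standardized (instance-style over
   spatial positions per channel for convolutions; per sample over units for
   dense layers; stabilizer 1e-5 on the standard deviation) and passed
   through a ReLU; the phase of `z₁` is kept.

All linear maps are bias-free, which makes the whole chain equivariant to a
global phase rotation of the input — rotating every phase by φ rotates every
downstream phase by φ and leaves every magnitude unchanged. The phase of a
zero-magnitude activity is defined as 0; the choice is inert because the
corresponding amplitude is 0.

### Readout and losses

The class scores are the last layer's gated magnitudes after normalization
but **without** rectification, used as logits for 10 per-class sigmoids
(rectified magnitudes would be nonnegative and saturate the sigmoids
one-sidedly). A scene with K objects is scored correct iff the top-K logits
pick exactly the true label set (ties break toward the lower class index);
per-label accuracy is logged as a secondary metric.

Training minimizes

    L = Σ_t BCE(ŷ_t, y) + τ · CSLoss(θ_T)

the binary cross-entropy accumulated over the unrolled timesteps plus τ
times the cluster synchrony loss of the final phases,

    CSLoss = 1/2 · (1/G) Σ_l V_l + 1/(2G) · ‖Σ_l e^{i⟨θ⟩_l}‖² ,

where `V_l` and `⟨θ⟩_l` are the circular variance and circular mean of group
l's phases (all channels pooled over the group's pixels) and G counts the
ground-truth object groups. The first term rewards tight within-object
phases; the second rewards object centroids that cancel on the unit circle
(two objects antipodal, three at 120°, …). Overlap regions form an extra
group that is excluded from both terms. A group whose phases cancel exactly
has no circular mean; the loss raises an error in that case rather than
substituting a value (continuous-valued phases never hit it in practice).

### Top-down feedback

The feedback variant adds Kuramoto-style terms from the higher layers into
the first-layer update. The stride-2 convolutional layer feeds back through
a C×C×h₁×w₁ kernel applied in transposed orientation (its grid is lifted
back to the full-resolution grid by zero-stuffing, so L1 site (i₂,j₂)
couples into L0 sites around (2i₂, 2j₂)); each dense layer couples every one
of its units to every L0 site of a channel through a C×D matrix — spatially
unstructured, carrying object-identity information. Feedback terms use the
sine of the phase difference gated by `tanh` of the feeding layer's
magnitude, each scaled by a per-layer gain; there is no ε term on feedback
paths. Kernels are initialized near zero (σ=1e-3) so that negative
(desynchronizing) couplings are reachable. Layer activities used at step t
are those computed at step t−1; feedback is inactive at the first step.

### Model kinds

`real` (same shapes and normalization placement on real activations),
`complex_random` (phases frozen at their random initialization),
`complex_ideal` (phases assigned from ground-truth masks: a random global
offset, N equidistant values randomly permuted over objects, circular-mean
values in overlap regions — antipodal parents tie-break to the first
parent's value + π/2 — and fresh random phases on the background),
`komplexnet` (lateral dynamic) and `komplexnet_fb` (lateral + feedback).
All kinds share identical layer widths; kinds without a phase dynamic are
evaluated once and their scores replicated over timesteps.

## Default constants

| constant | value | meaning |
| --- | --- | --- |
| canvas, channels | 32×32, 8 | input size and first-layer channels |
| k_conv0, k_l1 | 5, 5 | feature / complex conv kernels |
| k_l0, sigma_l0, scale_l0 | 7, 1.5, 0.02 | lateral coupling kernel |
| epsilon | 0.0033 | global desynchronization |
| eta_l0 | 1.0 | lateral gain (Euler step absorbed) |
| eta_fb | (0.2, 0.05, 0.05) | feedback gains (L1, L2, L4) |
| timesteps T | 15 | unrolled Kuramoto steps |
| tau | 2.0 | loss balance |
| lr, batch | 1e-3, 32 | single-run training defaults |

The Kuramoto constants were fixed once by requiring the *untrained* dynamic
to form per-object phase clusters on generated scenes within the default 15
timesteps (mean cluster synchrony loss falling from the random-phase level,
≈1, well below half of it — the README example prints one such trajectory);
they sit in the middle of a broad region where this holds — at roughly
double the coupling scale or the ε/coupling ratio the dynamic
over-synchronizes or fragments.

## Synthetic scenes

The generator emulates a Multi-MNIST-style protocol with a built-in glyph
bank so everything runs without downloads. Glyphs are stroke-drawn,
4-connected, mostly vertical shapes in 10 distinct template classes
(bar, O, L, U, T, Z, H, 7, X, E) with per-instance endpoint jitter,
thickness and intensity variation, drawn in a box narrower than tall
(width ≈ 0.68 × height; 14 px boxes for 2–3 objects, 10 px for more).
Scenes composite K distinct-class glyphs by maximum onto a black 32×32
canvas; the first object lands in the upper-left quadrant of the admissible
region, the rest are rejection-sampled under a pairwise overlap bound
(fraction of each glyph's active pixels). Each object contributes a binary
membership mask; pixels covered by two objects move to an extra excluded
mask, keeping object masks disjoint; the background belongs to no mask.
Perturbations: additive Gaussian pixel noise (clipped to [0,1]), smoothed-
noise background textures composited by maximum (hook for external
grayscale backgrounds), and multi-frame videos of the same glyph instances
translating at integer velocities, with the maximum-overlap frame recorded.

What the generator does **not** emulate: handwriting's stroke statistics and
within-class style diversity, grayscale antialiasing of downsampled MNIST,
and natural-image backgrounds. Passing the scaled studies therefore shows
that the synchrony mechanism binds and helps classification under the
modeled conditions — compact connected objects on mostly-empty canvases —
not that the specific accuracy numbers transfer to Multi-MNIST.

## Training at desk scale

Exact backpropagation through 15 unrolled Kuramoto steps is the dominant
cost on a single CPU, and with random initial phases the early timesteps
carry mostly interference noise: a classifier trained on them learns as
slowly as the random-phase baseline. Training therefore uses a **late-window
schedule**: the phase chain runs all T=15 steps, the first T−k gradient-free,
and the autodiff graph covers only the last k steps — BCE on those steps
(rescaled by T/k to keep the loss scale of the full sum) and the synchrony
loss on the final phases. This trains the classifier in the synchronized
regime it is evaluated in, and trains the coupling kernels through the late
steps. It deviates from backpropagating through all T steps; the gradient
it drops is the early-step contribution to the kernel and feature weights.
Static kinds (real, random, ideal) are algebraically collapsed to a single
step whose BCE is multiplied by T.

Committed study conditions (see `StudyScale`): 4000 two-object,
non-overlapping training scenes, 2 epochs, batch 32, Adam with lr 6e-3,
k = 1, τ = 2, 3 seeds, evaluation on 100 held-out scenes per protocol at
the full T = 15. The paired feedforward-vs-feedback synchrony comparison
runs both models under identical, smaller conditions (1500 scenes, 1 epoch)
because the synchrony organization — driven by the τ·CSLoss term — converges
with far fewer optimization steps than the classifier. These sizes are the
package's desk-scale study design; larger runs (more scenes, more seeds,
full-window BPTT) sharpen the same orderings.

Evaluation protocols: `in_dist` (clean, non-overlapping), `overlap` (25%
maximum overlap at test on models trained without overlap; a 5% minimum
overlap guarantees the scenes actually contain overlapping objects),
`noise` (σ=0.1 additive), `background`, `n_objects` (2–9 objects at test),
and `video` (accuracy indexed relative to the maximum-overlap frame, the
phase state carried across frames).

## Numerical choices

- Phases wrap to (−π, π]; the wrap offset is an integer multiple of 2π and
  gradient-transparent.
- The magnitude `√(re²+im²)` carries a 1e-24 additive stabilizer inside the
  square root; `atan2` gradients are zeroed at the origin, where the phase
  is conventionally 0 and the amplitude vanishes.
- Normalization divides by (sd + 1e-5); degenerate constant fields simply
  map to zero output.
- The efficient Kuramoto step expands sin(θ_k−θ_c) trigonometrically into a
  convolution (local term) plus per-sample resultant sums (global term); an
  O(N²) double-loop oracle verifies it to 1e-5. Large stride-1 convolutions
  go through an FFT path (verified against im2col); gradient-free chains use
  numba-fused elementwise kernels that compute the same values.
- Energy bookkeeping for the graph form counts ordered pairs i≠j (each
  undirected pair twice).
- All learnable tensors are float32; tests of analytic identities use
  float64 inputs.

## Known limitations

- The scaled studies run near the low end of the learning curve; absolute
  accuracies are far below what the full Multi-MNIST training reaches, and
  the random-phase baseline in particular is data-starved. Orderings, not
  levels, are the supported claims.
- The late-window schedule is an approximation to full-unroll BPTT; with
  k = T they coincide.
- The ideal-phase model here assigns phases on image-pixel masks while the
  amplitude field spreads slightly beyond them (convolution halo), so its
  phase information is imperfect near object borders — the same effect the
  full-scale experiments report.
- Single oscillation frequency; natural frequencies are fixed at zero in
  the network path.
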