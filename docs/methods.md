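# Methods

## Model

A cohort of closed vascular surfaces is registered to a fixed template
by a family of diffeomorphisms sharing one velocity network. Surfaces
are represented as weighted point clouds (triangle centroids, weights =
normalized cell areas, per-cell outward normals), embedded in the unit
cube by a single anisotropic affine transform fitted over the whole
cohort — template and sources share one coordinate frame, and the stored
transform converts unit-cube distances back to cm for reporting. An
optional rigid CPD pre-alignment (rotation, isotropic scale,
translation; uniform outlier weight 0.1) precedes the normalization.

The deformation of shape i is the unit-time flow of a stationary
velocity field `v(x; Θ, z_i)`. The network has three stages:

1. **FA** — a shallow MLP consuming `(x, z̄_i(x))`, 3 layers of width 64
   by default, Leaky-ReLU slope 0.2, linear final layer (whether an
   activation precedes the encoder is a free choice; the linear variant
   was selected so the encoder sees an unconstrained feature range);
2. **FPE** — deterministic Fourier features with base-2 frequencies
   `[u | sin(2^k π u) | cos(2^k π u)], k < N_e`, N_e = 3, width
   (2·N_e+1)·64 = 448, mitigating the spectral bias of coordinate MLPs;
3. **DF** — the flow head proper, 5 layers of width 256 on
   `(features, z̄_i(x))`, followed by a linear 3-output layer.

The latent code z_i ∈ R^{N_z} (N_z = 256 by default, 2/N_z-variance
Gaussian initialization) is reshaped row-major onto a g_z³ grid
(g_z = 2: the 8 corners of Ω) and trilinearly interpolated at the query
point, making the conditioning position-aware; query points are clamped
to Ω for the lookup only. The composition order is FA → FPE → DF.

The DF output layer is initialized at zero (all other layers
Kaiming-normal), so training starts from the identity map — the flow
cannot tear the geometry before it has learned anything.

## Integration

The direct map uses K = 10 forward-Euler steps; the inverse map the
explicit modified-Euler scheme, whose logged outer velocities also feed
the kinetic-energy regularizer. The implicit backward-Euler scheme —
the exact inverse of the forward scheme — is solved per step by
fixed-point iteration warm-started at the modified-Euler estimate; it
converges when Lip(v)/K < 1 and is used as a testing oracle and an
optional inference mode. Points are never re-clamped during
integration, which would destroy invertibility. Gradients flow through
the unrolled steps directly (no adjoint method; at K = 10 the tape is
short).

## Attachment measures

Chamfer distance (squared Euclidean, both directions, means over each
cloud), weighted Chamfer (per-point weights inside each directional sum;
the prefactors are read as the cloud cardinalities), Chamfer + normals
penalty (w_n = 1e-2; the penalty compares each cloud's own normals at
the Euclidean nearest-neighbour pairs, and deformed clouds carry their
source normals unchanged), point-to-plane Chamfer (minimum taken over
the projected quantity itself), and the debiased Sinkhorn divergence
(quadratic unhalved cost ||x−y||², ε = 1e-4, ε-scaling factor 0.9,
log-domain iterations; point masses are uniform or the cloud weights).
Nearest-neighbour ties break to the lowest index, deterministically.
FLD/BLD error maps are unsquared distances, reported in cm via the
stored unit-cube transform.

The Sinkhorn value enters the loss through its dual potentials; its
gradient with respect to the point positions uses the converged
transport plan (Danskin's theorem) rather than differentiating through
the iterations.

## Training

Per epoch the cohort is shuffled and partitioned into ⌊N_s/B⌋ batches
(B = 8) whose sizes differ by at most one and sum exactly to N_s — the
literal batch-count bound combined with "B+1 for the first N_s mod B
batches" would over-count, so the partition rule is enforced instead.
For each batch one template sub-cloud of M points (M = 2000 at full
scale) is drawn and shared across the batch; each source draws its own
M points. Sampling is adaptive: ⌊aM⌋ points (a = 0.15) with the highest
current pointwise loss are retained, the rest drawn uniformly without
replacement; measures without a pointwise decomposition (Sinkhorn) fall
back to uniform sampling. Mapped sub-clouds are compared against the
full opposite cloud — subsampling caps the integration cost, while the
attachment target stays exact; for the Sinkhorn measures both sides stay
sampled (the solver is quadratic in both cardinalities).

The loss is the batch-mean bidirectional error plus w_z·||Z||²
(w_z = 1e-3), w_Θ·||Θ||² (w_Θ = 0 by default — no value is established
for it, the term is exposed), and w_v·L_reg (w_v = 1e-4), with L_reg the
raw sum of squared logged velocities over both directions, all sampled
points and all K steps. Adam updates Θ and the batch's codes at the same
learning rate λ (1e-3 at full scale); a batch update touches no other
shape's code. Divergence (non-finite loss) aborts with a diagnostic
error.

At test time only the code of the unseen shape is optimized, starting
from zero (the prior mean under the w_z shrinkage): 100 Adam epochs at
50λ, then 10 L-BFGS iterations on a fixed subsample (the quasi-Newton
phase needs a deterministic objective; scipy's L-BFGS-B line search is
used as-is). If the line search fails or worsens the objective, the
best first-order iterate is returned with a flag.

## Generative layer

Σ_z is the unbiased covariance of the trained codes; sampling draws from
N(0, Σ_z) via an eigendecomposition square root with negative
eigenvalues clipped at zero, centred at the origin rather than the
empirical mean. Latent interpolation is linear or great-arc SLERP
(falling back to linear, with a warning, for near-antipodal codes).
Code perturbations are white Gaussian noise rescaled so that
||e||/||z|| equals the requested noise-to-signal fraction — "SNR = 5%"
displaces the code by 5% of its norm; the per-entry-variance reading
would be an equally defensible convention. Decoding applies the
modified-Euler inverse flow to the template, so point count and weights
are preserved by construction.

## Synthetic fixtures

The fixture generator emulates aorta-like anatomies at desk scale: a
spline-centerline tube (parallel-transport frames, tapering radius,
capped ends, consistently outward orientation enforced via the signed
volume) with up to three branch *stubs* realized as smooth radial
protrusions — the meshes stay genus-0 and closed, mirroring the
assumption that all shapes share one topology. Cohorts perturb control
points, radii and stub parameters by Gaussian factors of relative scale
0.1 (the default "anatomical variability" of the fixtures); a curvature
guard rejects self-intersecting configurations and shrinks the radius
profile if a perturbation violates it. Analytic sinusoidal warps with a
closed-form displacement-gradient bound < 1 provide ground-truth
diffeomorphisms, inverted to 1e-12 by contraction iteration.

What the fixtures do **not** emulate: patient-level statistics, true
branching topology (stubs are protrusions, not vessels), open
inlets/outlets (available via a flag but not default), segmentation
noise, or partial overlaps. Passing the desk-scale experiments
therefore demonstrates the machinery — measures, flows, optimization,
latent conditioning — not clinical-grade accuracy on real aortas.

## Numerical choices

* Everything is float64 except the Fourier-feature trigonometry, which
  by default runs in float32 (`NetConfig.fast_fpe`): the ~1e-7 feature
  noise is far below attainable registration accuracy but 20–30× faster
  on platforms with scalar libm. High-precision work (the implicit
  inverse oracle, finite-difference checks) sets `fast_fpe=False`.
* The autodiff tape is a ~300-line reverse-mode implementation over
  numpy with fused ops for the linear+activation layers, the Fourier
  encoder and the trilinear lookup; every op is checked against central
  differences in the test suite.
* CPD's E-step runs in log-space; σ² is floored at 1e-12. The TPS
  system is solved densely and rejected above condition number 1e12.
* Unit-cube margin defaults to 0.05 so integrated trajectories rarely
  leave Ω.

## Desk-scale problem sizes

The test suite and the acceptance script run scaled-down versions of
the full-size experiments: cohorts of 4–5 synthetic vessels of ~2000
points each, a reduced network (FA 2×32, DF 3×64, N_z = 32, g_z = 2,
N_e = 3), M = 500 sampled points, K = 10, and 100–150 epochs. Two
small-cohort calibrations differ from the full-scale defaults: the
batch size is 1 (with four shapes and the default B = 8 an epoch would
be a single optimizer step; one shape per batch restores several steps
per epoch at unchanged cost) and the learning rate is 2e-3 — a pilot
sweep showed 1e-3 to 2e-3 converging smoothly at this scale while 5e-3
and above made the end-of-training error oscillate. The
registration-recovery experiment trains three seeds and checks that the
cohort-mean bidirectional Chamfer error drops by at least 75% from its
pre-registration value; held-out inference checks a ≥4× improvement
over the zero-code decode.

## Known limitations

* Cohort registration quality is bounded by the shared-template
  assumption; no atlas/template estimation is provided.
* The Sinkhorn path supports no pointwise decomposition, hence no
  adaptive sampling and no per-point error maps.
* CPU-only: the intended cohort sizes are desk scale; the full-scale
  configuration (N_z = 256, M = 2000, hundreds of shapes) trains but
  slowly.
* Normals of deformed clouds are carried, not recomputed; under large
  deformations the normals-aware measures use stale directions.
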