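# Methods

This note records the models implemented by the `wfm` package, the
numerical choices behind them, and what the synthetic data generator does
and does not emulate.

## Elastic model and traction force microscopy

The substrate is a linear-elastic, isotropic, incompressible half-space
(Young's modulus `E = 5400 Pa`, Poisson's ratio `ν = 0.5` by default; both
configurable). A surface traction field `t(y)` produces surface
displacements through the Boussinesq convolution

    u(x) = ∫ G(x − y) t(y) dS(y),

with the in-plane 2×2 Green's tensor

    G(r) = (1 + ν) / (π E r³) · [ (1−ν) r² + ν r_x²   ν r_x r_y          ]
                                [ ν r_x r_y           (1−ν) r² + ν r_y²  ]

The inverse problem (Fourier-transform traction cytometry, FTTC) is the
per-wavevector Tikhonov solve

    t̃(k) = (G̃ᵀG̃ + λ² I)⁻¹ G̃ᵀ ũ(k),

with the analytic spectral kernel

    G̃(k) = 2(1+ν) / (E k³) · [ (1−ν)k² + ν k_y²   −ν k_x k_y         ]
                              [ −ν k_x k_y         (1−ν)k² + ν k_x²  ]

### Discretization

* Traction is treated as piecewise constant over grid cells: the kernel
  carries a separable boxcar (sinc) factor, the transform of one pixel
  cell. This matches a cell-averaged quadrature of the real-space
  integral; on an 8×8 grid the spectral forward map agrees with direct
  real-space summation (64-point midpoint quadrature per cell) to 1.5%
  relative L2.
* The `k = 0` mode is zeroed in both directions: an adherent cell exerts
  no net force, and rigid substrate translation is unobservable.
  Consequently every inverted traction field sums to the zero vector.
* **Periodic mode** evaluates the cyclic convolution and is the exact
  inverse pair of the FTTC solve (round-trip relative error < 1e-6 at
  λ = 0 on band-limited fields) — the configuration used by the oracle
  tests.
* **Padded mode** approximates an isolated cell on an infinite substrate.
  The forward map zero-pads ×4 per axis. The inverse does *not* zero-pad
  the displacement (the half-space response does not vanish outside the
  window); instead it minimizes the same Tikhonov objective under the
  aperiodic padded operator with the traction support constrained to the
  observed window, solved by conjugate gradients on the normal equations
  (≤ 120 iterations, tolerance 1e-12). This reduces the boundary error
  of inverting windowed data from ≈20% to ≈2% on noiseless fields.

### Choosing the regularization parameter

The default λ grid spans five decades (1e-3 – 1e2) around the smallest
nonzero singular value of the spectral kernel, 40 log-spaced points.

The discrete FTTC system is square and invertible, so the residual norm
has no noise floor — the classic two-branch L-curve degenerates, and no
geometric corner rule alone is reliable. Two selectors are provided:

* `select_lambda_lcurve` — the L-curve criterion: maximum curvature of
  the axis-normalized, spline-smoothed log–log curve after pruning the
  machine-fit branch (residuals below 1e-3 of maximum), cross-checked
  against generalized cross-validation. When GCV prefers (nearly) no
  damping — the signature of noiseless data — the GCV choice is returned;
  the corner is also never allowed below the GCV optimum. On white
  displacement noise of 5% this lands within 2× of the grid-best
  reconstruction error; on noiseless data it returns the bottom decade.
* `select_lambda_gcv` — generalized cross-validation in closed form from
  the per-wavevector eigenvalues. It remains well behaved when the
  displacement errors are spatially correlated (PIV window averaging),
  which is why the bead-image pipeline uses it.

### PIV

Displacements are estimated by block-wise normalized cross-correlation
(window 32 px, step 16 px) with a three-point Gaussian sub-pixel peak
fit (parabolic fallback for non-positive lobes). Featureless windows are
flagged NaN and filled by nearest-neighbour interpolation before
inversion. A `passes` option adds iterative image-deformation
refinement: the deformed image is warped back by the current estimate
(cubic interpolation) and the residual shift re-measured. This removes
the loss-of-pairs bias of single-pass correlation (≈0.16 px on a 3 px
uniform shift) and roughly halves the error on spatially varying fields;
the pipeline helper `traction_from_bead_images` uses three passes.

### End-to-end error budget

On synthetic cells at the default conditions (26×26 force grid at
3.44 µm, adhesion footprint σ = 5 µm, peak tractions up to 300 Pa,
displacements 0.05–0.5 µm), the full chain — bead rendering → multi-pass
PIV → resampling → GCV-selected FTTC — recovers the generating traction
with relative L2 error ≈0.21–0.27 (padded mode, default displacement
jitter of 0.02 µm) and ≈0.31–0.36 (periodic forward, noiseless). The
tests assert budgets of 0.35 and 0.40 respectively. The limiting factor
is not correlation noise (the multi-pass PIV reaches ≈0.02 px) but the
spatial resolution of window-based correlation: displacement structure
at the adhesion scale is averaged over ≈7 µm windows, and the inversion
amplifies that smooth deficit. Sharper adhesions than the force grid can
resolve would make the budget worse, not better — a real constraint of
the measurement, not of the implementation.

## Wrinkle statistics

Per-cell traction is summarized by the mean traction
`f̄ = (1/M) Σ |f_m|` and the force-weighted stress tensor

    S_ij = 1/(2M) Σ_m { n_j f_i + n_i f_j },   n = (x_m − x_0)/|x_m − x_0|,

whose eigendecomposition gives the principal direction φ_s, the principal
traction f_p (negative = contractile) and isotropy I = |f_p / f_p_min|.
Nodes coinciding with the center x_0 are skipped (at most one on odd
grids). Angles are axial quantities in degrees in [0, 180), measured
counter-clockwise from +x in a y-up frame; the image-to-physical y-flip
is applied once, inside the angle-producing operations.

Wrinkle length is the pixel count of the skeletonized mask. The wrinkle
direction φ_w comes from the orientation histogram of the Hann-windowed
2-D power spectrum: power is restricted to the inscribed k-disk (the
corners of a square spectrum otherwise bias the histogram toward the
diagonals — on white noise the argmax would always be ≈135°), binned per
orientation in 2° bins as *mean* power per bin, circularly smoothed over
5 bins; φ_w is the argmax orientation + 90°. Wavevectors below 6
cycles/image are masked — the wrinkle-region envelope (a band elongated
along the force axis) otherwise leaks low-k power perpendicular to the
true answer. The direction is flagged undefined for foregrounds under
10 px or max/median bin power under 1.5 (isotropic spectrum).

Topology counts 8-connected wrinkle regions of ≥ 20 px: one region (or
none) is "clustered", several are "dispersed". Cell morphometrics use
Crofton perimeters and roundness 4πA/P².

## Bilayer buckling mechanics

A stiff oxidized skin (modulus E_p, thickness h ≈ 0.1 µm) on an
elastomer (E_m) buckles under compression with

    λ/h  = 2π (E_p / 3E_m)^{1/3}
    ε_c  = −(1/4)(3E_m/E_p)^{2/3}
    A/h  = (ε/ε_c − 1)^{1/2}        (A = 0 below onset)

Compressive strains are carried as negative numbers, exactly as ε_c is
defined; sub-critical strain returns zero amplitude rather than a
complex number. Observed λ/h ≈ 30 pins E_p/E_m ≈ 300 and ε_c ≈ −0.01;
resolving 20 wrinkles across a 100 µm cell requires E_p/E_m ≲ 1500; at
the strongest compression ε ≈ −0.05 the amplitude is ≈ 200 nm. Because
the buckling criteria depend only on the stiffness *ratio*, a traction
field inferred on one substrate transfers to a substrate of equal ratio
by scaling forces with the modulus ratio (`rescale_prediction`).

## Synthetic cells

The generator is the package's test bed: it must produce data whose
*statistics* match the measurement scenario, not photorealistic images.

* **Traction fields**: 6–16 adhesion spots on a randomly oriented
  ellipse (mean radius 20 µm, aspect 0.45–0.85 — spindle-shaped,
  matching contractile smooth-muscle morphology), pulling inward with a
  small tangential jitter. Spot strength is weighted toward the poles of
  the long axis (0.35 + 0.65 cos²), reflecting stress fibres running
  along the cell axis; this is what makes the population's principal
  axes well defined. Spot footprint σ = 5 µm — about 1.5 grid cells, the
  smallest structure the 3.44 µm force grid can represent, and the value
  that puts the population mean traction in the measured tens-of-Pa
  range (population mean ≈ 35 Pa, range ≈ 5–70 Pa at default scales of
  50–300 Pa peak). Every field is projected to exactly zero net force
  and zero net torque.
* **Bead images**: beads at 0.4 /µm² with Gaussian point-spread spots on
  a grid 8–16× finer than the force grid; the deformed image moves each
  bead by the forward displacement interpolated to its position plus
  0.02 µm jitter.
* **Wrinkles**: where the locally smoothed force magnitude exceeds the
  10 Pa extinction floor (and the image-mean traction is above the same
  floor — below it the mask is empty), ridge segments are drawn
  perpendicular to the local force axis, snapped to phase lines spaced
  by the bilayer wavelength; total ridge length is proportional to the
  local force magnitude (0.05 µm/Pa per node), so skeleton length grows
  linearly with traction by construction. Ridges longer than two
  wavelengths split onto adjacent phase lines. The orientation field is
  smoothed harder than the magnitude so nearby segments stay parallel.
  The pseudo-micrograph adds a soft cell body and Gaussian noise.
* **Datasets**: each base cell is rotated 0/90/180/270° with force
  components co-rotated ((f_x, f_y) → (−f_y, f_x) per quarter turn), so
  63 base cells give exactly 252 pairs; the train/test split is drawn
  per base cell so augmented copies never straddle the split.

What the generator does **not** emulate: phase-contrast optics and
illumination artifacts, focal-adhesion turnover, curved/branched
wrinkles, wrinkle hysteresis, segmentation errors of real wrinkle
extraction, and cell-to-cell correlations in morphology. Passing tests
therefore demonstrate that the pipeline is self-consistent and that its
estimators behave correctly on data obeying the stated physics — not
that the trained translator would reach the same accuracy on
experimental micrographs.

## Force codec and error metrics

A force component maps to intensity through
`I(f) = a·arctan(f/b) + I_mid` with `a = 81.2`, `b = 50 Pa`,
`I_mid = 127.5`; decoding inverts with `f = b·tan((I − I_mid)/a)`.
Quantized encoding rounds half-up and clamps to [0, 255]; intensities at
the arctan asymptotes are not decodable and either raise or (in the
prediction path) are clipped half a step inside the open interval, with
saturated pixels countable via `n_saturated`.

The translator evaluates one axis at a time: pair 1 is (image, encoded
f_x); pair 2 rotates the image a quarter turn and encodes the rotated
field's x-component (derived from f_y). Prediction un-rotates on the
26×26 force grid, where the quarter turn is exact — the uneven
nearest-neighbour pixel blocks of the 26→64 upsampling do not commute
with rotation.

Errors are weighted by true magnitude (ω_m = f_m/f̄): the magnitude
error reduces to Σ|Δf| / (M f̄), which is singularity-free at zero-force
nodes; the direction error uses the full-quadrant arctangent with
differences wrapped to [0°, 180°] (the principal-value variant is
selectable); R is the Pearson correlation over pooled f_x and f_y.

## Translator networks

Implemented in a small numpy layer library with explicit backprop
(im2col convolutions, nearest-neighbour upsampling + 3×3 convolution in
the decoder to avoid checkerboard artifacts, instance normalization,
Adam). Generator: U-Net encoder–decoder, depth log2(size) − 2 (four
levels at 64 px), widths 16/32/64/64, skip concatenations, tanh output
mapped to the 8-bit range. Discriminator: PatchGAN over the 2-channel
(input, force) concatenation; two strided layers at 64 px (≈34 px
receptive field, scaling to ≈3 strided layers at 256 px). Objective:

    L(G,D) = E[log D(x,y)] + E[log(1 − D(x,G(x)))] + λ·L1(y, G(x)),

λ = 100, Adam(lr 2e-4, β₁ 0.5, β₂ 0.9), 100 epochs at batch size 1 for
full-scale work. The baseline model is the identical generator trained
with the adversarial terms disabled. Discriminator and generator
gradients are computed from the same forward tapes and both optimizers
step simultaneously. Inputs are normalized to [−1, 1]. Training is fully
seeded and reproduces loss trajectories bit-for-bit; checkpoints embed
the config and reload to bit-identical predictions.

The desk-scale configuration exercised by the tests — 252 augmented
64-px pairs, 20 epochs, batch 4, base width 16 (≈195k generator
parameters) — reaches held-out pooled correlation R ≈ 0.9 and direction
error ≈ 15° on 9 test cells, with the GAN's held-out L1 within 5% of the
baseline's. These numbers characterize the synthetic benchmark, not
performance on experimental data, which requires full-scale training on
real image pairs.

## Known limitations

* The half-space model ignores finite substrate thickness and any
  mechanical feedback of the wrinkled skin on the displacement field.
* Window-based PIV bounds the recoverable traction resolution; see the
  error-budget section.
* The wrinkle renderer draws straight λ-spaced segments; real wrinkles
  curve, branch and merge.
* The translator is resolution- and scale-specific: a model trained at
  one substrate stiffness transfers only when the skin/elastomer
  stiffness ratio is unchanged (then forces rescale by the modulus
  ratio); otherwise retraining is required.
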