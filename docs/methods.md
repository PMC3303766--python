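# Methods

## Model and discretization

The snake energy combines four terms over a closed curve `v(s)`,
`s ∈ [0, 1]`: elastic `w1 ∫|v′|²`, bending `w2 ∫|v″|²`, external `∫P(v)`
with `P = −λ|∇I|²`, and an optional balloon `−∫det(c0·v, v′)`. Weights are
constants (non-constant weight profiles are out of scope), and the Legendre
condition requires `w2 > 0` for the stationarity equation to deliver a
minimum; the package therefore rejects `w2 = 0` in `SnakeParams` while the
diagnostic operators accept `β = 0` (they analyze the operator, not the
minimization).

The gradient-descent flow of this energy is discretized explicitly on N
periodic nodes. Space derivatives use the standard second/fourth central
differences except the balloon term, which uses the one-sided forward
difference — retained deliberately (fidelity to the scheme being analyzed)
even though it costs one order of spatial accuracy. Collecting terms gives
the circulant update `V^{k+1} = (I − δK)V^k − γδL(J2 V^k) + δg^k`.

Two sign/scale conventions are fixed here because the update formula alone
does not determine them:

- **γ = c0/h.** Only this scaling makes the node-wise balloon term
  `−γ J2 (V_{i+1} − V_i)` an approximation of `−c0 J2 v′`; the alternative
  reading `c0·h` leaves the term O(h²) and dimensionally inconsistent with
  the continuum equation. The same reading propagates into the stability
  algebra (where only `r1 = αδ`, `r2 = βδ` appear, so the criterion itself
  is unaffected).
- **(LV)_i = V_i − V_{i+1}** (first row `(1, −1, 0, …)`). With the minus
  sign in the update this reproduces `+γδ J2(V_{i+1} − V_i)` node-wise,
  i.e. the discrete balloon force points along the rotated forward tangent.
  The identity is asserted in the test suite.

Energy quadrature (for monitoring, not for the update) uses centered
differences and the periodic rectangle rule, which is spectrally accurate
on smooth closed curves; the discrete energies on a 256-node unit circle
match the closed forms 4π², 16π⁴ and −2π to a few parts in 10³.

## Stability

Fourier ansatz on the error recursion gives the amplification factor
`μ(η) = 1 − 4 r1 sin²η − 16 r2 sin⁴η`, which equals `1 − δ·(DFT symbol of
K at θ = 2η)` — an identity tested to 1e-12. Nonnegative rates make
`μ ≤ 1` automatic, so boundedness reduces to `μ(π/2) ≥ −1`, i.e.
`2r1 + 8r2 ≤ 1`; the equivalent printed form `2ε(4w2 + w1h²) ≤ 1`
(`ε = δ/h⁴`) is the same inequality after substituting α and β and is
property-tested as such. `check_stability` also reports the largest stable
step `δ_max = 1/(2α + 8β)` and the iteration bound `⌊1/(6εw2)⌋` from the
convergence analysis. Because K is positive semidefinite and circulant,
any circulant quadratic energy — including the centered-difference
quadrature used for monitoring — is mode-wise non-increasing under a
stable step with `c0 = 0`; this is the discrete sense in which the scheme
is a gradient descent, and it is verified over random stable parameter
draws.

Evolution refuses an unstable step by default (`StabilityError`); an
`allow_unstable` flag exists for instability experiments, which confirm
iterate growth at criterion 1.2 and boundedness at 0.8 over 500 steps.

## Consistency and the residue

Applying the (undivided) discrete spatial operator to samples of an exact
smooth closed curve and subtracting the analytic operator
`w2 v⁗ − w1 v″ − c0 J2 v′` isolates the truncation defect. Time-independent
test curves remove the O(δ) time term, so the spatial orders can be
measured alone; analytic derivatives are obtained by FFT differentiation
of the samples, exact for trigonometric polynomials such as the unit-circle
test curve. The defect is additionally resolved **per term** (bending,
elastic, balloon), because the terms decay at different rates: the centered
differences are O(h²) while the one-sided balloon difference is O(h). On
the unit circle with `w1 = w2 = c0 = 1` the balloon defect at N = 64 is
≈ 0.31 against a bending defect of ≈ 2.5, so the aggregate defect still
shrinks at rate ≈ 1.9 over N ∈ {64, …, 256}; the per-term resolution is
what exposes the asymptotic first-order behavior at practical grid sizes.
`estimate_order` therefore reports the per-term slopes, the aggregate
slope, and an overall order equal to the smallest active per-term slope
(2.0 without balloon, 1.0 with). The truncature error is `δ ×` the residue
max-norm; its ratio to δ vanishing under refinement is the consistency
check. The convergence-bound constants of the error analysis are not
implemented; only the order behavior is tested empirically.

## Scalar reduction and the worked example

`reduce_elp` reduces the stationarity system with constant weights to the
normalized form `x⁗ − (w1/w2)x″ − tr(∇k)/(2w2)·y′ + (∂P/∂x)/(2w2) = 0`
(and symmetrically in y with the coupling sign flipped). The coefficient
ingredients `tr(∇k)` and `∂P/∂x = −2λ(I_x I_xx + I_y I_xy)` are computed by
fourth-order central differences (step 0.01) on the user-supplied
callables, and constancy is verified by sampling at ≥ 3 points with
relative-spread tolerance 1e-8; non-constant coefficients raise unless the
caller opts out. An exact symbolic (sympy) differentiation serves as the
independent oracle in the tests, never as the implementation. For the
worked example (`w1 = w2 = 1`, `k(v) = 10v`,
`I = (2√2/3)(x^{3/2} + y^{3/2})`, `λ = 1`) the reduction yields
`x⁗ − x″ − 10y′ − 1 = 0`. The companion closed-form curve is exposed by
`evaluate_example2` for its boundary anchors (`v(0) = (1,1)`,
`v′(0) = (3.1, −8.1)`, `y(π) = −2 − π/10 − 3cosh 2π`); it is *not* asserted
to satisfy the reduced system, whose printed solution appears to have
suffered typographical loss (substitution does not vanish, and the x(π)
boundary value carries the opposite sign of the closed form).

## Potential and sampling

Images are normalized to [0, 1] (λ absorbs intensity units; the model does
not fix a normalization). The potential grid is `−λ(I_x² + I_y²)` on the
σ-smoothed image with central differences (one-sided at edges); the force
grids ∇P are differentiated from the P grid rather than analytically from
I, so the force is exactly the discrete gradient of the discrete potential.
Off-grid values use bilinear interpolation with clamping to the image
rectangle (edge replication), which keeps the explicit iteration defined if
a transient iterate briefly exits the image; a strict mode errors instead.
Pixel coordinates are `x = column`, `y = row`, 0-based, pixel-centered,
everywhere in the package.

## Phantoms and what passing tests show

Phantoms are binary disks/ellipses/harmonic blobs rendered at pixel
centers, Gaussian-blurred (default σ_e = 2 px, giving the edge a ramp whose
steepest slope sits on the true boundary), plus optional additive Gaussian
noise drawn from the stated seed (the seed governs only the noise). They
emulate the geometry of a blurred object boundary but not the speckle,
shadowing, attenuation or anisotropic texture of clinical ultrasound — so
sub-pixel accuracy on phantoms demonstrates correctness of the scheme, not
expected clinical accuracy. The reference segmentation setting used in the
tests (`w1 = 0.005`, `w2 = 1e-6`, `λ = 5000`, `σ = 1`, N = 60, tol = 0.05
px/unit-time) localizes a radius-30 blurred disk edge to ≈ 0.4 px mean
error in ≈ 300 steps; λ is large because the [0, 1]-normalized image makes
`|∇I|² ~ 0.04` at a blurred edge, and the potential force must dominate the
elastic shrinking force for the snake to lock on rather than pass through.

## Slices and surfaces

Volumes are segmented slice-by-slice; `propagate` mode (default) seeds each
slice with the previous converged curve, `independent` mode reuses the
initial curve. The slice parameter r defaults to the slice index scaled to
[0, 1] and becomes the z coordinate of the mesh vertices exactly. Bands
between consecutive slices are split into 2N triangles wrapping modulo N;
the seam is watertight (every interior edge shared by exactly two faces),
and meshes round-trip through Wavefront OBJ.

## Numerical choices and limitations

- Auto time step `δ = 0.5 × δ_max`; the safety factor is a choice (the
  stability analysis gives only the bound), overridable.
- Stopping tolerance default 1e-3 px/unit-time, max 10⁵ iterations;
  segmentation examples use looser tolerances since sub-pixel stationarity
  arrives long before the default threshold.
- Divergence is declared on non-finite iterates or displacement beyond 10×
  the domain diagonal, reported with the iteration index.
- Open (non-periodic) snakes, non-constant weights, semi-implicit stepping,
  snake resampling during evolution, gradient-vector-flow potentials, and
  the full 3D surface evolution are out of scope; the slice reduction is
  the supported 3D path.
- The acceptance script's consistency study uses N = 64 and 128 (the
  defect ratio is already within 0.1% of its asymptote there); the
  stability-threshold search uses a 101-point r2 grid with bisection in r1
  against a 4097-point frequency grid.
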