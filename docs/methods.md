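# Methods

## Physical model

A flat patch (or line) of cardiac tissue at `z = 0` carries a transmembrane
potential field `v_m(r')` (mV); a parallel plane of ideal point sensors at
the catchment height `z0` records the extracellular potential `v_e(r)`.
Under the quasielectrostatic approximation in a homogeneous conducting
medium, each tissue element contributes a 1/distance potential

    Γ(r − r') = c / sqrt(|r − r'|² + z0²),   c = a² σ_i / (4 σ_e),

with `a` the element radius and `σ_i`, `σ_e` the intra-/extracellular
conductivities, and the recorded potential is the surface integral of
`Γ · ∇²v_m` over the tissue.  Moving the in-plane (source-surface) Laplacian
onto Γ turns this into a spatial convolution — a linear, space-invariant
system whose impulse response is the in-plane Laplacian of Γ evaluated at
the sensor height:

    1-D:  h(x)   = c (2x² − z0²)   / (x² + z0²)^{5/2}
    2-D:  h(ρ)   = c (ρ² − 2 z0²)  / (ρ² + z0²)^{5/2}

Both are even, negative at the origin (a sensor directly above a
depolarized element sees a negative deflection), cross zero at `z0/√2`
(1-D) or `√2·z0` (2-D), and integrate to ≈ 0 over a wide window: the
forward map nearly annihilates spatially constant sources, which is one
root of the inverse problem's difficulty.  Because Γ is harmonic away from
its singularity, the in-plane Laplacian equals minus the normal second
derivative at `(x, y, z0)`; the test-suite checks both forms against
finite differences.

`c` defaults to 1 (model units) because no element radius or conductivity
values are part of the reference conditions; all potentials are then
expressed in the units of `v_m` (mV).  `PhysicalConstants.from_cell`
derives `c` when microscopic parameters are available.

## Discretization

Node centers sit at `(i + 0.5)·Δ − L/2` with `Δ = 1/density`, so the grid
is symmetric about the origin; source and sensor grids share coordinates.
The convolution is discretized by a Riemann sum with the cell measure (`Δ`
or `Δ²`) folded into the matrix, sources assumed zero outside the patch
(truncated convolution, no wrap-around):

    H[i, j] = h(r_i − r_j) · Δ^d.

`H` is symmetric Toeplitz in 1-D and symmetric block-Toeplitz with
Toeplitz blocks in 2-D — both guaranteed *exactly*, because the matrix is
always rebuilt from the sampled impulse response over signed offsets.  The
reference conditions are `L = 3 cm`, 80 elements/cm per axis and
`z0 = 0.02 cm`, giving 240 nodes in 1-D and 240 × 240 = 57 600 in 2-D;
2-D computations run on a decimated grid (the sampled impulse response is
simply subsampled), with decimation 8 (30 × 30 nodes) used for the
benchmark runs in this repository to keep dense 900 × 900 operators.

The operator's conditioning worsens as `z0` grows (neighboring rows become
more similar); at the reference height the 1-D operator has a condition
number of order 10², which is mild — the hard regimes in the benchmarks
come from noise, not from conditioning alone.

## Synthetic sources

The benchmark source is a spatial snapshot of a propagating action
potential: baseline 0 mV, plateau amplitude 100 mV, a steep depolarization
wavefront near −0.5 cm (edge width 0.02 cm) and a gradual repolarization
edge that returns to baseline at about +0.5 cm (edge center 0.2 cm, width
0.1 cm).  The template is a product of two Gaussian-CDF sigmoids; the
Gaussian CDF is used rather than the logistic because its tails decay fast
enough that the plateau reaches the nominal amplitude within 0.05 mV while
the profile stays C^∞.  With these defaults the 1-D source has
mean |v_m| = 23.3 mV, which is also the error of the degenerate
all-zero estimate — the floor that every method falls back to when noise
destroys the operator (see below).

In 2-D the `radial` mode is a depolarized disc: rim at radius 0.5 cm
carrying the repolarization-edge profile, plateau inside, baseline outside
(mean |v_m| = 9.1 mV); a `separable` product-of-templates mode is also
provided.  A `delta_source` places a point source on the nearest grid node
(ties to the lower index) for the ill-conditioning demonstration.

Only one spatial snapshot is modelled — no temporal propagation, no ionic
dynamics, and no sources or sinks at the tissue boundary.  Real
electrograms add far-field activity, fractionation, electrode geometry and
baseline drift that these templates do not emulate, so passing benchmarks
here demonstrate correctness of the machinery under the model's own
assumptions, not clinical performance.

## Noise model

Observation noise ("SNR", dB): i.i.d. zero-mean Gaussian with variance
`mean(v_e²)·10^(−SNR/10)`.

Transfer noise ("HNR", dB) is defined on matrix entries:
`10·log10(meansq(H)/meansq(perturbation))`.  The default `generator` mode
draws an even (mirror-symmetric) noise sample on the signed-offset impulse
response and rebuilds the matrix, so Toeplitz/BTTB structure *and* exact
symmetry survive; the realized perturbation is rescaled so the matrix-level
ratio matches the request exactly.  A `symmetrize` mode
(`H + (E + Eᵀ)/2`) keeps only `H = Hᵀ` and is retained as an alternative.

## Classical inverse solvers

With `R` the identity (order 0) or banded first/second difference stencils
(rows (−1, 1) and (−1, 2, −1); stacked per axis in 2-D):

* **Tikhonov** (`zot`/`fot`/`sot`): `v̂ = (HᵀH + γ²RᵀR)⁻¹Hᵀv_e`, solved by
  Cholesky factorization, never explicit inversion.
* **Modified TSVD** (`ztsvd`/`ftsvd`/`stsvd`): rank-`k` pseudoinverse
  solution; for derivative penalties the component in the discarded
  right-singular subspace `V0` is chosen to minimize `‖Rv‖`
  (`x_k − V0 (R V0)⁺ R x_k`).  The SVD is computed once per operator and
  cached.
* **Total variation** (`ftv`/`stv`): `½‖v_e − Hv‖² + γ‖Rv‖₁` by ADMM on
  the splitting `z = Rv`, with residual balancing of the penalty parameter,
  relative (Boyd-style) stopping at tolerance 1e-8 by default and a 5000
  iteration budget; non-convergence raises an error carrying the last
  iterate, and scans along a γ path warm-start each solve from the previous
  one.  The data term is squared — the standard TV objective — which is a
  deliberate choice where an unsquared reading would also have been
  possible.  The ℓ1 norm is taken over all stacked difference rows
  (anisotropic TV in 2-D).

## DSM–SVR

The dual-signal-model solver fits a ν-SVR to the sensor samples with a
*precomputed* kernel equal to the system's own impulse response, so the
dual expansion `v̂_e = Kβ + b` is the discrete forward convolution and the
dual coefficients `β_i = α_i − α_i*` are read off as the source estimate
(divided by the quadrature measure so units match `v_m`; the rescale is a
flag).  No matrix is ever inverted in this module — fits use libsvm's SMO
or projected gradient — which is the structural property behind the
method's robustness to operator errors.

Kernel.  `laplacian_distance_kernel` implements the analytic form: the
impulse-response profile evaluated at the **L1** inter-point distance.  The
end-to-end solver instead samples the kernel from the transfer operator
itself (`K = H / Δ^d`): for a clean 1-D operator the two coincide exactly,
and when the operator carries HNR noise this is what makes the noise reach
the method at all.  In 2-D the operator sample is the Euclidean-radius
profile; it is preferred over the L1 form because it keeps the dual
expansion identical to the forward model.

Convexity.  The raw kernel is the Laplacian of a positive-definite
potential and its spectrum is (numerically) entirely negative, so it is
not a Mercer kernel as-is.  `psd_correct` flips the global sign when the
spectrum is predominantly negative (recorded; the flip is compensated when
the estimate is read off), clips residual negative eigenvalues and adds an
optional diagonal loading `γ_dl` — the method's numerical regularization
parameter, tuned jointly with ν and C.

Bias modes.  With a free bias (`b_mode="kkt"`, the default contract) the
dual carries the equality constraint Σβ = 0: the coefficient vector can
only represent zero-mean sources, and the estimate saturates at the floor
mean|v_m| no matter how clean the data.  Because the reference experiments
require recovering a source with a large spatial mean — and because the
method's own free-parameter list includes `b` — the solver also supports a
fixed bias (`b_mode=<number>`): the equality constraint disappears and the
dual becomes a box- plus ℓ1-ball-constrained QP

    min ½βᵀKβ − βᵀ(y − b·1)  s.t.  |β_i| ≤ C/N,  Σ|β_i| ≤ C·ν,

solved by FISTA with adaptive restart and an exact projection onto the
constraint intersection (soft-threshold with clipping, threshold by
bisection).  All benchmarks use `b = 0`, appropriate for synthetic
electrograms with no offset.  The KKT route (libsvm) solves an exactly
equivalent normalized problem (kernel, targets and C rescaled jointly) so
its stopping tolerance acts on an O(1) problem; the ν-properties (margin
errors ≤ νN ≤ support vectors) and the Σβ = 0 constraint are asserted in
the tests for that mode.

## Free-parameter selection

* **L-curve**: per candidate, (log residual, log seminorm); both axes are
  min–max normalized, then the corner is the interior vertex with the
  sharpest angle to the curve endpoints (triangle method), restricted to
  the convex side of the chord.  One special case is handled explicitly:
  when the final segment carries most of the residual range at nearly
  constant seminorm — the shape of a truncated-SVD curve in which *only*
  full truncation fits the data — the corner is the final candidate itself,
  which no interior-vertex rule can select.  Degenerate (collinear) curves
  fall back to the median candidate with a warning.
* **Leave-one-out** (observation space): refit without sensor `i`, predict
  it through its row of `H` (classical) or its kernel row (DSM–SVR),
  average absolute errors.  A `folds` cap scores a seeded random subset of
  sensors on large problems; for the DSM–SVR the subset is drawn with
  probability proportional to `|v_e|`, because on a field with a small
  active area uniformly sampled folds mostly score quiet sensors, which
  the degenerate all-zero model predicts perfectly.  Two further
  structural corrections: the TSVD
  truncation is clamped to the fold's rank, and for the DSM–SVR the dual
  coefficient co-located with the held-out sensor (whose self-term
  `h(0)β_i` dominates the prediction) is interpolated from its grid
  neighbors — without it, leave-one-out always prefers the all-zero model.
* **Shrinking grid search**: lo/mid/hi per parameter (midpoint on a linear
  or log scale), all 3^p combinations scored, bounds re-centered and shrunk
  (factor 0.5) around the best point, until the intervals collapse below
  1e-3 of their initial width or 10 iterations.  Objective failures score
  +∞ and the search continues.  DSM–SVR tuning searches (ν linear,
  γ_dl log, C log); the γ_dl range is capped at 1e-2 of the kernel scale —
  larger loadings turn the fit into a nearest-neighbor interpolator of the
  smooth electrogram, which games the leave-one-out score while recovering
  nothing.

Default tuner assignment in the benchmarks, chosen from observed behavior
that also matches the reference study's own tables: under transfer noise
all classical methods use leave-one-out (the L-curve corner is unstable
there); under observation noise TSVD methods use the L-curve, because
their leave-one-out score cannot see the full-truncation optimum — a
leave-one-out-tuned TSVD sits at the zero-estimate floor at every SNR,
which is precisely the behavior the reference study reports for that
combination.

## Benchmarks and problem sizes

The error metric is the mean absolute error (MAE, mV) between estimated
and true transmembrane potentials.  Protocols:

* classical methods are re-tuned per noise realization for the headline
  HNR = 0 dB cell (20 realizations), and tuned once per cell on a dedicated
  realization for the matched-dB SNR/HNR comparison grid;
* DSM–SVR is grid-tuned once per noise level (subsampled leave-one-out,
  8–10 folds) and the parameters reused across realizations;
* the 2-D benchmark runs at decimation 8 (30 × 30 nodes) with FTV re-tuned
  per realization by L-curve and DSM–SVR grid-tuned once.

These sizes are the package's default study conditions; every knob
(seeds, folds, decimation, repetition counts) is an explicit argument.

Characteristic behaviors these benchmarks reproduce: tuned classical MAE
under worst-case transfer noise plateaus at the 23–25 mV floor set by the
source's spatial mean; the MAE-vs-HNR curve is dome-like (mid-range levels
are *worse* than 0 dB, because tuners lock onto plausible-looking but wrong
operators) while MAE-vs-SNR decays to negligible past 30 dB; transfer
noise at matched dB hurts classical methods more than observation noise;
and DSM–SVR stays at or below the floor across the low-HNR range,
beating the classical average there.

## Numerical choices and degenerate inputs

Linear systems are solved by factorization; SVDs are cached per operator.
Tie-breaks: delta sources snap to the lower node index; the L-curve
fallback is the median candidate.  `z0 ≤ 0`, empty grids (< 2 nodes per
axis after decimation), out-of-range truncations, ν outside (0, 1) and
non-symmetric kernels all raise typed exceptions.  An all-zero signal has
no defined SNR and is rejected.  Noise injection is deterministic given a
seed; benchmark cell seeds are derived from a base seed by fixed integer
mixing, kept below 2³¹.

## Known limitations

Flat tissue and sensor planes at a single constant height; no electrode
geometry, torso inhomogeneity or curvature; one temporal snapshot; dense
operators (the 2-D model at decimation 1 would need ~25 GB and is out of
scope — decimation ≥ 2 is assumed); the modified-TSVD solution family is
erratic under tuning on well-conditioned operators (only full truncation
fits), which mirrors the reference study's own tables rather than a defect
of the implementation; and the fixed-bias DSM–SVR mode, while convex and
deterministic, is an interpretation forced by the requirement to recover
sources with nonzero spatial mean under a dual equality constraint.
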