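# Methods

## Model

Two coupled fields on a periodic square lattice describe one crawling
cell: the phase field φ (cell shape; membrane at φ = 0.5) and the
polarity component c (an effective concentration lumping front markers
such as activated Ras, PI3K and PIP₃ that promote protrusion), driven
by a per-site Ornstein–Uhlenbeck noise ξ confined to the cortex by the
coupling φ(1−φ). The equations are given in the README. The model's
assumptions, in brief: overdamped membrane dynamics with uniform
substrate friction τ; a soft global area constraint instead of volume
mechanics; generic cubic bistability for c rather than a specific
signaling network; no advection of c by the moving boundary (transport
is diffusive only); and noise that is white in space — it represents
unresolved cortical fluctuations, not discrete pseudopod-triggering
events.

### Parameters

| name | default | units | meaning |
|------|---------|-------|---------|
| τ | 2.0 | pN·s·µm⁻² | membrane time scale (friction) |
| γ | 2.0 | pN | surface tension |
| ε | 0.75 | µm | interface width |
| β | 22.2 | pN·µm⁻³ | area-constraint strength |
| A₀ | 113 | µm² | target cell area |
| α | 3 | pN·µm⁻¹ | active tension per unit c |
| k_a | 2–5 (default 3) | s⁻¹ | bistable reaction rate; the polarity knob |
| δ₀ | 0.5 | — | base bistability threshold |
| C₀ | 28 | µm² | target total amount of c (quarter of the cell) |
| M | 0.045 | µm⁻² | feedback strength on δ |
| ρ | 0.1 | s⁻¹ | degradation rate of c |
| D | 0.5 | µm²/s | diffusivity of c |
| σ | 0.15 | s⁻² | white-noise intensity |
| k_η | 0.1 | s⁻¹ | OU relaxation rate (correlation time 10 s) |

Grid and time step: dx = 0.15 µm, dt = 0.002 s on a 200×200 (30 µm) box.
The explicit scheme requires D·dt/dx² and (γ/τ)·dt/dx² below 0.25; the
defaults give 0.044 and 0.089.

c is treated as dimensionless (the active tension α carries the force
units); C₀ is an area coverage, so a saturated patch (c ≈ 1) covers
about C₀ µm².

## Numerics

* Five-point Laplacian, central-difference gradients, periodic wrap.
* The masked diffusion (1/φ)∇·(φD∇c) uses the conservative flux form
  with arithmetic face means of φ, a regularization floor
  φ_floor = 10⁻³ in the division, and exact zero outside the cell
  (φ below the floor on the cell and all faces). The flux form makes
  the no-flux membrane condition automatic; the floor confines the
  only conservation leak to the sub-floor skirt (measured ≲1% over
  2 s in an adversarial fixture, <10⁻⁶ with a 10⁻⁹ floor).
* Explicit forward Euler in time for φ and c; Euler–Maruyama for ξ.
  Update order per step: threshold δ from the pre-update fields → ξ →
  c (using the new ξ, pre-update φ) → φ (using the pre-update c). The
  O(dt) ordering error is far below the noise floor.
* The spatial delta function in the noise variance is discretized as
  1/dx² per cell, giving per-cell increments of std √(2σ²dt/dx²) and a
  stationary variance σ²/(k_η dx²) = 10 at the default dx. The
  absolute noise amplitude is therefore anchored to dx = 0.15 µm;
  coarser test grids change the effective forcing.
* No clipping of φ or c: the double well restores φ, the cubic
  restores c, and excursions beyond φ ∈ [−0.05, 1.05] are treated as
  numerical failure, not as states to repair silently.
* Initialization: φ is the equilibrium disk profile
  ½(1 − tanh(3(r−R)/ε)) with R = √(A₀/π); ξ is drawn from its
  stationary distribution. By default c starts as a seeded quarter-disk
  patch of active state, which puts the budget at its balance point
  (δ ≈ δ₀) from the start. The alternative c ≡ 0 start is available
  but puts δ(0) = −0.76 and triggers a violent global activation burst
  while the feedback catches up; at the default force scale this
  transient can transiently stretch the cell across the box for some
  seeds.
* Recentering: whenever the φ-weighted centroid strays more than 2 µm
  from the box centre, all fields are rolled by the integer pixel
  displacement and the offset accumulated, so unwrapped trajectories
  are exact to machine precision. If the membrane ever comes within 3ε
  of the box edge after recentering the run aborts with an error
  rather than silently wrapping.
* Production stepping uses a fused numba kernel that updates only the
  interface band (φ within (10⁻⁶, 1−10⁻⁶), dilated by 3 px — φ, c and
  ξ) and the saturated interior (c only), with membership refreshed
  every 100 steps; everything else is at a fixed point to below the
  band threshold. Partial sums over frozen cells keep the global
  integrals exact. The kernel reproduces the reference
  (module-operator) integrator to ~10⁻⁶ µm in the centre of mass over
  60 s deterministic runs; with noise on, the two paths consume random
  numbers in different orders and realize different, equally
  distributed trajectories. Frozen-skirt ξ values are stationary
  samples, so the forcing that actually enters the c equation is
  distributionally unchanged by the banding.

## Analysis pipeline

* Contours: marching squares at φ = 0.5 (sub-pixel), counterclockwise,
  resampled to 400 equidistant nodes. Node correspondence between
  frames is the least-squares cyclic shift; kymograph chaining uses
  the parabolically refined fractional shift with circular resampling,
  which keeps cumulative material slippage bounded by a fraction of a
  node spacing (integer-only chaining random-walks by ~0.3√n spacings
  through start-point quantization). Limitation: least-squares
  matching minimizes displacement, so for nearly circular shapes rigid
  rotation is absorbed as slippage rather than tracked — material
  tracking under rotation requires pronounced boundary features
  (relative modulation × mode number ≳ 1).
* Local displacement is the node displacement projected on the outward
  normal of the previous frame (positive = protrusion). Centroid
  distance uses the shoelace polygon centroid. Curvature is computed
  spectrally after truncating the closed curve to its first N/25
  Fourier modes; this suppresses pixelation noise that otherwise
  swamps the second derivative on flat segments (a Gaussian smoother
  wide enough to fix the flat segments biases the high-curvature poles
  by >5%). Boundary concentration is bilinear interpolation of c at
  the nodes.
* Motility statistics at 1 Hz: instantaneous speed from consecutive
  positions with no smoothing; speed ACF (mean-subtracted, normalized,
  FFT-based) with τ_a the linearly interpolated first crossing of 0.5;
  time-averaged MSD with lags capped at a quarter of the trajectory;
  unweighted nonlinear least squares of Fürth's formula with initial
  guesses from the diffusive asymptote, positivity bounds, and errors
  on non-convergence or boundary-pinned parameters.
* The persistent-random-walk generator is a 2D OU velocity process
  with per-component variance D_a/τ_P, integrated by Euler–Maruyama at
  20 substeps per 1 s sample (discretization error ≲0.2% in the
  displacement variance); its ensemble MSD is Fürth's formula exactly,
  which makes it the known-truth control for the fitting pipeline.
  Single-trajectory Fürth fits scatter with ~14% relative sd in D_a
  even at 10⁴ s, so recovery is validated at ensemble level.

## What the synthetic fixtures do and do not emulate

The shape fixtures (tanh disks, ellipses, bumpy disks; translating,
expanding, rotating sequences) have exact closed-form geometry and
exercise extraction, tracking, curvature and sampling. The PRW
fixtures have exact MSD and Gaussian velocities and exercise the
trajectory statistics. Neither reproduces the full model's
morphodynamics (finite interface width interacting with noise,
protrusion-driven shape irregularity), so passing fixture tests
validates the measurement pipeline, not the biology; the run-ensemble
tests close that gap at the phenomenological level.

## Problem sizes used by the tests and the acceptance script

Run-ensemble statistics use 400 s runs (100 s burn-in, 1 Hz snapshots)
with two to three seeds per k_a ∈ {2, 3, 4, 5} on the standard 30 µm
box — long enough that area, budget, speed and τ_a estimates are
stable to a few percent, while a full ensemble stays in the
ten-minute range on one CPU. Persistence fits would prefer multi-
thousand-second runs; at 400 s they are reported with that caveat.

## Known limitations

* **Speed scale.** A steadily polarized cell obeys the force balance
  v ≈ α·c_mem/(2τ) at the membrane patch, and the bistable kinetics pin
  the active branch at c ≈ 0.86–0.91 for k_a ∈ [2, 5] (roots of
  k_a(1−c)(c−δ) = ρ at the feedback-parked δ). The default parameter
  table therefore yields 0.65–0.88 µm/s across k_a = 2–5 — several-fold
  faster than typical slow amoeboid crawling (0.09–0.19 µm/s), although
  the ordering and near-linearity of speed in k_a, the area and budget
  control, and the speed-correlation time all behave as expected. The
  noise amplitude is not the lever: the patch state is insensitive to
  it across a 60× amplitude range (white-in-space noise carries almost
  no power at the patch scale). Reproducing slow cells with this model
  structure requires a smaller effective active tension (α·c_mem/2τ of
  order 0.1 µm/s).
* Consequences of that scale: trajectories are nearly ballistic on
  desk-scale runs, so Fürth fits return very large D_a and τ_P; the
  velocity-component distribution is platykurtic (bimodal from
  persistence) rather than leptokurtic; and the polarity patch is
  persistent even at k_a = 2, so the slow-cell "hopping" regime does
  not appear.
* At high protrusion speeds the patch left behind the advancing front
  can sustain a long retracting tail (the area constraint re-inflates
  thin filaments); the box-margin guard converts the rare escape of
  such a tail into a hard error.
* ξ is anchored to the lattice spacing (see above), so results are
  grid-consistent only at fixed dx.
* Single cell only; no chemotaxis, confinement, or cell–cell
  interactions. The linear-in-time k_a schedule is exposed as a config
  hook (`k_a_ramp`) but untested beyond smoke level.
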