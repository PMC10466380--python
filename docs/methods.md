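# Methods

## Forward model

The coherent SANS cross section of M scattering centres is evaluated with
the Debye equation, dσ(q)/dΩ = (1/M) Σᵢⱼ bᵢbⱼ sinc(q·rᵢⱼ), including the
i = j self terms (sinc(0) = 1).  The 1/M prefactor is a convention: it
cancels under the q₀ normalization and only affects raw values.  The
removable singularity of sinc is guarded by the series 1 − x²/6 for
x < 10⁻⁴ (truncation error < 10⁻¹⁷).  Distances are open-boundary by
default because the intended scatterer selection is a compact solute; a
minimum-image option covers whole-box studies with orthorhombic boxes.
Two evaluation paths exist — an explicit O(M²) double loop kept as the
reference, and a vectorized condensed-distance path chunked to bound
memory — and a property test holds them to 10⁻¹⁰ relative agreement.

Reported intensities are normalized by the value at the lowest selected
scattering vector q₀ and, when an experimental curve is supplied, anchored
to I_exp(q₀).  When smearing is active the *smeared* intensity is
normalized by its own q₀ value, so the anchor I(q₀) = I_exp(q₀) holds
exactly in every mode; without smearing this reduces to dividing by
dσ(q₀)/dΩ.  Trajectory spectra average the per-frame scaled curves by
default (averaging raw cross sections before scaling is available).

Known limitation: a finite collection of M point scatterers carries an
irreducible incoherent contribution of order 1/M of the forward intensity
(the self terms).  For a 5000-site uniform ball this floor is ~2.6 % of
the continuum sphere form factor at its first-minimum approach (qR = 4)
and placement noise adds several per cent more there, while for qR ≲ 3.5
the scaled curve tracks the analytic form factor to better than 2 %.
Validation tests therefore compare against the continuum limit away from
form-factor minima.

## Resolution smearing

The per-point resolution kernel is the standard pinhole form
R(⟨q⟩, q) = (q/σ₁²)·exp(−(q²+⟨q⟩²)/(2σ₁²))·I₀(q⟨q⟩/σ₁²).  It is evaluated
with the exponentially scaled Bessel function i0e, rewriting the product
as exp(−(q−⟨q⟩)²/(2σ₁²))·i0e(q⟨q⟩/σ₁²), which is overflow-free even at
q⟨q⟩/σ₁² ~ 10⁶.  Smearing integrates the kernel over N evenly spaced
nodes on [⟨q⟩ − 3σ₁, ⟨q⟩ + 3σ₁], clamped below at q = 10⁻⁶ Å⁻¹.  The
truncated window loses ≈ 0.3 % of the kernel mass, so weights are
renormalized to unit sum — a flat spectrum then smears to itself, which
protects the q₀ anchor.  The renormalization choice is recorded in output
headers.  N = 21 is the processing default; N ≈ 10 is already converged
to well under 1 % on smooth spectra (the measured smallest converged N on
the reference synthetic spectrum is 3), and N = 1 or σ₁ = 0 degenerate to
no smearing.

Because quadrature nodes fall between the selected ⟨q⟩ᵢ, the cross
section is interpolated by a natural cubic spline through the knots, with
linear extrapolation beyond the span (end-point windows can protrude).
The spline is linear in its knot values, so smearing is a fixed matrix C
applied to knot intensities; C is built once by smearing each cardinal
basis spline and, by the chain rule, also maps knot gradients to smeared
gradients.  This keeps the per-update cost of a biased run at one Debye
evaluation (values + gradients) per knot.

## Metainference bias

With a Gaussian noise model the bias energy for N_d points and N_r
replicas is E = k_BT Σ_r Σᵢ [(s·Ī_calc,ᵢ + I₀ − I_exp,ᵢ)²/(2σ_{r,i}²) +
½ln(2πσ_{r,i}²) − ln p(σ_{r,i})], the replica-averaged calculated
intensity entering every residual; the structural prior is the physical
force field and lives in the simulator.  Design choices where the
convention was open: the scale multiplies the calculated intensity
(s·calc + I₀ − I_exp); the σ-prior defaults to flat on
[SIGMA_MIN, SIGMA_MAX] (its −ln p is then constant and drops from MC
ratios) with Jeffreys 1/σ behind a flag; a single replica is the default.

Per-point uncertainty bounds follow the 8 %/25 %/4 % heuristic:
SIGMA_MAX = 0.08·I_exp, SIGMA_MIN = 0.25·SIGMA_MAX,
DSIGMA = 0.04·SIGMA_MAX, one value per q, which balances biasing forces
across the spectrum.  Each MC sweep proposes uniform moves of every
σ_{r,i} (point-wise independent at fixed residuals, so accepted
vectorized), then s, then I₀; proposals outside bounds are rejected
outright; everything is deterministic under a seeded generator.
σ acceptance counters count only accepted moves that changed the value.

Forces are −∂E/∂x propagated analytically: dE/dI through the residuals,
the Jacobian of the scaled spectrum with respect to raw knot values
(quotient rule through the q₀ normalization), the smearing matrix, and
the analytic Debye gradients.  They sum to zero by translation invariance
and match central finite differences of the total energy to 10⁻⁵
relative.

## Toy simulator and synthetic structures

The Langevin engine uses BAOAB splitting (accurate configurational
sampling at moderate dt); friction 0 reduces it to velocity Verlet.
Internal units are Å, fs, Da (k_B = 8.31446×10⁻⁷ Da Å²fs⁻²K⁻¹).  The pair
potential — soft-core repulsion A(1 − r/r_c)² plus a Gaussian well
−B·exp(−(r−r₀)²/w²) — is the simplest form giving cohesive, deformable
droplets; it is deliberately not a production force field.  Synthetic
structures are uniform balls (rejection sampling) and two-ball dumbbells.

The bias demonstration uses a 2×30-site dumbbell (lobe radius 8 Å,
separation 28 Å), a volume-equivalent single ball as target, dt = 8 fs,
T = 300 K, friction 2 ps⁻¹, bias refresh every 10 steps, 3000 steps, and
bias prefactor k_BT_bias = 10·k_B·300 K.  The prefactor was set so the
bias force is comparable to the thermal force scale — the stability
balance the σ heuristic aims for; much larger values catapult the cluster
instead of steering it.  What passing shows: the restraint reliably pulls
a mismatched structure toward the target spectrum against thermal noise.
What it does not show: quantitative micelle thermodynamics, solvent
effects, or force-field realism — the generator emulates geometry and
contrast only, with no chemistry in the labels and no excluded-volume or
solvent scattering.

## Shape and aggregation analysis

R_g and the principal moments of inertia are computed about the centre of
mass with true masses when present (unit masses otherwise); moments are
reported in Da·Å², with a helper for the conventional 10⁻⁴ Da nm² unit.
Asphericity α = (2I₁ − I₂ − I₃)/(I₁ + I₂ + I₃) is 0 for a sphere and 0.5
for an ideal rod or disc.  Aggregates are single-linkage connected
components of the graph with edges where the (minimum-image) distance is
at most the cutoff (default 10 Å); when molecule identities are supplied,
a molecule joins a cluster as soon as any selected site does, clusters
sharing a molecule merge, and sizes are counted in molecules.  Whether α
should be averaged per frame or computed from averaged moments is
genuinely open; per-frame is the default and both are accessible.

## Input preparation

q points are chosen as the experimental points nearest to npoints evenly
spaced targets (linear by default, log-spaced optionally), deduplicated,
with user-supplied extra q mapped to their nearest grid members — selected
q are always members of the experimental grid.  The emitted configuration
block reuses the QVALUE/EXPINT/SIGMARES/SIGMA_MIN/SIGMA_MAX/DSIGMA
keyword vocabulary for traceability and round-trips exactly
(emit → parse → emit is byte-identical).

## Problem sizes and numerical defaults

Test-suite simulations are sized for a laptop-class single core:
equipartition uses 256 independent harmonic particles × 4000 steps, the
NVE drift check 10 sites × 10⁴ steps, the sphere-limit validation 4000
sites, the bias-efficacy comparison 5 seeds × 2 runs × 3000 steps, and
scale recovery 10⁴ MC sweeps.  Tolerances: optimized-vs-brute Debye
10⁻¹⁰ relative; gradient and force finite-difference checks 10⁻⁵–10⁻⁶
relative; spline-vs-dense Debye 1 %; equipartition 5 %.
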