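# sansmi

Small-angle neutron scattering (SANS) forward modelling and Bayesian
metainference biasing for molecular simulations, aimed at soft-matter
systems such as surfactant micelles studied with coarse-grained models.

SANS reports the orientationally averaged coherent cross section of a
solute.  For M scattering centres with coherent scattering lengths
*b<sub>i</sub>* the package evaluates the Debye equation

    dσ(q)/dΩ = (1/M) Σᵢ Σⱼ bᵢ bⱼ sin(q rᵢⱼ) / (q rᵢⱼ)

normalized by its value at the lowest scattering vector q₀ and scaled to
the experimental intensity there.  When a per-point resolution width
σ₁(q) is available, intensities are smeared with the pinhole-instrument
kernel

    R(⟨q⟩, q) = (q/σ₁²) · exp(−(q² + ⟨q⟩²)/(2σ₁²)) · I₀(q⟨q⟩/σ₁²)

(I₀ the zeroth-order modified Bessel function) by an N-point quadrature on
[⟨q⟩ − 3σ₁, ⟨q⟩ + 3σ₁], with the cross section interpolated by a cubic
spline so it is only ever evaluated at the user-selected ⟨q⟩ᵢ.

On top of the forward model sits a metainference restraint: a
Gaussian-noise bias energy

    E = k_BT Σ_r Σ_i [ (s·I_calc(⟨q⟩ᵢ) + I₀ − I_exp(⟨q⟩ᵢ))² / (2σ_{r,i}²)
                       + ½ ln(2πσ_{r,i}²) − ln p(σ_{r,i}) ]

whose per-point uncertainties σ (and optionally scale s and offset I₀) are
Metropolis-sampled within bounds, and whose forces — propagated through the
q₀ scaling, the smearing matrix and the analytic Debye gradients — can
drive a simulation toward an experimental curve.  A minimal BAOAB Langevin
engine with a soft pair potential demonstrates this end-to-end: a two-lobe
bead cluster biased toward the spectrum of a single compact ball merges
its lobes, the toy analogue of experiment-driven micelle reshaping.

Also included: Sears atomic scattering lengths and coarse-grained bead
sums with H↔D contrast swaps (SCATLEN file dialect), experimental-curve
q-point selection with the SIGMA_MAX = 8 %·I_exp heuristic, and micelle
shape/aggregation analysis (R_g, principal moments of inertia, asphericity
α = (2I₁ − I₂ − I₃)/(I₁ + I₂ + I₃), single-linkage aggregates under a
maximum-distance criterion).

## Worked example

`examples/04_metainference_bias.py` builds a dumbbell of 2×30 beads,
takes the spectrum of a volume-equivalent single ball as the experimental
target and runs 3000 Langevin steps with and without the bias:

```
initial chi^2:    146.0
final chi^2 (unbiased):    282.5
final chi^2 (biased ):     23.6
```

χ² = Σ (I_calc − I_exp)²/σ² measures spectrum mismatch at the selected q
points with σ from the 8 % heuristic; the biased run reshapes the cluster
until its spectrum matches the target an order of magnitude better, while
the unbiased control drifts.  The other examples cover the sphere-limit
validation of the Debye sum, bead scattering lengths with deuteration,
quadrature convergence of the resolution smearing, and shape/aggregate
analysis — each prints its numbers with a line on what they mean.

A `sansmi` console command exposes the same pipeline for shell use
(`scatlen`, `prepare`, `spectrum`, `analyze`, `demo-mi`); see
`sansmi --help`.

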