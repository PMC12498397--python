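# Methods

## The model

The package analyses ligand photosubstitution on a triplet
hypersurface through two collective variables: s₁ = d(Ru–S), the bond
to the leaving thioether, and s₂ = d(Ru–O_min), the distance to the
nearest water oxygen. The electronic-structure engine that would
supply forces on a real complex is out of scope; in its place the
`potentials` module provides six analytic *archetype* surfaces that
realize the canonical ligand-exchange topologies:

| archetype | defining feature on the (s₁, s₂) surface |
| --- | --- |
| dissociative | ³MC minimum, then a pentacoordinate minimum (both CVs > 4.0 Å), then ³P |
| interchange-dissociative | single barrier; s₁ crosses 4.0 Å while s₂ is still large |
| interchange | near-flat diagonal channel (barrier < k_BT) |
| interchange-associative | single barrier; s₂ crosses 4.0 Å while s₁ is still short |
| associative | heptacoordinate minimum (both CVs < 4.0 Å) before ³P |
| inactive | a single ³MLCT basin, uphill everywhere else |

Each surface is a *path valley*: a polyline reaction path in the CV
plane, a free-energy profile along its normalized arclength (sums of
Gaussians, the first well anchored at the path start so the ³MLCT
anchor (2.3, 4.5) Å is an exact minimum), harmonic confinement
transverse to the path (k⊥ = 30 kJ/mol/Å², thermal width ≈ 0.3 Å at
300 K) and soft walls outside [1.8, 6.5] Å. This construction pins
minima, barriers and cutoff-crossing orders exactly, so the archetypes
serve as ground truth for the estimators and the classifier. The
declared minima are refined numerically at construction (L-BFGS) and
verified to be true local minima in the tests.

All minima relevant to the taxonomy are 6–14 kJ/mol deep and ≥ 0.4 Å
wide — comfortably above both thermal energy and the reconstruction
resolution discussed below.

## Sampling

CVs are propagated directly by a BAOAB-split Langevin integrator
(temperature 300 K, friction 10 ps⁻¹, timestep 2 fs, fictitious mass
1 amu per CV). The friction is a free parameter of the toy engine —
only configurational statistics matter — and the integrator's
configurational accuracy and free-particle diffusion are verified
against closed forms in the tests. Sampling is bitwise-reproducible
for a fixed seed.

The enhanced-sampling protocol is the package default everywhere: 20
umbrella windows along s₁ centered 2.50–5.35 Å in 0.15 Å steps with
k = 350 kJ/mol/Å² (interpreted per the usual convention for a distance
restraint), 5 ps equilibration plus 40 ps production per window, and a
well-tempered metadynamics bias along s₂ with initial height
2.0 kJ/mol, width σ_G = 0.1 Å, deposition every 50 steps and bias
factor γ = 15. Hills are reset between windows; the persisted variant
is available behind `reset_hills_per_window=False` but measured worse
at this scale (the accumulated bias mismatches later windows'
conditional free energy along s₂ and inflates reweighting variance).

## Free-energy reconstruction

Per-sample weights w ∝ exp(+β V̄(s₂)) remove the metadynamics bias,
where V̄ is the deposited bias *time-averaged over the late half of
the deposition schedule* (equivalently: each hill's height scaled by
the fraction of late deposit times at which it already existed). The
average suppresses both the build-up transient and the ripple the
instantaneous hill sum carries at the kernel width; on a single-window
test it roughly halves the reconstruction error relative to the final
instantaneous bias. A c(t)-normalized time-dependent estimator and a
formulation folding the bias into the WHAM window potentials were both
evaluated and gave no further improvement.

Weighted histograms on a 60 × 60 grid over [2, 6] Å × [2, 6] Å then
enter standard self-consistent WHAM over the umbrella windows
(tolerance 10⁻⁶ kJ/mol on max |Δf_j|, max 10⁴ iterations; f₁ ≡ 0
gauge). Bins with fewer than 5 raw samples are masked; the surface is
gauge-fixed to min F = 0 over sampled bins. Degenerate cases reduce
correctly: a single unbiased window is Boltzmann inversion, and two
overlapping windows on a linear potential recover its slope (tested).

**Accuracy.** Against the analytic archetypes the reconstruction
achieves an RMSE of 0.4–0.95 k_BT over sampled bins at the default
protocol. The broad-plateau interchange-dissociative surface is the
hardest case: its error (≈ 0.9–1.1 k_BT depending on the random seed)
is dominated by per-window well-tempered convergence within 40 ps of
production — with γ = 15, k_BΔT ≈ 35 kJ/mol, so hill heights temper
only mildly over the relevant free-energy range and the deposited bias
retains kJ/mol-scale structure error. This is a property of the
protocol scale, not of the estimator: longer windows would reduce it.

## Classification

The photon-absorption (³MLCT) region is an axis-aligned ellipse —
per-CV mean ± 1.96σ from unbiased dynamics on a harmonic ground-state
surrogate centered at the bound geometry. The per-axis convention
follows from computing per-CV standard deviations; its joint coverage
of a 2D Gaussian is 1 − exp(−1.96²/2) ≈ 0.854, and the tests assert
that value, not 0.95.

Attack geometry: a sample is *cis* when the S–Ru–O_min angle is ≤ 90°
(ties to cis) and *trans* otherwise; attack percentages are taken over
samples with d(Ru–O_min) < 4.0 Å. On the 2D model surfaces the angle
is not defined, so the pipeline assigns it stochastically with a
per-archetype cis fraction mirroring the corresponding compound's
attack-percentage table row; the chelate dihedral likewise runs as an
independent Ornstein–Uhlenbeck process (exact discretization,
relaxation time 0.1 ps, per-archetype mean/sd).

Mechanism assignment works on the dominant pathway's surface:

1. All decisions are taken on a mask-aware Gaussian-smoothed copy of
   the grid (σ = 0.2 Å ≈ 2 × the metadynamics kernel width).
   Reconstruction noise is correlated at the kernel width and would
   otherwise masquerade as shallow minima or spurious barriers; the
   real features are several times broader and survive the blur.
2. Minima are found as strict 8-neighborhood minima with a minimax
   escape depth ≥ 3 kJ/mol, restricted to bins within 10 k_BT of the
   surface minimum (higher bins are thermally irrelevant and their
   F estimates unreliable).
3. Minima beyond the absorption region are labeled by geometry
   against the thresholds (interaction cutoff 4.0 Å, product bond
   2.5 Å with a 0.25 Å borderline margin); an optional per-bin spin
   field gates the ³MC label. A pentacoordinate minimum ⇒
   dissociative; heptacoordinate ⇒ associative (flagged borderline if
   it hugs the cutoff); no minima beyond the region on either surface
   ⇒ photoinactive.
4. Otherwise the verdict is interchange, sub-typed by which CV crosses
   the interaction cutoff first along the minimax ("watershed")
   minimum-energy path from the absorption region to the product
   basin; a path whose smoothed barrier is below k_BT stays plain
   interchange.

The minimax path minimizes the maximum F along 8-connected sampled
bins, with ties broken by the lowest integrated F (two-stage
Dijkstra); its minimax value is verified against exhaustive
level-threshold enumeration on small random grids.

## Descriptors and statistics

The signed chelate dihedral θ (angle between the normals of the
Ru–N_C–C_C and Ru–N_T–C_T planes; sign from a fixed triple-product
convention) is folded to [0°, 90°] by 90 − |90 − (|θ| mod 180)|,
making left and right bending equivalent. Planarity μ(θ) and rigidity
σ(θ) are the mean and population standard deviation of the folded
series (sample convention available).

Spearman ρ uses average ranks with an exact permutation p-value for
n ≤ 10 (all n! orderings, evaluated as one matrix product) and the
t-approximation above. The packaged compound tables give ρ = −0.40 /
−0.43 and R² = 0.01 for the quantum-yield-vs-barrier analyses under
the zero-assignment rule: the photoinactive complex's empty
quantum-yield cells enter as Φ = 0, the only reading consistent with
the reported coefficients. OLS confidence bands use
t·s·√(1/n + (x−x̄)²/Sxx) on n − 2 degrees of freedom; empirical
coverage of the 95% band is verified by simulation.

## What the synthetic data do and do not show

The generators emulate the *statistical structure* of biased
triplet-surface trajectories — two CVs under umbrella + metadynamics
bias on surfaces with the right topology, an OU dihedral with
prescribed moments, a smooth monotone spin surrogate anchored at the
³MLCT/³MC/³P signatures, and toy Cartesian frames that reproduce
requested CV tuples exactly. They do not emulate explicit solvent,
intersystem crossing, CV-coupled chelate motion (a coupling hook
exists but is off by default), or any electronic structure. Passing
tests therefore demonstrate that the estimators and classifiers are
correct and well-calibrated at realistic noise levels — not that any
particular real complex follows a given mechanism.

## Problem sizes and determinism

Default problem sizes, also used by the tests and the acceptance
script: 20 windows × (5 + 40) ps at 2 fs (22,500 steps/window,
samples kept every 2 steps), a 20 ps ground-state run for the
absorption region, 20,000-frame dihedral series, a 200,000-step 1D
run for the well-tempered convergence check, and the 60 × 60 grid
above. One archetype pipeline takes ≈ 75 s on one CPU; the six-
archetype suite ≈ 7–8 min. Every stochastic component draws from a
single seed via independent spawned streams; reruns are
byte-identical. Mechanism verdicts are stable across the seeds
examined; the flat-interchange barrier decision and the
interchange-dissociative recovery RMSE carry the least margin, as
discussed above.
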