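# Methods

## Model and assumptions

`pullpmf` analyses constant-velocity pulling experiments in which a harmonic
spring (stiffness *k*, kcal/mol/Å²) is dragged along a reaction coordinate at
speed *v* (Å/ps), so its scheduled position is λ(t) = λ₀ + v·t.  The external
work up to time *t* is

    W(0→t) = −k·v ∫₀ᵗ ( r(t′) − λ(t′) ) dt′ ,

with r the projection of the pulled group onto the pulling direction.  The
pipeline assumes the stiff-spring regime: profiles are indexed by the
scheduled coordinate λ(t) rather than the instantaneous r(t), and the
work-derived free energy is read directly as the PMF.  No deconvolution of
the finite spring width is applied — the estimate converges to the
spring-convolved free energy F(λ) = −k_BT ln ∫ exp(−[U(r) + k(r−λ)²/2]/k_BT) dr,
which is what `true_delta_g(..., spring=k)` returns as the matching ground
truth.  A deconvolution step could be layered on the returned profile; it is
a deliberate non-feature here, since at k = 12 kcal/mol/Å² and 310 K the
spring width √(k_BT/k) ≈ 0.23 Å is below the analysis grid spacing.

Free energies come from Jarzynski exponential averaging over replicates,
ΔG(λ) = −β⁻¹ ln⟨exp(−βW(λ))⟩.  The estimator is exact in expectation but
biased at finite replicate counts when the work spread exceeds a few k_BT;
the companion second-order cumulant estimator ΔG = ⟨W⟩ − β·Var(W)/2
(unbiased sample variance) agrees with it for Gaussian work distributions,
so their disagreement is used as an anharmonicity/sampling diagnostic.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| spring constant k | 12 | kcal/mol/Å² | stiff-spring pulling regime |
| temperature | 310 | K | physiological bath, k_BT = 0.616 kcal/mol |
| grid spacing | 0.125 (analysis), 0.1 (reference study) | Å | = v × trace output period |
| bootstrap resamples | 1000 | — | SE of the SE ≈ 2% at 1000 draws |
| smoothing window | 11 | points | ≈ 1.1–1.4 Å at the default spacings; wide enough to kill sampling ripple, narrower than any feature of interest |
| flatness tolerance (metastable) | 0.5 | kcal/mol/Å | below this slope a 1 Å drift changes ΔG by < k_BT |
| minimum flat width | 0.5 | Å | excludes single-point zero crossings of m(λ) |
| barrier prominence | 0.5 | kcal/mol | ≈ 0.8 k_BT, suppresses noise maxima |
| force-peak prominence | 50 pN (0.72 kcal/mol/Å) | — | same role on the force axis |
| H-bond / salt-bridge cutoff | 3.5 | Å | geometric distance criterion; no angular term (see below) |
| vdW switching | 8 → 10 | Å | cubic switch in r², zero beyond cutoff |
| pocket inclusion cutoff | 5.0 | Å | water oxygen within 5 Å of any pocket heavy atom |

All forces are carried internally in kcal/mol/Å and converted to pN
(× 69.4786) only at reporting boundaries.  k_B = 0.0019872041 kcal/mol/K.

## Synthetic data: what it emulates and what it does not

The Langevin module generates the inputs the pipeline needs at desk scale.
It integrates overdamped dynamics

    γ·dr = [ −U′(r) − k·(r − λ₀ − v·t) ]·dt + √(2 γ k_BT)·dW

by Euler–Maruyama on parametric 1-D landscapes (flat, harmonic,
double-Gaussian bump) whose ΔG between any two points is known in closed
form.  The reference scenario mirrors a peptide-dissociation pulling
protocol — 75 replicates, k = 12 kcal/mol/Å², T = 310 K — on a landscape
with bumps of 4 and 2.5 kcal/mol at 3 and 7 Å (width 0.5 Å) over a 10 Å
domain, friction γ = 5 kcal·ps/mol/Å².  The pulling velocity (0.005 Å/ps
over 2 ns per replicate) is faster, relative to the landscape, than the
velocities used in atomistic work, chosen so a full 75-replicate set
integrates in seconds while staying in the low-dissipation regime
(mean dissipated work ≈ 0.4 kcal/mol ≈ 0.7 k_BT); replicas are seeded by
`SeedSequence([master, replica_index])` so any replica is reproducible in
isolation.

What passing on this generator demonstrates: the work quadrature, the
λ-alignment, the exponential average, the bootstrap and the feature
annotation are correct, and the whole chain recovers a known free-energy
surface from noisy nonequilibrium traces.  What it does not demonstrate:
anything about force-field quality, solvent effects, multidimensional
reaction coordinates, replicate-to-replicate heterogeneity of real pulling
directions, or convergence of exponential averaging at the 10–100 k_BT work
spreads typical of atomistic dissociation, where the estimator is dominated
by rare low-work trajectories.  Equally, the toy frame sets script contact
distances and water placements directly — they validate the geometry and
bookkeeping of the contact/solvation analyses, not any structural model.

## Numerical choices

- **Quadrature.** Trapezoidal on the native (possibly non-uniform) time
  grid; second-order, matching typical SMD output periods.  Work curves are
  interpolated linearly onto the uniform λ grid, whose span is the
  intersection of all replicates so no extrapolation occurs; W is pinned to
  0 at λ₀.
- **Trace output period.** The simulator records every 1 ps by default.
  At the toy system's positional fluctuation amplitude (≈ 0.23 Å) a 20 ps
  sampling period would make the trapezoidal work sum itself a significant
  noise source (O(kcal/mol) at the trace end); at 1 ps, successive samples
  are already nearly decorrelated (relaxation time γ/k ≈ 0.4 ps) and the
  added quadrature noise is ≈ 0.02 kcal/mol.
- **Stabilised averaging.** exp(−βW) underflows near W ≈ 90 kcal/mol, so the
  exponential average is computed as a log-mean-exp shifted by the per-point
  minimum work.  ΔG is re-zeroed at the first grid point after estimation.
- **Error bars.** Replicate bootstrap (whole work curves resampled with
  replacement, preserving along-λ correlation), 1000 draws, seeded; the
  choice is recorded in the profile metadata.  Pointwise SD of the
  resampled profiles is reported as the standard error.
- **Derivatives and features.** Profiles are smoothed with a centred moving
  average (truncated at the ends, output length preserved); derivatives are
  central differences on the smoothed profile, one-sided at the ends.
  Smoothing damps the apparent height of features narrower than the window
  — reported barrier heights are those of the smoothed profile, while
  positions are unaffected for symmetric features.  Peak detection is
  prominence-based; endpoints are never peaks.  Metastable intervals
  touching the first or last grid point are discarded as the global
  bound/dissociated plateaus.  Simultaneous contact events are ordered by
  label.
- **Integrator step.** The stability condition dt·(k + max|U″|)/γ < 0.1 is
  enforced before any integration.  For the equilibrium (Boltzmann)
  validation the step is reduced to dt = 0.002 ps because Euler–Maruyama
  inflates the stationary variance of an Ornstein–Uhlenbeck process by
  ≈ k_tot·dt/(2γ); at 0.3% that bias is below what a χ² test at 10⁵ samples
  resolves, so the check measures the physics rather than the integrator.
- **Degenerate inputs.** Empty traces, non-monotonic times, atom-count
  mismatches, ambiguous selectors and missing LJ parameters raise typed
  errors naming the offending record; a topology without waters yields an
  all-zero solvation series with a warning rather than an error.

## Design choices in open territory

- **Hydrogen bonds and salt bridges** use a pure distance criterion
  (donor-side atom to acceptor heavy atom ≤ 3.5 Å) with no angular term.
  Angle-augmented definitions are common elsewhere, but the distance-only
  rule keeps the timeline analysis symmetric in the two atoms and matches
  the convention of the dissociation studies this pipeline targets.
  An optional dual-cutoff hysteresis (form ≤ 3.5 Å, rupture > 4.0 Å) can be
  enabled to suppress event chatter; it is off by default, and the per-frame
  `bound` series always reflects the single cutoff.
- **Binding-pocket occupancy** is operationalised as "water oxygen within a
  cutoff of any pocket heavy atom" (≤ convention, one count per molecule).
  A convex-hull pocket volume is a documented non-goal; the chosen
  definition is monotone in the cutoff and exactly testable against an
  all-pairs oracle.
- **Forces** logged in 3-D are reduced to their signed projection on the
  pulling direction by default; a magnitude convention is available as a
  reader flag for logs that store |F|.  A trace without a force column gets
  the spring force k·(λ(t) − r) reconstructed and flagged as such.
- **LJ parameters** come from the atom records or a per-atom-name table;
  force-field file parsing is out of scope — the correctness target is the
  pairwise summation, Lorentz–Berthelot combination and switching, verified
  against a brute-force double loop.

## Problem sizes

The shipped study and test suite use: 75 replicas × 2 ns (200k steps at
dt = 0.01 ps) for PMF recovery; 20 replicas per velocity over three pulling
decades (0.5/0.05/0.005 Å/ps) for the quasi-static trend; 400 replicas ×
250 samples (10⁵ total) for the equilibrium χ² check; 1000 seeded trials
for the calibration of the 2-SE force-tail test.  These sizes give
comfortably resolvable statistics for every assertion while the whole suite
runs in well under a minute.

## Known limitations

- The Jarzynski estimator's finite-sample bias is not corrected; at large
  work spreads (β·σ_W ≫ 1) the profile converges slowly from above and the
  bootstrap underestimates the systematic part of the error.
- The reaction coordinate is strictly 1-D; orthogonal relaxation enters only
  through the effective friction.
- PDB reading collapses altloc records to the highest-occupancy alternative
  and has no notion of periodic boundaries; distances are plain Euclidean,
  so trajectories must be unwrapped upstream.
- The moving-average smoother biases feature heights (not positions) for
  features narrower than the window; choose the window per dataset when
  absolute barrier heights matter.
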