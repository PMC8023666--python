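# Methods

## Model and assumptions

`torsbo` searches conformer space in the building-block approximation: the
molecular energy is treated as a function of the N searchable proper
dihedrals alone, with every bond length and bond angle frozen at its
reference value.  Changing a dihedral is a rigid rotation of the downstream
fragment (the connected component containing the third atom of the
quadruple after cutting the central bond) about the bond axis; central
bonds that lie in rings are rejected as non-rotatable.  Angles are degrees
throughout, canonicalized to the half-open interval [−180, 180); the
dihedral sign follows the IUPAC right-hand rule, and the implementation's
`set_torsions`/`measure_torsions` pair round-trips to 1e−6°.

This reduction is exact only for the search stage.  The refinement stage
deliberately abandons it: candidates are re-relaxed with all 3n Cartesian
degrees of freedom free, so frozen-frame bias affects which basins are
proposed, not the final geometries or energies.

## Gaussian-process surrogate

The surrogate PES is a zero-mean-shifted GP (prior mean = training mean)
with a product of periodic kernels,

    k(x, y) = σ_f² ∏_j exp(−2 sin²(π Δ_j / 360) / u_j²),   u_j = π ℓ_j / 360,

with Δ_j the per-dimension angle difference.  The substitution `u_j` makes
the lengthscale ℓ_j read directly in degrees: for small separations the
factor reduces to exp(−2 Δ_j²/ℓ_j²).  The period is pinned at 360° in every
dimension — torsional energies are exactly periodic by construction, so the
period is not a free parameter.

Hyperparameters (log ℓ_j, log σ_f²) maximize the log marginal likelihood
with analytic gradients, by L-BFGS-B from a fixed multi-start schedule:
ℓ ∈ {30, 60, 120}° isotropic starts, the previous optimum when warm-started
inside the search loop, plus two seeded log-uniform draws.  Bounds are
ℓ ∈ [5, 720]° and σ_f² ∈ [1e−8, 1e4] eV².  Observation noise is held at a
numerical floor of 1e−4 eV (standard deviation): the energies fed to the
model are deterministic, so the floor only regularizes the Cholesky
factorization, with jitter escalation 1e−10 → 1e−6 as a fallback.  Up to
200 samples the hyperparameters are refit every iteration; beyond that,
every 10th iteration, reusing the previous optimum in between.  All
randomness flows from a single integer seed recorded in traces, manifests
and checkpoints.

Posterior mean, variance and their analytic gradients are exposed; the
gradients are what make multi-start minimization of the surrogate (for
acquisition and minima extraction) cheap.

## Active-learning loop

* **Initial design**: scrambled Sobol points over [−180, 180)^N, count
  max(5, 2N).  Acquisition counts reported by the package include these
  initial evaluations.
* **Energy transform**: energies are shifted to be relative to the lowest
  observation so far, then values above `E_cut` (default 2.0 eV) are damped
  to `E_cut + log10(E)`.  The damping tames steric-clash spikes that would
  otherwise wreck hyperparameter fitting while leaving the chemically
  relevant window untouched.  As printed the transform is discontinuous at
  `E = E_cut`; a continuous variant `E_cut + log10(1 + (E − E_cut))` is
  available behind `SearchConfig.continuous_transform`.  The default keeps
  the discontinuous form for fidelity to the established recipe.  Failed
  evaluations (non-finite energies) are recorded, flagged, and fed to the
  model as a relative energy of 1e6 eV on the damped branch.
* **Acquisition**: minimize `eLCB(x) = μ(x) − √β_t σ(x)` by multi-start
  L-BFGS-B (12 seeded uniform starts plus the incumbent best input),
  unconstrained — the kernel is periodic, so the optimizer may roam and the
  result is wrapped.  The exploration schedule is the standard
  `β_t = 2 ln(t^(N/2+2) π²/(3δ))` with δ = 0.1.
* **Tracking**: after every fit the predicted global minimum is located by
  multi-start minimization of the posterior mean (5 best observed inputs +
  5 seeded random starts).  Convergence is declared at the first iteration
  whose trailing window (default 5 iterations) keeps the predicted-minimum
  energy within 0.025 eV and every predicted dihedral within 10° (periodic
  distance).  These thresholds are the adopted study conditions, not tuned
  values.

## Minima extraction and purging

All acquisition locations seed L-BFGS minimizations of the posterior mean.
A candidate is accepted when its gradient norm is below 1e−4 eV/deg *and*
the numeric Hessian of the posterior mean at the candidate is positive
semidefinite — the curvature check matters because a quasi-Newton start
placed exactly on a saddle or maximum of a symmetric landscape is a fixed
point of the minimizer.  Duplicates are merged greedily in ascending energy
order: two candidates merge when every dihedral agrees within 15°
(periodic) and the energies within 0.01 eV; the deepest representative
survives, making the purge deterministic and idempotent.  The thresholds
are this package's defaults (chosen to absorb numerical jitter while
keeping chemically distinct rotamers); final pruning remains the user's
call.

The energy-versus-conformer-index convergence diagnostic sorts each
budget's minima energies, references each budget to its own minimum, and
reports the symmetric Hausdorff distance between consecutive budgets'
relative energies below a ceiling (default 0.25 eV).  The Hausdorff form
makes the deviation 0 for identical or uniformly shifted sets and equal to
the relative energy of any minimum present in one budget but missing from
the other — the property a convergence indicator needs when the sets can
differ in size.

## Refinement and thermodynamics

Relaxation runs L-BFGS-B on the calculator's energy/forces until the
maximum per-atom force norm is below `fmax` (default 0.01 eV/Å), with a
500-step limit; inputs already below `fmax` return unchanged.  The
mass-weighted Hessian uses central finite differences of forces with
displacement δ = 0.0025 Å, symmetrized as (H + Hᵀ)/2.  Rigid-body modes
are removed by projecting the 6 (5 for linear molecules, 3 for single
atoms; rank-detected by SVD) mass-weighted translation/rotation vectors
out of the Hessian before diagonalization, which is robust when low
internal modes are nearly degenerate with the rigid ones.  Eigenvalues map
to vibrational quanta via ħω in eV; modes with |ħω| below the 10 cm⁻¹
threshold count as numerically zero, more negative ones as imaginary —
both are reported, flagged as suspicious, and excluded from the
thermodynamics.

The harmonic free energy is the discrete-mode sum

    F_vib(T) = Σ_i [ħω_i/2 + k_B T ln(1 − exp(−ħω_i/(k_B T)))],

whose T = 0 limit is the zero-point energy (a molecule's vibrational
density of states is a sum of delta functions, so the integral form and
the sum are the same object).  The ZPE and the thermal term are reported
separately and summed, giving the hierarchy stages +VE(0 K) = E_opt + ZPE
and +VE(300 K) = E_opt + F_vib(300 K).  Constants: k_B = 8.617333e−5 eV/K;
the ħω conversion is derived from CODATA values via `scipy.constants`.

High-level single-point corrections enter as Δ = E_high − E_opt per
conformer label; records without a correction are simply absent from the
final stage.  Hierarchy tables reference each stage to its own most stable
conformer, rank ascending, and break ties lexicographically by label, so
assembly is invariant under input order.

## Synthetic landscapes

The analytic torsional PES is a per-dimension cosine series up to order 3
(the 1-, 2- and 3-fold barriers of real torsional profiles) plus optional
pairwise difference couplings `c_ij cos(d_i − d_j)`.  Amplitudes drawn in
[0.02, 0.25] eV give barrier heights of a few tenths of an eV, the scale of
single-bond rotation barriers.  The generator redraws (up to 50 times) until
a brute-force periodic-grid enumeration (1° spacing up to 2D, 5° up to 4D,
15° above) finds a minima count in the requested range, so every fixture's
well structure is known exactly.  The fixed `cysteine_like_d1_profile`
emulates an sp3–sp3 backbone rotation: dominant 3-fold term with 1- and
2-fold asymmetry, three staggered wells of distinct depth (global minimum
near −57°) and 0.2–0.3 eV barriers.

What these landscapes do not emulate: steric-clash walls (energies stay
bounded, so the log damping is rarely triggered), coupling strengths beyond
the pairwise cosine form, and any Cartesian-space anharmonicity.  Passing
tests on them demonstrates the correctness of the search/extraction
machinery and its sample efficiency on torsion-like multi-well landscapes —
not the accuracy of any particular energy backend on real molecules.

## Problem sizes and determinism

The bundled benchmark (`scripts/acceptance.py`) uses the 1D profile with a
15-evaluation budget over 20 seeds; the end-to-end reference run uses a
seeded 2D fixture with a 150-acquisition search.  These sizes resolve the
relevant well structures completely while keeping a full run in tens of
seconds.  Reruns with the same config and seed reproduce traces and
hierarchies bit-for-bit on the same platform; reference comparisons in the
tests use 1e−6 eV tolerances rather than bitwise equality to stay robust
to BLAS reduction order.

## Known limitations

* Dihedrals sharing a rotation axis (or straddling one another's axes) are
  not independent coordinates; the package applies rotations sequentially
  and verifies the final angles, but selecting a well-posed dihedral set is
  the user's responsibility.
* The GP is dense: fitting is O(n³) and practical to a few thousand
  samples, matching the intended budget scale.
* Acquisitions are strictly sequential; no batching.
* Rotational/translational partition functions and anharmonic corrections
  are out of scope; the harmonic treatment is only as good as the local
  quadratic expansion.
* The MMFF adapter perceives bonding once from the reference geometry;
  reactive or ionic systems need an explicit charge and may fall outside
  MMFF94's parameterization.
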