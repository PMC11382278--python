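# Methods

`evbkit` implements the computational chain used to study the rate-limiting
step of L-DOPA autoxidation — the intramolecular Michael addition of
dopaquinone's amine nitrogen onto the quinone ring, concerted with proton
transfer to a hydroxide ion — as a tested, desk-scale package: a two-state
empirical valence bond (EVB) free-energy engine exercised on low-dimensional
toy reactive systems, plus the kinetics layer that turns chemical barriers
into pH-dependent rate constants.

## The two-state EVB model

A reactive event is written as resonance between two diabatic valence
states: state 1 (reactants, force-field energy ε₁) and state 2 (products,
ε₂). The adiabatic ground state is the lower eigenvalue of

    H = [[ε₁, H_ij], [H_ij, ε₂]],
    E_g = ½(ε₁+ε₂) − ½√((ε₁−ε₂)² + 4 H_ij²),

with two empirical parameters: the off-diagonal coupling `H_ij ≥ 0` (only
H_ij² enters) and the gas-phase shift `α` added to ε₂ so the surface
reproduces reference quantum-chemical energetics. α is applied in exactly
one place — the system's evaluation of ε₂ — never inside estimators.

Conventions fixed package-wide: energies kcal mol⁻¹, lengths Å, times fs,
temperatures K; k_B = 0.0019872041 kcal mol⁻¹ K⁻¹. The reaction coordinate
is the energy gap ε₂ − ε₁. Under this sign convention the reactant basin,
where state 1 is the lower diabat, always sits at **positive** gap; profiles
record this orientation in an anchor tag so downstream feature extraction
does not depend on an implicit axis direction.

## Toy reactive systems

The solvated reactive complex is out of scope; it is replaced by
low-dimensional surrogates with the statistical structure the estimator
assumes. The canonical toy (`make_marcus_system`) is a Marcus-like pair of
harmonic diabats,

    ε₁ = ½k₁(x−x₁)²,   ε₂ = ½k₂(x−x₂)² + Δe + α,

with defaults k₁ = k₂ = 200 kcal mol⁻¹ Å⁻², x₁ = 0, x₂ = 1 Å, Δe = 0 and
mass 12 amu — a stiff proton-transfer-like surface whose reorganization
energy (½kΔx² = 100 kcal mol⁻¹) puts barriers and gaps on chemically
realistic scales. Morse wells, Buckingham-type exponential repulsion
(defaults A = 10⁴ kcal mol⁻¹, b = 3 Å⁻¹; the reference protocol does not
fix them) and constant offsets are available for custom systems of one or
two coordinates.

Restraints follow the two kinds used to keep a dissociating anion pair
associated in explicit simulations: a flat-bottom distance restraint (zero
inside `[lo, hi]`, harmonic outside, continuous first derivative at the
bounds) and soft positional restraints. All harmonic-type energies use the
`½k(Δ)²` prefactor convention; quoted force constants (10 and
0.1 kcal mol⁻¹ Å⁻²) are interpreted under it. Restraints act identically on
both states, so they cancel in the gap but enter every sampling weight.

## Sampling

Each λ-frame is sampled by BAOAB-split Langevin dynamics on the mapping
potential (1−λ)ε₁ + λε₂ plus restraints. The production protocol mirrors an
explicit-solvent EVB calculation: 51 uniformly spaced λ-frames, production
at 310 K with a 1 fs time-step, several independent replicas, and an
optional equilibration ramp raising the temperature from 1 K to the target
while the time-step grows from 0.1 to 1 fs and tightened restraints are
released. Frames are chained (each starts from the previous frame's end) so
adjacent windows overlap.

Frame lengths are scaled down from the reference 0.1 ns (10⁵ steps) to
10⁴ steps per frame in the shipped default configuration with 3 replicas;
the validation suite and acceptance script use 2×10⁴ steps and the full
10 replicas, which the compiled kernel covers in seconds. The first 20% of
each frame is discarded; samples are saved every 10 steps.

The friction coefficient is 0.2 fs⁻¹, near critical damping of the stiffest
toy mode (ω ≈ 0.08–0.13 fs⁻¹ for k = 200–400, m = 12). This is a
deliberate choice: the FEP/US averages are logs of exponential means, whose
finite-sample bias scales with the inverse number of *effective* samples
per frame. Weak coupling (e.g. 0.01 fs⁻¹) leaves positions correlated over
~200 fs and produces a measurable shared bias in the profile
(~0.03–0.08 kcal mol⁻¹ at the default frame length, verified to scale as
1/n against the exact oracle); near-critical damping minimizes the
positional decorrelation time and removes it. Because the thermostat only
affects sampling efficiency, equilibrium observables are unchanged.

Determinism: a master seed fully determines every trajectory. Replica r
uses seed `base + r`; per-frame generators are spawned from it by
`SeedSequence` keys. Identical inputs give bit-identical samples.

## The FEP/US estimator

Free energies along the ladder are stitched by exponential averaging
between adjacent frames (Zwanzig: ΔG = −kT ln⟨exp(−Δε/kT)⟩, with
Δε = Δλ·(ε₂−ε₁)). By default each step averages the forward and reverse
one-sided estimates, which cancels the leading O(1/n) bias of a single
direction; the one-sided form remains available as `fep_increment`.

Within each frame the umbrella correction removes the bias of sampling on
the mapping potential instead of the ground state, binned on the gap:

    ΔG(bin) = ΔG_map(λ_m) − kT ln⟨1_bin · exp(−(E_g − ε_map)/kT)⟩_m,

with frame contributions to a bin combined weighted by their sample counts
in that bin. All exponentials are evaluated in log space; gaps of tens of
kcal/mol would otherwise overflow. Default bin width is 2 kcal mol⁻¹ with a
data-driven range; the same width is used by every evaluator (calibration
included) so binning conventions cancel in comparisons. Bins with no
samples are reported missing, never zero, and missing bins between the two
basins invalidate thermodynamic extraction rather than being bridged.

Each replica is estimated and anchored independently (reactant-basin
minimum set to zero); the pooled profile is the per-bin mean over replicas
with the standard error of that mean, re-anchored. Profiles carry *basin
hints* — the mean gap of the λ=0 and λ=1 ensembles (or, for the oracle, the
gap at the diabatic minima) — and the basin minima are located as the
lowest well-populated bin near each hint. A fallback splits the populated
range into thirds when no hints exist (e.g. a bare profile read from disk);
note the thirds rule mislocates the reactant basin for strongly exergonic
profiles, where the reactant well occupies only a sliver of the gap range.
The transition state is the highest bin strictly between the minima, ties
broken toward gap 0.

`analyze` locates the three feature bins once on the pooled profile and
reads every replica at those fixed bins before pooling mean ± SEM across
replicas. Locating an argmax independently in each replica would bias every
replica's barrier upward (an extreme-value selection effect, not sampling
error); fixing the locations on the lowest-noise profile removes it.

## The exact oracle

For systems of dimension ≤ 2 the binned profile has a deterministic
reference: −kT ln of the Boltzmann integral of exp(−(E_g+restraints)/kT)
over each bin's preimage, by composite Gauss–Legendre quadrature refined
until successive panel doublings agree to 10⁻⁸. In one dimension the grid
is aligned with the preimages of the bin edges (the gap is split into
monotone pieces; each edge crossing is bracketed with `brentq`), so every
panel integrand is smooth and convergence is exponential. The oracle is
seed-free and never shares code with the stochastic estimator beyond the
Hamiltonian itself.

Two distinct "reaction free energies" exist and are both provided: the
minimum-to-minimum difference of the binned profile (what `extract_thermo`
reports) and the basin free-energy difference −kT ln(Z_p/Z_r) with the
basins split at the diabatic crossing (`basin_free_energies`). For
uncoupled deep harmonic basins the latter equals Δe + α + ½kT ln(k₂/k₁)
exactly, while the profile difference instead carries the Jacobian of the
gap coordinate (kT ln(k₁/k₂) for harmonic wells); conflating the two is a
classic pitfall, so the distinction is kept explicit.

Estimator-vs-oracle validation (`evbkit.validation.compare_to_oracle`)
compares bins between (and including) the two basin minima that are
populated in every replica with a pooled count ≥ 20, requiring
|deviation| ≤ max(3·SEM, 0.1 kcal mol⁻¹). The comparison is restricted to
the inter-basin region because outer-wall bins beyond the minima are
reached only by rare excursions whose shared finite-sampling bias replica
scatter cannot detect — and they lie outside the reactant→product segment
the profile describes. The 0.1 kcal mol⁻¹ floor (0.16 kT) keeps a
simultaneous ~100-bin comparison meaningful: with SEMs estimated from 10
replicas, a strict per-bin 3·SEM band would be violated by a perfect
estimator a few percent of the time per bin.

## Calibration

`calibrate` fits (H_ij, α) so the system's profile reproduces target
activation and reaction free energies — here the gas-phase reference
values ΔG‡ = 1.28 and ΔrG = −47.04 kcal mol⁻¹. The residual vector is
driven to zero by a damped Newton iteration with a finite-difference
Jacobian (step 0.05), tolerances 0.05 kcal mol⁻¹, search box
H_ij ∈ [0, 200], α ∈ [−100, 100]. The solve is well conditioned because,
with the basins fixed, ΔrG increases monotonically in α while ΔG‡ decreases
monotonically in H_ij (verified numerically on the fixtures).

The evaluator inside the fit loop is the deterministic quadrature oracle;
root-finding on a stochastic objective is fragile, so the sampled FEP/US
estimator validates the calibrated parameters instead of driving the fit.
On the default toy the fit lands at H_ij ≈ 8.0, α ≈ −47.9 kcal mol⁻¹;
these are surface-specific numbers with no claim of transferability to any
molecular force field.

## Kinetics layer

The rate-limiting step consumes a hydroxide ion and requires a neutral
amine, so the observable barrier at a given pH decomposes as

    ΔG‡(pH) = ΔG‡_chem + kT ln10 (pKa_water − pH) + kT ln10 (pKa_amine − pH),

with pKa_water = 15.7 and pKa_amine = 8.11 (experimental values). The
carboxyl group (pKa 2.3) stays deprotonated over the modelled range and
contributes no term. Rate constants follow from the Eyring–Polanyi
equation k = (k_B T/h)·exp(−ΔG‡/kT) with transmission coefficient 1, so
log₁₀ k is affine in pH with slope exactly +2; the model warns above
pKa_amine, where the amine "cost" would turn favourable and the two-term
decomposition leaves its intended range.

Two thermal energies coexist deliberately: the physical k_B·T (0.6163
kcal mol⁻¹ at 310.15 K) and the conventional rounded 0.617 kcal mol⁻¹ used
in experimental-kinetics arithmetic (`KT_37C`); `KineticContext` records
which is active. The familiar two-decimal numbers (corrections 11.79 and
1.01, composite barriers 30.93 / 21.34 / 23.60, decomposition 14.75) are
recovered only with 0.617. Converting the experimental rate constant
2.56×10⁻⁷ s⁻¹ with kT = 0.617 yields 27.56 kcal mol⁻¹, one printed digit
above the conventional 27.55; propagating the three-decimal rounding of kT
gives ±0.03 kcal mol⁻¹ on this conversion, which is the tolerance the
regression tests use.

## What the toys do and do not show

The synthetic systems reproduce the *statistical structure* the estimator
assumes — two diabatic surfaces with distinct minima, constant coupling, a
gas-phase shift, restraints, λ-driven window overlap — at desk scale.
Passing tests therefore demonstrate the correctness of the estimator chain
(sampling → stitching → umbrella binning → extraction → calibration) and
of the kinetics arithmetic. They do not validate force fields, solvation,
long-range electrostatics, multi-dimensional reaction coordinates, or any
property of the real solvated system; the aqueous chemical barrier
(18.13 kcal mol⁻¹ in the reference calculation) enters only as a fixed
input to the barrier-assembly arithmetic.

## Numerical choices and degenerate inputs

- Ground-state energy uses `hypot` for the discriminant (no overflow).
- λ outside [0,1], non-positive rates, temperatures, or distances, and
  decreasing equilibration ramps are rejected with range errors.
- A non-finite coordinate or force aborts the frame with a diagnostic and
  invalidates only the affected replica.
- Zero-step frames return the initial configuration only.
- Profiles with fewer than three populated bins, monotone profiles, and
  adjacent basins raise typed errors (`NoBarrierError`, `MissingBinsError`).
- With a single replica, pooled errors are reported as NaN and flagged.
- The jitted kernels fall back to the identical pure-Python code path when
  numba is unavailable (at roughly 500× the cost).

## Known limitations

- Two EVB states only; no geometry-dependent coupling.
- The quadrature oracle covers dimension ≤ 2, with edge-aligned (fast,
  10⁻⁸-converged) integration only in 1-D.
- Frame-to-bin combination is count-weighted; multistate reweighting
  estimators (MBAR/WHAM) are out of scope.
- The pH model is two-term and intended for pH ≤ pKa_amine.
- Replica SEM with few replicas is itself noisy (t-distributed); the
  validation layer's tolerance floor exists for exactly this reason.
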