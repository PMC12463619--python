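# Methods

## Pre-nucleation equilibrium

The branched oligomerization scheme is solved as a coupled mass-action
system in the free-monomer concentration.  Conventions (all molar):

    KD1  = [m]²/[D]       monomer ⇌ productive dimer
    KD1* = [m]²/[D*]      monomer ⇌ off-pathway dimer
    KD2  = [D]²/[T]       dimer ⇌ tetramer
    KD,mI = [m][I]/[mI]   monomer ⇌ monomer-inhibitor complex

With these definitions [T] = [m]⁴/(KD1²·KD2), so the tetramer mass
fraction scales as [m]³.  Free inhibitor is eliminated analytically
(I_free = I_tot/(1 + m/KD_mI)), leaving a single protein-balance function
f(m) = m + mI + 2D + 2D* + 4T − P_tot that is strictly increasing on
[0, P_tot].  The root is bracketed and found with Brent's method
(xtol 1e-18) and polished with analytic-derivative Newton steps to an
absolute tolerance of 1e-15 M; solutions are rejected if the residual
exceeds 1e-9·P_tot.  Populations are reported as monomer-unit mass
fractions (stoichiometry-weighted), the only convention that reproduces
the ~1% D* / ~3% D populations at 1.2 mM with the constants above.

The mI complex is inert: no (mI)₂, (mI)₄ or mixed m₂I/mI₂ species.  An
optional off-pathway dimer of mI is deliberately not modelled; the species
list stops at the tetramer.

Free-energy differences between dissociation constants are computed as
R·T·ln(KD_a/KD_b) with R = 1.9872e-3 kcal/(mol·K).

## Exchange model

The exchange network is anchored on the monomer.  Site populations are
monomer-unit weights renormalized over the exchange-visible sites, and all
pairwise rates obey detailed balance: within a connected pair,
k(i→j) = k_ex·p_j/(p_i + p_j) with k_ex = 1/τ for that step.  Defaults:
τ = 750 μs for m↔D* and τ = 50 μs for the productive branch.  Two
topologies are available — the full linear chain m↔D↔T (default; both
steps carry k_ex = 1/τ_mT) and a lumped two-site m↔T branch ("star") that
drops D from the network.  The experimental record does not say which
reduction the original simulations used; the chain is the default because
it keeps every populated species visible to the observables.

* **δ_ex** (fast limit): Σ pᵢδᵢ with δ_m ≡ 0.
* **Observed line / Rex**: eigendecomposition of L = K − R2·I + iΩ; the
  observed mode maximizes the detected amplitude |c_k·(1ᵀv_k)| for the
  equilibrium starting vector; shift = Im λ, Rex = −Re λ − R2_0.  Degenerate
  dominant modes are resolved by amplitude with a warning.
* **CPMG**: in-phase magnetization propagated through repeating τ–180°–τ
  blocks, τ = 1/(4ν), ideal pulses as complex conjugation; the block count
  rounds to fill T_relax (40 ms default) and R2_eff uses the actual
  propagated duration.  No off-resonance effects, finite-pulse effects,
  scalar coupling or cross-correlated relaxation — the model carries
  population/exchange information only.
* **R1ρ**: on-resonance convention (carrier at the population-averaged
  shift, tilt 90°); R1ρ = −Re of the eigenvalue of the 3N×3N rotating-frame
  matrix whose eigenvector overlaps the spin-locked equilibrium
  magnetization.  R1 defaults to 0 (configurable), so R1ρ = R2_0 + Rex.

Chemical shifts of the invisible oligomers are not experimentally printed
anywhere; they are fixture parameters (defaults δ_D = 1.0, δ_D* = −0.4,
δ_T = 6.0 ppm at a ¹⁵N Larmor frequency of 60.8 MHz) chosen to give
realistic δ_ex (tens of ppb) and Rex (0.3–20 s⁻¹) magnitudes over the
0.2–1.2 mM range.  mI is excluded from the microsecond network by default
(small-molecule binding is ms-to-s, far slower than the exchange window);
a flag adds it with its own timescale.

## Aggregation cascade

State: m, mI, D, D*, T, P (free nuclei), PI, M (fibril mass in
monomer-equivalent units, including nucleus mass).  Rate laws:

    dP/dt = k_conv·[T] + k₂·[m]^n₂·M − (PI binding flux)
    dM/dt = 4·k_conv·[T] + n_c·k₂·[m]^n₂·M + 2·k_e·[m]·[P]

Primary nucleation consumes one tetramer (4 monomer units transferred into
M); secondary nucleation consumes n_c monomers per nucleus (default 4);
elongation adds monomer at two fibril ends.  Every term is individually
switchable.  The reaction orders are the standard
nucleation–elongation forms for the named processes; n₂ is exposed as a
parameter (default 2).  PI binds free nuclei only and cannot elongate;
fibril ends of mature fibrils are not separately modelled.  Monomer-unit
conservation m + mI + 2D + 2D* + 4T + M = P_tot holds along every
trajectory to ≤ 1e-8 relative (tested).

Two integration modes, agreeing within 1% on fixtures (tested):

* **dynamic** (default): pre-nucleation steps as explicit reversible
  mass-action reactions with dissociation rates of 1e3 s⁻¹ (≥10³× the
  aggregation rates), integrated with BDF;
* **quasi_equilibrium**: the pre-nucleation pool is re-solved algebraically
  at every step from P_tot − M and I_tot − PI, and only (P, PI, M) are
  integrated (LSODA).  This mode backs the fitting loops.

Initial conditions pre-equilibrate the soluble pool (including mI when the
scheme binds monomer), with P(0) = P0 and M(0) = 0.  P0 defaults to 0;
scheme-divergence analyses use P0 > 0, under which the monomer- and
nucleus-binding mechanisms start identically (shared pre-existing nuclei)
and separate as de-novo nucleation proceeds differently.

## Time-resolved observables

All exchange quantities are adiabatic: the microsecond network is rebuilt
from the instantaneous species state at each output time.  PRD intensity is
the visible monomer-unit fraction (m, mI, D, D*, T visible; P, PI, M
solid-like and invisible).  NT intensity uses the Lorentzian
height-∝-area/linewidth model, I ∝ V·R2_ref/(R2_ref + Rex); the intensity
shows an interior maximum whenever Rex(0) ≳ R2_ref/2, because Rex ∝ [m]³
relaxes three times faster (relatively) than the visible pool shrinks.  mI
contributes volume with monomer-like linewidth (no extra broadening).

## Fixture constants (synthetic scenarios)

Values the printed record fixes: KD1 = 70 mM, KD1* = 200 mM, KD2 = 30 μM
(Q7) or 11 μM (Q35), KD,mI = KD,PI = 50 μM, τ = 750 μs / 50 μs, protein
series 0.20–0.75 mM (to 1.2 mM for Q7), inhibitor series 0.2/0.4/0.8 mM,
spin locks 750/1500/3000 Hz.  Values it does not fix, set here once for
realism: k_conv = 2e-5 s⁻¹, k_e = 500 M⁻¹s⁻¹, k₂ = 0.25 M⁻²s⁻¹, P0 = 1e-9 M
(hours-scale fibrillation with a strong concentration dependence at
0.2–0.75 mM), R2_0 = 8 s⁻¹, R2_ref = 3 s⁻¹, oligomer shifts as above,
noise 2% relative (Gaussian, seeded; per-point sigma floored at 5% of the
dataset maximum so weights stay finite near zero crossings).

What the generator emulates: population-driven shifts/broadening, dose
ordering, fibrillation kinetics and their noise.  What it does not: residue
resolution, baseline/phasing artefacts, field inhomogeneity, temperature
drift, or any heterotypic inhibitor stoichiometry.  Passing recovery and
classification tests therefore demonstrate identifiability under the
modelled noise, not robustness to systematic experimental error.

## Fitting and classification

Weighted least squares over all datasets simultaneously
(inverse-variance — the record does not state how heterogeneous observables
were weighted, so the statistically standard choice is adopted), strictly
positive parameters on log10 scale, trust-region-reflective minimizer with
seeded multi-start (default 8; classification uses 4 and 2 in the test
studies since the 1–2 parameter objectives are unimodal in practice).
Standard errors from the Jacobian (JᵀJ)⁻¹ with delta-method back-transform.

Scheme selection uses AICc = χ² + 2k + 2k(k+1)/(n−k−1) (Gaussian likelihood
with known σ).  AICc was chosen because the candidate schemes are nested
with very few extra parameters and datasets are small; on noiseless data
the dual scheme ties the generating single scheme in χ² and loses by the
complexity penalty (tested).  KD bounds for the binding parameters default
to [1 nM, 1 M]: the upper end lets a binding step become negligible so the
dual scheme properly nests the single ones.

Identifiability: equilibrium constants require concentration-resolved
δ_ex/V-I (fitting them from PRD decay alone triggers a warning);
KD,mI needs an equilibrium observable at ≥2 inhibitor levels; KD,PI needs
a fibrillation observable.  The classifier refuses datasets that lack an
equilibrium-sensitive and a fibrillation observable at ≥2 inhibitor
concentrations.

## Known limitations and degenerate inputs

* P_tot = 0 returns the empty state; population fractions are undefined
  (empty mapping).
* The printed "~5% T" at 1.2 mM is not reproducible from the rounded
  printed constants by mass action (the solver gives 3.45%), nor are the
  inhibited "~1.5%/2%" D/T figures (solver: 0.52%/0.11%); the original
  unrounded fit constants evidently differ.  These numbers are not forced.
* The nucleus-binding invariance of δ_ex/V-I versus the uninhibited run is
  exact at t = 0 and holds only while fibril mass is negligible; afterwards
  the two runs differ through monomer depletion, which is the mechanism's
  actual kinetic signature, not an error.
* No fibril fragmentation, length distributions, saturating elongation,
  spatial effects, or activity corrections; oligomers stop at the tetramer.
* Test-suite problem sizes: 13-point decay curves, 4-concentration series,
  20 recovery and 40 classification replicates — chosen as the smallest
  designs at which the statistical criteria are stable.
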