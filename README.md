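# amykin

NMR-driven kinetic modelling of amyloid aggregation and its inhibition by
small molecules, built around the early aggregation pathway of huntingtin
exon 1 (htt-ex1).

Transient, sparsely populated oligomers — not mature fibrils — are the
species most implicated in amyloid toxicity, and they are exactly the
species a candidate inhibitor should engage.  Solution NMR sees them only
indirectly, through chemical exchange with the visible monomer resonance.
`amykin` provides the forward models and fitting machinery to turn those
indirect observables into a mechanistic verdict: *where in the pathway does
a compound act?*

The package is for NMR spectroscopists and kineticists who simulate or fit:

* **Pre-nucleation equilibria.**  A branched mass-action scheme in which
  monomer m forms a productive coiled-coil dimer D that assembles into a
  tetrameric helical bundle T, in competition with an off-pathway dimer D*:

      KD1 = [m]²/[D],   KD1* = [m]²/[D*],   KD2 = [D]²/[T]

  with optional competitive monomer–inhibitor binding
  KD,mI = [m][I]/[mI].  Because [T] ∝ [m]⁴, the tetramer mass fraction
  scales as [m]³ — the lever that makes every exchange observable strongly
  concentration dependent.

* **Exchange observables.**  Exchange-induced chemical shifts
  (δ_ex = Σ pᵢδᵢ in the fast limit), CPMG relaxation dispersion
  (Bloch–McConnell matrix propagation through τ–180°–τ echo blocks), and
  on-resonance R1ρ dispersion (dominant eigenvalue of the 3N rotating-frame
  evolution matrix), for an N-site network whose rate matrix satisfies
  detailed balance with the equilibrium populations (m↔D* at τ ≈ 750 μs,
  the productive branch at τ ≈ 50 μs).

* **The aggregation cascade.**  Tetramers convert irreversibly into
  elongation-competent nuclei P (rate k_conv·[T]), fibrils grow by monomer
  addition at two ends (dM/dt = 2k_e·[m]·[P]), and fibril mass catalyzes
  secondary nucleation (k₂·[m]^n₂·M).  Four inhibitor schemes: none,
  monomer sequestration (m + I ⇌ mI), nucleus sequestration (P + I ⇌ PI,
  elongation-incompetent), or both.

* **Time-resolved observables.**  PRD intensity decay (clean fibrillation
  readout), NT cross-peak volume/intensity with its transient intensity
  rise (V falls with the visible pool while I ∝ V·R2_ref/(R2_ref+Rex)
  recovers as tetramer broadening relaxes), and δ_ex(t).

* **Global fitting and classification.**  `GlobalFitModel(...).fit()`
  returns a results object with log-scale trust-region estimates, standard
  errors and a `summary()` table; `MechanismClassifier` fits all four
  inhibitor schemes and ranks them by AICc, operationalizing the
  experimental signatures: changed δ_ex/V-I **and** slowed PRD decay →
  monomer sequestration; unchanged δ_ex/V-I with slowed decay → nucleus
  sequestration; nothing changed → inert.

## Worked example

Solve the pre-nucleation equilibrium at 1.2 mM protein with a 50 μM
monomer binder at 0.8 mM:

```yaml
# example.yaml
equilibrium:
  kd1: 70 mM
  kd1_star: 200 mM
  kd2: 30 uM
  kd_mi: 50 uM
conditions:
  p_tot: 1.2 mM
  i_tot: 0.8 mM
```

```bash
amykin simulate-equilibrium --config example.yaml
```

```
p_tot   i_tot   m             D             D_star        T             mI           frac_m  frac_D   frac_Dstar  frac_T   frac_mI
0.0012  0.0008  0.0004675...  3.1229e-06    1.0930e-06    3.2509e-07   0.0007227... 0.3896  0.00520  0.00182     0.00108  0.6022
```

60% of the protein is sequestered as mI; the off-pathway dimer falls to
0.18% of monomer units (from 1.03% without inhibitor) and the tetramer to
0.11% — the inhibitor has collapsed the productive pathway.  Without the
inhibitor section the same command reproduces the uninhibited populations
(1.03% D*, 2.94% D, 3.45% T at 1.2 mM).

Classify a (synthetic) inhibitor from its NMR fingerprint:

```python
from amykin import MechanismClassifier, make_scenario, simulate_experiments

spec = make_scenario("q35_monomer_inhibition", noise=0.02, seed=7)
experiments = simulate_experiments(spec)
verdict = MechanismClassifier(experiments, params=spec.params).fit(seed=7)
print(verdict.summary())
```

```
Mechanism classification
========================
verdict: monomer_sequestration

scheme                    AICc        chi2   k
monomer_binding          67.08       65.03   1
dual                     69.15          65   2
nucleus_binding       1.57e+06    1.57e+06   1
none                 1.631e+06   1.631e+06   0
```

The monomer-binding scheme fits all 84 points at reduced χ² ≈ 0.8; the
dual scheme matches it but pays the AICc complexity penalty; schemes that
cannot move δ_ex and V/I (nucleus binding, none) fail by six orders of
magnitude.

Other entry points: `amykin simulate-dispersion` (δ_ex/CPMG/R1ρ),
`amykin simulate-kinetics` (trajectories), `amykin simulate-observables`
(PRD, V/I, δ_ex(t)), `amykin make-synthetic`, `amykin fit`,
`amykin classify`.

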