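# Methods

## Model structure

The destruction complex is modelled as a site-graph rule system over five
explicit proteins (β-catenin, an APC form, Axin, GSK-3β, CK1α); CK1ε and
the phosphatases (PP2A and the β-catenin phosphatase) act implicitly
through rule contexts and first-order dephosphorylation. A chemical
species is a connected graph of molecule instances with site states and
bonds, identified up to isomorphism by an exact canonical form (partition
refinement with backtracking on ties — never hashing). Rules are
bind/unbind, state change, synthesis and degradation, each with pattern
contexts; "colocalized" contexts (e.g. S45 phosphorylation requires
β-catenin in the same complex as Axin-bound CK1α) are expressed as
multi-molecule patterns that must embed into one species, i.e. any
connected path counts, with the kinase required to sit on Axin. This
resolves the ambiguity between "in complex with Axin" and "colocalized via
Axin": both are read as same-complex membership.

Key mechanistic commitments, in the package's own reading:

* **Competition at ARM 3–4.** One β-catenin site (`arm34`) binds either
  Axin or a phosphorylated APC 20-aa repeat; occupancy is exclusive by
  construction (one bond per site).
* **Two lumped 20-aa repeats.** Full-length APC carries the high-affinity
  third repeat only (K_D 0.27 nM when phosphorylated); APC1338-like forms
  carry the first repeat only (80 nM). The full-length first-repeat
  interaction is omitted as negligible beside the third.
* **Intracomplex closure.** Whenever both reactant sites of a binding rule
  are free and co-resident in one species, the bond closes unimolecularly
  at k_f·χ. The engine detects this structurally at expansion time instead
  of enumerating bridge-context rules; this covers every tether topology
  uniformly and is the package's reading of tethered-reactant kinetics.
* **Degradation with release.** Degradation deletes the β-catenin molecule
  wherever it sits and splits the remainder into connected components
  (slow if S33/37 is unphosphorylated, fast if phosphorylated).
* **APC dephosphorylation** requires the 20-aa site to be exposed
  (unbound) *and* APC to be in a complex containing Axin, which recruits
  PP2A; β-catenin dephosphorylation is context-free because its
  phospho-sites are never occupied by binding partners.

## Network expansion and its size

Expansion applies every rule to every species (or species pair) to a fixed
point, with per-complex stoichiometry caps {any APC form: 1, β-catenin: 1,
Axin: 2, GSK-3β: 2, CK1α: 2} preventing unbounded APC–β-catenin–Axin
polymers. The largest complex is then the eight-molecule assembly with one
Axin on the SAMP arm and one on ARM 3–4, each carrying both kinases. Under
these caps the normal-cell network closes at **340 species / 3,481
reactions**, a count confirmed by hand enumeration of the admissible
topologies and by an independent brute-force enumerator (VF2 isomorphism,
exhaustive embeddings) on mini-models.

The originally reported size of this network is 410 species. No documented
convention reproduces that number exactly: per-type cap grids over
{1,2,3} give 180–2,598 with nearest values 340/348/364; allowing APC
dephosphorylation while bound gives 380; a max-aggregate bound of 4 with
two APCs and two β-catenins per complex gives 406 but amputates the full
five-protein complex. The published count evidently depends on the exact
original rule encoding (bridge-pattern intracomplex rules and generator
options) that is not recoverable from the text, so the package keeps the
mechanistically motivated caps above, reports 340, and treats closure,
per-reaction mass balance and oracle equivalence as the binding
correctness criteria. `expand()` exposes both per-type caps and a
`__max_agg__` bound so the alternatives remain one keyword away.

## Dynamics and steady states

The network compiles to mass-action ODEs `dy/dt = S v(y)` with sparse
stoichiometry and an analytic Jacobian. Transients use LSODA (dense
Jacobian) below ~900 species and BDF (sparse) above. Steady states are
found by long-horizon integration with doubling horizons (start 10⁵ s)
until `max |dyᵢ/dt| / max(yᵢ, 10⁻⁶ nM) < 10⁻¹⁰ s⁻¹`; integration rather
than root-finding avoids landing on unphysical roots, and BDF is used for
every leg because restarting LSODA at a fixed point can stall its
stiffness switching. Tolerance-level negative concentrations are clipped
only in the returned state. Conservation of APC/Axin/GSK-3β/CK1α holds to
≤10⁻⁶ relative drift along trajectories (tested); β-catenin changes only
through synthesis and degradation reactions.

Units are nM and seconds throughout. Copy-number conversions use a
cytoplasmic volume of 5.2375×10⁻¹³ L with N_A = 6.022×10²³, which makes
100 nM exactly 31,540 copies/cell after rounding (and 10 nM 3,154); the
synthesis rate of 4.0 molecules/s is 1.268×10⁻² nM/s.

## Parameters and calibration

Literature-pinned values: K_D(15-aa↔ARM5–9) = 273 nM,
K_D(phospho-20-aa-1↔ARM3–4) = 80 nM, χ = 10⁴ nM, the five totals
(β-catenin 35, APC 100, Axin 10, GSK-3β 100, CK1α 100 nM), the synthesis
rate, and k_deg,slow = ln2/4.5 h (the mutant pulse-chase half-life, which
the model reproduces exactly because degradation is state-independent).
k_f = 10⁻³ nM⁻¹s⁻¹ is the generic near-diffusion-limited association
constant shared by all bindings.

The remaining constants are behaviourally calibrated, in the spirit of
pinning parameters to observed system behaviours rather than direct
measurements:

* **k_p,bcat = 6.413×10⁻² s⁻¹** solves steady-state total β-catenin
  = 35.000 nM in the normal cell (one-dimensional bisection; the steady
  state is monotone in this rate).
* **k_dp,bcat = 7.833×10⁻⁴ s⁻¹** solves the *measured* phospho-pool
  half-life of 10.00 min when both β-catenin phosphorylation rates are
  switched off at steady state. This sits below ln2/600 s⁻¹ because slow
  and fast degradation also drain the phospho pool; anchoring the rate
  constant itself at ln2/600 would make the measured half-life 7.7 min.
  The two 1-D solves are alternated to convergence (`refine_anchors`).
* **K_D(Axin↔ARM3–4) = 500 nM**, within the "comparable to 273/80 nM"
  range, chosen so that the 15-aa-only fragment (class C) at 1× dose
  leaves SW480 β-catenin within 1% of baseline — the observed "no effect"
  — while all other transfection signs are preserved. At 100 nM this
  affinity makes class C depress β-catenin by ~5%, contradicting the
  transfection panel.
* **k_deg,fast = 2×10⁻³ s⁻¹** (≈6 min turnover of the phospho-marked pool)
  and **k_p,APC = k_dp,APC = 0.03 s⁻¹** (equal by construction, making the
  phosphorylation ratio scans well-defined) are retained defaults; the
  calibrated behaviours are insensitive to both over at least a
  half-decade. K_D(SAMP↔RGS) = K_D(CK1α↔Axin) = K_D(GSK-3β↔GID) = 100 nM.

With this set the model yields: steady state 35.0 nM (11,039
copies/cell), wild-type pulse-chase half-life 27.8 min (the ~30 min
observation; the value is emergent, not fitted), mutant half-life 4.500 h,
phospho-pool half-life 10.00 min, and the transfection sign pattern
A↓ E↓ B↑ C≈ D≈ F≈ in SW480 cells.

## Virtual experiment conventions

* **Transfection dose scans** (constructs added to a background) express
  dose as exogenous protein on top of the endogenous 100 nM, matching the
  "introduced exogenously in addition to" protocol. Transfecting the class
  that matches the endogenous form (A into normal, B into SW480) raises
  the endogenous pool rather than duplicating the molecule type.
* **Axin-association scans** vary the *total* amount of the background's
  APC form over 0.01–10 × 100 nM. This is the reading under which the
  scaffold bell exists: its rising limb lies where APC is scarcer than
  β-catenin (< 35 nM), below the endogenous level, so an
  exogenous-on-top axis could only show the falling limb. The SW480 curve
  is monotone decreasing (pure sequestration); the normal-cell curve peaks
  at ~0.3×.
* **Pulse-chase** defaults to the synthesis-shutoff protocol (set
  synthesis to zero at steady state, track total β-catenin). A cohort
  protocol — a labelled pool decaying in a background held at steady
  state, which is exactly linear because complexes hold at most one
  β-catenin — is implemented as an option; the two agree to ~0.3% at the
  calibrated point.
* **Kinase inhibition (LiCl)** divides the GSK-3β-mediated rates (S33/37
  and APC 20-aa phosphorylation) by the fold at t = 0 from the untreated
  steady state; CK1α is untouched. Outputs are normalized to the untreated
  steady-state phospho levels. Under the calibrated parameters pS33/37
  drops sharply (to ~0.15 at fold 20) with pointwise ordering in the fold
  and extinction at infinite fold, but partially recovers as unmarked
  β-catenin accumulates, and pS45 *rises* — a pS45 decline would require
  the standing pS45 pool to be dominated by fast-degrading doubly
  phosphorylated molecules, which is incompatible with the 10-minute
  phospho-pool anchor above. The anchor was kept; the LiCl time courses
  are therefore only qualitatively constrained (see limitations).
* **Interface ablation** zeroes one association rate constant
  (15-aa↔ARM5–9, Axin↔ARM3–4, or SAMP↔RGS) leaving its dissociation rate
  untouched, and compares steady-state β-catenin to the unperturbed normal
  cell. The two cyclic-core contacts move the level by <5%; only the
  APC–Axin interface matters (level ×4.5), by the diversion-sink
  mechanism, not cyclic-complex stability.
* **Local sensitivity** uses central finite differences on each parameter
  (default δ = 5%), reported as (p/Y)(∂Y/∂p) for Y = steady-state total
  β-catenin.

## Synthetic data and recovery

The synthetic-data layer emulates the calibration behaviours — pulse-chase
decays, normalized LiCl phospho-courses, and transfection dose-response
curves — as noise-free model curves under multiplicative lognormal noise
(default CV 5%, median-unbiased so E[log obs] = log curve). Noise is
applied after normalization for normalized observables, keeping the t = 0
anchor exactly 1 (switchable). Generators are deterministic per seed.
These datasets reproduce the *statistical* structure the fitting layer
assumes, not real-data artefacts (blot saturation, batch effects,
correlated residuals), so recovery results certify identifiability within
the model, not robustness to real experimental error.

Recovery: the S33/S37-mutant decay isolates k_deg,slow, which is recovered
to <0.01% from noiseless data and within 25% in ≥80% of replicates at 5%
noise (20 replicates, seeded). Fits run Nelder-Mead on log₁₀ parameters
with Latin-hypercube multistarts; the dataset-fitting path shares the
steady-state solve across candidate evaluations because the normalized
mutant decay is initialization-independent (exactly exponential).

## Known limitations

* The expanded network size (340) does not match the originally reported
  410; see above. All structural correctness criteria are independent of
  this count.
* The LiCl pS45 time course rises rather than falls under the calibrated
  regime (see the conflict analysis above).
* The elevation of SW480 β-catenin upon 10× excess APC1338 is ~2.5× the
  untransfected level here, somewhat above the reported ~2× figure-read
  value.
* No Wnt ligand/receptor layer, E-cadherin or Tcf/Lef pools, nuclear
  shuttling, Axin polymerization, or explicit CK1ε/ubiquitination
  machinery: the model describes the cytosolic destruction cycle at steady
  state, per its scope.
* Deterministic mass action only; with thousands of copies per cell for
  every species of note, stochastic corrections are immaterial at the
  questions asked.
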