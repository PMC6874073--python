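# Methods

## Scope and model

`tautkin` analyzes reversible unimolecular proton-transfer steps R ⇌ P on a
molecular potential-energy surface, each characterized by a single
first-order saddle point. The inputs are thermochemical and
electron-topological quantities produced upstream by electronic-structure
and Atoms-in-Molecules software: forward Gibbs activation barriers ΔΔG_f and
reaction Gibbs energies ΔG (kcal·mol⁻¹, product minus reactant), the
magnitude ν̃ᵢ of the TS imaginary wavenumber (cm⁻¹), and per-contact
(3,−1) bond-critical-point descriptors (electron density ρ, Laplacian Δρ,
ellipticity ε in atomic units; donor–acceptor geometry in Å/degrees).

Rate constants follow conventional transition-state theory with a
multiplicative Wigner tunneling factor,

    k_{f,r} = Γ · (k_B T / h) · exp(−ΔΔG_{f,r} / RT),
    Γ       = 1 + (1/24) · (h c ν̃ᵢ / k_B T)².

Assumptions inherited from this form: a single reactive mode, separable and
parabolic near the saddle point (the Wigner expansion is the leading-order
tunneling correction, adequate for moderate barriers and ν̃ᵢ ≲ 2200 cm⁻¹ at
room temperature, where Γ ≤ ~5.5); no recrossing; equilibrium solvation is
absent because the target systems are isolated molecules. Variational TST,
Eckart/small-curvature tunneling and master-equation kinetics are out of
scope.

Derived observables: reverse barrier ΔΔG_r = ΔΔG_f − ΔG (an exact
bookkeeping identity, so only forward barriers and reaction energies are
stored); equilibrium constant K = exp(−ΔG/RT) (the prefactor and Γ cancel in
k_f/k_r — detailed balance is enforced by construction and property-tested
to 1e-10 relative); product lifetime τ = 1/k_r; equilibration time
τ₉₉.₉% = ln(10³)/(k_f + k_r) for a two-state reversible system.

### Stability classification

A product is `barrierless_reverse` when ΔΔG_r ≤ 0: the nominal minimum has
no kinetic bound in the reverse direction. Otherwise it is
`dynamically_unstable` when its lifetime is shorter than the period
1/(c·ν̃) of its lowest-frequency torsional mode — the well cannot support
even one vibrational cycle. The torsional wavenumber must be supplied by the
caller; when it is absent the classifier never issues the
dynamically-unstable verdict rather than inventing a threshold. Precedence:
barrierless_reverse > dynamically_unstable > stable.

### Empirical contact energies

Three linear/empirical maps from BCP descriptors to interaction energies
(kcal·mol⁻¹):

| formula | expression | domain |
|---|---|---|
| NBH | E = −3.09 + 239·ρ | classical OH⋯O H-bonds |
| BYH | E = 248.501·ρ − 0.367 | strong CH⋯O H-bonds (E > 10) |
| EML | E = ½·|V(r)|·627.5095 | weak CH⋯O, OH⋯C, vdW O⋯O / C⋯O |

Validity criterion: ρ > 0 and Δρ > 0 at the BCP (BCP existence and a bond
path are implied by the record being present at all). Invalid contacts are
flagged, never silently dropped.

Dispatch rules. OH⋯O always goes to NBH, including the strong
ρ ≈ 0.107 a.u. case at a double-well TS — the reference table scores that
row with the OH⋯O formula, not the strong-CH⋯O one. The strong/weak CH⋯O
decision is circular as stated (the formula choice depends on the energy the
formula produces); we resolve it by evaluating the BYH estimate and
comparing it with the 10 kcal·mol⁻¹ threshold, equivalent to a density
cutoff ρ ≥ 0.04173 a.u. EML returns the magnitude ½|V| converted at
627.5095 kcal·mol⁻¹ per hartree because V(r) is negative by definition while
bond energies are reported positive. Records lacking V(r) — the usual case
for published tables, which do not print it — yield an explicit
"unscorable" EML outcome instead of a number.

## Reference fixtures and the comparison harness

The package embeds the 13-reaction quercetin proton-transfer network
(kinetics table: barriers, reaction energies, imaginary wavenumbers) and the
per-structure BCP contact table (33 stationary points, 103 contacts).
Published outputs — rate constants, lifetimes, equilibration times, contact
energies — are stored in `reference` annotation blocks. These are read
exclusively by the comparison harness in `tautkin.report`; compute paths
never see them (a dedicated test strips all annotations and asserts that no
computed number changes).

Comparison tolerances, fixed by the precision of the printed inputs rather
than tuned to outcomes:

- **Time-scale identities** (τ₉₉.₉% and τ rebuilt from printed k_f, k_r):
  0.5 % relative. The printed rates carry three significant figures, so
  quantities recomputed from them can deviate from the printed time columns
  by up to half a percent; 11 of 13 rows agree to the last printed digit and
  the other two differ only through this input rounding.
- **Barrier bookkeeping** (ΔΔG_r = ΔΔG_f − ΔG): 0.01 kcal·mol⁻¹, the
  printed precision. Holds exactly for all 13 rows.
- **Full rate reproduction** (k_r from barrier + wavenumber): 15 % relative,
  and forward-rate decadic exponents within ±1 (forward rates span 10⁻⁵⁸ to
  10³ s⁻¹). The source does not state its constants convention, and
  two-decimal barriers alone move a rate by ~1.7 % per 0.01 kcal·mol⁻¹;
  under CODATA 2018 constants with the thermochemical calorie the largest
  observed deviation is ≈12.7 %.
- **Contact energies**: ±0.13 kcal·mol⁻¹ — half an ulp of a three-decimal ρ
  propagated through the steeper slope (0.0005 × 248.501 ≈ 0.12).

One published entry (6.78 kcal·mol⁻¹ at ρ = 0.026, the O3H⋯O4 row of the
TS of the 5↔5\*C8H2 transition) does not follow the OH⋯O formula, which
gives 3.12 there exactly as in the analogous rows of other conformers. The
fixture stores the printed value flagged `inconsistent`; the harness treats
it as an *expected mismatch* — it must fail to match, and it surfaces in the
anomaly list rather than being corrected or silently passed.

## Physical constants

CODATA 2018 exact SI values (k_B = 1.380649·10⁻²³ J·K⁻¹,
h = 6.62607015·10⁻³⁴ J·s, c = 2.99792458·10¹⁰ cm·s⁻¹,
R = 8.31446261815324 J·mol⁻¹·K⁻¹) with the thermochemical calorie
(4.184 J), giving k_BT/h = 6.2124·10¹² s⁻¹ and k_BT/hc = 207.22 cm⁻¹ at the
default temperature of 298.15 K. The whole convention is one injectable
frozen object (`ConstantsConvention`), so alternative conventions are a
constructor call, not a code change.

A harmonic-frequency scaling factor (default 0.9668, appropriate for the
B3LYP/6-311++G(d,p) frequencies behind the reference data) is available and
can optionally be applied to ν̃ᵢ before the tunneling factor
(`use_scaled_nu` / `--apply-scale-to-gamma`). It is **off** by default:
whether tabulated imaginary wavenumbers are raw harmonic or already scaled
values is generally not stated, so the choice is exposed rather than
guessed.

## Synthetic data

`tautkin.synth.generate` produces validated reaction sets with the
statistical footprint of the reference system: forward barriers uniform in
[0.9, 96.5] kcal·mol⁻¹, imaginary wavenumbers uniform in [800, 2200] cm⁻¹,
reaction energies a uniform fraction [0, 0.99] of the barrier (keeping
reverse barriers positive unless the exothermic-reverse option forces a
negative one), and per-class BCP densities inside the windows observed in
the reference tables (OH⋯O 0.020–0.060, strong CH₂⋯O 0.100–0.130, weak
CH⋯O/OH⋯C 0.010–0.022, vdW 0.010–0.030 a.u.). Only ranges are known for the
real system, so sampling is uniform; Gaussian noise appears solely in the
explicit `perturb_fixture` operation. A contaminant mode emits contacts with
Δρ ≤ 0 at a stated rate to exercise the validity filter.

Determinism: one global seed; record *i* draws from a substream derived as
`SeedSequence(seed, spawn_key=(i,))`, so draws are independent of insertion
order and prefixes of a larger set reproduce a smaller one exactly.

What the generator does **not** emulate: correlations between barrier height
and imaginary wavenumber, between contact geometry and density, or any
molecular-geometry realism. Passing tests on synthetic data demonstrate
numerical correctness and pipeline invariants (round-trips, inversion
recovery, classification logic), not chemical realism; fidelity to real
systems is checked against the embedded reference tables instead.

## Numerical choices and edge cases

- Negative barriers are computed, not rejected — the reference network
  contains a genuine ΔΔG_r = −1.20 kcal·mol⁻¹ step — and surface through
  the `barrierless_reverse` class.
- Rates are evaluated in double precision directly; the smallest reference
  forward rate (~10⁻⁵⁸ s⁻¹) is far above the underflow threshold.
  Barrier inversion −RT·ln(k/(Γ·k_BT/h)) recovers inputs to 1e-10
  kcal·mol⁻¹ across the full range.
- Pathway ranking sorts on the forward Gibbs activation barrier (an input),
  not on rates, so the ordering is independent of the constants convention;
  ties break lexicographically on the reaction name.
- Reaction and structure names exist in a display form (`1↔1*_O1H`) and an
  ASCII alias (`1__1s_O1H`); lookups normalize both, and underscores are
  ignored during matching so spellings with or without the subscript
  separator resolve identically.
- Emitted tables render floats at 3 significant figures by default
  (`--precision` overrides); reruns with the same configuration
  byte-reproduce the output files.

## Problem sizes

Everything here is desk-scale: the reference network has 13 reactions and
103 contacts, synthetic sets used in tests contain 1–20 reactions, and the
full test suite plus the acceptance script complete in a few seconds on one
CPU.

## Known limitations

- Wigner is a high-temperature, small-tunneling correction; for the largest
  tabulated imaginary wavenumbers (~2100 cm⁻¹) Γ ≈ 5.3 and the parabolic
  approximation is stretched — more elaborate tunneling models would change
  absolute rates but not the qualitative ordering.
- The two-state τ₉₉.₉% formula ignores coupling between reactions sharing a
  species; the network is analyzed step by step, not as a master equation.
- EML scoring is unavailable whenever V(r) is not supplied, which includes
  the entire embedded contact table; those rows carry published EML energies
  as annotations but cannot be recomputed from the stored descriptors.
- The empirical energy formulas are calibrations with their own scatter;
  the ±0.13 kcal·mol⁻¹ reproduction tolerance covers only the ρ rounding of
  the inputs, not the physical uncertainty of the calibrations.
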