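# tautkin

Kinetic and energetic analysis of intramolecular proton-transfer
tautomerization, built for quantum-chemistry workflows on flavonoids and
similar polyhydroxylated heterocycles. Quercetin
(3,3′,4′,5,7-pentahydroxyflavone) is the bundled reference system: its five
hydroxyl and several CH groups support a network of 13 single-proton-transfer
reactions between conformers, tautomers and ring-opened forms.

The package takes *post-electronic-structure* inputs — relative Gibbs/electronic
energies (kcal·mol⁻¹), transition-state imaginary wavenumbers (cm⁻¹), and
(3,−1) bond-critical-point descriptors from an Atoms-in-Molecules analysis —
and computes everything downstream. Producing those inputs (DFT optimization,
TS searches, IRC, AIM integration) is out of scope.

## What it computes

**Kinetics.** For each reversible step R ⇌ P over a single saddle point:

- Wigner tunneling factor  Γ = 1 + (1/24)·(h·c·ν̃ᵢ / k_BT)²
- Eyring rates  k_{f,r} = Γ·(k_BT/h)·exp(−ΔΔG_{f,r}/RT)
- reverse barrier  ΔΔG_r = ΔΔG_f − ΔG  (bookkeeping identity)
- equilibrium constant  K = exp(−ΔG/RT)
- product lifetime  τ = 1/k_r  and equilibration time
  τ₉₉.₉% = ln(10³)/(k_f + k_r)
- a dynamic-stability class: `barrierless_reverse` when ΔΔG_r ≤ 0,
  `dynamically_unstable` when τ is shorter than the period of the lowest
  torsional vibration, `stable` otherwise.

**Contact energetics.** Empirical energies of intramolecular H-bonds and
attractive van der Waals contacts from BCP descriptors:

- classical OH⋯O:  E = −3.09 + 239·ρ  (NBH formula)
- strong CH⋯O (> 10 kcal·mol⁻¹, e.g. HCH⋯O at a proton-transfer TS):
  E = 248.501·ρ − 0.367  (BYH formula)
- everything else (weak CH⋯O, OH⋯C, vdW O⋯O / C⋯O):  E = ½·|V(r)|
  (EML formula), when the local potential energy density is available.

A contact qualifies only if ρ > 0 and the Laplacian Δρ > 0 at the BCP.

Both reference tables of the quercetin study ship as embedded fixtures with
the published outputs stored as *reference annotations* that compute paths
never read — a comparison harness checks recomputed values against them.

## Worked example

```python
import tautkin as tk

rs = tk.table1_reaction_set()                  # the 13-reaction network
r = rs.get_reaction("1↔1*_O5H/O4H")            # O3H -> O4 proton transfer
res = tk.compute_kinetics(r)
print(f"gamma={res.gamma:.3f} k_f={res.k_forward:.3e} k_r={res.k_reverse:.3e} "
      f"tau999={res.tau_999:.3e} tau={res.tau_lifetime:.3e} {res.stability.value}")
```

prints

```
gamma=1.772 k_f=2.750e+03 k_r=8.344e+13 tau999=8.279e-14 tau=1.198e-14 barrierless_reverse
```

Reading: with ΔΔG_f = 13.10 and ΔG = 14.30 kcal·mol⁻¹ the reverse barrier is
−1.20 kcal·mol⁻¹, so the nominal product decays faster than any vibration
(τ ≈ 1.2·10⁻¹⁴ s) — the transfer is classified `barrierless_reverse`: this
tautomer is not a kinetically bounded species at 298.15 K.

The same pipeline from the shell:

```sh
tautkin fixtures --table 1 --out t1.json
tautkin compute  --input t1.json --out out/     # kinetics + comparison tables
tautkin rank     --input t1.json                # pathways by forward barrier
```

`rank` orders the 13 transitions by forward Gibbs activation barrier, from
13.10 kcal·mol⁻¹ (`1↔1*_O5H/O4H`, most probable) to 96.31 kcal·mol⁻¹
(`1↔1*_O1H`, the ring-opening C8H→O1 transfer, least probable).

Synthetic reaction sets for testing are generated with
`tautkin synth --seed 1 --n-reactions 10 --out synth.json` or
`tautkin.synth.generate(SynthSpec(...))`.

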