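# pfasbind

Fluorescence-titration binding analysis for protein–ligand interactions,
built around the human serum albumin (HSA) – PFAS system: quenching
mechanism inference, binding constants and thermodynamics, binding-site
assignment by competitive site markers, MM/GBSA decomposition validation,
and descriptor correlation — plus a forward simulator of titration spectra
with known ground truth.

## Who it is for

Anyone working up fluorescence quenching titrations of a protein against a
small-molecule ligand series: environmental toxicology (protein binding of
per-/polyfluoroalkyl substances and similar contaminants), drug–albumin
binding, or any 1:n static-quenching system measured at several
temperatures.

## The models

With F0 and F the fluorescence intensities without and with quencher at
concentration [Q]:

- **Stern–Volmer:** F0/F = 1 + Ksv[Q]; Kq = Ksv/τ0 with τ0 ≈ 10⁻⁸ s.
  Ksv falling with temperature, or Kq above the diffusion limit
  (~2×10¹⁰ L·mol⁻¹·s⁻¹), indicates static (complex-forming) quenching;
  rising Ksv indicates dynamic (collisional) quenching; both signatures
  together indicate mixed quenching.
- **Double-log binding model:** log((F0−F)/F) = log Kb + n log[Q], giving
  the binding constant Kb and apparent site number n.
- **Van't Hoff:** ln Kb = −ΔH/RT + ΔS/R across temperatures;
  ΔG = −RT ln Kb. The (ΔH, ΔS) sign pattern classifies the dominant
  interaction force (hydrophobic, hydrogen bond/van der Waals,
  electrostatic).
- **Site-marker displacement:** φ = (Kb − Kb′)/Kb × 100 for site markers of
  known albumin subdomains (warfarin → IIA, ibuprofen → IIIA, lidocaine →
  IB); the marker with maximal φ names the binding site.
- **MM/GBSA identity:** ΔG_bind = ΔE_vdw + ΔE_elec + ΔG_GB + ΔG_SA,
  validated against tabulated decompositions, plus Pearson correlation of
  binding constants against energy metrics and molecular descriptors.
- **Inner-filter correction:** F_corr = F_obs·10^((A_ex+A_em)/2) applied
  before any fit when absorbances are available.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from pfasbind import SimulationConfig, double_log_fit, simulate_study, thermodynamic_analysis

config = SimulationConfig(delta_h_kj_mol=-50.0, delta_s_j_mol_k=-63.5,
                          n_true=1.2, peak_bound_nm=337.0)
pairs = []
for series, truth in simulate_study(config):
    fit = double_log_fit(series)
    print(f"T={fit.temperature_K:.0f} K: Kb = {fit.kb:.4g} L/mol, "
          f"n = {fit.n_sites:.4f}, r^2 = {fit.r_squared:.6f}")
    pairs.append((fit.temperature_K, fit.kb))
r = thermodynamic_analysis(pairs)
print(f"dH = {r.delta_h_kj_mol:.2f} kJ/mol, dS = {r.delta_s_j_mol_k:.1f} "
      f"J/mol/K -> {r.force_class}")
```

prints

```
T=298 K: Kb = 2.802e+05 L/mol, n = 1.2000, r^2 = 1.000000
T=304 K: Kb = 1.882e+05 L/mol, n = 1.2000, r^2 = 1.000000
T=310 K: Kb = 1.283e+05 L/mol, n = 1.2000, r^2 = 1.000000
dH = -50.00 kJ/mol, dS = -63.5 J/mol/K -> hbond_vdw
```

— a noiseless three-temperature titration simulated from a chosen
(ΔH, ΔS) is inverted exactly: the per-temperature binding constants, the
enthalpy/entropy, and the force class (both signs negative → hydrogen
bonding / van der Waals) all match the generating truth.

The `examples/` directory has one short script per capability
(`quenching_mechanism.py`, `binding_thermodynamics.py`,
`site_competition.py`, `energy_decomposition.py`,
`simulate_and_recover.py`); each builds or loads a small input, runs the
analysis, and prints what the numbers mean. The published reference tables
for the six PFAS–HSA systems ship in `pfasbind.datasets`.

A thin CLI wraps the same calls:

```bash
pfasbind simulate --kb 1e5 --noise 0.01 --out-dir scratch/sim
pfasbind quench scratch/sim/*.csv
pfasbind affinity scratch/sim/*.csv
pfasbind report --config config.yaml --out-dir out/
```

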