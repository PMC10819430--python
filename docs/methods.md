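# Methods

This note documents the models behind `pfasbind`, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real spectra.

## The measurement model

A titration series records the intrinsic fluorescence of a protein (here
human serum albumin, HSA, excited at 275 nm and emitting around 337 nm from
its tryptophan/tyrosine residues) at a ladder of ligand concentrations
[Q] = 0, 3, …, 18 µM with the protein at 1 µM. The zero-ligand spectrum
provides the unquenched intensity F0. Two corrections/readings precede any
fit:

- **Inner-filter correction.** When the sample absorbs at the excitation or
  emission wavelength, the measured intensity is attenuated; the standard
  correction F_corr = F_obs · 10^((A_ex + A_em)/2) is applied wherever
  absorbances are supplied and silently skipped (with a log line) where they
  are not.
- **Intensity extraction.** Stern–Volmer theory assumes intensity at a fixed
  emission wavelength, so the default policy reads every spectrum at the
  peak wavelength of the zero-ligand spectrum (`fixed_reference`). Because
  the emission band of a protein–ligand complex often shifts as the bound
  fraction grows, a `per_spectrum_max` policy that tracks each spectrum's
  own maximum is provided; with a shifting band the fixed-wavelength reading
  convolves quenching with the shift and the per-spectrum maximum isolates
  the quenching amplitude.

## Quenching analysis (Stern–Volmer)

F0/F = 1 + Ksv[Q] is fitted by unweighted ordinary least squares over all
titration points; the zero-ligand point contributes its exact (0, 1) anchor,
which pins the intercept near the theoretical 1. Kq = Ksv/τ0 with the
customary unquenched lifetime τ0 = 10⁻⁸ s (configurable). The mechanism call
uses two classical facts: static (ground-state complex) quenching weakens on
heating, so Ksv falls with temperature, while collisional quenching
strengthens; and a Kq above the diffusion-controlled limit of about
2 × 10¹⁰ L·mol⁻¹·s⁻¹ (configurable) cannot be purely collisional. The
decision table is: decreasing → static; increasing with over-limit Kq →
mixed; increasing otherwise → dynamic; flat (relative tolerance 10⁻⁶, which
real data never triggers) or non-monotonic → static if over-limit, else
indeterminate.

## Binding constant and site number (double-log)

For static quenching by 1:n complexation, log₁₀((F0−F)/F) = log₁₀Kb +
n·log₁₀[Q]. OLS over the nonzero concentrations gives n as the slope and
Kb = 10^intercept. [Q] is the nominal total added concentration — the usual
approximation when ligand is dosed in large excess over protein; a
depletion-aware free-ligand model is deliberately out of scope. Points with
(F0−F)/F ≤ 0 (no quenching) raise a domain error rather than being clipped:
they indicate a data problem the analyst should see.

## Thermodynamics and interaction forces

ln Kb is linear in 1/T (Van't Hoff): ΔH = −R·slope, ΔS = R·intercept, with
R = 8.314 J·mol⁻¹·K⁻¹. ΔG at each temperature is reported as −RT ln Kb
rather than ΔH − TΔS: with three temperatures the former tracks the measured
constants exactly while the latter compounds regression error (on the
shipped reference table the two disagree by ~1 kJ/mol). The
Ross–Subramanian sign rules classify the dominant force, with precedence:
|ΔH| ≤ 10 kJ/mol (configurable) and ΔS > 0 → electrostatic; (+,+) →
hydrophobic; (−,−) → hydrogen bond / van der Waals; (−,+) → electrostatic;
anything else → undetermined. The near-zero band has no canonical value;
10 kJ/mol is roughly thermal-energy-scale at several RT and is exposed as
configuration.

## Site-marker competition

φ = (Kb_free − Kb_probe)/Kb_free × 100 measures how much a site marker
suppresses the ligand's binding constant. The marker map defaults to
warfarin → IIA, ibuprofen → IIIA, lidocaine → IB (lidocaine's subdomain is
reported inconsistently in the literature — IIB and IB both appear; the map
is configuration, and reassigning it changes only the label, not the
arithmetic). The marker with maximal φ names the subdomain; "dominant"
means φ ≥ 80% (no canonical threshold exists; all clearly site-sharing
reference cases sit above 93%, all clearly non-sharing ones below 50%).
Negative φ (enhancement) is allowed and logged, not an error. Note the
displacement formula is sometimes printed with the probe-bound constant in
the denominator and a ×10 factor; the shipped reference percentages are
consistent with the free-constant denominator and ×100, which is what this
package computes.

## MM/GBSA validation and correlation

The end-point decomposition ΔG_bind = ΔE_vdw + ΔE_elec + ΔG_GB + ΔG_SA is
an identity, so tabulated components must sum to the stated total within the
table's printed precision (0.01 kcal/mol); mismatches warn with the residual
and never abort. Ranking is ascending ΔG_bind (tightest first) with
alphabetical tie-break. Correlations are plain Pearson product–moment
coefficients on the raw metric values (not log-transformed — the reference
coefficients reproduce on raw values; a log option can be had by
transforming the table before the call), pairwise-complete over missing
entries, with both the signed matrix and the magnitude view returned since
inverse relationships between a binding constant and a (negative) energy
appear with positive magnitude in common reporting. A constant metric has
no defined correlation and is reported as missing, never zero.

## The synthetic-data generator

The simulator composes exactly the physics the fitters invert:
F(Q) = F0/(1 + Kb·Qⁿ) for the band height (with n = 1 this is also the
linear Stern–Volmer law), a Gaussian emission band whose centre slides from
the free-protein peak (default 337 nm) toward the bound-form peak (default
317 nm, the largest blue shift observed in the reference system) in
proportion to the bound fraction, optional inner-filter attenuation by
10^−((A_ex+A_em)/2), and multiplicative Gaussian noise applied last from a
`numpy` `default_rng` seeded per (seed, temperature). Kb's temperature
dependence can be generated from a (ΔH, ΔS) pair through the Van't Hoff
relation. Defaults mirror the reference assay: 0–18 µM in 3 µM steps,
298/304/310 K, emission grid 275–500 nm at 1 nm, F0 = 1000 a.u., bandwidth
(Gaussian σ) 25 nm — a realistic tryptophan emission width.

What the generator does **not** emulate: Raman/Rayleigh scatter, baseline
drift, instrument response, detector saturation, ligand depletion,
excited-state kinetics (FRET, transient quenching), or correlated noise.
Passing recovery tests therefore demonstrate the estimators invert the
stated model, not that they are robust to every artefact of real spectra.

## Numerical choices and known limitations

- **Noiseless identities.** With the band shift disabled
  (`peak_bound_nm == peak_free_nm`) the generator is the exact inverse of
  the fits, and all three regressions recover their parameters to ≤ 10⁻⁹
  relative error. With the shift enabled, a fixed-wavelength reading mixes
  shift into the apparent quenching by design — the tests exercising exact
  inversion use the no-shift mode.
- **Conditioning at weak binding.** When Kb·Q_max ≪ 1 the quenched signal
  F0−F is a small difference of large numbers; float64 cancellation caps
  noiseless recovery near 10⁻³ relative at the weakest tested corner
  (Kb = 100 L/mol, n = 2.5), and under 1% noise the per-replicate Kb scatter
  grows to a geometric SD of ~3× (versus ~1.3× at Kb ≈ 10⁵ L/mol, where the
  0–18 µM design actually resolves the constant). The log-intercept sits
  ~5 decades outside the sampled concentration window, so weak-binding Kb
  values from this design carry large uncertainties — true of the method,
  not just the implementation.
- **Noisy reference spectra.** The default reference wavelength is the
  argmax of the zero-ligand spectrum. On noisy data that argmax selects the
  most positive noise excursion near the peak, inflating F0 by a few percent
  and biasing Kb; when the band centre is known (as in simulations or a
  well-characterised assay) pass `reference_nm` explicitly. Stochastic tests
  do so.
- **Peak refinement.** Peak positions default to the grid argmax
  (bit-reproducible); 3-point parabolic interpolation is opt-in and places a
  1 nm-sampled Gaussian centre to better than 0.1 nm.
- **Shift classification tolerance** is 0.5 nm, absorbing grid resolution.
- **Test problem sizes.** Stochastic bands use 500 replicates (single-
  temperature Kb recovery) and 100 replicates (end-to-end ΔH recovery),
  7-point titrations each; both complete in seconds and give medians stable
  to a few percent. The end-to-end band is asserted at a mid-affinity
  ground truth (Kb ≈ 1–3 × 10⁵ L/mol) for the design-resolution reason
  above; the weak-binding regime is pinned by a dedicated scatter test
  instead.

## Reference tables

The `datasets` module ships the published per-temperature binding constants,
competition constants, MM/GBSA components and docking energies for the six
PFAS–HSA systems as plain DataFrames. Three rows of the binding table print
mutually inconsistent Kb/ΔG values (flagged in
`datasets.DG_INCONSISTENT_ROWS`; the PFOA 304/310 K Kb entries are
demonstrable typos — the Kb implied by the ΔG column reproduces the
published ΔH/ΔS within 1%, the printed Kb does not), and the HFPO-TA and
PFOA competition blocks are internally inconsistent (flagged via the
`consistent` column). Derived quantities are always recomputed from these
inputs, never read back from the reported columns.
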