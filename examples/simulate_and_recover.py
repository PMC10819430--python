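"""Round trip: simulate a noisy titration, write it to disk, read it back,
and recover the generating parameters.

Demonstrates the fixture CSV dialect, inner-filter attenuation/correction,
and the double-log fit's recovery of the ground truth.
"""

import tempfile
from pathlib import Path

from pfasbind import SimulationConfig, double_log_fit, peak_metrics, read_fixture, simulate_titration, write_fixture

absorbances = [0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12]
config = SimulationConfig(
    kb_true=2.27e5,
    n_true=1.26,
    noise_sd_rel=0.01,
    seed=42,
    ife_a_ex=absorbances,
    ife_a_em=absorbances,
)
series, truth = simulate_titration(config)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "titration.csv"
    write_fixture(series, truth, path)
    back, truth_back = read_fixture(path)
    assert truth_back == truth

ref = back.points[0].spectrum
for point in back.points[1:]:
    m = peak_metrics(point.spectrum, ref, refine=True)
    print(
        f"[Q] = {point.ligand_conc * 1e6:4.0f} uM: peak {m.lambda_max_nm:6.1f} nm "
        f"({m.shift_class:4s} {m.delta_lambda_nm:+5.1f} nm), quench {m.quench_pct:5.1f}%"
    )

# The band shifts while it quenches, so a fixed-wavelength reading would
# conflate the two effects; tracking each spectrum's own maximum isolates
# the quenching amplitude.
fit = double_log_fit(back, policy="per_spectrum_max")
print(
    f"\nrecovered Kb = {fit.kb:.3g} L/mol (truth {truth.kb:.3g}), "
    f"n = {fit.n_sites:.3f} (truth {truth.n_sites}), r^2 = {fit.r_squared:.5f}"
)

# The band blue-shifts toward the bound-form peak and quenches as the bound
# fraction grows.  A single 1%-noise replicate recovers n well but scatters
# tens of percent in Kb (the intercept extrapolates far beyond the sampled
# concentration window); medians over many replicates land within ~1%.
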