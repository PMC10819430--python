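"""Van't Hoff thermodynamics and interaction-force classification.

ln Kb is linear in 1/T with slope -dH/R and intercept dS/R; the Gibbs energy
at each temperature is reported as -RT ln Kb.  The sign pattern of (dH, dS)
classifies the dominant interaction force (Ross-Subramanian rules):
(+,+) hydrophobic, (-,-) hydrogen bond / van der Waals, dH near zero or
negative with dS > 0 electrostatic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spectra import ValidationError

__all__ = [
    "R_J_MOL_K",
    "ThermoResult",
    "gibbs_from_kb",
    "vant_hoff_fit",
    "classify_forces",
    "thermodynamic_analysis",
]

#: Ideal gas constant, J mol^-1 K^-1.
R_J_MOL_K = 8.314

#: Default |dH| band (kJ/mol) treated as "close to zero" by classify_forces.
DEFAULT_NEAR_ZERO_KJ_MOL = 10.0


@dataclass(frozen=True)
class ThermoResult:
    delta_h_kj_mol: float
    delta_s_j_mol_k: float
    r_squared: float
    delta_g_by_temp: Mapping[float, float]  # T (K) -> dG (kJ/mol), via -RT ln Kb
    force_class: str  # hydrophobic | hbond_vdw | electrostatic | undetermined


def gibbs_from_kb(kb: float, temperature_K: float) -> float:
    """Gibbs energy of binding, dG = -R T ln(Kb), in kJ/mol."""
    if kb <= 0 or temperature_K <= 0:
        raise ValueError("kb and temperature must be positive")
    return -R_J_MOL_K * temperature_K * math.log(kb) / 1000.0


def vant_hoff_fit(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """OLS of ln Kb on 1/T; returns (dH in kJ/mol, dS in J/mol/K, r^2).

    dH = -R * slope, dS = R * intercept.  With only two points r^2 is 1 by
    construction; with the usual three it quantifies Van't Hoff linearity.
    """
    if len(pairs) < 2:
        raise ValidationError("need >= 2 (temperature, kb) pairs")
    temps = np.array([t for t, _ in pairs], dtype=float)
    kbs = np.array([k for _, k in pairs], dtype=float)
    if np.any(temps <= 0) or np.any(kbs <= 0):
        raise ValueError("temperatures and kb values must be positive")
    if np.unique(temps).size < 2:
        raise ValidationError("need >= 2 distinct temperatures")
    res = stats.linregress(1.0 / temps, np.log(kbs))
    delta_h = -R_J_MOL_K * float(res.slope) / 1000.0
    delta_s = R_J_MOL_K * float(res.intercept)
    return delta_h, delta_s, float(res.rvalue**2)


def classify_forces(
    delta_h_kj_mol: float,
    delta_s_j_mol_k: float,
    near_zero_kj_mol: float = DEFAULT_NEAR_ZERO_KJ_MOL,
) -> str:
    """Dominant interaction force from the signs of dH and dS.

    Precedence: (1) |dH| <= near_zero with dS > 0 -> electrostatic;
    (2) dH > 0, dS > 0 -> hydrophobic; (3) dH < 0, dS < 0 -> hydrogen
    bond / van der Waals; (4) dH < 0, dS > 0 -> electrostatic; otherwise
    undetermined.
    """
    if not (math.isfinite(delta_h_kj_mol) and math.isfinite(delta_s_j_mol_k)):
        raise ValueError("dH and dS must be finite")
    if abs(delta_h_kj_mol) <= near_zero_kj_mol and delta_s_j_mol_k > 0:
        return "electrostatic"
    if delta_h_kj_mol > 0 and delta_s_j_mol_k > 0:
        return "hydrophobic"
    if delta_h_kj_mol < 0 and delta_s_j_mol_k < 0:
        return "hbond_vdw"
    if delta_h_kj_mol < 0 and delta_s_j_mol_k > 0:
        return "electrostatic"
    return "undetermined"


def thermodynamic_analysis(
    pairs: Sequence[tuple[float, float]],
    near_zero_kj_mol: float = DEFAULT_NEAR_ZERO_KJ_MOL,
) -> ThermoResult:
    """Full thermodynamic work-up from per-temperature binding constants.

    dG at each temperature is computed directly as -RT ln Kb rather than as
    dH - T dS: with only a few temperatures the former tracks the measured
    constants exactly while the latter compounds the regression error.
    """
    delta_h, delta_s, r2 = vant_hoff_fit(pairs)
    dg = {float(t): gibbs_from_kb(k, t) for t, k in pairs}
    return ThermoResult(
        delta_h_kj_mol=delta_h,
        delta_s_j_mol_k=delta_s,
        r_squared=r2,
        delta_g_by_temp=dg,
        force_class=classify_forces(delta_h, delta_s, near_zero_kj_mol),
    )
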