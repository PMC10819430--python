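"""Stern-Volmer quenching analysis and mechanism classification.

The Stern-Volmer relation F0/F = 1 + Ksv[Q] is fitted per temperature; the
bimolecular quenching rate constant Kq = Ksv/tau0 (tau0 ~ 1e-8 s for the
unquenched fluorophore) is compared with the diffusion-controlled limit
(~2e10 L mol^-1 s^-1), and the temperature trend of Ksv separates static
(ground-state complex) from dynamic (collisional) quenching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .spectra import TitrationSeries, ValidationError, series_intensities

__all__ = ["SVFit", "MechanismCall", "stern_volmer_fit", "classify_mechanism", "DIFFUSION_LIMIT"]

#: Maximum diffusion-controlled quenching rate constant, L mol^-1 s^-1.
DIFFUSION_LIMIT = 2.0e10

#: Default unquenched fluorophore lifetime, s.
DEFAULT_TAU0_S = 1e-8


@dataclass(frozen=True)
class SVFit:
    """Per-temperature Stern-Volmer regression result."""

    temperature_K: float
    ksv: float  # L mol^-1
    ksv_stderr: float
    kq: float  # L mol^-1 s^-1 == ksv / tau0
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class MechanismCall:
    """Static/dynamic/mixed verdict from multi-temperature Stern-Volmer fits."""

    mechanism: str  # static | dynamic | mixed | indeterminate
    trend: str  # decreasing | increasing | non_monotonic | flat
    kq_exceeds_diffusion_limit: bool
    evidence: str


def stern_volmer_fit(
    series: TitrationSeries,
    tau0_s: float = DEFAULT_TAU0_S,
    policy: str = "fixed_reference",
    reference_nm: Optional[float] = None,
) -> SVFit:
    """Fit F0/F = 1 + Ksv[Q] by ordinary least squares.

    All titration points enter the regression, the zero-ligand point
    contributing its exact (0, 1) anchor; the slope is Ksv and Kq = Ksv/tau0.
    """
    pairs = series_intensities(series, policy=policy, reference_nm=reference_nm)
    if len(pairs) < 3:
        raise ValidationError(f"need >= 3 titration points, got {len(pairs)}")
    q = np.array([c for c, _ in pairs])
    f = np.array([v for _, v in pairs])
    if np.any(f <= 0):
        bad = q[f <= 0]
        raise ValueError(f"non-positive fluorescence intensity at concentration(s) {bad}")
    f0 = f[q == 0.0][0]
    ratio = f0 / f
    res = stats.linregress(q, ratio)
    ksv = float(res.slope)
    return SVFit(
        temperature_K=series.temperature_K,
        ksv=ksv,
        ksv_stderr=float(res.stderr),
        kq=ksv / tau0_s,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pairs),
    )


def sv_fit_from_constants(
    temperature_K: float, ksv: float, tau0_s: float = DEFAULT_TAU0_S, n_points: int = 7
) -> SVFit:
    """Wrap an externally tabulated Ksv as an SVFit (for mechanism calls on
    published constants where the raw spectra are unavailable)."""
    return SVFit(
        temperature_K=temperature_K,
        ksv=ksv,
        ksv_stderr=float("nan"),
        kq=ksv / tau0_s,
        intercept=1.0,
        r_squared=float("nan"),
        n_points=n_points,
    )


def _trend(ksv: np.ndarray, rel_tol: float) -> str:
    diffs = np.diff(ksv)
    scale = np.maximum(np.abs(ksv[:-1]), np.abs(ksv[1:]))
    flat = np.abs(diffs) <= rel_tol * np.where(scale > 0, scale, 1.0)
    if np.all(flat):
        return "flat"
    if np.all(diffs < 0):
        return "decreasing"
    if np.all(diffs > 0):
        return "increasing"
    return "non_monotonic"


def classify_mechanism(
    fits: Sequence[SVFit],
    kq_limit: float = DIFFUSION_LIMIT,
    flat_rel_tol: float = 1e-6,
) -> MechanismCall:
    """Classify the quenching mechanism from Ksv's temperature dependence.

    Decision table (fits ordered by temperature):

    =============  =====================  =============
    Ksv trend      max Kq vs kq_limit     mechanism
    =============  =====================  =============
    decreasing     (any)                  static
    increasing     above                  mixed
    increasing     at or below            dynamic
    flat/other     above                  static
    flat/other     at or below            indeterminate
    =============  =====================  =============

    A falling Ksv means heating dissociates the ground-state complex (static
    quenching); a rising Ksv means faster collisional quenching (dynamic),
    but a Kq above the diffusion limit proves complexation also occurs, hence
    "mixed".
    """
    if len({f.temperature_K for f in fits}) < 2:
        raise ValidationError("mechanism classification needs fits at >= 2 distinct temperatures")
    fits = sorted(fits, key=lambda f: f.temperature_K)
    ksv = np.array([f.ksv for f in fits])
    temps = [f.temperature_K for f in fits]
    trend = _trend(ksv, flat_rel_tol)
    kq_max = max(f.kq for f in fits)
    exceeds = kq_max > kq_limit
    if trend == "decreasing":
        mechanism = "static"
    elif trend == "increasing":
        mechanism = "mixed" if exceeds else "dynamic"
    else:
        mechanism = "static" if exceeds else "indeterminate"
    evidence = (
        f"Ksv {trend} over T={temps} K (values {ksv.tolist()} L/mol); "
        f"max Kq = {kq_max:.3g} L/mol/s is "
        f"{'above' if exceeds else 'not above'} the diffusion limit {kq_limit:.3g}"
    )
    return MechanismCall(
        mechanism=mechanism,
        trend=trend,
        kq_exceeds_diffusion_limit=exceeds,
        evidence=evidence,
    )
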