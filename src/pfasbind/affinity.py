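"""Binding constant and binding-site number from the double-logarithmic plot.

For static quenching by 1:n complex formation, log((F0-F)/F) is linear in
log[Q] with slope n (apparent number of binding sites) and intercept log Kb.
Base-10 logarithms throughout.  [Q] is the nominal (total) added ligand
concentration, not the free concentration — a standard approximation for
titrations with ligand in large excess over protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .spectra import TitrationSeries, ValidationError, series_intensities

__all__ = ["BindingFit", "double_log_fit"]


@dataclass(frozen=True)
class BindingFit:
    """Per-temperature double-log regression result."""

    temperature_K: float
    kb: float  # L mol^-1
    n_sites: float
    kb_stderr_log10: float
    n_stderr: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.kb <= 0 or self.n_sites <= 0:
            raise ValidationError("kb and n_sites must be positive")


def double_log_fit(
    series: TitrationSeries,
    policy: str = "fixed_reference",
    reference_nm: Optional[float] = None,
) -> BindingFit:
    """Fit log10((F0-F)/F) = log10(Kb) + n*log10([Q]) by OLS.

    Only nonzero concentrations enter (log 0 is undefined); every such point
    must show quenching (F < F0), otherwise the data cannot support the model
    and a domain error is raised rather than silently dropping points.
    """
    pairs = series_intensities(series, policy=policy, reference_nm=reference_nm)
    f0 = next(v for c, v in pairs if c == 0.0)
    nonzero = [(c, v) for c, v in pairs if c > 0.0]
    if len(nonzero) < 3:
        raise ValidationError(f"need >= 3 nonzero-concentration points, got {len(nonzero)}")
    for c, v in nonzero:
        if v >= f0:
            raise ValueError(f"no quenching at concentration {c} mol/L (F >= F0)")
        if v <= 0:
            raise ValueError(f"non-positive intensity at concentration {c} mol/L")
    q = np.array([c for c, _ in nonzero])
    f = np.array([v for _, v in nonzero])
    x = np.log10(q)
    y = np.log10((f0 - f) / f)
    res = stats.linregress(x, y)
    return BindingFit(
        temperature_K=series.temperature_K,
        kb=float(10.0**res.intercept),
        n_sites=float(res.slope),
        kb_stderr_log10=float(res.intercept_stderr),
        n_stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
    )
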