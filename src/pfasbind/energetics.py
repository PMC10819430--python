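"""MM/GBSA decomposition-table validation, affinity ranking, and metric
correlation.

An MM/GBSA end-point estimate decomposes the binding free energy as
dG_bind = dE_vdw + dE_elec + dG_GB + dG_SA (gas-phase van der Waals and
electrostatics plus polar and non-polar solvation).  This module validates
tabulated decompositions against that identity, ranks systems by affinity,
and correlates heterogeneous per-compound metrics (binding constants,
energies, quantum-chemical descriptors) with a Pearson matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .spectra import FormatError, ValidationError

__all__ = [
    "EnergyDecomposition",
    "MetricTable",
    "read_gbsa_table",
    "total_binding_energy",
    "rank_by_affinity",
    "pearson_matrix",
    "CONSISTENCY_TOL_KCAL",
]

log = logging.getLogger(__name__)

#: Allowed |component sum - printed dG_bind|, matching 2-decimal tables.
CONSISTENCY_TOL_KCAL = 0.01

_GBSA_COLUMNS = ("system", "de_vdw", "de_elec", "dg_gb", "dg_sa")


@dataclass(frozen=True)
class EnergyDecomposition:
    """One system's MM/GBSA components (kcal/mol)."""

    system: str
    de_vdw: float
    de_elec: float
    dg_gb: float
    dg_sa: float
    dg_bind: Optional[float] = None


@dataclass(frozen=True)
class MetricTable:
    """Per-compound metric vectors for correlation analysis."""

    compounds: tuple[str, ...]
    metrics: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        n = len(self.compounds)
        for name, vec in self.metrics.items():
            if len(vec) != n:
                raise ValidationError(
                    f"metric {name!r} has {len(vec)} values for {n} compounds"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(self.metrics), index=list(self.compounds), dtype=float)


def total_binding_energy(d: EnergyDecomposition) -> float:
    """Sum of the four MM/GBSA components, kcal/mol."""
    return d.de_vdw + d.de_elec + d.dg_gb + d.dg_sa


def validate_decomposition(d: EnergyDecomposition, tol: float = CONSISTENCY_TOL_KCAL) -> float:
    """Residual between the component sum and a stated dG_bind (0 if absent).

    Residuals above ``tol`` are logged as warnings, never silently accepted.
    """
    if d.dg_bind is None:
        return 0.0
    residual = total_binding_energy(d) - d.dg_bind
    if abs(residual) > tol:
        log.warning(
            "decomposition for %s inconsistent: components sum to %.2f but dG_bind = %.2f "
            "(residual %.3f kcal/mol)",
            d.system,
            total_binding_energy(d),
            d.dg_bind,
            residual,
        )
    return residual


def read_gbsa_table(path) -> list[EnergyDecomposition]:
    """Read an MM/GBSA component CSV (system, de_vdw, de_elec, dg_gb, dg_sa[, dg_bind]).

    A missing dg_bind column (or cell) is filled with the component sum;
    stated values are validated against the sum with a warning on mismatch.
    """
    df = pd.read_csv(path, comment="#")
    for col in _GBSA_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"GBSA CSV missing required column {col!r}")
    if df.empty:
        raise ValidationError("GBSA table contains no records")
    records = []
    for _, row in df.iterrows():
        dg_bind = None
        if "dg_bind" in df.columns and pd.notna(row["dg_bind"]):
            dg_bind = float(row["dg_bind"])
        d = EnergyDecomposition(
            system=str(row["system"]),
            de_vdw=float(row["de_vdw"]),
            de_elec=float(row["de_elec"]),
            dg_gb=float(row["dg_gb"]),
            dg_sa=float(row["dg_sa"]),
            dg_bind=dg_bind,
        )
        validate_decomposition(d)
        if d.dg_bind is None:
            d = EnergyDecomposition(
                system=d.system,
                de_vdw=d.de_vdw,
                de_elec=d.de_elec,
                dg_gb=d.dg_gb,
                dg_sa=d.dg_sa,
                dg_bind=total_binding_energy(d),
            )
        records.append(d)
    return records


def rank_by_affinity(records: Sequence[EnergyDecomposition]) -> list[tuple[str, float]]:
    """Systems ordered by binding free energy, most negative (tightest) first.

    Stable alphabetical tie-break on the system name.  Records without a
    stated dG_bind are ranked on their component sum.
    """
    if not records:
        raise ValidationError("need at least one record to rank")
    keyed = [
        (r.system, r.dg_bind if r.dg_bind is not None else total_binding_energy(r))
        for r in records
    ]
    return sorted(keyed, key=lambda kv: (kv[1], kv[0]))


def pearson_matrix(table: MetricTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix across metrics, pairwise-complete.

    Returns ``(signed, magnitude)`` DataFrames indexed by metric name.  A
    constant metric has no defined correlation; its row/column is NaN
    (missing), never coerced to zero.
    """
    if len(table.compounds) < 3:
        raise ValidationError("correlation needs >= 3 compounds")
    df = table.to_frame()
    for name in df.columns:
        col = df[name].dropna()
        if col.nunique() < 2:
            log.warning("metric %r is constant; correlations reported as missing", name)
    signed = df.corr(method="pearson", min_periods=3)
    # wipe constant metrics explicitly (pandas already yields NaN, incl. diagonal)
    return signed, signed.abs()


def metric_table_from_frame(df: pd.DataFrame, compound_col: str = "compound") -> MetricTable:
    """Build a MetricTable from a wide CSV frame (one row per compound)."""
    if compound_col not in df.columns:
        raise FormatError(f"metrics CSV missing compound column {compound_col!r}")
    compounds = tuple(str(c) for c in df[compound_col])
    metrics = {
        str(col): df[col].to_numpy(dtype=float)
        for col in df.columns
        if col != compound_col
    }
    if len(metrics) < 2:
        raise ValidationError("need at least two metric columns to correlate")
    return MetricTable(compounds=compounds, metrics=metrics)
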