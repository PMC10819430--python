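"""Forward simulator of multi-temperature fluorescence titration experiments.

The simulator composes the same physics the fitting modules invert, so every
fit has an exact ground truth: static quenching of a single emission band by
1:n complexation, F(Q) = F0 / (1 + Kb * Q**n) — the exact inverse of the
double-log fit, and with n = 1 also of the linear Stern-Volmer relation —
with the band centre sliding from the free-protein peak toward the bound-form
peak in proportion to the bound fraction b(Q) = Kb Q**n / (1 + Kb Q**n)
(the blue shift seen on ligand binding), optional inner-filter attenuation
by 10**-((A_ex+A_em)/2), and multiplicative Gaussian noise applied last.

Kb's temperature dependence can be generated from a (dH, dS) pair via the
Van't Hoff relation, closing the loop for thermodynamic recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectra import (
    EmissionSpectrum,
    TitrationPoint,
    TitrationSeries,
    ValidationError,
)
from .thermo import R_J_MOL_K

__all__ = ["SimulationConfig", "GroundTruth", "simulate_titration", "simulate_study", "write_fixture", "read_fixture"]

#: Study-condition defaults: 0-18 uM ligand in 3 uM steps, three temperatures.
DEFAULT_CONCENTRATIONS_M = (0.0, 3e-6, 6e-6, 9e-6, 12e-6, 15e-6, 18e-6)
DEFAULT_TEMPERATURES_K = (298.0, 304.0, 310.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a simulated titration study.

    Either ``kb_true`` (one constant for all temperatures) or a
    ``(delta_h_kj_mol, delta_s_j_mol_k)`` pair (Kb per temperature via the
    Van't Hoff relation) must be given.  Defaults mirror the standard assay:
    1 uM protein, 275 nm excitation, emission 275-500 nm at 1 nm, free-peak
    337 nm shifting to 317 nm when bound, 25 nm bandwidth (Gaussian sigma).
    """

    kb_true: Optional[float] = None
    delta_h_kj_mol: Optional[float] = None
    delta_s_j_mol_k: Optional[float] = None
    n_true: float = 1.0
    f0: float = 1000.0
    peak_free_nm: float = 337.0
    peak_bound_nm: float = 317.0
    bandwidth_nm: float = 25.0
    concentrations_M: Sequence[float] = DEFAULT_CONCENTRATIONS_M
    temperatures_K: Sequence[float] = DEFAULT_TEMPERATURES_K
    wavelength_min_nm: float = 275.0
    wavelength_max_nm: float = 500.0
    wavelength_step_nm: float = 1.0
    ife_a_ex: Optional[Sequence[float]] = None  # per-concentration absorbances
    ife_a_em: Optional[Sequence[float]] = None
    noise_sd_rel: float = 0.0
    seed: int = 0
    series_id: str = "sim"

    def __post_init__(self) -> None:
        if self.kb_true is None and (self.delta_h_kj_mol is None or self.delta_s_j_mol_k is None):
            raise ValidationError("give kb_true or both delta_h_kj_mol and delta_s_j_mol_k")
        if self.kb_true is not None and self.kb_true <= 0:
            raise ValidationError("kb_true must be positive")
        if self.n_true <= 0 or self.f0 <= 0 or self.bandwidth_nm <= 0:
            raise ValidationError("n_true, f0 and bandwidth must be positive")
        concs = list(self.concentrations_M)
        if min(concs) < 0 or 0.0 not in concs:
            raise ValidationError("concentrations must be non-negative and include 0")
        if self.noise_sd_rel < 0:
            raise ValidationError("noise_sd_rel must be >= 0")
        for a in (self.ife_a_ex, self.ife_a_em):
            if a is not None and len(a) != len(concs):
                raise ValidationError("IFE absorbance sequences must match concentrations")
        if (self.ife_a_ex is None) != (self.ife_a_em is None):
            raise ValidationError("ife_a_ex and ife_a_em must be supplied together")

    def kb_at(self, temperature_K: float) -> float:
        """Ground-truth Kb at a temperature (Van't Hoff if dH/dS given)."""
        if self.kb_true is not None:
            return self.kb_true
        return math.exp(
            -self.delta_h_kj_mol * 1000.0 / (R_J_MOL_K * temperature_K)
            + self.delta_s_j_mol_k / R_J_MOL_K
        )


@dataclass(frozen=True)
class GroundTruth:
    """The generating parameters echoed next to an emitted series."""

    series_id: str
    temperature_K: float
    kb: float
    n_sites: float
    f0: float
    peak_free_nm: float
    peak_bound_nm: float
    bandwidth_nm: float
    noise_sd_rel: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _rng_for(config: SimulationConfig, temperature_K: float) -> np.random.Generator:
    # independent, reproducible stream per (seed, temperature)
    return np.random.default_rng([config.seed, int(round(temperature_K * 1000))])


def simulate_titration(
    config: SimulationConfig, temperature_K: Optional[float] = None
) -> tuple[TitrationSeries, GroundTruth]:
    """Simulate one titration series at one temperature.

    The zero-ligand point carries intensity exactly ``f0`` at exactly
    ``peak_free_nm`` (before noise); peak intensity falls and the band centre
    shifts monotonically toward ``peak_bound_nm`` as concentration rises.
    """
    if temperature_K is None:
        temperature_K = float(config.temperatures_K[0])
    kb = config.kb_at(temperature_K)
    wl = np.arange(
        config.wavelength_min_nm,
        config.wavelength_max_nm + config.wavelength_step_nm / 2,
        config.wavelength_step_nm,
    )
    rng = _rng_for(config, temperature_K)
    points = []
    concs = sorted(config.concentrations_M)
    for i, q in enumerate(concs):
        kqn = kb * q**config.n_true
        height = config.f0 / (1.0 + kqn)
        bound_frac = kqn / (1.0 + kqn)
        centre = config.peak_free_nm + (config.peak_bound_nm - config.peak_free_nm) * bound_frac
        intensities = height * np.exp(-0.5 * ((wl - centre) / config.bandwidth_nm) ** 2)
        a_ex = a_em = None
        if config.ife_a_ex is not None:
            idx = list(config.concentrations_M).index(q)
            a_ex = float(config.ife_a_ex[idx])
            a_em = float(config.ife_a_em[idx])
            intensities = intensities / 10.0 ** ((a_ex + a_em) / 2.0)
        if config.noise_sd_rel > 0:
            intensities = intensities * (
                1.0 + config.noise_sd_rel * rng.standard_normal(intensities.size)
            )
        points.append(
            TitrationPoint(
                ligand_conc=float(q),
                spectrum=EmissionSpectrum(wl, intensities),
                a_ex=a_ex,
                a_em=a_em,
            )
        )
    series_id = f"{config.series_id}_{temperature_K:g}K"
    series = TitrationSeries(
        series_id=series_id,
        temperature_K=float(temperature_K),
        points=tuple(points),
    )
    truth = GroundTruth(
        series_id=series_id,
        temperature_K=float(temperature_K),
        kb=kb,
        n_sites=config.n_true,
        f0=config.f0,
        peak_free_nm=config.peak_free_nm,
        peak_bound_nm=config.peak_bound_nm,
        bandwidth_nm=config.bandwidth_nm,
        noise_sd_rel=config.noise_sd_rel,
        seed=config.seed,
    )
    return series, truth


def simulate_study(config: SimulationConfig) -> list[tuple[TitrationSeries, GroundTruth]]:
    """Simulate the full multi-temperature study (one series per temperature)."""
    return [simulate_titration(config, t) for t in config.temperatures_K]


def write_fixture(series: TitrationSeries, truth: GroundTruth, path) -> None:
    """Write a titration series plus its ground truth to a fixture CSV.

    The ground truth travels in a commented header line; the body is the
    standard titration CSV dialect, numbers at 12 significant digits so a
    read-back equals the in-memory series to that precision.
    """
    rows = []
    for point in series.points:
        for w, it in zip(point.spectrum.wavelengths_nm, point.spectrum.intensities):
            rows.append(
                (
                    series.series_id,
                    series.temperature_K,
                    point.ligand_conc,
                    w,
                    it,
                    point.a_ex if point.a_ex is not None else "",
                    point.a_em if point.a_em is not None else "",
                )
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ground_truth: {truth.to_json()}\n")
        fh.write("series_id,temperature_K,ligand_conc_M,wavelength_nm,intensity,a_ex,a_em\n")
        for sid, t, q, w, it, aex, aem in rows:
            aex_s = f"{aex:.12g}" if aex != "" else ""
            aem_s = f"{aem:.12g}" if aem != "" else ""
            fh.write(f"{sid},{t:.12g},{q:.12g},{w:.12g},{it:.12g},{aex_s},{aem_s}\n")


def read_fixture(path) -> tuple[TitrationSeries, Optional[GroundTruth]]:
    """Read a fixture CSV back into (series, ground truth or None)."""
    from .spectra import read_titration_csv

    truth = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# ground_truth:"):
                truth = GroundTruth.from_json(line.split(":", 1)[1])
    return read_titration_csv(path), truth
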