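"""Domain types and spectral operations for fluorescence titration data.

A titration series is one protein solution at one temperature whose emission
spectrum is recorded at a ladder of ligand concentrations, the zero-ligand
spectrum providing the unquenched reference intensity F0.  This module holds
the validated containers, CSV I/O, the inner-filter correction, and spectral
feature extraction (peak position and shift, quench percentage,
excitation-emission-matrix peak picking).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "TitrationPoint",
    "TitrationSeries",
    "EEMGrid",
    "PeakMetrics",
    "EEMPeak",
    "read_titration_csv",
    "correct_inner_filter",
    "series_intensities",
    "peak_metrics",
    "eem_peaks",
]

#: Titration CSV columns (long format, UTF-8, comma separated, '.' decimals).
REQUIRED_COLUMNS = ("series_id", "temperature_K", "ligand_conc_M", "wavelength_nm", "intensity")
OPTIONAL_COLUMNS = ("a_ex", "a_em")


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Data violates a structural invariant (ordering, missing reference...)."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission scan: intensity versus emission wavelength.

    Wavelengths must be strictly increasing and intensities finite; both are
    stored as float arrays of equal length.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1:
            raise ValidationError("spectrum axes must be one-dimensional")
        if wl.size != it.size:
            raise ValidationError(
                f"wavelengths ({wl.size}) and intensities ({it.size}) differ in length"
            )
        if wl.size == 0:
            raise ValidationError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(it))):
            raise ValidationError("spectrum contains non-finite values")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def intensity_at(self, wavelength_nm: float) -> float:
        """Linearly interpolated intensity at ``wavelength_nm`` (exact on grid)."""
        wl = self.wavelengths_nm
        if not (wl[0] <= wavelength_nm <= wl[-1]):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside spectrum range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength_nm, wl, self.intensities))


@dataclass(frozen=True)
class TitrationPoint:
    """One rung of the titration ladder: a spectrum at a ligand concentration.

    ``a_ex``/``a_em`` are the optional sample absorbances at the excitation
    and emission wavelengths used for inner-filter correction; they must be
    supplied together or not at all.
    """

    ligand_conc: float
    spectrum: EmissionSpectrum
    a_ex: Optional[float] = None
    a_em: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.ligand_conc) or self.ligand_conc < 0:
            raise ValidationError(f"ligand concentration must be finite and >= 0, got {self.ligand_conc}")
        if (self.a_ex is None) != (self.a_em is None):
            raise ValidationError("a_ex and a_em must be supplied together")
        if self.a_ex is not None and (self.a_ex < 0 or self.a_em < 0):
            raise ValidationError("absorbances must be non-negative")

    @property
    def has_absorbances(self) -> bool:
        return self.a_ex is not None


@dataclass(frozen=True)
class TitrationSeries:
    """Emission spectra of one protein solution across ligand concentrations.

    Points are sorted by ascending concentration and exactly one point must
    sit at zero ligand (the F0 reference).  At least three points are needed
    for any downstream fit.
    """

    series_id: str
    temperature_K: float
    points: tuple[TitrationPoint, ...]
    protein_conc: float = 1e-6
    excitation_nm: float = 275.0

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        if self.temperature_K <= 0:
            raise ValidationError("temperature must be positive")
        if self.protein_conc <= 0:
            raise ValidationError("protein concentration must be positive")
        concs = [p.ligand_conc for p in pts]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValidationError("points must be sorted by strictly ascending ligand concentration")
        if sum(1 for c in concs if c == 0.0) != 1:
            raise ValidationError("series must contain exactly one zero-concentration (F0) point")
        object.__setattr__(self, "points", pts)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.ligand_conc for p in self.points])

    @property
    def reference_point(self) -> TitrationPoint:
        """The zero-ligand point carrying F0."""
        return self.points[0]


@dataclass(frozen=True)
class EEMGrid:
    """A dense excitation-emission matrix (rows = excitation, cols = emission)."""

    excitations_nm: np.ndarray
    emissions_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        ex = np.asarray(self.excitations_nm, dtype=float)
        em = np.asarray(self.emissions_nm, dtype=float)
        z = np.asarray(self.intensities, dtype=float)
        if not (np.all(np.diff(ex) > 0) and np.all(np.diff(em) > 0)):
            raise ValidationError("EEM axes must be strictly increasing")
        if z.shape != (ex.size, em.size):
            raise ValidationError(
                f"intensity matrix shape {z.shape} does not match axes ({ex.size}, {em.size})"
            )
        object.__setattr__(self, "excitations_nm", ex)
        object.__setattr__(self, "emissions_nm", em)
        object.__setattr__(self, "intensities", z)


@dataclass(frozen=True)
class PeakMetrics:
    """Peak position/shift/quenching of a spectrum relative to a reference."""

    lambda_max_nm: float
    f_max: float
    delta_lambda_nm: float
    shift_class: str  # blue | red | none
    quench_pct: float


@dataclass(frozen=True)
class EEMPeak:
    """A located EEM peak (local maximum near a labelled seed position)."""

    label: str
    excitation_nm: float
    emission_nm: float
    intensity: float


def correct_inner_filter(f_obs: float, a_ex: float, a_em: float) -> float:
    """Undo inner-filter attenuation of a measured fluorescence intensity.

    F_corr = F_obs * 10**((A_ex + A_em) / 2), where A_ex and A_em are the
    sample absorbances at the excitation and emission wavelengths.  The
    correction is >= 1, so F_corr >= F_obs always.
    """
    if a_ex < 0 or a_em < 0:
        raise ValueError("absorbances must be non-negative")
    if f_obs < 0:
        raise ValueError("observed intensity must be non-negative")
    return f_obs * 10.0 ** ((a_ex + a_em) / 2.0)


def _corrected_spectrum_intensities(point: TitrationPoint) -> np.ndarray:
    it = point.spectrum.intensities
    if point.has_absorbances:
        return it * 10.0 ** ((point.a_ex + point.a_em) / 2.0)
    return it


def series_intensities(
    series: TitrationSeries,
    policy: str = "fixed_reference",
    reference_nm: Optional[float] = None,
) -> list[tuple[float, float]]:
    """Extract one fluorescence intensity F per titration point.

    ``fixed_reference`` reads every spectrum at a single emission wavelength
    (default: the peak wavelength of the zero-ligand spectrum), which is the
    assumption behind the Stern-Volmer and double-log treatments.
    ``per_spectrum_max`` tracks each spectrum's own maximum, useful when the
    band shifts during the titration.  Inner-filter correction is applied
    first wherever absorbances are present.
    """
    if policy not in ("fixed_reference", "per_spectrum_max"):
        raise ValueError(f"unknown intensity policy {policy!r}")
    out: list[tuple[float, float]] = []
    if policy == "fixed_reference" and reference_nm is None:
        ref = series.reference_point.spectrum
        reference_nm = float(ref.wavelengths_nm[int(np.argmax(ref.intensities))])
    for point in series.points:
        corrected = _corrected_spectrum_intensities(point)
        wl = point.spectrum.wavelengths_nm
        if policy == "fixed_reference":
            if not (wl[0] <= reference_nm <= wl[-1]):
                raise ValueError(
                    f"reference wavelength {reference_nm} nm outside spectrum range "
                    f"[{wl[0]}, {wl[-1]}] nm"
                )
            f = float(np.interp(reference_nm, wl, corrected))
        else:
            f = float(np.max(corrected))
        out.append((point.ligand_conc, f))
    return out


def _parabolic_refine(wl: np.ndarray, it: np.ndarray, i: int) -> tuple[float, float]:
    # 3-point parabola through the argmax and neighbours; falls back to the
    # grid point at the edges or on a degenerate (flat) triple.
    if i == 0 or i == it.size - 1:
        return float(wl[i]), float(it[i])
    y0, y1, y2 = it[i - 1], it[i], it[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(wl[i]), float(it[i])
    delta = 0.5 * (y0 - y2) / denom
    step = wl[i + 1] - wl[i]
    peak_wl = wl[i] + delta * step
    peak_f = y1 - 0.25 * (y0 - y2) * delta
    return float(peak_wl), float(peak_f)


def peak_metrics(
    spectrum: EmissionSpectrum,
    reference: EmissionSpectrum,
    shift_tolerance_nm: float = 0.5,
    refine: bool = False,
) -> PeakMetrics:
    """Peak wavelength, signed shift vs a reference spectrum, and quench %.

    Negative shifts are hypsochromic (blue), positive bathochromic (red);
    shifts within ``shift_tolerance_nm`` of zero classify as "none".  The
    quench percentage compares band maxima: (F0_max - F_max)/F0_max * 100.
    By default peak positions are grid argmaxes (bit-reproducible); with
    ``refine=True`` a 3-point parabolic interpolation sharpens both position
    and height below the grid spacing.
    """
    ref_max_idx = int(np.argmax(reference.intensities))
    ref_max = float(reference.intensities[ref_max_idx])
    if ref_max <= 0:
        raise ValueError("reference spectrum has non-positive maximum")
    spec_idx = int(np.argmax(spectrum.intensities))
    if refine:
        lam, fmax = _parabolic_refine(spectrum.wavelengths_nm, spectrum.intensities, spec_idx)
        lam_ref, ref_max = _parabolic_refine(
            reference.wavelengths_nm, reference.intensities, ref_max_idx
        )
    else:
        lam = float(spectrum.wavelengths_nm[spec_idx])
        fmax = float(spectrum.intensities[spec_idx])
        lam_ref = float(reference.wavelengths_nm[ref_max_idx])
    delta = lam - lam_ref
    if delta < -shift_tolerance_nm:
        shift_class = "blue"
    elif delta > shift_tolerance_nm:
        shift_class = "red"
    else:
        shift_class = "none"
    quench_pct = (ref_max - fmax) / ref_max * 100.0
    return PeakMetrics(
        lambda_max_nm=lam,
        f_max=fmax,
        delta_lambda_nm=delta,
        shift_class=shift_class,
        quench_pct=quench_pct,
    )


def eem_peaks(
    grid: EEMGrid,
    seeds: Iterable[tuple[str, float, float]],
    search_radius_nm: float = 15.0,
) -> list[EEMPeak]:
    """Locate EEM peaks near labelled seed positions.

    For each ``(label, excitation_nm, emission_nm)`` seed, returns the maximal
    grid point within ``search_radius_nm`` (Chebyshev window on both axes).
    Intensity ratios between two grids (e.g. protein alone vs with ligand) are
    left to the caller.
    """
    out = []
    ex, em, z = grid.excitations_nm, grid.emissions_nm, grid.intensities
    for label, seed_ex, seed_em in seeds:
        if not (ex[0] <= seed_ex <= ex[-1] and em[0] <= seed_em <= em[-1]):
            raise ValueError(f"seed {label!r} at ({seed_ex}, {seed_em}) nm outside grid")
        ex_mask = np.abs(ex - seed_ex) <= search_radius_nm
        em_mask = np.abs(em - seed_em) <= search_radius_nm
        window = z[np.ix_(ex_mask, em_mask)]
        i, j = np.unravel_index(int(np.argmax(window)), window.shape)
        out.append(
            EEMPeak(
                label=label,
                excitation_nm=float(ex[ex_mask][i]),
                emission_nm=float(em[em_mask][j]),
                intensity=float(window[i, j]),
            )
        )
    return out


def read_eem_csv(path) -> EEMGrid:
    """Read a dense EEM grid from a long-format CSV (excitation_nm, emission_nm, intensity)."""
    df = pd.read_csv(path, comment="#")
    for col in ("excitation_nm", "emission_nm", "intensity"):
        if col not in df.columns:
            raise FormatError(f"EEM CSV missing required column {col!r}")
    pivot = df.pivot_table(index="excitation_nm", columns="emission_nm", values="intensity")
    if pivot.isna().any().any():
        raise ValidationError("EEM grid is not dense: missing (excitation, emission) cells")
    return EEMGrid(
        excitations_nm=pivot.index.to_numpy(dtype=float),
        emissions_nm=pivot.columns.to_numpy(dtype=float),
        intensities=pivot.to_numpy(dtype=float),
    )


def read_titration_csv(
    path,
    series_id: Optional[str] = None,
    protein_conc: float = 1e-6,
    excitation_nm: float = 275.0,
) -> TitrationSeries:
    """Read a long-format titration CSV into a validated TitrationSeries.

    Expected columns: series_id, temperature_K, ligand_conc_M, wavelength_nm,
    intensity, and optionally a_ex / a_em (one value per concentration).
    Lines starting with '#' are ignored, so simulator fixtures with ground
    truth headers read back directly.  ``series_id`` selects one series from
    a multi-series file; protein concentration and excitation wavelength are
    not part of the CSV dialect and default to the standard assay conditions
    (1 uM protein, 275 nm excitation).
    """
    df = pd.read_csv(path, comment="#")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"titration CSV missing required column {col!r}")
    if series_id is not None:
        df = df[df["series_id"] == series_id]
        if df.empty:
            raise ValidationError(f"no rows with series_id {series_id!r}")
    else:
        ids = df["series_id"].unique()
        if len(ids) != 1:
            raise ValidationError(
                f"file contains {len(ids)} series ({list(ids)}); pass series_id to select one"
            )
        series_id = str(ids[0])
    temps = df["temperature_K"].unique()
    if len(temps) != 1:
        raise ValidationError(f"series {series_id!r} spans multiple temperatures: {sorted(temps)}")
    has_ife = all(c in df.columns for c in OPTIONAL_COLUMNS)
    points = []
    for conc, group in sorted(df.groupby("ligand_conc_M"), key=lambda kv: kv[0]):
        wl = group["wavelength_nm"].to_numpy(dtype=float)
        it = group["intensity"].to_numpy(dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValidationError(
                f"wavelengths not strictly increasing within the spectrum at {conc} mol/L"
            )
        a_ex = a_em = None
        if has_ife and not group["a_ex"].isna().all():
            a_ex = float(group["a_ex"].iloc[0])
            a_em = float(group["a_em"].iloc[0])
        points.append(
            TitrationPoint(
                ligand_conc=float(conc),
                spectrum=EmissionSpectrum(wl, it),
                a_ex=a_ex,
                a_em=a_em,
            )
        )
    return TitrationSeries(
        series_id=series_id,
        temperature_K=float(temps[0]),
        points=tuple(points),
        protein_conc=protein_conc,
        excitation_nm=excitation_nm,
    )
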