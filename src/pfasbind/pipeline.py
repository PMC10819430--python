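"""End-to-end orchestration: spectra -> quenching -> affinity -> thermo ->
competition -> energetics -> correlation, driven by one YAML config.

Stages whose inputs are absent from the config are skipped (and logged);
any stage failure aborts with the failing stage named.  Outputs are CSV
tables shaped like the standard per-temperature binding/competition/energy
summaries plus a single JSON report; re-running on identical inputs and seed
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import competition as comp
from .affinity import BindingFit, double_log_fit
from .energetics import (
    MetricTable,
    metric_table_from_frame,
    pearson_matrix,
    rank_by_affinity,
    read_gbsa_table,
)
from .quenching import (
    DEFAULT_TAU0_S,
    DIFFUSION_LIMIT,
    MechanismCall,
    SVFit,
    classify_mechanism,
    stern_volmer_fit,
)
from .spectra import TitrationSeries, ValidationError, read_titration_csv
from .thermo import DEFAULT_NEAR_ZERO_KJ_MOL, ThermoResult, thermodynamic_analysis

__all__ = ["AnalysisReport", "PipelineError", "run_full_analysis", "load_config"]

log = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "systems",
    "competition_csv",
    "gbsa_csv",
    "metrics_csv",
    "tau0_s",
    "kq_limit",
    "near_zero_kj_mol",
    "site_map",
    "dominance_pct",
    "wavelength_policy",
    "reference_nm",
    "seed",
    "out_dir",
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class SystemReport:
    """Per-system spectroscopic results."""

    system: str
    sv_fits: list[SVFit] = field(default_factory=list)
    mechanism: Optional[MechanismCall] = None
    binding_fits: list[BindingFit] = field(default_factory=list)
    thermo: Optional[ThermoResult] = None
    competition: list[comp.CompetitionResult] = field(default_factory=list)
    site: Optional[comp.SiteAssignment] = None


@dataclass
class AnalysisReport:
    """Everything the pipeline computed, stage by stage."""

    systems: dict[str, SystemReport] = field(default_factory=dict)
    ranking: Optional[list[tuple[str, float]]] = None
    correlation_signed: Optional[pd.DataFrame] = None
    correlation_magnitude: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"systems": {}}
        for name, rep in self.systems.items():
            out["systems"][name] = {
                "sv_fits": [dataclasses.asdict(f) for f in rep.sv_fits],
                "mechanism": dataclasses.asdict(rep.mechanism) if rep.mechanism else None,
                "binding_fits": [dataclasses.asdict(f) for f in rep.binding_fits],
                "thermo": (
                    {
                        **dataclasses.asdict(rep.thermo),
                        "delta_g_by_temp": {
                            str(t): g for t, g in rep.thermo.delta_g_by_temp.items()
                        },
                    }
                    if rep.thermo
                    else None
                ),
                "competition": [dataclasses.asdict(c) for c in rep.competition],
                "site": dataclasses.asdict(rep.site) if rep.site else None,
            }
        out["ranking"] = self.ranking
        if self.correlation_signed is not None:
            out["correlation_signed"] = self.correlation_signed.round(6).to_dict()
            out["correlation_magnitude"] = self.correlation_magnitude.round(6).to_dict()
        return out


def load_config(path) -> dict:
    """Load and sanity-check the pipeline YAML config."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config: top level must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("spectra")
def _load_series(entries: Sequence[Mapping], base: Path) -> list[TitrationSeries]:
    series = []
    for entry in entries:
        path = base / entry["path"]
        if not path.exists():
            raise FileNotFoundError(f"titration file {path} does not exist")
        series.append(read_titration_csv(path, series_id=entry.get("series_id")))
    return series


def run_full_analysis(config, out_dir=None) -> AnalysisReport:
    """Run every stage the config provides inputs for.

    ``config`` is a YAML path or an already-loaded mapping.  Relative input
    paths resolve against the config file's directory.  When ``out_dir`` (or
    the config's ``out_dir``) is set, per-stage CSVs and a JSON report are
    written there.
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        cfg = load_config(config)
    else:
        cfg = dict(config)
        unknown = set(cfg) - _KNOWN_KEYS
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        base = Path.cwd()
    out_dir = Path(out_dir or cfg.get("out_dir")) if (out_dir or cfg.get("out_dir")) else None

    tau0 = float(cfg.get("tau0_s", DEFAULT_TAU0_S))
    kq_limit = float(cfg.get("kq_limit", DIFFUSION_LIMIT))
    near_zero = float(cfg.get("near_zero_kj_mol", DEFAULT_NEAR_ZERO_KJ_MOL))
    site_map = dict(cfg.get("site_map", comp.DEFAULT_SITE_MAP))
    dominance = float(cfg.get("dominance_pct", comp.DEFAULT_DOMINANCE_PCT))
    policy = cfg.get("wavelength_policy", "fixed_reference")
    reference_nm = cfg.get("reference_nm")

    report = AnalysisReport()

    for sys_cfg in cfg.get("systems", []):
        name = sys_cfg.get("name")
        if not name:
            raise PipelineError("config: each system needs a 'name' key")
        rep = SystemReport(system=name)
        series_list = _load_series(sys_cfg.get("titrations", []), base)
        if series_list:
            try:
                rep.sv_fits = [
                    stern_volmer_fit(s, tau0_s=tau0, policy=policy, reference_nm=reference_nm)
                    for s in sorted(series_list, key=lambda s: s.temperature_K)
                ]
                rep.binding_fits = [
                    double_log_fit(s, policy=policy, reference_nm=reference_nm)
                    for s in sorted(series_list, key=lambda s: s.temperature_K)
                ]
            except (ValueError, ValidationError) as exc:
                raise PipelineError(f"stage 'quenching/affinity' failed for {name}: {exc}")
            if len(rep.sv_fits) >= 2:
                rep.mechanism = classify_mechanism(rep.sv_fits, kq_limit=kq_limit)
                rep.thermo = thermodynamic_analysis(
                    [(f.temperature_K, f.kb) for f in rep.binding_fits],
                    near_zero_kj_mol=near_zero,
                )
            else:
                log.info("system %s: single temperature; mechanism/thermo skipped", name)
        report.systems[name] = rep

    if "competition_csv" in cfg:
        path = base / cfg["competition_csv"]
        try:
            df = pd.read_csv(path, comment="#")
            for col in ("system", "probe", "kb_free", "kb_probe"):
                if col not in df.columns:
                    raise ValueError(f"competition CSV missing column {col!r}")
        except Exception as exc:
            raise PipelineError(f"stage 'competition' failed: {exc}") from exc
        for system, group in df.groupby("system"):
            rep = report.systems.setdefault(system, SystemReport(system=system))
            kb_by_probe = dict(zip(group["probe"], group["kb_probe"]))
            kb_free = float(group["kb_free"].iloc[0])
            rep.competition = comp.competition_results(kb_free, kb_by_probe, site_map)
            rep.site = comp.assign_binding_site(rep.competition, site_map, dominance)
    else:
        log.info("no competition input; stage skipped")

    if "gbsa_csv" in cfg:
        try:
            records = read_gbsa_table(base / cfg["gbsa_csv"])
        except Exception as exc:
            raise PipelineError(f"stage 'energetics' failed: {exc}") from exc
        report.ranking = rank_by_affinity(records)
    else:
        log.info("no GBSA input; stage skipped")

    if "metrics_csv" in cfg:
        try:
            df = pd.read_csv(base / cfg["metrics_csv"], comment="#")
            table = metric_table_from_frame(df)
            report.correlation_signed, report.correlation_magnitude = pearson_matrix(table)
        except Exception as exc:
            raise PipelineError(f"stage 'correlation' failed: {exc}") from exc
    else:
        log.info("no metrics input; stage skipped")

    if out_dir is not None:
        _write_outputs(report, out_dir)
    return report


def _write_outputs(report: AnalysisReport, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, rep in report.systems.items():
        kb_by_t = {f.temperature_K: f for f in rep.binding_fits}
        for f in rep.sv_fits:
            b = kb_by_t.get(f.temperature_K)
            rows.append(
                {
                    "system": name,
                    "temperature_K": f.temperature_K,
                    "ksv": f.ksv,
                    "kq": f.kq,
                    "sv_r_squared": f.r_squared,
                    "kb": b.kb if b else None,
                    "n_sites": b.n_sites if b else None,
                    "kb_r_squared": b.r_squared if b else None,
                    "delta_g_kj_mol": (
                        rep.thermo.delta_g_by_temp.get(f.temperature_K) if rep.thermo else None
                    ),
                    "delta_h_kj_mol": rep.thermo.delta_h_kj_mol if rep.thermo else None,
                    "delta_s_j_mol_k": rep.thermo.delta_s_j_mol_k if rep.thermo else None,
                    "force_class": rep.thermo.force_class if rep.thermo else None,
                    "mechanism": rep.mechanism.mechanism if rep.mechanism else None,
                }
            )
    if rows:
        pd.DataFrame(rows).to_csv(out_dir / "binding_summary.csv", index=False, float_format="%.6g")
    comp_rows = [
        {
            "system": name,
            "probe": c.probe,
            "site": c.site_label,
            "kb_free": c.kb_free,
            "kb_probe": c.kb_probe,
            "phi_pct": c.phi_pct,
            "assigned_site": rep.site.assigned_site if rep.site else None,
            "dominant": rep.site.dominant if rep.site else None,
        }
        for name, rep in report.systems.items()
        for c in rep.competition
    ]
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(out_dir / "competition_summary.csv", index=False, float_format="%.6g")
    if report.ranking:
        pd.DataFrame(report.ranking, columns=["system", "dg_bind"]).to_csv(
            out_dir / "affinity_ranking.csv", index=False, float_format="%.6g"
        )
    if report.correlation_signed is not None:
        report.correlation_signed.to_csv(out_dir / "correlation_signed.csv", float_format="%.6g")
        report.correlation_magnitude.to_csv(out_dir / "correlation_magnitude.csv", float_format="%.6g")
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
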