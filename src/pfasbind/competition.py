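"""Competitive site-marker displacement analysis.

Site markers with known albumin subdomains (warfarin -> IIA, ibuprofen ->
IIIA, lidocaine -> IB) are co-incubated with the protein; the fractional drop
of the ligand's binding constant in the marker's presence,
phi = (Kb_free - Kb_probe)/Kb_free * 100, reports how strongly the ligand
shares the marker's site.  The marker with the largest phi names the binding
subdomain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .spectra import ValidationError

__all__ = [
    "CompetitionResult",
    "SiteAssignment",
    "displacement_ratio",
    "assign_binding_site",
    "DEFAULT_SITE_MAP",
    "DEFAULT_DOMINANCE_PCT",
]

log = logging.getLogger(__name__)

#: Canonical albumin site markers and the subdomain each occupies.
DEFAULT_SITE_MAP: dict[str, str] = {"warfarin": "IIA", "ibuprofen": "IIIA", "lidocaine": "IB"}

#: phi (%) above which the winning probe is called dominant.
DEFAULT_DOMINANCE_PCT = 80.0


@dataclass(frozen=True)
class CompetitionResult:
    """phi for one (ligand, probe) pair."""

    probe: str
    site_label: str
    kb_free: float
    kb_probe: float
    phi_pct: float


@dataclass(frozen=True)
class SiteAssignment:
    assigned_site: str
    winning_probe: str
    phi_winning: float
    margin: float  # phi_winner - phi_runner_up (0 with a single probe)
    dominant: bool


def displacement_ratio(kb_free: float, kb_probe: float) -> float:
    """Percent decrease of the binding constant in the probe's presence.

    Negative values (binding enhancement by the probe) are allowed but
    logged, since they usually indicate an allosteric effect rather than
    site competition.
    """
    if kb_free <= 0 or kb_probe <= 0:
        raise ValueError("binding constants must be positive")
    phi = (kb_free - kb_probe) / kb_free * 100.0
    if phi < 0:
        log.warning("negative displacement (%.1f%%): probe enhances binding", phi)
    return phi


def assign_binding_site(
    results: Sequence[CompetitionResult],
    site_map: Mapping[str, str] = DEFAULT_SITE_MAP,
    dominance_pct: float = DEFAULT_DOMINANCE_PCT,
) -> SiteAssignment:
    """Name the binding subdomain from probe displacement results.

    The probe with maximal phi wins (ties broken alphabetically, logged);
    ``dominant`` is True when the winning phi reaches ``dominance_pct``.
    """
    if not results:
        raise ValidationError("need at least one competition result")
    for r in results:
        if r.probe not in site_map:
            raise KeyError(f"probe {r.probe!r} missing from site map {sorted(site_map)}")
    ranked = sorted(results, key=lambda r: (-r.phi_pct, r.probe))
    winner = ranked[0]
    if len(ranked) > 1 and ranked[1].phi_pct == winner.phi_pct:
        log.info("phi tie between %r and %r; broken alphabetically", winner.probe, ranked[1].probe)
    margin = winner.phi_pct - ranked[1].phi_pct if len(ranked) > 1 else 0.0
    return SiteAssignment(
        assigned_site=site_map[winner.probe],
        winning_probe=winner.probe,
        phi_winning=winner.phi_pct,
        margin=margin,
        dominant=winner.phi_pct >= dominance_pct,
    )


def competition_results(
    kb_free: float,
    kb_by_probe: Mapping[str, float],
    site_map: Mapping[str, str] = DEFAULT_SITE_MAP,
) -> list[CompetitionResult]:
    """Build CompetitionResult records from a free Kb and per-probe Kb values."""
    out = []
    for probe, kb_probe in sorted(kb_by_probe.items()):
        if probe not in site_map:
            raise KeyError(f"probe {probe!r} missing from site map {sorted(site_map)}")
        out.append(
            CompetitionResult(
                probe=probe,
                site_label=site_map[probe],
                kb_free=kb_free,
                kb_probe=kb_probe,
                phi_pct=displacement_ratio(kb_free, kb_probe),
            )
        )
    return out
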