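"""Deterministic derived quantities ahead of the statistical analyses.

Covers relative weight difference (RWD), cube-root shell-weight scaling
of POI distances, per-fight zone proportions, the POI-count vs rap-count
consistency check, and the outlier-sensitivity protocol (Tukey fences).
Everything here is a pure function of its inputs.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coarse import TauResult, kendall_tau_b
from .io_model import FightRecord, POIRecord, ScaledPOI, ZoneSummary

__all__ = [
    "PreprocessReport",
    "compute_rwd",
    "scale_poi",
    "zone_proportions",
    "poi_rap_consistency",
    "flag_outliers",
    "build_report",
]

logger = logging.getLogger(__name__)


def compute_rwd(attacker_weight: float, defender_weight: float) -> float:
    """Relative weight difference RWD = 1 - defender/attacker.

    Lies in (0, 1) when the attacker is heavier; a negative value
    (defender heavier — the roles reversed) is allowed with a warning.
    Nonpositive weights are a domain error.
    """
    if attacker_weight <= 0 or defender_weight <= 0:
        raise ValueError("weights must be positive")
    rwd = 1.0 - defender_weight / attacker_weight
    if rwd < 0:
        _warnings.warn(
            "negative RWD: defender heavier than attacker (role convention violated)",
            UserWarning,
        )
    return rwd


def scale_poi(poi: POIRecord, defender_shell_weight: float) -> ScaledPOI:
    """Divide both landmark distances by cbrt(defender shell weight).

    The cube root makes the correction dimension-neutral: shell weight
    grows roughly with the cube of linear shell size.
    """
    if defender_shell_weight <= 0:
        raise ValueError("defender_shell_weight must be positive")
    c = np.cbrt(defender_shell_weight)
    return ScaledPOI(
        fight_id=poi.fight_id,
        poi_id=poi.poi_id,
        dist_A=poi.dist_A,
        dist_B=poi.dist_B,
        zone=poi.zone,
        scaled_dist_A=poi.dist_A / c,
        scaled_dist_B=poi.dist_B / c,
    )


def zone_proportions(pois: Sequence[POIRecord]) -> ZoneSummary:
    """Per-fight zone-1/zone-2 proportions over ALL POIs (incl. "other")."""
    if len(pois) == 0:
        raise ValueError("zone proportions undefined for a fight with zero POIs")
    fight_ids = {p.fight_id for p in pois}
    if len(fight_ids) != 1:
        raise ValueError(f"POIs from multiple fights: {sorted(fight_ids)}")
    n = len(pois)
    n1 = sum(1 for p in pois if p.zone == "1")
    n2 = sum(1 for p in pois if p.zone == "2")
    return ZoneSummary(
        fight_id=pois[0].fight_id, n_poi=n, prop_zone1=n1 / n, prop_zone2=n2 / n
    )


def poi_rap_consistency(
    n_pois: Sequence[int], total_raps: Sequence[int]
) -> TauResult:
    """Kendall tau-b between per-fight POI counts and rap counts.

    A positive association is the sanity check that marks on the shell
    track the raps actually performed, despite multiple marks per rap
    and undetected raps pulling in opposite directions.
    """
    return kendall_tau_b(np.asarray(n_pois, float), np.asarray(total_raps, float))


def flag_outliers(x: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Tukey-fence outlier flags: x outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation.  With fewer than 4 values the
    fences are meaningless, so nothing is flagged (with a warning).
    A constant vector has zero IQR and yields no flags.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        _warnings.warn("fewer than 4 values: no outlier flags assigned", UserWarning)
        return np.zeros(x.size, dtype=bool)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    return (x < q1 - k * iqr) | (x > q3 + k * iqr)


@dataclass
class PreprocessReport:
    """Everything the downstream analyses consume, plus bookkeeping.

    ``outlier_flags`` aligns with ``zone_summaries`` (POI-bearing fights
    in input order) and is computed on the zone-1 proportion, the
    variable entering the spatial-temporal correlations.
    """

    zone_summaries: list[ZoneSummary]
    rwd: dict[str, float]
    scaled_pois: list[ScaledPOI]
    consistency: TauResult | None
    outlier_flags: np.ndarray
    outlier_rule: dict
    excluded_fight_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def flagged_fight_ids(self) -> tuple[str, ...]:
        return tuple(
            s.fight_id for s, f in zip(self.zone_summaries, self.outlier_flags) if f
        )


def build_report(
    fights: Sequence[FightRecord],
    pois: Sequence[POIRecord],
    outlier_k: float = 3.0,
) -> PreprocessReport:
    """Run the full deterministic preprocessing pass.

    Fights with zero POIs are excluded from the spatial analyses and
    logged; they keep their RWD entry.
    """
    by_fight: dict[str, list[POIRecord]] = {f.fight_id: [] for f in fights}
    for p in pois:
        if p.fight_id not in by_fight:
            raise ValueError(f"POI {p.poi_id} references unknown fight {p.fight_id}")
        by_fight[p.fight_id].append(p)

    shell_weight: Mapping[str, float] = {
        f.fight_id: f.defender_shell_weight for f in fights
    }
    rwd = {f.fight_id: compute_rwd(f.attacker_weight, f.defender_weight) for f in fights}

    zone_summaries: list[ZoneSummary] = []
    scaled: list[ScaledPOI] = []
    excluded: list[str] = []
    for f in fights:
        group = by_fight[f.fight_id]
        if not group:
            excluded.append(f.fight_id)
            logger.info("fight %s excluded: zero POIs", f.fight_id)
            continue
        zone_summaries.append(zone_proportions(group))
        scaled.extend(scale_poi(p, shell_weight[f.fight_id]) for p in group)

    raps_by_fight = {f.fight_id: f.total_raps for f in fights}
    n_pois = [s.n_poi for s in zone_summaries]
    raps = [raps_by_fight[s.fight_id] for s in zone_summaries]
    try:
        consistency = poi_rap_consistency(n_pois, raps) if len(n_pois) >= 3 else None
    except ValueError as exc:
        logger.warning("POI-rap consistency undefined: %s", exc)
        consistency = None

    pz1 = [s.prop_zone1 for s in zone_summaries]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        flags = flag_outliers(pz1, k=outlier_k)

    return PreprocessReport(
        zone_summaries=zone_summaries,
        rwd=rwd,
        scaled_pois=scaled,
        consistency=consistency,
        outlier_flags=flags,
        outlier_rule={"method": "tukey_fences", "k": outlier_k, "variable": "prop_zone1"},
        excluded_fight_ids=tuple(excluded),
    )
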