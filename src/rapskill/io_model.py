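"""Domain records, CSV schemas, validation, and result serialization.

The pipeline exchanges two flat tables:

``fights.csv``
    one row per staged contest between a larger attacker and a smaller
    defender (masses in g, outcome, temporal rap structure), and

``pois.csv``
    one row per point of impact (POI) left on the defender's shell, with
    distances to two anatomical landmarks (A: shell apex; B: junction of
    the outer lip and the body whorl) and a coarse zone label.

Distances are unitless in files; the analysis is scale-equivariant apart
from the cube-root shell-weight scaling, which is dimension-neutral.
Validation never mutates data: records are returned as read, with an
ordered list of row-indexed warnings attached.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Sequence

import pandas as pd

__all__ = [
    "FightRecord",
    "POIRecord",
    "ScaledPOI",
    "ZoneSummary",
    "TruthRecord",
    "ValidationIssue",
    "ValidatedRecords",
    "SchemaError",
    "RowParseError",
    "ReferentialIntegrityError",
    "read_fights",
    "read_pois",
    "write_fights",
    "write_pois",
    "write_results",
    "read_results",
    "FIGHT_COLUMNS",
    "POI_COLUMNS",
    "OUTCOME_EVICTION",
    "OUTCOME_NONEVICTION",
    "ZONES",
]

OUTCOME_EVICTION = "eviction"
OUTCOME_NONEVICTION = "noneviction"
ZONES = ("1", "2", "other")

FIGHT_COLUMNS = [
    "fight_id",
    "attacker_weight",
    "defender_weight",
    "attacker_shell_weight",
    "defender_shell_weight",
    "outcome",
    "total_raps",
    "total_bouts",
    "mean_raps_per_bout",
]

POI_COLUMNS = ["fight_id", "poi_id", "dist_A", "dist_B", "zone"]


class SchemaError(ValueError):
    """A required column is missing or carries an unusable header."""


class RowParseError(ValueError):
    """A cell could not be parsed; the message names the row index."""


class ReferentialIntegrityError(ValueError):
    """A POI references a fight_id absent from the fights table."""


@dataclass(frozen=True)
class FightRecord:
    """One contest: opponents, shells, outcome, and rap timing summary."""

    fight_id: str
    attacker_weight: float
    defender_weight: float
    attacker_shell_weight: float
    defender_shell_weight: float
    outcome: str  # "eviction" | "noneviction"
    total_raps: int
    total_bouts: int
    mean_raps_per_bout: float

    @property
    def outcome_code(self) -> int:
        """1 for eviction (attacker success), 0 for noneviction."""
        return 1 if self.outcome == OUTCOME_EVICTION else 0

    @property
    def rwd(self) -> float:
        """Relative weight difference, 1 - defender/attacker."""
        return 1.0 - self.defender_weight / self.attacker_weight


@dataclass(frozen=True)
class POIRecord:
    """One point of impact: distances to landmarks A and B plus zone label."""

    fight_id: str
    poi_id: str
    dist_A: float
    dist_B: float
    zone: str  # "1" | "2" | "other"


@dataclass(frozen=True)
class ScaledPOI:
    """A POI with distances divided by cbrt(defender shell weight)."""

    fight_id: str
    poi_id: str
    dist_A: float
    dist_B: float
    zone: str
    scaled_dist_A: float
    scaled_dist_B: float


@dataclass(frozen=True)
class ZoneSummary:
    """Per-fight zone occupancy: POI count and zone-1/zone-2 proportions.

    Proportions use ALL POIs of the fight (including "other") as the
    denominator, so prop_zone1 + prop_zone2 <= 1 always.
    """

    fight_id: str
    n_poi: int
    prop_zone1: float
    prop_zone2: float


@dataclass
class TruthRecord:
    """Ground truth serialized next to every synthetic dataset.

    ``config`` holds every generator parameter; ``fights`` holds the
    per-fight latent state (individual accuracy/precision effects,
    vigour, residual SD, latent zone-1 propensity ...).
    """

    config: dict[str, Any]
    fights: list[dict[str, Any]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "fights": self.fights},
            indent=2,
            sort_keys=True,
            allow_nan=False,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        obj = json.loads(text)
        return cls(config=obj["config"], fights=obj["fights"])

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "TruthRecord":
        return cls.from_json(Path(path).read_text())


@dataclass(frozen=True)
class ValidationIssue:
    row: int
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row} [{self.field}]: {self.message}"


class ValidatedRecords(Sequence):
    """A sequence of records with an attached, row-ordered warning report."""

    def __init__(self, records: list, warnings: list[ValidationIssue]):
        self.records = records
        self.warnings = sorted(warnings, key=lambda w: w.row)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator:
        return iter(self.records)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_float(value, row: int, name: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError) as exc:
        raise RowParseError(f"row {row}: cannot parse {name}={value!r} as a number") from exc
    if math.isnan(out):
        raise RowParseError(f"row {row}: {name} is missing/NaN")
    return out


def _parse_int(value, row: int, name: str) -> int:
    x = _parse_float(value, row, name)
    if abs(x - round(x)) > 1e-9:
        raise RowParseError(f"row {row}: {name}={value!r} is not an integer")
    return int(round(x))


# tolerance for mean_raps_per_bout == total_raps/total_bouts: the stored
# mean may be the pre-rounding rate, so allow half a rap spread over bouts
def _raps_tolerance(total_bouts: int) -> float:
    return 0.5 / max(total_bouts, 1) + 1e-9


def read_fights(path: str | Path) -> ValidatedRecords:
    """Read and validate fights.csv.

    Invariant breaches (defender at least as heavy as the attacker,
    nonpositive weights, inconsistent rap accounting) are warnings, not
    errors: the record is retained so synthetic edge cases stay usable.
    Structural problems (missing columns, unparseable numbers) raise.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, FIGHT_COLUMNS, path)
    records: list[FightRecord] = []
    warnings: list[ValidationIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        outcome = str(row.outcome).strip()
        if outcome not in (OUTCOME_EVICTION, OUTCOME_NONEVICTION):
            raise RowParseError(
                f"row {i}: outcome must be '{OUTCOME_EVICTION}' or "
                f"'{OUTCOME_NONEVICTION}', got {row.outcome!r}"
            )
        rec = FightRecord(
            fight_id=str(row.fight_id),
            attacker_weight=_parse_float(row.attacker_weight, i, "attacker_weight"),
            defender_weight=_parse_float(row.defender_weight, i, "defender_weight"),
            attacker_shell_weight=_parse_float(
                row.attacker_shell_weight, i, "attacker_shell_weight"
            ),
            defender_shell_weight=_parse_float(
                row.defender_shell_weight, i, "defender_shell_weight"
            ),
            outcome=outcome,
            total_raps=_parse_int(row.total_raps, i, "total_raps"),
            total_bouts=_parse_int(row.total_bouts, i, "total_bouts"),
            mean_raps_per_bout=_parse_float(row.mean_raps_per_bout, i, "mean_raps_per_bout"),
        )
        for name in (
            "attacker_weight",
            "defender_weight",
            "attacker_shell_weight",
            "defender_shell_weight",
        ):
            if getattr(rec, name) <= 0:
                warnings.append(ValidationIssue(i, name, "weight must be positive"))
        if rec.attacker_weight <= rec.defender_weight:
            warnings.append(
                ValidationIssue(
                    i,
                    "defender_weight",
                    "defender is not lighter than attacker (role convention violated)",
                )
            )
        if rec.total_raps < 0:
            warnings.append(ValidationIssue(i, "total_raps", "must be nonnegative"))
        if rec.total_bouts < 1:
            warnings.append(ValidationIssue(i, "total_bouts", "must be >= 1"))
        else:
            implied = rec.total_raps / rec.total_bouts
            if abs(implied - rec.mean_raps_per_bout) > _raps_tolerance(rec.total_bouts):
                warnings.append(
                    ValidationIssue(
                        i,
                        "mean_raps_per_bout",
                        f"inconsistent with total_raps/total_bouts={implied:.4f}",
                    )
                )
        records.append(rec)
    return ValidatedRecords(records, warnings)


def read_pois(
    path: str | Path, fights: Sequence[FightRecord] | None = None
) -> ValidatedRecords:
    """Read and validate pois.csv.

    If ``fights`` is supplied, every POI's fight_id must resolve against
    it (referential-integrity error otherwise).  An out-of-vocabulary
    zone label is a hard error: downstream zone proportions would be
    silently wrong.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, POI_COLUMNS, path)
    known = {f.fight_id for f in fights} if fights is not None else None
    records: list[POIRecord] = []
    warnings: list[ValidationIssue] = []
    for i, row in enumerate(df.itertuples(index=False)):
        zone = str(row.zone).strip()
        if zone not in ZONES:
            raise RowParseError(
                f"row {i}: zone must be one of {ZONES}, got {row.zone!r}"
            )
        rec = POIRecord(
            fight_id=str(row.fight_id),
            poi_id=str(row.poi_id),
            dist_A=_parse_float(row.dist_A, i, "dist_A"),
            dist_B=_parse_float(row.dist_B, i, "dist_B"),
            zone=zone,
        )
        if known is not None and rec.fight_id not in known:
            raise ReferentialIntegrityError(
                f"row {i}: POI {rec.poi_id} references unknown fight_id {rec.fight_id!r}"
            )
        if rec.dist_A < 0:
            warnings.append(ValidationIssue(i, "dist_A", "negative distance"))
        if rec.dist_B < 0:
            warnings.append(ValidationIssue(i, "dist_B", "negative distance"))
        records.append(rec)
    return ValidatedRecords(records, warnings)


def _records_to_frame(records: Sequence, columns: list[str]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(rows, columns=columns)


def write_fights(records: Sequence[FightRecord], path: str | Path) -> None:
    _records_to_frame(records, FIGHT_COLUMNS).to_csv(path, index=False)


def write_pois(records: Sequence[POIRecord], path: str | Path) -> None:
    _records_to_frame(records, POI_COLUMNS).to_csv(path, index=False)


def _jsonable(x: Any) -> Any:
    """Recursively convert to JSON-safe values; NaN becomes null."""
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, float):
        return None if (math.isnan(x) or math.isinf(x)) else x
    if hasattr(x, "item"):  # numpy scalar
        return _jsonable(x.item())
    return x


def write_results(results: Any, path: str | Path) -> None:
    """Serialize fitted results to a machine-readable JSON file.

    ``results`` may be a result object exposing ``to_json_dict()`` (the
    CoarseResult / DHGLMPosterior types do), a mapping of stage name to
    such objects, or a plain nested mapping already in the documented
    ``stage -> parameter -> {estimate_mean, estimate_sd, ci_low, ci_high,
    p}`` layout.  NaN values are encoded as null.
    """
    payload = _results_payload(results)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _results_payload(results: Any) -> Any:
    if hasattr(results, "to_json_dict"):
        return _jsonable(results.to_json_dict())
    if isinstance(results, dict):
        return {
            str(k): _results_payload(v) if hasattr(v, "to_json_dict") else _jsonable(v)
            for k, v in results.items()
        }
    if isinstance(results, list):
        return [_results_payload(v) for v in results]
    return _jsonable(results)


def read_results(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())
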