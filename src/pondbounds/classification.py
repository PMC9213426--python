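"""Rule-based classification of lentic waterbodies.

Two rule sets are implemented:

* the literature candidate-pond filter — keep waterbodies <= 20 ha in surface
  area and <= 9 m in maximum depth, the screen used when compiling pond data
  from published studies;
* the functional pond definition — ponds are small (< 5 ha), shallow (< 5 m)
  waterbodies with < 30% emergent vegetation cover.  Vegetation takes
  precedence (a heavily vegetated small basin is a wetland, not a pond); among
  open-water bodies depth separates shallow from deep, and area separates
  ponds from shallow lakes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger("pondbounds")

POND = "pond"
WETLAND = "wetland"
SHALLOW_LAKE = "shallow_lake"
LAKE = "lake"
UNCLASSIFIED = "unclassified"
CLASSES = (WETLAND, POND, SHALLOW_LAKE, LAKE, UNCLASSIFIED)


@dataclass
class WaterbodyRecord:
    """One waterbody: morphometry, vegetation cover, labels and metric values."""

    id: str
    surface_area_ha: float | None = None
    max_depth_m: float | None = None
    emergent_veg_pct: float | None = None
    source_label: str = ""
    hydroperiod: str = "unknown"   # permanent | temporary | unknown
    origin: str = "unknown"        # natural | constructed | unknown
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.surface_area_ha is not None and self.surface_area_ha < 0:
            raise ValueError(f"{self.id}: surface_area_ha must be >= 0")
        if self.max_depth_m is not None and self.max_depth_m < 0:
            raise ValueError(f"{self.id}: max_depth_m must be >= 0")
        if self.emergent_veg_pct is not None and not (0 <= self.emergent_veg_pct <= 100):
            raise ValueError(f"{self.id}: emergent_veg_pct must be in [0, 100]")


@dataclass
class ClassificationRule:
    """Thresholds of the functional pond definition.

    Defaults use strict ``<`` for the pond bounds (5 ha, 5 m, 30% vegetation);
    the ``inclusive_*`` flags switch individual bounds to ``<=``.
    """

    area_max_ha: float = 5.0
    depth_max_m: float = 5.0
    veg_max_pct: float = 30.0
    inclusive_area: bool = False
    inclusive_depth: bool = False
    inclusive_veg: bool = False

    def __post_init__(self) -> None:
        if min(self.area_max_ha, self.depth_max_m, self.veg_max_pct) <= 0:
            raise ValueError("all classification thresholds must be > 0")

    def _below(self, value: float, bound: float, inclusive: bool) -> bool:
        return value <= bound if inclusive else value < bound


def filter_pond_candidates(
    records: list[WaterbodyRecord],
    area_max: float = 20.0,
    depth_max: float = 9.0,
    keep_missing_depth: bool = True,
) -> list[WaterbodyRecord]:
    """Literature screen: retain records with area <= area_max and depth <= depth_max.

    Records with missing depth are retained by default (with a logged count);
    records with missing area are always dropped — the screen is area-led.
    """
    kept: list[WaterbodyRecord] = []
    n_missing_depth = 0
    for rec in records:
        if rec.surface_area_ha is None or rec.surface_area_ha > area_max:
            continue
        if rec.max_depth_m is None:
            n_missing_depth += 1
            if keep_missing_depth:
                kept.append(rec)
            continue
        if rec.max_depth_m <= depth_max:
            kept.append(rec)
    if n_missing_depth:
        logger.info(
            "candidate filter: %d record(s) lacked depth (%s)",
            n_missing_depth, "retained" if keep_missing_depth else "dropped",
        )
    return kept


def classify_waterbody(record: WaterbodyRecord, rule: ClassificationRule | None = None) -> str:
    """Assign one of wetland / pond / shallow_lake / lake / unclassified.

    Decision order: (1) any required field missing -> unclassified;
    (2) vegetation at or above the wetland bound -> wetland; (3) shallow and
    small -> pond; (4) shallow but large -> shallow_lake; (5) deep -> lake.
    """
    rule = rule or ClassificationRule()
    area, depth, veg = record.surface_area_ha, record.max_depth_m, record.emergent_veg_pct
    if area is None or depth is None or veg is None:
        return UNCLASSIFIED
    if not rule._below(veg, rule.veg_max_pct, rule.inclusive_veg):
        return WETLAND
    if rule._below(depth, rule.depth_max_m, rule.inclusive_depth):
        if rule._below(area, rule.area_max_ha, rule.inclusive_area):
            return POND
        return SHALLOW_LAKE
    return LAKE


def classify_records(
    records: list[WaterbodyRecord], rule: ClassificationRule | None = None
) -> dict[str, str]:
    """Classify a collection; returns ``{record id: class}``."""
    rule = rule or ClassificationRule()
    return {rec.id: classify_waterbody(rec, rule) for rec in records}
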