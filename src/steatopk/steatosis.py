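"""Aggregation and grading of steatosis surfaces from classified tiles.

Whole-slide scans are divided into uniform square tiles, each classified
as microvesicular steatosis, macrovesicular steatosis, non-steatotic
hepatocytes, or vessel lumen (the upstream classifier is out of scope
here).  Surfaces are percentages over non-lumen tiles; micro and macro
add up to the total steatotic surface.  Severity follows the clinical
convention on the fat-laden surface: < 33% mild, 33-66% moderate,
> 66% severe.  Per-animal values average the four liver lobes, weighted
by lobe surface area.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "TILE_LABELS",
    "TileGrid",
    "SteatosisSurfaces",
    "aggregate_tiles",
    "severity_grade",
    "micro_macro_ratio",
    "mean_across_lobes",
]

TILE_LABELS = ("micro", "macro", "non_steatotic", "lumen")

MIN_TILES = 30


@dataclass
class TileGrid:
    """Classified square tiles of one slide region (uniform tile area)."""

    labels: np.ndarray  # 1-D array of strings from TILE_LABELS
    tile_area: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object).reshape(-1)
        bad = set(self.labels) - set(TILE_LABELS)
        if bad:
            raise ValueError(f"unknown tile labels: {sorted(bad)}")
        if self.tile_area <= 0:
            raise ValueError("tile_area must be > 0")


@dataclass
class SteatosisSurfaces:
    """Relative surfaces (%) covered by each steatosis pattern."""

    micro_pct: float
    macro_pct: float
    total_steatotic_pct: float
    lipid_droplet_pct: float | None = None

    def __post_init__(self) -> None:
        for v in (self.micro_pct, self.macro_pct, self.total_steatotic_pct):
            if not 0 <= v <= 100:
                raise ValueError("surfaces must lie in [0, 100]")
        if abs(self.total_steatotic_pct - (self.micro_pct + self.macro_pct)) > 1e-9:
            raise ValueError("total must equal micro + macro")


def aggregate_tiles(grid: TileGrid) -> SteatosisSurfaces:
    """Surface percentages over non-lumen tiles.

    Lumen tiles are excluded from the denominator; requires at least 30
    tiles per image.
    """
    labels = grid.labels
    if labels.size < MIN_TILES:
        raise ValueError(f"need at least {MIN_TILES} tiles, got {labels.size}")
    n_micro = int(np.sum(labels == "micro"))
    n_macro = int(np.sum(labels == "macro"))
    n_non = int(np.sum(labels == "non_steatotic"))
    denom = n_micro + n_macro + n_non
    if denom == 0:
        raise ValueError("all tiles are lumen: no tissue to quantify")
    micro = 100.0 * n_micro / denom
    macro = 100.0 * n_macro / denom
    return SteatosisSurfaces(micro_pct=micro, macro_pct=macro,
                             total_steatotic_pct=micro + macro)


def severity_grade(fat_laden_pct: float) -> str:
    """Clinical severity grade from the fat-laden surface percentage."""
    if not 0 <= fat_laden_pct <= 100:
        raise ValueError("fat-laden surface must lie in [0, 100]")
    if fat_laden_pct < 33:
        return "mild"
    if fat_laden_pct <= 66:
        return "moderate"
    return "severe"


def micro_macro_ratio(micro_pct: float, macro_pct: float) -> float:
    """Micro-to-macrovesicular surface ratio, rounded half-up to 1 decimal.

    Printed as "x.y : 1" in study summaries.
    """
    if macro_pct <= 0:
        raise ValueError("macro surface must be > 0 for a ratio")
    ratio = Decimal(repr(micro_pct / macro_pct)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(ratio)


def mean_across_lobes(per_lobe_surfaces: list[SteatosisSurfaces],
                      per_lobe_areas=None,
                      weighted: bool = True) -> SteatosisSurfaces:
    """Mean steatosis severity across the liver lobes of one animal.

    Weighted by the total surface area of each lobe by default; pass
    ``weighted=False`` (or equal areas) for a plain mean.
    """
    n = len(per_lobe_surfaces)
    if n < 1:
        raise ValueError("need at least one lobe")
    if per_lobe_areas is None:
        areas = np.ones(n)
    else:
        areas = np.asarray(per_lobe_areas, dtype=float)
    if areas.size != n:
        raise ValueError("areas and surfaces must have equal length")
    if np.any(areas <= 0):
        raise ValueError("areas must be > 0")
    w = areas / areas.sum() if weighted else np.full(n, 1.0 / n)

    def avg(vals):
        if any(v is None for v in vals):
            return None
        return float(np.dot(w, np.asarray(vals, dtype=float)))

    micro = avg([s.micro_pct for s in per_lobe_surfaces])
    macro = avg([s.macro_pct for s in per_lobe_surfaces])
    return SteatosisSurfaces(
        micro_pct=micro, macro_pct=macro, total_steatotic_pct=micro + macro,
        lipid_droplet_pct=avg([s.lipid_droplet_pct for s in per_lobe_surfaces]),
    )
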