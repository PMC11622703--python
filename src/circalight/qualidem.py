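"""QUALIDEM well-being scoring: weekly item responses to subscale scores.

QUALIDEM is a proxy-rated quality-of-life instrument for people living with
dementia, completed weekly by care staff. Items are 4-point ratings grouped
into subscales: A care relationship, B positive affect, C negative affect,
D restless tense behaviour, E positive self image, F social relationships,
G social isolation, H feeling at home, I occupation, J other/research items.
Negative-worded items are reverse-coded before summing so larger scores
always mean better quality of life. Subscales I and J are scored and
reported but excluded from the statistical analysis.

The item-to-subscale map ships as editable YAML (see data/qualidem_items.yaml)
because instrument versions differ in item count; scoring logic is
map-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

ANALYSIS_SUBSCALES = tuple("ABCDEFGH")
REPORT_ONLY_SUBSCALES = ("I", "J")


class QualidemError(ValueError):
    """Invalid response sheet or item map."""


@dataclass(frozen=True)
class ItemMap:
    """Instrument structure: item -> (subscale, reverse flag) plus rating range."""

    items: dict[str, tuple[str, bool]]
    rating_min: int
    rating_max: int

    @property
    def subscales(self) -> list[str]:
        return sorted({s for s, _ in self.items.values()})

    def items_of(self, subscale: str) -> list[str]:
        return [i for i, (s, _) in self.items.items() if s == subscale]

    def subscale_max(self, subscale: str) -> int:
        return len(self.items_of(subscale)) * (self.rating_max - self.rating_min)


def load_item_map(source=None) -> ItemMap:
    """Load an item map from YAML (path or parsed dict); default: packaged map."""
    if source is None:
        with resources.files("circalight.data").joinpath("qualidem_items.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    items = {e["item"]: (str(e["subscale"]), bool(e["reverse"])) for e in raw["items"]}
    if len(items) != len(raw["items"]):
        raise QualidemError("duplicate item ids in item map")
    return ItemMap(items=items, rating_min=int(raw["rating_min"]),
                   rating_max=int(raw["rating_max"]))


def score_qualidem(
    response: dict[str, int | float],
    item_map: ItemMap,
    min_answered_fraction: float = 2 / 3,
) -> dict[str, float]:
    """Subscale scores for one weekly response sheet.

    Reverse-coded items contribute (rating_max - rating). A subscale with at
    least ``min_answered_fraction`` of its items answered is prorated to its
    full item count; below that it is flagged missing (NaN).
    """
    lo, hi = item_map.rating_min, item_map.rating_max
    for item, rating in response.items():
        if item in item_map.items and not (pd.isna(rating) or lo <= rating <= hi):
            raise QualidemError(f"rating {rating} for {item} outside [{lo}, {hi}]")
    scores: dict[str, float] = {}
    for sub in item_map.subscales:
        items = item_map.items_of(sub)
        contributions = []
        for item in items:
            rating = response.get(item)
            if rating is None or pd.isna(rating):
                continue
            _, reverse = item_map.items[item]
            contributions.append((hi - rating) if reverse else (rating - lo))
        if len(contributions) < min_answered_fraction * len(items):
            scores[sub] = float("nan")
        else:
            scores[sub] = float(sum(contributions) * len(items) / len(contributions))
    return scores


def score_panel(
    panel: pd.DataFrame,
    item_map: ItemMap | None = None,
    min_answered_fraction: float = 2 / 3,
) -> pd.DataFrame:
    """Score a weekly panel (columns resident_id, week, item_*) to subscales."""
    item_map = item_map or load_item_map()
    item_cols = [c for c in panel.columns if c in item_map.items]
    if not item_cols:
        raise QualidemError("panel contains no known item columns")
    rows = []
    for rec in panel.to_dict("records"):
        resp = {c: rec[c] for c in item_cols}
        scores = score_qualidem(resp, item_map, min_answered_fraction)
        rows.append({"resident_id": rec["resident_id"], "week": rec["week"], **scores})
    return pd.DataFrame(rows)


def select_analysis_subscales(scores: pd.DataFrame) -> pd.DataFrame:
    """Drop report-only subscales (I, J) from a scored table for statistics."""
    keep = [c for c in scores.columns if c not in REPORT_ONLY_SUBSCALES]
    return scores[keep]
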