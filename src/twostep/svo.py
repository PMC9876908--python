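"""Social value orientation (SVO) slider scoring and group classification.

The slider measure presents six primary allocation items; on each the
respondent picks one of nine (self, other) payoff splits.  The SVO angle is

    angle = atan( (mean_other - 50) / (mean_self - 50) )   [degrees]

where the means are taken over the six chosen allocations and 50 points is
the scale origin.  Archetypal responders on the bundled item menu score
7.82 deg (complete individualism), -16.26 deg (competitiveness) and 61.39
deg (perfect altruism, the measure's attainable maximum).

Two classifications are provided: a strict one keeping only pronounced
groups (prosocial at or above the inequity-aversion archetype 37.48 deg,
proself at or below the individualism archetype 7.82 deg, everyone else
intermediate) and the measure's conventional prosocial/proself split at
22.45 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Sequence

import pandas as pd

STRICT_PROSOCIAL_DEG = 37.48  # inequity-aversion archetype
STRICT_PROSELF_DEG = 7.82  # complete-individualism archetype
CONVENTIONAL_SPLIT_DEG = 22.45
ALTRUIST_BOUNDARY_DEG = 57.15
COMPETITOR_BOUNDARY_DEG = 12.04

_ORIGIN = 50.0


class SvoUndefinedError(ValueError):
    """Mean allocation sits exactly at the (50, 50) origin; angle undefined."""


@dataclass(frozen=True)
class SliderResponse:
    """One primary item's chosen allocation."""

    item_id: int
    self_payoff: float
    other_payoff: float


@dataclass(frozen=True)
class SvoResult:
    angle_deg: float
    group_strict: str
    group_conventional: str
    category_full: str
    at_boundary: bool


def load_item_table() -> pd.DataFrame:
    """The six primary slider items: item_id, option (1-9), self/other payoff."""
    text = resources.files("twostep.data").joinpath("svo_primary_items.csv").read_text()
    return pd.read_csv(StringIO(text))


def _validate_responses(
    responses: Sequence[SliderResponse], item_table: pd.DataFrame
) -> None:
    ids = sorted(r.item_id for r in responses)
    expected = sorted(item_table["item_id"].unique())
    if ids != expected:
        raise ValueError(f"expected exactly items {expected}, got {ids}")
    for r in responses:
        rows = item_table[item_table["item_id"] == r.item_id]
        ok = (
            (rows["self_payoff"] == r.self_payoff)
            & (rows["other_payoff"] == r.other_payoff)
        ).any()
        if not ok:
            raise ValueError(
                f"item {r.item_id}: allocation ({r.self_payoff}, {r.other_payoff}) "
                "is not one of the item's slider options"
            )


def svo_angle(
    responses: Sequence[SliderResponse],
    item_table: pd.DataFrame | None = None,
    validate: bool = True,
) -> float:
    """SVO angle in degrees from the six primary-item allocations."""
    if item_table is None:
        item_table = load_item_table()
    if validate:
        _validate_responses(responses, item_table)
    mean_self = sum(r.self_payoff for r in responses) / len(responses)
    mean_other = sum(r.other_payoff for r in responses) / len(responses)
    dx, dy = mean_self - _ORIGIN, mean_other - _ORIGIN
    if dx == 0.0 and dy == 0.0:
        raise SvoUndefinedError("mean allocation equals the 50-point origin")
    return math.degrees(math.atan2(dy, dx))


def classify_strict(angle_deg: float) -> str:
    """Pronounced groups only: prosocial >= 37.48, proself <= 7.82, else intermediate.

    Boundary angles are included in the named group (an archetypal
    responder must fall in its own category).
    """
    if angle_deg >= STRICT_PROSOCIAL_DEG:
        return "prosocial"
    if angle_deg <= STRICT_PROSELF_DEG:
        return "proself"
    return "intermediate"


def classify_conventional(angle_deg: float) -> str:
    """Conventional split: prosocial strictly above 22.45 deg, else proself."""
    return "prosocial" if angle_deg > CONVENTIONAL_SPLIT_DEG else "proself"


def classify_full(angle_deg: float) -> str:
    """Four-way categories of the original measure."""
    if angle_deg > ALTRUIST_BOUNDARY_DEG:
        return "altruist"
    if angle_deg > CONVENTIONAL_SPLIT_DEG:
        return "prosocial"
    if angle_deg > COMPETITOR_BOUNDARY_DEG:
        return "individualist"
    return "competitor"


def score_responses(
    responses: Sequence[SliderResponse], item_table: pd.DataFrame | None = None
) -> SvoResult:
    angle = svo_angle(responses, item_table)
    return SvoResult(
        angle_deg=angle,
        group_strict=classify_strict(angle),
        group_conventional=classify_conventional(angle),
        category_full=classify_full(angle),
        at_boundary=angle in (STRICT_PROSOCIAL_DEG, STRICT_PROSELF_DEG,
                              CONVENTIONAL_SPLIT_DEG),
    )


# -- CSV dialect -----------------------------------------------------------

RESPONSE_COLUMNS = ["participant_id", "item_id", "self_payoff", "other_payoff"]


def responses_to_frame(cohort: dict) -> pd.DataFrame:
    rows = [
        {
            "participant_id": pid,
            "item_id": r.item_id,
            "self_payoff": r.self_payoff,
            "other_payoff": r.other_payoff,
        }
        for pid, responses in cohort.items()
        for r in responses
    ]
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def read_responses(path: str | Path) -> dict[str, list[SliderResponse]]:
    df = pd.read_csv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SVO response file missing columns: {missing}")
    return {
        str(pid): [
            SliderResponse(int(r.item_id), float(r.self_payoff), float(r.other_payoff))
            for r in grp.itertuples(index=False)
        ]
        for pid, grp in df.groupby("participant_id", sort=True)
    }


def score_cohort(cohort: dict, item_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Angle and group labels per participant, CSV-ready."""
    if item_table is None:
        item_table = load_item_table()
    rows = []
    for pid, responses in cohort.items():
        res = score_responses(responses, item_table)
        rows.append(
            {
                "participant_id": pid,
                "angle_deg": res.angle_deg,
                "group_strict": res.group_strict,
                "group_conventional": res.group_conventional,
            }
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "angle_deg", "group_strict",
                       "group_conventional"]
    )
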