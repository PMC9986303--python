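"""Composite neurological scoring rubric for the ovine stroke model.

Ten criteria grouped into demeanour (activity/consciousness), behaviour
(food debris, torticollis, limb flexion, ataxia, circling), left/right
postural reactions (hemi-standing, forelimb hopping, lateral dragging —
scored per body side with quarter-point per-limb modifiers for knuckling,
partial correction and limb drag), and wheelbarrowing.  Zero is normal;
higher scores indicate worse deficit.

The rubric's maximum total is computed from the criterion definitions, not
hard-coded: read literally, the per-side postural maximum is 11.75 and the
grand total 36.5, whereas the protocol's prose quotes a maximum of 36.  The
0.5-point discrepancy is surfaced via :func:`rubric_max_total` and never
silently resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BASELINE_SESSIONS, ValidationError

MODIFIER_STEP = 0.25

SIDES = ("left", "right")
SIDE_LIMBS = {"left": ("FL_L", "HL_L"), "right": ("FL_R", "HL_R")}


@dataclass(frozen=True)
class Criterion:
    id: int
    name: str
    max_base: int
    laterality: str = "none"          # none | per_side | per_limb
    limbs: tuple[str, ...] = ()       # limbs carrying per-limb bases/modifiers
    modifiers: tuple[str, ...] = ()   # quarter-point modifier names, one slot per limb

    def base_components(self) -> tuple[str, ...]:
        if self.laterality == "none":
            return ("base",)
        if self.laterality == "per_side":
            return tuple(f"base_{s}" for s in SIDES)
        return tuple(f"base_{limb}" for limb in self.limbs)

    def modifier_components(self) -> tuple[str, ...]:
        return tuple(f"{m}_{limb}" for m in self.modifiers for limb in self.limbs)

    def components(self) -> tuple[str, ...]:
        return self.base_components() + self.modifier_components()

    def max_score(self) -> float:
        n_bases = len(self.base_components())
        return n_bases * self.max_base + len(self.modifier_components()) * MODIFIER_STEP


@dataclass(frozen=True)
class Rubric:
    criteria: tuple[Criterion, ...]

    def criterion(self, cid: int) -> Criterion:
        for c in self.criteria:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def max_total(self) -> float:
        return float(sum(c.max_score() for c in self.criteria))


ALL_LIMBS = ("FL_L", "FL_R", "HL_L", "HL_R")
FORELIMBS = ("FL_L", "FL_R")

#: The study rubric.  Named score levels are listed in each criterion's docstring
#: equivalent below: e.g. demeanour 0 normal / 1 apathetic / 2 stupor / 3 comatose.
DEFAULT_RUBRIC = Rubric(criteria=(
    Criterion(1, "state_of_activity_consciousness", 3),
    Criterion(2, "food_debris_in_mouth", 1),
    Criterion(3, "torticollis", 1),
    Criterion(4, "partial_flexion_fetlock_carpus", 1),
    Criterion(5, "ataxia_dysmetria", 3),
    Criterion(6, "circling", 2),
    Criterion(7, "hemi_standing", 4, "per_side", ALL_LIMBS, ("knuckling",)),
    Criterion(8, "forelimb_hopping", 2, "per_side", FORELIMBS, ("knuckling",)),
    Criterion(9, "lateral_dragging", 2, "per_limb", ALL_LIMBS, ("partial", "drag")),
    Criterion(10, "wheelbarrowing", 2),
))

#: Named demeanour levels of criterion 1.
DEMEANOUR_LEVELS = {"normal": 0, "apathetic": 1, "stupor": 2, "comatose": 3}

BEHAVIOUR_CRITERIA = (2, 3, 4, 5, 6)
POSTURAL_CRITERIA = (7, 8, 9)


def rubric_max_total(rubric: Rubric = DEFAULT_RUBRIC) -> tuple[float, str]:
    """Computed maximum total plus a note on the documented 36 vs 36.5 gap."""
    total = rubric.max_total()
    note = (
        "Computed from the criterion table; the protocol prose quotes a "
        "maximum of 36, a 0.5-point discrepancy left visible by design."
        if total != 36.0 else ""
    )
    return total, note


@dataclass
class NeuroScore:
    """Validated per-criterion entries with derived subscores."""

    animal_id: str
    session: str
    entries: dict[int, dict[str, float]]  # criterion id -> component -> value
    rubric: Rubric = field(default=DEFAULT_RUBRIC, repr=False)

    @property
    def demeanour(self) -> float:
        return sum(self.entries[1].values())

    @property
    def behaviour(self) -> float:
        return float(sum(sum(self.entries[c].values()) for c in BEHAVIOUR_CRITERIA))

    def _postural(self, side: str) -> float:
        limbs = SIDE_LIMBS[side]
        total = 0.0
        for cid in POSTURAL_CRITERIA:
            for comp, val in self.entries[cid].items():
                if comp == f"base_{side}":
                    total += val
                elif any(comp.endswith(f"_{limb}") for limb in limbs):
                    total += val
        return float(total)

    @property
    def postural_left(self) -> float:
        return self._postural("left")

    @property
    def postural_right(self) -> float:
        return self._postural("right")

    @property
    def wheelbarrow(self) -> float:
        return sum(self.entries[10].values())

    @property
    def total(self) -> float:
        return (self.demeanour + self.behaviour + self.postural_left
                + self.postural_right + self.wheelbarrow)

    def subscores(self) -> dict[str, float]:
        return {
            "demeanour": self.demeanour,
            "behaviour": self.behaviour,
            "postural_left": self.postural_left,
            "postural_right": self.postural_right,
            "wheelbarrow": self.wheelbarrow,
            "total": self.total,
        }


def _check_value(crit: Criterion, comp: str, value: float) -> str | None:
    if not np.isfinite(value) or value < 0:
        return f"criterion {crit.id} {comp}: value {value} is not a non-negative number"
    if round(value / MODIFIER_STEP, 9) != round(value / MODIFIER_STEP):
        return f"criterion {crit.id} {comp}: value {value} is off the 0.25-point grid"
    if comp.startswith("base"):
        if value != int(value):
            return f"criterion {crit.id} {comp}: base scores are whole points, got {value}"
        if value > crit.max_base:
            return (f"criterion {crit.id} {comp}: base score {value} exceeds "
                    f"maximum {crit.max_base}")
    else:
        if value not in (0.0, MODIFIER_STEP):
            return (f"criterion {crit.id} {comp}: modifier must be 0 or "
                    f"{MODIFIER_STEP}, got {value}")
    return None


def validate_sheet(
    raw: pd.DataFrame, rubric: Rubric = DEFAULT_RUBRIC
) -> NeuroScore:
    """Build a NeuroScore from a tidy score sheet.

    The sheet has columns ``animal, session, criterion, component, value``
    with one row per criterion component; modifier components may be omitted
    (treated as 0), base components are mandatory.  Out-of-range or
    off-grid values are rejected with per-field messages.
    """
    required_cols = {"animal", "session", "criterion", "component", "value"}
    missing_cols = required_cols - set(raw.columns)
    if missing_cols:
        raise ValidationError(f"score sheet missing columns: {sorted(missing_cols)}")
    animals = raw["animal"].astype(str).unique()
    sessions = raw["session"].astype(str).unique()
    if len(animals) != 1 or len(sessions) != 1:
        raise ValidationError(
            "validate_sheet expects one animal-session sheet; "
            f"got animals={list(animals)}, sessions={list(sessions)}"
        )
    errors: list[str] = []
    entries: dict[int, dict[str, float]] = {}
    seen = {(int(r.criterion), str(r.component)) for r in raw.itertuples()}
    for crit in rubric.criteria:
        entries[crit.id] = {}
        sheet = raw[raw["criterion"] == crit.id]
        by_comp = dict(zip(sheet["component"].astype(str), sheet["value"].astype(float)))
        unknown = set(by_comp) - set(crit.components())
        if unknown:
            errors.append(f"criterion {crit.id}: unknown components {sorted(unknown)}")
        for comp in crit.base_components():
            if comp not in by_comp:
                errors.append(f"criterion {crit.id} ({crit.name}): missing entry {comp!r}")
                continue
            err = _check_value(crit, comp, by_comp[comp])
            if err:
                errors.append(err)
            else:
                entries[crit.id][comp] = by_comp[comp]
        for comp in crit.modifier_components():
            val = by_comp.get(comp, 0.0)
            err = _check_value(crit, comp, val)
            if err:
                errors.append(err)
            elif val:
                entries[crit.id][comp] = val
    stray = {c for c, _ in seen} - {c.id for c in rubric.criteria}
    if stray:
        errors.append(f"unknown criteria in sheet: {sorted(stray)}")
    if errors:
        raise ValidationError("invalid score sheet:\n  " + "\n  ".join(errors))
    return NeuroScore(str(animals[0]), str(sessions[0]), entries, rubric)


def load_score_sheets(
    raw: pd.DataFrame, rubric: Rubric = DEFAULT_RUBRIC
) -> list[NeuroScore]:
    """Validate every (animal, session) sheet in a combined score file."""
    out = []
    for (_, _), sheet in raw.groupby(["animal", "session"], sort=True):
        out.append(validate_sheet(sheet, rubric))
    return out


def scores_frame(scores: list[NeuroScore]) -> pd.DataFrame:
    """Tidy per-animal-session subscore table."""
    rows = []
    for s in scores:
        row = {"animal": s.animal_id, "session": s.session}
        row.update(s.subscores())
        rows.append(row)
    return pd.DataFrame(rows)


def subscore_summary(
    scores: list[NeuroScore],
    baseline_sessions=BASELINE_SESSIONS,
    post_session: str = "D3",
) -> pd.DataFrame:
    """Per-animal mean-baseline and post values for every subscore.

    Baseline sessions are averaged into a single pre-stroke value per
    subscore (the pre/post comparisons use this mean); animals without a
    post session are excluded with a warning.
    """
    df = scores_frame(scores)
    subcols = ["demeanour", "behaviour", "postural_left", "postural_right",
               "wheelbarrow", "total"]
    rows = []
    for animal, grp in df.groupby("animal", sort=True):
        base = grp[grp["session"].isin(baseline_sessions)]
        post = grp[grp["session"] == post_session]
        if base.empty:
            raise ValidationError(f"animal {animal}: no baseline sessions")
        if post.empty:
            warnings.warn(f"animal {animal}: no post session {post_session!r}; excluded")
            continue
        for sub in subcols:
            rows.append({
                "animal": animal,
                "subscore": sub,
                "mean_baseline": float(base[sub].mean()),
                "post": float(post[sub].iloc[0]),
            })
    return pd.DataFrame(rows)
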