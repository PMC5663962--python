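"""Focal-follow and interaction tables, and dyadic observation assembly.

The sampling design is the focal follow: one timed observation bout (up to 30
minutes) of a young female in one activity (feeding or resting), recording the
aggregation members present and every interaction of the focal. The analysis
unit is the dyad (focal j, partner i) within an activity: the affiliative
interaction count y_ij together with the co-occurrence exposure gamma_ij, the
total focal minutes of j during which i was present in the aggregation and
therefore available to interact. ln(gamma) enters the models as an offset.

CSV schemas
-----------
follows: follow_id, focal_id, date (ISO-8601), activity, duration_minutes,
         present_ids (semicolon-separated ids)
interactions: follow_id, partner_id, itype
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .population_model import (
    DataIntegrityError,
    FocalStatus,
    PartnerCategoryFlags,
    Registry,
    STRATA,
    categorize_partner,
    covariate_order,
    covariate_vector,
    orphan_status,
)

ACTIVITIES = ("feeding", "resting")
MAX_FOLLOW_MINUTES = 30.0

#: The six interaction types indicative of bonding; all others are retained
#: on read but filtered from analysis.
AFFILIATIVE_TYPES = frozenset({
    "bodily_contact", "trunk_touch", "greeting",
    "allomothering", "play", "trunk_to_mouth",
})


class ValidationError(ValueError):
    """Malformed input rows; message lists offending CSV line numbers."""


@dataclass(frozen=True)
class FocalFollow:
    """One timed observation bout of one focal in one activity."""

    follow_id: str
    focal_id: str
    date: _dt.date
    activity: str
    duration_minutes: float
    present_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"{self.follow_id}: unknown activity {self.activity!r}")
        if not (0.0 < self.duration_minutes <= MAX_FOLLOW_MINUTES):
            raise ValueError(
                f"{self.follow_id}: duration {self.duration_minutes} outside (0, 30]"
            )
        if self.focal_id in self.present_ids:
            raise ValueError(f"{self.follow_id}: focal listed among present_ids")


@dataclass(frozen=True)
class InteractionEvent:
    """A single interaction between the focal and one partner during a follow."""

    follow_id: str
    partner_id: str
    itype: str

    @property
    def is_affiliative(self) -> bool:
        return self.itype in AFFILIATIVE_TYPES


@dataclass
class DyadObservation:
    """Per-(focal, partner, activity) count, exposure, and covariates."""

    focal_id: str
    partner_id: str
    activity: str
    stratum: str
    y: int
    gamma_minutes: float
    covariates: np.ndarray
    flags: PartnerCategoryFlags = field(repr=False)

    def __post_init__(self) -> None:
        if self.gamma_minutes <= 0:
            raise ValueError("dyads with zero exposure must be excluded, not stored")
        if self.y < 0:
            raise ValueError("negative interaction count")

    @property
    def rate(self) -> float:
        """Interactions per minute of co-occurrence exposure."""
        return self.y / self.gamma_minutes


def _year_fraction(date: _dt.date) -> float:
    start = _dt.date(date.year, 1, 1)
    length = 366.0 if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0) else 365.0
    return date.year + (date - start).days / length


def read_follows(path) -> list[FocalFollow]:
    """Read and validate the follows CSV; malformed rows abort with line numbers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"follow_id", "focal_id", "date", "activity",
                "duration_minutes", "present_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"follows CSV missing columns: {sorted(missing)}")
    follows: list[FocalFollow] = []
    errors: list[str] = []
    seen_keys: dict[tuple[str, str, str], int] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            date = _dt.date.fromisoformat(row["date"])
            present = frozenset(p for p in row["present_ids"].split(";") if p)
            fol = FocalFollow(
                follow_id=row["follow_id"],
                focal_id=row["focal_id"],
                date=date,
                activity=row["activity"],
                duration_minutes=float(row["duration_minutes"]),
                present_ids=present,
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
            continue
        key = (fol.focal_id, fol.activity, row["date"])
        if key in seen_keys:
            errors.append(
                f"line {line}: second {fol.activity} follow of {fol.focal_id} on "
                f"{row['date']} (first at line {seen_keys[key]})"
            )
            continue
        seen_keys[key] = line
        follows.append(fol)
    if errors:
        raise ValidationError("invalid follow rows:\n" + "\n".join(errors))
    return follows


def read_interactions(
    path, follows: Optional[Sequence[FocalFollow]] = None
) -> list[InteractionEvent]:
    """Read the interactions CSV; with ``follows`` given, check referential
    integrity (known follow_id, partner among that follow's present_ids)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"follow_id", "partner_id", "itype"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"interactions CSV missing columns: {sorted(missing)}")
    events = [
        InteractionEvent(row["follow_id"], row["partner_id"], row["itype"])
        for _, row in df.iterrows()
    ]
    if follows is not None:
        by_id = {f.follow_id: f for f in follows}
        errors = []
        for idx, ev in enumerate(events):
            line = idx + 2
            fol = by_id.get(ev.follow_id)
            if fol is None:
                errors.append(f"line {line}: unknown follow_id {ev.follow_id!r}")
            elif ev.partner_id not in fol.present_ids:
                errors.append(
                    f"line {line}: partner {ev.partner_id!r} not present in "
                    f"follow {ev.follow_id!r}"
                )
        if errors:
            raise ValidationError("invalid interaction rows:\n" + "\n".join(errors))
    return events


def write_follows(follows: Iterable[FocalFollow], path) -> None:
    pd.DataFrame([{
        "follow_id": f.follow_id,
        "focal_id": f.focal_id,
        "date": f.date.isoformat(),
        "activity": f.activity,
        "duration_minutes": f.duration_minutes,
        "present_ids": ";".join(sorted(f.present_ids)),
    } for f in follows]).to_csv(path, index=False)


def write_interactions(events: Iterable[InteractionEvent], path) -> None:
    pd.DataFrame([{
        "follow_id": e.follow_id, "partner_id": e.partner_id, "itype": e.itype,
    } for e in events]).to_csv(path, index=False)


def study_window(follows: Sequence[FocalFollow]) -> tuple[float, float]:
    """(start, end) of the study as fractional calendar years, from follow dates."""
    if not follows:
        raise ValueError("no follows")
    years = [_year_fraction(f.date) for f in follows]
    return min(years), max(years)


def focal_statuses(
    follows: Sequence[FocalFollow],
    registry: Registry,
    activity: Optional[str] = None,
    window: Optional[tuple[float, float]] = None,
) -> dict[str, FocalStatus]:
    """Orphan status and mean follow age for every focal appearing in ``follows``.

    Mean age is averaged over that focal's follows (restricted to ``activity``
    when given); orphan status is evaluated at the end of the study window, so
    a focal whose mother died during the study counts as an orphan.
    """
    if window is None:
        window = study_window(follows)
    subset = [f for f in follows if activity is None or f.activity == activity]
    by_focal: dict[str, list[FocalFollow]] = {}
    for f in subset:
        by_focal.setdefault(f.focal_id, []).append(f)
    statuses: dict[str, FocalStatus] = {}
    for focal_id, fols in by_focal.items():
        rec = registry.get(focal_id)
        if rec is None:
            raise DataIntegrityError(f"focal {focal_id!r} not in registry")
        mean_age = float(np.mean([_year_fraction(f.date) - rec.birth_year for f in fols]))
        statuses[focal_id] = orphan_status(
            rec, registry, reference_year=window[1], mean_age_years=mean_age
        )
    return statuses


def build_dyad_table(
    follows: Sequence[FocalFollow],
    interactions: Sequence[InteractionEvent],
    registry: Registry,
    activity: str,
    stratum: str,
    statuses: Optional[dict[str, FocalStatus]] = None,
    window: Optional[tuple[float, float]] = None,
) -> list[DyadObservation]:
    """Assemble the dyadic observation table for one activity and stratum.

    One row per (focal, partner) pair with positive co-occurrence exposure:
    gamma_ij sums the durations of j's follows of this activity in which i was
    present, and y_ij counts affiliative events with i during those follows.
    Pairs never co-present are omitted (no zero-exposure rows). Output is
    sorted by (focal_id, partner_id), so it is invariant to input row order.
    """
    if activity not in ACTIVITIES:
        raise ValueError(f"unknown activity {activity!r}")
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    if window is None:
        window = study_window(follows)
    if statuses is None:
        statuses = focal_statuses(follows, registry, activity=activity, window=window)

    act_follows = [f for f in follows if f.activity == activity]
    by_follow = {f.follow_id: f for f in act_follows}
    events_by_follow: dict[str, list[InteractionEvent]] = {}
    for ev in interactions:
        if ev.follow_id in by_follow:
            if ev.partner_id not in by_follow[ev.follow_id].present_ids:
                raise DataIntegrityError(
                    f"event with {ev.partner_id!r} in follow {ev.follow_id!r}: "
                    "partner not among present_ids"
                )
            events_by_follow.setdefault(ev.follow_id, []).append(ev)

    follows_by_focal: dict[str, list[FocalFollow]] = {}
    for f in act_follows:
        follows_by_focal.setdefault(f.focal_id, []).append(f)

    dyads: list[DyadObservation] = []
    for focal_id in sorted(follows_by_focal):
        status = statuses[focal_id]
        if status.stratum != stratum:
            continue
        focal_rec = registry[focal_id]
        fols = follows_by_focal[focal_id]
        gamma: dict[str, float] = {}
        counts: dict[str, int] = {}
        for f in fols:
            for pid in f.present_ids:
                gamma[pid] = gamma.get(pid, 0.0) + f.duration_minutes
            for ev in events_by_follow.get(f.follow_id, ()):
                if ev.is_affiliative:
                    counts[ev.partner_id] = counts.get(ev.partner_id, 0) + 1
        for pid in sorted(gamma):
            partner_rec = registry.get(pid)
            if partner_rec is None:
                raise DataIntegrityError(
                    f"partner {pid!r} (present with {focal_id}) not in registry"
                )
            flags = categorize_partner(focal_rec, partner_rec, registry, window)
            dyads.append(DyadObservation(
                focal_id=focal_id,
                partner_id=pid,
                activity=activity,
                stratum=stratum,
                y=counts.get(pid, 0),
                gamma_minutes=gamma[pid],
                covariates=covariate_vector(status, flags, stratum),
                flags=flags,
            ))
    return dyads


def dyads_to_frame(dyads: Sequence[DyadObservation]) -> pd.DataFrame:
    """Tidy audit table mirroring the dyadic observations."""
    if not dyads:
        return pd.DataFrame(columns=["focal_id", "partner_id", "activity",
                                     "stratum", "y", "gamma_minutes"])
    order = covariate_order(dyads[0].stratum)
    rows = []
    for d in dyads:
        row = {
            "focal_id": d.focal_id, "partner_id": d.partner_id,
            "activity": d.activity, "stratum": d.stratum,
            "y": d.y, "gamma_minutes": d.gamma_minutes,
        }
        row.update(dict(zip(order, d.covariates)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_dyad_table(dyads: Sequence[DyadObservation], path) -> None:
    dyads_to_frame(dyads).to_csv(path, index=False)


def sampling_summary(
    follows: Sequence[FocalFollow],
    statuses: dict[str, FocalStatus],
) -> pd.DataFrame:
    """Per-(activity, stratum) sampling effort in the study's reporting format.

    Columns: number of focals, total hours, and median (IQR) of per-focal
    minutes and follow counts.
    """
    rows = []
    for activity in ACTIVITIES:
        act = [f for f in follows if f.activity == activity]
        for stratum in STRATA:
            sub = [f for f in act if statuses[f.focal_id].stratum == stratum]
            focals = sorted({f.focal_id for f in sub})
            minutes = np.array([
                sum(f.duration_minutes for f in sub if f.focal_id == fid)
                for fid in focals
            ])
            n_follows = np.array([
                sum(1 for f in sub if f.focal_id == fid) for fid in focals
            ])
            row = {"activity": activity, "stratum": stratum,
                   "n_focals": len(focals),
                   "total_hours": minutes.sum() / 60.0 if focals else 0.0}
            for label, vals in (("minutes", minutes), ("follows", n_follows)):
                if len(vals):
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                else:
                    q1 = med = q3 = 0.0
                row[f"{label}_median"] = med
                row[f"{label}_q1"] = q1
                row[f"{label}_q3"] = q3
            rows.append(row)
    return pd.DataFrame(rows)
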