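"""Individual registry, orphan status, and partner-category covariates.

The unit of the study population is the individually known elephant: its sex,
birth year, maternal link, core social group, and (where relevant) death year
or natal dispersal. From these attributes we derive the focal-level quantities
(orphan status, age at orphaning, mean age over follows) and the dyad-level
partner categories (age mate, aunt, bull, calf, matriarch, mother, sister)
that enter the regression models as covariates.

Ages are computed as differences of (fractional) calendar years; the data do
not support finer resolution. "Adult" means a female aged >= 18 years, one
year past the upper bound of the focal sampling class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FEMALE = "F"
MALE = "M"

#: Covariates entering the orphan-stratum models, in declared order.
ORPHAN_COVARIATES: tuple[str, ...] = (
    "age", "age_orphaned", "age_mate", "aunt", "bull", "calf", "matriarch", "sister",
)
#: Covariates entering the non-orphan-stratum models, in declared order.
NON_ORPHAN_COVARIATES: tuple[str, ...] = (
    "age", "age_mate", "aunt", "bull", "calf", "matriarch", "mother", "sister",
)
#: Continuous covariates, z-scored within stratum before model fitting.
CONTINUOUS_COVARIATES = frozenset({"age", "age_orphaned"})

ADULT_AGE_YEARS = 18.0
AGE_MATE_WINDOW_YEARS = 2.0
CALF_MAX_AGE_YEARS = 0.5
FOCAL_AGE_RANGE = (6.0, 17.0)

STRATA = ("orphan", "non_orphan")


class DataIntegrityError(ValueError):
    """A record violates referential integrity (e.g. dangling mother id)."""


@dataclass(frozen=True)
class ElephantRecord:
    """One registry entry for an individually identified elephant."""

    id: str
    sex: str
    birth_year: float
    mother_id: Optional[str] = None
    core_group_id: str = ""
    death_year: Optional[float] = None
    dispersed_from_natal: bool = False

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"{self.id}: sex must be 'F' or 'M', got {self.sex!r}")
        if self.death_year is not None and self.death_year < self.birth_year:
            raise ValueError(f"{self.id}: death_year precedes birth_year")

    def age_at(self, year: float) -> float:
        return year - self.birth_year

    def alive_at(self, year: float) -> bool:
        return self.birth_year <= year and (self.death_year is None or self.death_year > year)


@dataclass(frozen=True)
class FocalStatus:
    """Orphan status and mean age of one focal female."""

    focal_id: str
    is_orphan: bool
    age_orphaned_years: Optional[float]
    mean_age_years: float

    def __post_init__(self) -> None:
        if self.is_orphan != (self.age_orphaned_years is not None):
            raise ValueError("age_orphaned_years must be present iff is_orphan")

    @property
    def stratum(self) -> str:
        return "orphan" if self.is_orphan else "non_orphan"


@dataclass(frozen=True)
class PartnerCategoryFlags:
    """Non-exclusive social-category flags of a partner relative to a focal.

    `mother` and `matriarch` are mutually exclusive by construction: the
    matriarch of a group is its oldest living female that is not the focal
    animal's mother (and not the focal itself).
    """

    age_mate: bool = False
    aunt: bool = False
    bull: bool = False
    calf: bool = False
    matriarch: bool = False
    mother: bool = False
    sister: bool = False

    def __post_init__(self) -> None:
        if self.mother and self.matriarch:
            raise ValueError("mother and matriarch are mutually exclusive")

    def as_dict(self) -> dict[str, bool]:
        return {
            "age_mate": self.age_mate,
            "aunt": self.aunt,
            "bull": self.bull,
            "calf": self.calf,
            "matriarch": self.matriarch,
            "mother": self.mother,
            "sister": self.sister,
        }

    def categories(self) -> list[str]:
        return [k for k, v in self.as_dict().items() if v]


class Registry:
    """Validated collection of :class:`ElephantRecord`, keyed by id."""

    def __init__(self, records: Iterable[ElephantRecord]):
        self._records: dict[str, ElephantRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise DataIntegrityError(f"duplicate id {rec.id!r}")
            self._records[rec.id] = rec
        for rec in self._records.values():
            if rec.mother_id is not None:
                mother = self._records.get(rec.mother_id)
                if mother is not None and mother.sex != FEMALE:
                    raise DataIntegrityError(
                        f"{rec.id}: mother_id {rec.mother_id!r} refers to a male record"
                    )

    def __getitem__(self, elephant_id: str) -> ElephantRecord:
        return self._records[elephant_id]

    def get(self, elephant_id: str) -> Optional[ElephantRecord]:
        return self._records.get(elephant_id)

    def __contains__(self, elephant_id: str) -> bool:
        return elephant_id in self._records

    def __iter__(self) -> Iterator[ElephantRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def ids(self) -> list[str]:
        return list(self._records)

    def members_of_group(self, group_id: str) -> list[ElephantRecord]:
        return [r for r in self._records.values() if r.core_group_id == group_id]

    def group_ids(self) -> list[str]:
        return sorted({r.core_group_id for r in self._records.values()})

    # ---- CSV interface: empty string means absent -------------------------

    @classmethod
    def from_csv(cls, path) -> "Registry":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"id", "sex", "birth_year", "mother_id", "core_group_id",
                    "death_year", "dispersed_from_natal"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry CSV missing columns: {sorted(missing)}")
        records = []
        for _, row in df.iterrows():
            records.append(ElephantRecord(
                id=row["id"],
                sex=row["sex"],
                birth_year=float(row["birth_year"]),
                mother_id=row["mother_id"] or None,
                core_group_id=row["core_group_id"],
                death_year=float(row["death_year"]) if row["death_year"] else None,
                dispersed_from_natal=row["dispersed_from_natal"].lower()
                in ("true", "1", "yes"),
            ))
        return cls(records)

    def to_csv(self, path) -> None:
        rows = [{
            "id": r.id,
            "sex": r.sex,
            "birth_year": r.birth_year,
            "mother_id": r.mother_id or "",
            "core_group_id": r.core_group_id,
            "death_year": "" if r.death_year is None else r.death_year,
            "dispersed_from_natal": r.dispersed_from_natal,
        } for r in self._records.values()]
        pd.DataFrame(rows).to_csv(path, index=False)


def matriarch_of_group(
    registry: Registry,
    group_id: str,
    at_year: float,
    exclude_ids: Iterable[str] = (),
) -> Optional[str]:
    """Id of the oldest living female in a core group at ``at_year``.

    Ids in ``exclude_ids`` (typically the focal and its mother) are not
    eligible. Ties in birth year break lexicographically for determinism.
    Returns None if the group has no eligible living female.
    """
    excluded = set(exclude_ids)
    candidates = [
        r for r in registry.members_of_group(group_id)
        if r.sex == FEMALE and r.id not in excluded and r.alive_at(at_year)
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda r: (r.birth_year, r.id)).id


def orphan_status(
    focal: ElephantRecord,
    registry: Registry,
    reference_year: float,
    mean_age_years: Optional[float] = None,
) -> FocalStatus:
    """Classify a focal female as orphan or non-orphan at ``reference_year``.

    A focal is an orphan iff her mother died on or before the reference year;
    age at orphaning is the mother's death year minus the focal's birth year.
    ``mean_age_years`` is the focal's average age across her follows; when not
    supplied, the age at the reference year is used.

    Raises
    ------
    DataIntegrityError
        If ``focal.mother_id`` is set but the mother's record is absent.
    """
    if focal.sex != FEMALE:
        raise ValueError(f"focal {focal.id} is not female")
    if mean_age_years is None:
        mean_age_years = focal.age_at(reference_year)
    is_orphan = False
    age_orphaned: Optional[float] = None
    if focal.mother_id is not None:
        mother = registry.get(focal.mother_id)
        if mother is None:
            raise DataIntegrityError(
                f"focal {focal.id}: mother {focal.mother_id!r} not in registry"
            )
        if mother.death_year is not None and mother.death_year <= reference_year:
            is_orphan = True
            age_orphaned = mother.death_year - focal.birth_year
    return FocalStatus(focal.id, is_orphan, age_orphaned, mean_age_years)


def categorize_partner(
    focal: ElephantRecord,
    partner: ElephantRecord,
    registry: Registry,
    study_window: tuple[float, float],
) -> PartnerCategoryFlags:
    """Assign partner-category flags for one (focal, partner) dyad.

    Flags are non-exclusive: a maternal sister born within two years of the
    focal is both ``sister`` and ``age_mate``. Age comparisons use ages at the
    study midpoint; the calf criterion (at most six months old at some point
    during the study) uses the full study window. Missing ancestry information
    yields False for kin flags and is logged.
    """
    if focal.id == partner.id:
        raise ValueError("focal and partner must differ")
    start, end = study_window
    mid = 0.5 * (start + end)

    age_mate = abs(partner.age_at(mid) - focal.age_at(mid)) <= AGE_MATE_WINDOW_YEARS
    bull = partner.sex == MALE and partner.dispersed_from_natal
    calf = (partner.birth_year + CALF_MAX_AGE_YEARS >= start
            and partner.birth_year <= end)
    mother = focal.mother_id is not None and partner.id == focal.mother_id

    sister = False
    aunt = False
    if focal.mother_id is None:
        logger.debug("focal %s has no recorded mother; kin flags false", focal.id)
    else:
        sister = (partner.sex == FEMALE
                  and partner.mother_id == focal.mother_id
                  and not mother)
        mother_rec = registry.get(focal.mother_id)
        if mother_rec is None or mother_rec.mother_id is None:
            logger.debug(
                "focal %s: maternal grandmother unknown; aunt flag false", focal.id
            )
        else:
            aunt = (partner.sex == FEMALE
                    and not mother
                    and partner.mother_id == mother_rec.mother_id
                    and partner.age_at(mid) >= ADULT_AGE_YEARS)

    exclude = {focal.id}
    if focal.mother_id is not None:
        exclude.add(focal.mother_id)
    matriarch = partner.id == matriarch_of_group(
        registry, partner.core_group_id, mid, exclude_ids=exclude
    )

    return PartnerCategoryFlags(
        age_mate=age_mate, aunt=aunt, bull=bull, calf=calf,
        matriarch=matriarch, mother=mother, sister=sister,
    )


def covariate_order(stratum: str) -> tuple[str, ...]:
    if stratum == "orphan":
        return ORPHAN_COVARIATES
    if stratum == "non_orphan":
        return NON_ORPHAN_COVARIATES
    raise ValueError(f"unknown stratum {stratum!r}")


def covariate_vector(
    status: FocalStatus,
    flags: PartnerCategoryFlags,
    stratum: str,
) -> np.ndarray:
    """Raw covariate values for one dyad, in the stratum's declared order.

    Continuous entries (age, age orphaned) are raw years here; they are
    z-scored within stratum when the design matrix is assembled (see
    :func:`standardize_design`).
    """
    if status.stratum != stratum:
        raise ValueError(
            f"focal {status.focal_id} is {status.stratum}, "
            f"but {stratum} stratum was requested"
        )
    d = flags.as_dict()
    values = []
    for name in covariate_order(stratum):
        if name == "age":
            values.append(status.mean_age_years)
        elif name == "age_orphaned":
            values.append(float(status.age_orphaned_years))  # type: ignore[arg-type]
        else:
            values.append(float(d[name]))
    return np.asarray(values, dtype=float)


def standardize_design(X: np.ndarray, order: tuple[str, ...]) -> np.ndarray:
    """Z-score the continuous columns of a stacked covariate matrix.

    Standardization is within the supplied matrix (i.e. within stratum and
    activity). A continuous column with zero variance is centered only, which
    leaves an all-zero column; the model then estimates its coefficient from
    the prior alone.
    """
    X = np.array(X, dtype=float, copy=True)
    if X.ndim != 2 or X.shape[1] != len(order):
        raise ValueError("X must be (n_dyads, n_covariates) matching `order`")
    for k, name in enumerate(order):
        if name in CONTINUOUS_COVARIATES:
            col = X[:, k]
            sd = col.std()
            X[:, k] = (col - col.mean()) / sd if sd > 0 else col - col.mean()
    return X
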