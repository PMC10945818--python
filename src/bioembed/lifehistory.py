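"""Early-life adversity scoring from longitudinal life-history records.

Individuals accumulate a 0-5 count of binary early-life exposures: drought
in the first year of life, maternal loss before independence, a close-in-age
younger sibling, low maternal dominance rank at birth, and birth into a
large social group.  A separate cohort-level flag records whether the
individual was born before (low-quality) or after (high-quality) the study
population's home-range shift.

Thresholds: drought is < 200 mm first-year rainfall; maternal loss is a
mother's death strictly before the focal's fourth birthday (earliest age of
maturation); a close sibling is a live birth strictly within 1.5 years after
the focal birth; rank and group-size flags use the lowest/highest quartile
of the supplied cohort, computed as the empirical 25th/75th percentile with
linear interpolation and a strict inequality, so ties resolve toward
non-adversity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25

DROUGHT_RAINFALL_MM = 200.0
MATERNAL_LOSS_AGE_Y = 4.0
CLOSE_SIBLING_WINDOW_Y = 1.5

ADVERSITY_COMPONENTS = (
    "drought",
    "maternal_loss",
    "close_sibling",
    "low_maternal_rank",
    "large_group",
)


@dataclass
class LifeHistoryRecord:
    """One individual's early-life record."""

    individual_id: str
    sex: str
    birthdate: date
    mother_id: str | None = None
    maternal_ordinal_rank_at_birth: int | None = None
    group_size_at_birth: int | None = None
    rainfall_first_year_mm: float | None = None
    mother_death_date: date | None = None
    sibling_birthdates: list[date] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.birthdate is None:
            raise ValueError(
                f"individual {self.individual_id!r} has no birthdate"
            )
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if (
            self.maternal_ordinal_rank_at_birth is not None
            and self.maternal_ordinal_rank_at_birth < 1
        ):
            raise ValueError("ordinal rank must be >= 1 (1 = highest status)")
        if (
            self.rainfall_first_year_mm is not None
            and self.rainfall_first_year_mm < 0
        ):
            raise ValueError("rainfall must be non-negative")
        if (
            self.mother_death_date is not None
            and self.mother_death_date < self.birthdate
        ):
            raise ValueError("mother_death_date precedes focal birthdate")


@dataclass
class AdversityProfile:
    """Binary exposures, their 0-5 sum, and the habitat cohort flag.

    Component values are 0, 1, or None (missing; the individual is then
    excluded from models that use the cumulative score).
    """

    individual_id: str
    drought: int | None
    maternal_loss: int | None
    close_sibling: int | None
    low_maternal_rank: int | None
    large_group: int | None
    cumulative: int | None
    habitat_low_quality_at_birth: int | None = None

    @property
    def components(self) -> dict[str, int | None]:
        return {name: getattr(self, name) for name in ADVERSITY_COMPONENTS}

    @property
    def missing_components(self) -> list[str]:
        return [k for k, v in self.components.items() if v is None]


def years_between(start: date, end: date) -> float:
    """Elapsed time in years, days/365.25 convention."""
    return (end - start).days / DAYS_PER_YEAR


def quartile_cutoffs(values: np.ndarray) -> tuple[float, float]:
    """Empirical 25th and 75th percentiles with linear interpolation."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no non-missing values for quartile computation")
    return float(np.percentile(v, 25)), float(np.percentile(v, 75))


def cumulative_adversity(flags: tuple[int | None, ...] | list[int | None]) -> int:
    """Sum of the five binary exposure flags.

    Raises if any flag is missing; callers should exclude such individuals
    from cumulative-score models instead of imputing.
    """
    flags = tuple(flags)
    if len(flags) != len(ADVERSITY_COMPONENTS):
        raise ValueError(f"expected {len(ADVERSITY_COMPONENTS)} flags")
    if any(f is None for f in flags):
        missing = [
            name for name, f in zip(ADVERSITY_COMPONENTS, flags) if f is None
        ]
        raise ValueError(
            "missing adversity flag(s) "
            f"{missing}; exclude this individual from cumulative-score models"
        )
    if any(f not in (0, 1) for f in flags):
        raise ValueError("adversity flags must be binary")
    return int(sum(flags))


def habitat_at_birth(birthdate: date, shift_date: date) -> str:
    """Cohort label: born strictly before the home-range shift -> 'low'."""
    return "low" if birthdate < shift_date else "high"


def score_adversity_components(
    record: LifeHistoryRecord,
    cohort: list[LifeHistoryRecord],
) -> AdversityProfile:
    """Score the five binary early-adversity exposures for one individual.

    Quartile cutoffs for maternal rank and group size are computed over the
    supplied cohort (the population of individuals with data).  A missing
    rank or group size yields a None flag and a None cumulative score.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if not any(r.individual_id == record.individual_id for r in cohort):
        raise ValueError("record must be a member of the supplied cohort")

    # drought: strict < 200 mm in the first year of life
    if record.rainfall_first_year_mm is None:
        drought: int | None = None
    else:
        drought = int(record.rainfall_first_year_mm < DROUGHT_RAINFALL_MM)

    # maternal loss: mother died strictly before focal age 4.0 y
    if record.mother_death_date is None:
        maternal_loss = 0
    else:
        maternal_loss = int(
            years_between(record.birthdate, record.mother_death_date)
            < MATERNAL_LOSS_AGE_Y
        )

    # close-in-age younger sibling: live birth strictly within 1.5 y after focal
    close_sibling = 0
    for sib in record.sibling_birthdates:
        gap = years_between(record.birthdate, sib)
        if 0 < gap < CLOSE_SIBLING_WINDOW_Y:
            close_sibling = 1
            break

    ranks = np.array(
        [
            np.nan
            if r.maternal_ordinal_rank_at_birth is None
            else float(r.maternal_ordinal_rank_at_birth)
            for r in cohort
        ]
    )
    sizes = np.array(
        [
            np.nan
            if r.group_size_at_birth is None
            else float(r.group_size_at_birth)
            for r in cohort
        ]
    )

    # low maternal rank: strictly beyond the 75th percentile of ordinal ranks
    # (larger ordinal = lower status); ties resolve toward non-adversity
    if record.maternal_ordinal_rank_at_birth is None:
        low_maternal_rank: int | None = None
    else:
        _, rank_hi = quartile_cutoffs(ranks)
        low_maternal_rank = int(record.maternal_ordinal_rank_at_birth > rank_hi)

    # large group: strictly above the 75th percentile of group sizes
    if record.group_size_at_birth is None:
        large_group: int | None = None
    else:
        _, size_hi = quartile_cutoffs(sizes)
        large_group = int(record.group_size_at_birth > size_hi)

    flags = (drought, maternal_loss, close_sibling, low_maternal_rank, large_group)
    cumulative = None if any(f is None for f in flags) else int(sum(flags))

    return AdversityProfile(
        individual_id=record.individual_id,
        drought=drought,
        maternal_loss=maternal_loss,
        close_sibling=close_sibling,
        low_maternal_rank=low_maternal_rank,
        large_group=large_group,
        cumulative=cumulative,
    )


def score_cohort(
    cohort: list[LifeHistoryRecord], shift_date: date
) -> pd.DataFrame:
    """Score every individual; returns one row per individual.

    Columns: individual_id, the five component flags, cumulative, and
    habitat_low_quality_at_birth.  Missing flags propagate as NA.
    """
    rows = []
    for rec in cohort:
        prof = score_adversity_components(rec, cohort)
        prof.habitat_low_quality_at_birth = int(
            habitat_at_birth(rec.birthdate, shift_date) == "low"
        )
        rows.append(
            {
                "individual_id": prof.individual_id,
                **prof.components,
                "cumulative": prof.cumulative,
                "habitat_low_quality_at_birth": prof.habitat_low_quality_at_birth,
            }
        )
    df = pd.DataFrame(rows)
    return df.astype(
        {c: "Int64" for c in (*ADVERSITY_COMPONENTS, "cumulative")}
    )


def build_sample_covariates(
    samples: pd.DataFrame,
    records: list[LifeHistoryRecord],
    ranks_by_month: pd.DataFrame,
    shift_date: date,
) -> pd.DataFrame:
    """Assemble per-sample covariates for the mixed models.

    Parameters
    ----------
    samples
        Columns: sample_id, individual_id, collection_date, batch,
        conversion_rate, mean_depth.
    records
        Life-history records for every sampled individual.
    ranks_by_month
        Columns: individual_id, year_month ("YYYY-MM"), ordinal_rank.
        A sample whose collection month has no entry gets a null rank
        (such samples are kept; only Model 1 drops them downstream).
    shift_date
        Home-range shift date, for days_since_habitat_shift.

    Returns
    -------
    DataFrame with one row per sample: sample_id, individual_id,
    age_at_sampling, rank_at_sampling (nullable), sex, batch,
    conversion_rate, mean_depth, days_since_habitat_shift, collection_date.
    """
    by_id = {r.individual_id: r for r in records}
    rank_lut = {
        (row.individual_id, row.year_month): int(row.ordinal_rank)
        for row in ranks_by_month.itertuples()
    }
    rows = []
    for s in samples.itertuples():
        rec = by_id.get(s.individual_id)
        if rec is None:
            raise KeyError(
                f"sample {s.sample_id!r} references unknown individual "
                f"{s.individual_id!r}"
            )
        cdate = _as_date(s.collection_date)
        age = years_between(rec.birthdate, cdate)
        if age < 0:
            raise ValueError(f"sample {s.sample_id!r} collected before birth")
        ym = f"{cdate.year:04d}-{cdate.month:02d}"
        rank = rank_lut.get((s.individual_id, ym))
        born_low = habitat_at_birth(rec.birthdate, shift_date) == "low"
        if born_low:
            days_since = max(0, (cdate - shift_date).days)
        else:
            days_since = 0
        rows.append(
            {
                "sample_id": s.sample_id,
                "individual_id": s.individual_id,
                "age_at_sampling": age,
                "rank_at_sampling": rank,
                "sex": rec.sex,
                "batch": s.batch,
                "conversion_rate": s.conversion_rate,
                "mean_depth": s.mean_depth,
                "habitat_low_quality_at_birth": int(born_low),
                "days_since_habitat_shift": days_since,
                "collection_date": cdate.isoformat(),
            }
        )
    df = pd.DataFrame(rows)
    df["rank_at_sampling"] = df["rank_at_sampling"].astype("Int64")
    return df


def _as_date(x) -> date:
    if isinstance(x, date):
        return x
    return date.fromisoformat(str(x)[:10])


def records_from_frame(df: pd.DataFrame) -> list[LifeHistoryRecord]:
    """Build records from a life-history table (empty string / NA = missing)."""

    def _opt_date(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return None
        return _as_date(v)

    def _opt_num(v, cast):
        if v is None or v == "" or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        return cast(v)

    recs = []
    for row in df.itertuples():
        sibs = []
        raw = getattr(row, "sibling_birthdates", "")
        if isinstance(raw, str) and raw:
            sibs = [_as_date(tok) for tok in raw.split(";") if tok]
        recs.append(
            LifeHistoryRecord(
                individual_id=str(row.individual_id),
                sex=str(row.sex),
                birthdate=_as_date(row.birthdate),
                mother_id=getattr(row, "mother_id", None) or None,
                maternal_ordinal_rank_at_birth=_opt_num(
                    getattr(row, "maternal_ordinal_rank_at_birth", None), int
                ),
                group_size_at_birth=_opt_num(
                    getattr(row, "group_size_at_birth", None), int
                ),
                rainfall_first_year_mm=_opt_num(
                    getattr(row, "rainfall_first_year_mm", None), float
                ),
                mother_death_date=_opt_date(
                    getattr(row, "mother_death_date", None)
                ),
                sibling_birthdates=sibs,
            )
        )
    return recs
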