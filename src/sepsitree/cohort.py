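"""Episode-level cohort model for suspected bacterial infection in
immunocompromised children.

One *episode* is a new clinical suspicion of bacterial infection, marked by
the acquisition of a blood culture, with a residual laboratory sample used
to measure a five-protein serum biomarker panel (IL-8, CCL3, HSPA1B, GZMB,
MMP-8, all in pg/mL).  A subject may contribute several episodes, provided
the utilized samples are spaced at least 24 hours apart.

This module holds the domain types, the eligibility and outcome predicates
(immunocompromise, 72-hour clinical deterioration), sample-selection rules,
and CSV round-trip I/O.  Missing biomarker values are represented as
``None`` — never as zero or a numeric sentinel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterator, Optional, Sequence

import pandas as pd

log = logging.getLogger(__name__)

#: Names of the candidate predictors a risk tree may consult, in canonical order.
BIOMARKERS = ("il8", "ccl3", "hspa1b", "gzmb", "mmp8")
PREDICTORS = BIOMARKERS + ("age_years", "platelet_k_mcl")

#: Neutropenia threshold for eligibility, absolute neutrophil count in K/mcL.
ANC_NEUTROPENIA_THRESHOLD = 0.5

#: Window around the qualifying blood culture within which a residual sample
#: may be used (hours), and the minimum spacing between a subject's utilized
#: samples (hours).
SAMPLE_WINDOW_H = 6.0
SAMPLE_SPACING_H = 24.0

#: Crystalloid resuscitation criterion: >=60 mL/kg in 24 h below 50 kg,
#: >=3 L above.
FLUID_ML_PER_KG = 60.0
FLUID_WEIGHT_CUT_KG = 50.0
FLUID_ABSOLUTE_ML = 3000.0


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """A required CSV column is missing or malformed."""


class IntegrityError(CohortError):
    """Record-level invariant violation (duplicate keys, impossible values)."""


@dataclass(frozen=True)
class BiomarkerPanel:
    """Serum concentrations of the five-biomarker panel, pg/mL.

    ``None`` marks a biomarker that was not measured; any present value must
    be finite and non-negative.
    """

    il8: Optional[float] = None
    ccl3: Optional[float] = None
    hspa1b: Optional[float] = None
    gzmb: Optional[float] = None
    mmp8: Optional[float] = None

    def __post_init__(self) -> None:
        for name in BIOMARKERS:
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise IntegrityError(f"biomarker {name} must be finite and >= 0, got {v!r}")

    def get(self, name: str) -> Optional[float]:
        if name not in BIOMARKERS:
            raise KeyError(name)
        return getattr(self, name)


@dataclass(frozen=True)
class ImmunoCriteria:
    """Inputs to the immunocompromise eligibility predicate.

    ``anc`` is the absolute neutrophil count in K/mcL (``None`` if not
    measured).  Transplant flags only confer eligibility together with
    recent immunosuppression exposure.
    """

    anc: Optional[float] = None
    chemo_within_7d: bool = False
    myeloablative_radiation_within_7d: bool = False
    solid_organ_transplant: bool = False
    bone_marrow_transplant: bool = False
    immunosuppression_within_7d: bool = False

    def __post_init__(self) -> None:
        if self.anc is not None and (not math.isfinite(self.anc) or self.anc < 0):
            raise IntegrityError(f"anc must be finite and >= 0, got {self.anc!r}")


@dataclass(frozen=True)
class DeteriorationEvents:
    """Clinical events within 72 h of evaluation, feeding the composite
    deterioration outcome."""

    icu_transfer_72h: bool = False
    new_respiratory_support_72h: bool = False
    crystalloid_ml_24h: float = 0.0
    weight_kg: float = float("nan")
    new_vasoactive_72h: bool = False
    new_altered_mental_status_72h: bool = False
    death_72h: bool = False

    def __post_init__(self) -> None:
        if self.crystalloid_ml_24h < 0:
            raise IntegrityError(
                f"crystalloid_ml_24h must be >= 0, got {self.crystalloid_ml_24h!r}"
            )


@dataclass(frozen=True)
class Episode:
    """One suspected-infection enrollment of one subject."""

    subject_id: str
    episode_id: str
    age_years: float
    sex: str
    location: str  # one of {"ward", "picu", "cicu"}
    platelet_k_mcl: float
    immuno: ImmunoCriteria
    culture_time: datetime
    sample_time: datetime
    biomarkers: BiomarkerPanel
    events: DeteriorationEvents
    bacterially_infected: bool
    death_28d: bool

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise IntegrityError(f"age_years must be >= 0, got {self.age_years!r}")
        if self.platelet_k_mcl < 0:
            raise IntegrityError(f"platelet_k_mcl must be >= 0, got {self.platelet_k_mcl!r}")
        if self.location not in ("ward", "picu", "cicu"):
            raise IntegrityError(f"unknown location {self.location!r}")
        if self.events.death_72h and not self.death_28d:
            raise IntegrityError(
                f"episode {self.subject_id}/{self.episode_id}: death_72h implies death_28d"
            )

    @property
    def in_icu(self) -> bool:
        return self.location in ("picu", "cicu")

    def predictor(self, name: str) -> Optional[float]:
        """Value of a candidate predictor (biomarker, age, or platelets)."""
        if name in BIOMARKERS:
            return self.biomarkers.get(name)
        if name == "age_years":
            return self.age_years
        if name == "platelet_k_mcl":
            return self.platelet_k_mcl
        raise KeyError(name)


@dataclass
class Cohort:
    """Ordered collection of episodes with unique (subject_id, episode_id)."""

    episodes: list[Episode] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.subject_id, e.episode_id) for e in self.episodes]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate (subject_id, episode_id): {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self) -> Iterator[Episode]:
        return iter(self.episodes)

    def __getitem__(self, i):
        return self.episodes[i]


# ---------------------------------------------------------------------------
# Predicates


def meets_immunocompromised(criteria: ImmunoCriteria) -> bool:
    """Eligibility predicate: does the subject meet any immunocompromise
    criterion?

    True iff any of: neutropenia (ANC < 0.5 K/mcL), chemotherapy within 7
    days, myeloablative radiation within 7 days, or receipt of a solid-organ
    or bone-marrow transplant *combined with* immunosuppression exposure
    within 7 days.  A missing ANC with no other criterion is not eligible.
    """
    c = criteria
    return bool(
        (c.anc is not None and c.anc < ANC_NEUTROPENIA_THRESHOLD)
        or c.chemo_within_7d
        or c.myeloablative_radiation_within_7d
        or (c.solid_organ_transplant and c.immunosuppression_within_7d)
        or (c.bone_marrow_transplant and c.immunosuppression_within_7d)
    )


def meets_deterioration(events: DeteriorationEvents) -> bool:
    """Composite 72-hour clinical-deterioration outcome.

    True iff any of: ICU transfer; new respiratory support (HFNC, NIPPV, or
    invasive ventilation); crystalloid >= 60 mL/kg in 24 h (>= 3 L if
    >= 50 kg); new vasoactive agents; new altered mental status; death.
    """
    w = events.weight_kg
    if not (w > 0):  # also rejects NaN
        raise IntegrityError(f"weight_kg must be > 0, got {w!r}")
    if w < FLUID_WEIGHT_CUT_KG:
        fluid = events.crystalloid_ml_24h >= FLUID_ML_PER_KG * w
    else:
        fluid = events.crystalloid_ml_24h >= FLUID_ABSOLUTE_ML
    return bool(
        events.icu_transfer_72h
        or events.new_respiratory_support_72h
        or fluid
        or events.new_vasoactive_72h
        or events.new_altered_mental_status_72h
        or events.death_72h
    )


def select_residual_sample(
    candidate_times: Sequence[datetime], culture_time: datetime
) -> Optional[datetime]:
    """Pick the residual sample to use for an episode.

    Among candidates within 6 hours (either side) of the qualifying blood
    culture, returns the one closest in time; at equal distance the earlier
    sample wins (favoring pre-culture specimens).  Returns ``None`` when no
    candidate qualifies.
    """
    window = timedelta(hours=SAMPLE_WINDOW_H)
    eligible = [t for t in candidate_times if abs(t - culture_time) <= window]
    if not eligible:
        return None
    return min(eligible, key=lambda t: (abs(t - culture_time), t))


def filter_episode_spacing(cohort: Cohort) -> Cohort:
    """Enforce >= 24 h spacing between a subject's utilized samples.

    Greedy per subject: an episode is kept iff its sample time is at least
    24 h after the last *kept* episode's sample time (the first is always
    kept).  Relative order is preserved.  Unsorted input is sorted
    internally with a warning.
    """
    spacing = timedelta(hours=SAMPLE_SPACING_H)
    order = list(cohort.episodes)
    keyed = sorted(order, key=lambda e: (e.subject_id, e.sample_time))
    if [(e.subject_id, e.episode_id) for e in keyed] != [
        (e.subject_id, e.episode_id) for e in order
    ]:
        log.warning("cohort not sorted by (subject, sample_time); sorting internally")
    kept: list[Episode] = []
    last_kept: dict[str, datetime] = {}
    for ep in keyed:
        prev = last_kept.get(ep.subject_id)
        if prev is None or ep.sample_time - prev >= spacing:
            kept.append(ep)
            last_kept[ep.subject_id] = ep.sample_time
    return Cohort(kept)


# ---------------------------------------------------------------------------
# CSV I/O

#: Canonical cohort CSV header, in order.
CSV_COLUMNS = [
    "subject_id", "episode_id", "age_years", "sex", "location",
    "platelet_k_mcl", "anc_k_mcl", "chemo_7d", "radiation_7d", "sot", "bmt",
    "immunosupp_7d", "culture_time", "sample_time",
    "il8", "ccl3", "hspa1b", "gzmb", "mmp8",
    "crystalloid_ml_24h", "weight_kg", "icu_transfer_72h", "resp_support_72h",
    "vasoactive_72h", "ams_72h", "death_72h", "infected", "death_28d",
]

_BOOL_COLUMNS = [
    "chemo_7d", "radiation_7d", "sot", "bmt", "immunosupp_7d",
    "icu_transfer_72h", "resp_support_72h", "vasoactive_72h", "ams_72h",
    "death_72h", "infected", "death_28d",
]

#: Missing-value dialect: empty cell or literal "NA".
_NA_TOKENS = ("", "NA")


def _parse_optional_float(cell) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s in _NA_TOKENS:
        return None
    try:
        return float(s)
    except ValueError:
        return None  # unparseable numeric cell -> explicit missing


def _parse_bool(cell, column: str) -> bool:
    s = str(cell).strip()
    if s in ("0", "1"):
        return s == "1"
    raise SchemaError(f"column {column!r}: boolean cells must be 0/1, got {cell!r}")


def episode_to_record(ep: Episode) -> dict:
    """Flatten an Episode into one CSV row (dict keyed by CSV_COLUMNS)."""

    def fmt(v: Optional[float]) -> str:
        # 12 significant digits: lossless for the precisions the generator
        # emits, comfortably above the documented 6-digit guarantee
        return "" if v is None else format(float(v), ".12g")

    return {
        "subject_id": ep.subject_id,
        "episode_id": ep.episode_id,
        "age_years": fmt(ep.age_years),
        "sex": ep.sex,
        "location": ep.location,
        "platelet_k_mcl": fmt(ep.platelet_k_mcl),
        "anc_k_mcl": fmt(ep.immuno.anc),
        "chemo_7d": int(ep.immuno.chemo_within_7d),
        "radiation_7d": int(ep.immuno.myeloablative_radiation_within_7d),
        "sot": int(ep.immuno.solid_organ_transplant),
        "bmt": int(ep.immuno.bone_marrow_transplant),
        "immunosupp_7d": int(ep.immuno.immunosuppression_within_7d),
        "culture_time": ep.culture_time.isoformat(),
        "sample_time": ep.sample_time.isoformat(),
        **{m: fmt(ep.biomarkers.get(m)) for m in BIOMARKERS},
        "crystalloid_ml_24h": fmt(ep.events.crystalloid_ml_24h),
        "weight_kg": fmt(ep.events.weight_kg),
        "icu_transfer_72h": int(ep.events.icu_transfer_72h),
        "resp_support_72h": int(ep.events.new_respiratory_support_72h),
        "vasoactive_72h": int(ep.events.new_vasoactive_72h),
        "ams_72h": int(ep.events.new_altered_mental_status_72h),
        "death_72h": int(ep.events.death_72h),
        "infected": int(ep.bacterially_infected),
        "death_28d": int(ep.death_28d),
    }


def record_to_episode(row: dict) -> Episode:
    """Build an Episode from one CSV row (inverse of :func:`episode_to_record`)."""
    immuno = ImmunoCriteria(
        anc=_parse_optional_float(row["anc_k_mcl"]),
        chemo_within_7d=_parse_bool(row["chemo_7d"], "chemo_7d"),
        myeloablative_radiation_within_7d=_parse_bool(row["radiation_7d"], "radiation_7d"),
        solid_organ_transplant=_parse_bool(row["sot"], "sot"),
        bone_marrow_transplant=_parse_bool(row["bmt"], "bmt"),
        immunosuppression_within_7d=_parse_bool(row["immunosupp_7d"], "immunosupp_7d"),
    )
    panel = BiomarkerPanel(**{m: _parse_optional_float(row[m]) for m in BIOMARKERS})
    events = DeteriorationEvents(
        icu_transfer_72h=_parse_bool(row["icu_transfer_72h"], "icu_transfer_72h"),
        new_respiratory_support_72h=_parse_bool(row["resp_support_72h"], "resp_support_72h"),
        crystalloid_ml_24h=float(row["crystalloid_ml_24h"]),
        weight_kg=float(row["weight_kg"]),
        new_vasoactive_72h=_parse_bool(row["vasoactive_72h"], "vasoactive_72h"),
        new_altered_mental_status_72h=_parse_bool(row["ams_72h"], "ams_72h"),
        death_72h=_parse_bool(row["death_72h"], "death_72h"),
    )
    return Episode(
        subject_id=str(row["subject_id"]),
        episode_id=str(row["episode_id"]),
        age_years=float(row["age_years"]),
        sex=str(row["sex"]),
        location=str(row["location"]),
        platelet_k_mcl=float(row["platelet_k_mcl"]),
        immuno=immuno,
        culture_time=datetime.fromisoformat(str(row["culture_time"])),
        sample_time=datetime.fromisoformat(str(row["sample_time"])),
        biomarkers=panel,
        events=events,
        bacterially_infected=_parse_bool(row["infected"], "infected"),
        death_28d=_parse_bool(row["death_28d"], "death_28d"),
    )


def read_cohort(path) -> Cohort:
    """Read a cohort CSV (see :data:`CSV_COLUMNS` for the schema).

    Unparseable numeric cells in optional columns become explicit missing
    values.  Raises :class:`SchemaError` for a missing mandatory column and
    :class:`IntegrityError` for duplicate (subject_id, episode_id).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing column(s): {', '.join(missing)}")
    episodes = [record_to_episode(row) for row in df.to_dict("records")]
    return Cohort(episodes)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV; values round-trip to 6 significant digits."""
    df = pd.DataFrame([episode_to_record(ep) for ep in cohort], columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Analysis view: one row per episode with numeric predictors and the
    two binary outcomes (``deterioration`` computed from the event flags,
    ``death_28d`` as recorded)."""
    rows = []
    for ep in cohort:
        row = {name: ep.predictor(name) for name in PREDICTORS}
        row["subject_id"] = ep.subject_id
        row["episode_id"] = ep.episode_id
        row["location"] = ep.location
        row["infected"] = ep.bacterially_infected
        row["deterioration"] = meets_deterioration(ep.events)
        row["death_28d"] = ep.death_28d
        rows.append(row)
    return pd.DataFrame(rows)
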