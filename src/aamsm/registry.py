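"""Registry records and deterministic derivation of multi-state paths.

A :class:`PatientRecord` carries one patient's baseline covariates and the
dated raw events of an aplastic anaemia registry: transfusions,
non-transplant therapy intervals, allogeneic stem-cell transplantation
(alloSCT), start of AML/MDS treatment, death and last follow-up, all as
days since the start of first-line immunosuppressive therapy (IST).

:func:`derive_state_path` applies the endpoint rules to a record:

* transfusion independence is reached after 28 transfusion-free days,
  counted from the last transfusion (entry = last transfusion + 28);
* freedom from therapy is reached 14 days after stopping all non-transplant
  therapy, provided no transfusion and no therapy restart occur in that
  window (entry = stop + 14);
* a new transfusion returns the patient to the transfusion-dependent
  state on the transfusion day; a therapy restart returns a
  therapy-free patient to the on-therapy state on the restart day;
* alloSCT, AML/MDS treatment and death move the patient to the
  corresponding failure state on the event day, pre-empting any pending
  window-based promotion;
* after alloSCT the 28-day transfusion rule applies again between the
  post-transplant transfusion-dependent/independent states.

Same-day events resolve with priority death > AML/MDS > alloSCT >
transfusion > therapy change, and a transfusion on the exact day a
promotion would complete cancels the promotion (strict comparison).
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .msdata import StructuralViolationError, TransitionStructure, default_structure

__all__ = [
    "PatientRecord",
    "StatePath",
    "ValidationError",
    "derive_state_path",
    "filter_first_line_cohort",
    "age_category",
    "records_to_covariates",
    "read_registry_csv",
    "write_state_paths_csv",
    "DAYS_PER_MONTH",
    "TRANSFUSION_WINDOW",
    "THERAPY_WINDOW",
]

logger = logging.getLogger(__name__)

#: Reporting conversion; internally everything is in days since IST start.
DAYS_PER_MONTH = 365.25 / 12.0
#: Transfusion-free days required for transfusion independence.
TRANSFUSION_WINDOW = 28.0
#: Therapy-free days required for the therapy-free state.
THERAPY_WINDOW = 14.0

_STANDARD_REGIMEN = "ATGAM+CsA"
_ELTROMBOPAG_REGIMEN = "ATGAM+CsA+Eltrombopag"


class ValidationError(ValueError):
    """A record violates the registry data-model invariants."""


@dataclass
class PatientRecord:
    """Baseline covariates plus the dated event log of one patient.

    All days are measured from the start of first-line IST (day 0) and may
    be fractional.  ``therapy_intervals`` are ``(start, stop)`` pairs with
    ``stop = None`` for ongoing therapy; first-line therapy typically
    starts at day 0.
    """

    patient_id: str
    age_at_ist: float
    severity: str                      # NSAA / SAA / VSAA
    pnh_clone: Optional[str]           # "<1%", ">=1%", or None (missing)
    sex: str                           # "M" / "F"
    last_followup_day: float
    first_line_regimen: str = _STANDARD_REGIMEN
    transfusion_dates: list[float] = field(default_factory=list)
    therapy_intervals: list[tuple[float, Optional[float]]] = field(default_factory=list)
    allosct_day: Optional[float] = None
    aml_mds_treatment_day: Optional[float] = None
    death_day: Optional[float] = None
    baseline_transfusion_dependent: bool = True

    @property
    def age_category(self) -> str:
        return age_category(self.age_at_ist)

    def validate(self) -> None:
        end = self.last_followup_day
        if not (end >= 0):
            raise ValidationError(f"{self.patient_id}: last_followup_day < 0")
        days = list(self.transfusion_dates)
        for a, b in zip(days, days[1:]):
            if b < a:
                raise ValidationError(f"{self.patient_id}: transfusion dates unordered")
        for d in days:
            if d < 0 or d > end:
                raise ValidationError(
                    f"{self.patient_id}: transfusion day {d} outside [0, {end}]"
                )
        if not self.baseline_transfusion_dependent and not any(d <= 0 for d in days):
            raise ValidationError(
                f"{self.patient_id}: not transfusion-dependent at IST start"
            )
        prev_stop = -math.inf
        for start, stop in self.therapy_intervals:
            if start < prev_stop:
                raise ValidationError(
                    f"{self.patient_id}: overlapping or unsorted therapy intervals"
                )
            if stop is not None:
                if stop < start:
                    raise ValidationError(f"{self.patient_id}: therapy stop before start")
                prev_stop = stop
            else:
                prev_stop = math.inf
        for name in ("allosct_day", "aml_mds_treatment_day", "death_day"):
            v = getattr(self, name)
            if v is not None and (v < 0 or v > end):
                raise ValidationError(
                    f"{self.patient_id}: {name}={v} outside [0, {end}]"
                )
        if self.death_day is not None and self.death_day != end:
            raise ValidationError(
                f"{self.patient_id}: death_day must equal last_followup_day"
            )


@dataclass
class StatePath:
    """Ordered sequence of (state, entry-day) visits for one patient."""

    patient_id: str
    visits: list[tuple[int, float]]
    terminal_status: str               # "censored" or "absorbed"
    censoring_day: float

    def validate(self, structure: TransitionStructure) -> None:
        if not self.visits or self.visits[0] != (1, 0.0):
            raise ValidationError(
                f"{self.patient_id}: path must start in state 1 at day 0"
            )
        for (g, t0), (h, t1) in zip(self.visits, self.visits[1:]):
            if not (t1 > t0):
                raise ValidationError(f"{self.patient_id}: entry days not increasing")
            structure.transition_id(g, h)
            if structure.is_absorbing(g):
                raise ValidationError(f"{self.patient_id}: visit after absorbing state")
        last = self.visits[-1][0]
        if self.terminal_status == "absorbed" and not structure.is_absorbing(last):
            raise ValidationError(f"{self.patient_id}: absorbed in non-absorbing state")


def age_category(age: float) -> str:
    """Age bands used throughout the analysis: 18-39, 40-59, 60+."""
    if age < 40:
        return "18-39"
    if age < 60:
        return "40-59"
    return "60+"


# ---------------------------------------------------------------------------
# event-log helpers


def _next_after(days: Sequence[float], t: float) -> float:
    """First element strictly after ``t`` (inf if none); ``days`` sorted."""
    i = bisect.bisect_right(days, t)
    return days[i] if i < len(days) else math.inf


def _therapy_status(intervals, t: float):
    """(active, current_stop, latest_stop_at_or_before_t, next_start_after_t).

    ``current_stop`` is the stop day of the interval covering ``t`` (inf if
    open) and is meaningful only when ``active``.
    """
    active = False
    current_stop = math.inf
    latest_stop = None
    next_start = math.inf
    for start, stop in intervals:
        s = math.inf if stop is None else stop
        if start <= t < s or (start <= t and s == math.inf):
            active = True
            current_stop = s
        if s <= t:
            latest_stop = s if latest_stop is None else max(latest_stop, s)
        if start > t:
            next_start = min(next_start, start)
    return active, current_stop, latest_stop, next_start


def _transfusion_promotion(transfusions, anchor: float, window: float) -> float:
    """First time ``p`` with a ``window``-long transfusion-free run ending at
    ``p``, walking the last-transfusion pointer forward from ``anchor``."""
    L = anchor
    while True:
        p = L + window
        nxt = _next_after(transfusions, L)
        if nxt <= p:            # a transfusion on the promotion day cancels it
            L = nxt
        else:
            return p


# ---------------------------------------------------------------------------


def derive_state_path(
    record: PatientRecord,
    structure: TransitionStructure | None = None,
) -> StatePath:
    """Derive the patient's multi-state path from the raw event log.

    Deterministic and idempotent; raises :class:`ValidationError` on an
    invalid record and :class:`~aamsm.msdata.StructuralViolationError` if
    the log implies an arrow absent from ``structure``.
    """
    structure = structure if structure is not None else default_structure()
    record.validate()

    transfusions = sorted(record.transfusion_dates)
    end = float(record.last_followup_day)

    # ordered failure events with same-day priority death > AML/MDS > alloSCT
    failures: list[tuple[float, int, int]] = []
    if record.death_day is not None:
        failures.append((record.death_day, 0, 8))
    if record.aml_mds_treatment_day is not None:
        failures.append((record.aml_mds_treatment_day, 1, 7))
    if record.allosct_day is not None:
        failures.append((record.allosct_day, 2, 4))
    failures.sort()

    visits: list[tuple[int, float]] = [(1, 0.0)]
    absorbed = False

    f_day, f_state = (failures[0][0], failures[0][2]) if failures else (math.inf, None)
    horizon = min(f_day, end)

    def _move(state: int, t: float) -> None:
        g = visits[-1][0]
        structure.transition_id(g, state)
        visits.append((state, t))

    # ---- pre-transplant phase: states 1, 2, 3 -------------------------
    state, now = 1, 0.0
    while now < horizon and not absorbed:
        if state == 1:
            anchor = now  # re-entry day carries a transfusion; day 0 anchors at 0
            p = _transfusion_promotion(transfusions, anchor, TRANSFUSION_WINDOW)
            if p < horizon:
                _move(2, p)
                state, now = 2, p
            else:
                break
        elif state == 2:
            exit_found = False
            probe = now
            entry = now
            while True:
                d = _next_after(transfusions, probe)
                active, cur_stop, latest_stop, nxt_start = _therapy_status(
                    record.therapy_intervals, probe
                )
                if active:
                    q = math.inf if cur_stop == math.inf else cur_stop + THERAPY_WINDOW
                else:
                    if latest_stop is None:
                        q = entry + 1.0
                        logger.warning(
                            "patient %s: transfusion-independent with no recorded "
                            "therapy; fast-tracked to therapy-free at day %.6g",
                            record.patient_id, q,
                        )
                    else:
                        q = latest_stop + THERAPY_WINDOW
                        if q <= entry:
                            q = entry + 1.0
                            logger.warning(
                                "patient %s: therapy stopped before transfusion "
                                "independence completed; therapy-free entry "
                                "tie-broken to day %.6g", record.patient_id, q,
                            )
                # a restart at or before q postpones the promotion
                if nxt_start <= q and nxt_start < d:
                    probe = nxt_start
                    continue
                if d <= q:      # transfusion (on or before promotion day) wins
                    if d < horizon:
                        _move(1, d)
                        state, now = 1, d
                        exit_found = True
                    break
                if q < horizon:
                    _move(3, q)
                    state, now = 3, q
                    exit_found = True
                break
            if not exit_found:
                break
        else:  # state 3
            d = _next_after(transfusions, now)
            _, _, _, nxt_start = _therapy_status(record.therapy_intervals, now)
            t = min(d, nxt_start)
            if t < horizon:
                if d <= nxt_start:   # same-day tie: transfusion beats therapy change
                    _move(1, d)
                    state, now = 1, d
                else:
                    _move(2, nxt_start)
                    state, now = 2, nxt_start
            else:
                break

    # ---- failure entry ------------------------------------------------
    if f_day is not None and f_state is not None and f_day <= end:
        _move(f_state, f_day)
        if f_state in (7, 8):
            absorbed = True
        elif f_state == 4:
            # ---- post-transplant phase: states 4, 5, 6 ---------------
            post_failures = [(t, pr, s) for (t, pr, s) in failures if t > f_day]
            if any(s == 7 for (_, _, s) in post_failures):
                raise StructuralViolationError(
                    f"patient {record.patient_id}: AML/MDS treatment after alloSCT "
                    "is not an arrow of the structure"
                )
            death = next((t for (t, _, s) in post_failures if s == 8), math.inf)
            horizon2 = min(death, end)
            state, now = 4, f_day
            while now < horizon2:
                if state == 4:
                    p = _transfusion_promotion(
                        transfusions, max(now, 0.0), TRANSFUSION_WINDOW
                    )
                    if p < horizon2:
                        _move(5, p)
                        state, now = 5, p
                    else:
                        break
                else:  # state 5
                    d = _next_after(transfusions, now)
                    if d < horizon2:
                        _move(4, d)
                        state, now = 4, d
                    else:
                        break
            if death <= end:
                _move(6, death)
                absorbed = True

    return StatePath(
        patient_id=record.patient_id,
        visits=visits,
        terminal_status="absorbed" if absorbed else "censored",
        censoring_day=end,
    )


def filter_first_line_cohort(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Keep patients whose first-line regimen was ATGAM+CsA alone.

    Patients treated with Eltrombopag-containing first-line therapy are
    excluded to preserve a uniform treatment cohort; order is preserved and
    the retained/excluded counts are logged.
    """
    records = list(records)
    for r in records:
        if not getattr(r, "first_line_regimen", None):
            raise ValidationError(f"{r.patient_id}: missing first_line_regimen")
    kept = [r for r in records if r.first_line_regimen == _STANDARD_REGIMEN]
    logger.info(
        "first-line cohort filter: retained %d of %d records (%d excluded)",
        len(kept), len(records), len(records) - len(kept),
    )
    return kept


def records_to_covariates(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Baseline covariate table (indexed by patient_id) for model fitting.

    Categorical levels are kept as strings; dummy encoding happens in the
    Cox module so that reference levels are defined in one place.
    """
    rows = {
        r.patient_id: {
            "age": r.age_at_ist,
            "age_cat": r.age_category,
            "severity": r.severity,
            "pnh": r.pnh_clone,
            "sex": r.sex,
        }
        for r in records
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


# ---------------------------------------------------------------------------
# CSV interfaces (documented schema; UTF-8, '.' decimal)

_EVENT_TYPES = {
    "transfusion", "therapy_start", "therapy_stop",
    "allosct", "aml_mds_treatment", "death", "last_followup",
}


def read_registry_csv(baseline_path, events_path) -> list[PatientRecord]:
    """Read records from a baseline CSV and an event-log CSV.

    Baseline columns: patient_id, age_at_ist, severity, pnh_clone, sex,
    first_line_regimen.  Event columns: patient_id, event_type, day
    (event_type one of transfusion, therapy_start, therapy_stop, allosct,
    aml_mds_treatment, death, last_followup).
    """
    base = pd.read_csv(baseline_path, dtype={"patient_id": str})
    events = pd.read_csv(events_path, dtype={"patient_id": str})
    bad = set(events["event_type"]) - _EVENT_TYPES
    if bad:
        raise ValidationError(f"unknown event types in log: {sorted(bad)}")
    records = []
    grouped = dict(tuple(events.groupby("patient_id")))
    for row in base.itertuples(index=False):
        ev = grouped.get(row.patient_id)
        if ev is None:
            raise ValidationError(f"{row.patient_id}: no events (need last_followup)")
        ev = ev.sort_values("day", kind="stable")

        def days_of(kind):
            return ev.loc[ev["event_type"] == kind, "day"].astype(float).tolist()

        def single(kind):
            d = days_of(kind)
            if len(d) > 1:
                raise ValidationError(f"{row.patient_id}: multiple {kind} events")
            return d[0] if d else None

        starts, stops = days_of("therapy_start"), days_of("therapy_stop")
        intervals: list[tuple[float, Optional[float]]] = []
        si = 0
        for s in starts:
            stop = next((x for x in stops[si:] if x >= s), None)
            if stop is not None:
                si = stops.index(stop, si) + 1
            intervals.append((s, stop))
        followup = single("last_followup")
        if followup is None:
            raise ValidationError(f"{row.patient_id}: missing last_followup event")
        pnh = getattr(row, "pnh_clone", None)
        if pd.isna(pnh):
            pnh = None
        rec = PatientRecord(
            patient_id=row.patient_id,
            age_at_ist=float(row.age_at_ist),
            severity=str(row.severity),
            pnh_clone=pnh,
            sex=str(row.sex),
            first_line_regimen=str(row.first_line_regimen),
            last_followup_day=float(followup),
            transfusion_dates=days_of("transfusion"),
            therapy_intervals=intervals,
            allosct_day=single("allosct"),
            aml_mds_treatment_day=single("aml_mds_treatment"),
            death_day=single("death"),
        )
        rec.validate()
        records.append(rec)
    return records


def write_state_paths_csv(paths: Sequence[StatePath], path) -> None:
    """Write derived paths as rows (patient_id, state, entry_day)."""
    rows = [
        {"patient_id": p.patient_id, "state": s, "entry_day": t}
        for p in paths for (s, t) in p.visits
    ]
    pd.DataFrame(rows, columns=["patient_id", "state", "entry_day"]).to_csv(
        path, index=False
    )
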