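"""Time-stratified referent selection and matched-stratum assembly.

In a time-stratified case-crossover design every case hour is compared with
the exposure at control hours drawn from the same calendar stratum: the same
hour of day, on the same weekday, in the same month and year.  Matching on
these attributes removes long-term trends, seasonality, day-of-week and
circadian structure from the exposure contrast, and because each patient is
their own control all time-invariant individual confounders cancel in the
conditional likelihood.

Any month contains a given weekday four or five times, so every case hour has
exactly three or four referent hours by construction.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["Stratum", "select_referents", "build_strata"]


@dataclass
class Stratum:
    """One matched set: a case event-hour and its surviving control hours."""

    stratum_id: int
    patient_id: str
    case_hour: pd.Timestamp
    control_hours: list[pd.Timestamp]
    covariates: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return 1 + len(self.control_hours)

    def event_hours(self) -> list[pd.Timestamp]:
        """Case hour first, controls after, controls in ascending order."""
        return [self.case_hour, *self.control_hours]


def select_referents(case_hour: pd.Timestamp) -> list[pd.Timestamp]:
    """Return the time-stratified control hours for ``case_hour``.

    Controls are every other occurrence of the case's weekday within the same
    calendar month and year, at the same hour of day, sorted ascending.  Pure
    calendar arithmetic: the result does not depend on any data.

    Parameters
    ----------
    case_hour
        Civil timestamp at hour precision (minutes/seconds zero).

    Examples
    --------
    >>> [t.day for t in select_referents(pd.Timestamp("2021-10-08 10:00"))]
    [1, 15, 22, 29]
    """
    ts = pd.Timestamp(case_hour)
    if ts.minute or ts.second or ts.microsecond or ts.nanosecond:
        raise ValueError(f"case hour must be at hour precision, got {ts!r}")
    n_days = calendar.monthrange(ts.year, ts.month)[1]
    controls = []
    for day in range(1, n_days + 1):
        t = ts.replace(day=day)
        if t.dayofweek == ts.dayofweek and day != ts.day:
            controls.append(t)
    return controls


def build_strata(
    records: pd.DataFrame,
    usable: "dict[tuple[str, pd.Timestamp], bool] | None" = None,
    covariate_columns: "list[str] | None" = None,
) -> tuple[list[Stratum], pd.DataFrame]:
    """Assemble one matched stratum per retained case.

    Parameters
    ----------
    records
        Patient table with at least ``patient_id`` and ``onset_time`` columns;
        any ``covariate_columns`` are copied onto the stratum.
    usable
        Optional map ``(patient_id, hour) -> bool`` saying whether the
        exposure history of that event-hour survived the trimming/missingness
        rules.  Hours absent from the map are treated as usable.  A stratum is
        excluded when its case hour is unusable or when no control survives.
    covariate_columns
        Subgroup labels to copy from each record.

    Returns
    -------
    (strata, exclusions)
        ``strata`` is the list of surviving :class:`Stratum`; ``exclusions``
        is a DataFrame (patient_id, reason) logging every dropped case.
    """
    if covariate_columns is None:
        covariate_columns = [
            c for c in ("age", "sex", "smoking", "alcohol", "gcs", "ich_location")
            if c in records.columns
        ]

    def ok(pid: str, hour: pd.Timestamp) -> bool:
        if usable is None:
            return True
        return usable.get((pid, hour), True)

    strata: list[Stratum] = []
    dropped: list[dict] = []
    for sid, row in enumerate(records.itertuples(index=False)):
        pid = str(row.patient_id)
        case_hour = pd.Timestamp(row.onset_time)
        controls = select_referents(case_hour)
        if not ok(pid, case_hour):
            dropped.append({"patient_id": pid, "reason": "case_hour_unusable"})
            continue
        kept = [h for h in controls if ok(pid, h)]
        if not kept:
            # a case with zero controls contributes a constant factor of 1
            # to the conditional likelihood; drop it rather than error
            dropped.append({"patient_id": pid, "reason": "no_surviving_controls"})
            continue
        covs = {c: getattr(row, c) for c in covariate_columns}
        strata.append(Stratum(sid, pid, case_hour, kept, covs))
    exclusions = pd.DataFrame(dropped, columns=["patient_id", "reason"])
    return strata, exclusions


def strata_to_frame(strata: list[Stratum]) -> pd.DataFrame:
    """Long-format export: one row per event-hour with its role."""
    rows = []
    for s in strata:
        rows.append(
            {"stratum_id": s.stratum_id, "role": "case",
             "timestamp": s.case_hour, "patient_id": s.patient_id}
        )
        for h in s.control_hours:
            rows.append(
                {"stratum_id": s.stratum_id, "role": "control",
                 "timestamp": h, "patient_id": s.patient_id}
            )
    return pd.DataFrame(rows, columns=["stratum_id", "role", "timestamp", "patient_id"])
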