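"""Measurement-window selection and time-to-event outcome construction.

A patient enters the cohort if, within some 180 consecutive days ending
before any psychiatric hospitalisation, they have at least five CGI-S and
five GAF ratings (the "measurement period"). The outcome is hospitalisation
within the 180 days *after* the window; patients without an event are
censored at their last visit to services or at 180 days, whichever comes
first. One window — the earliest qualifying one — is used per patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset

WINDOW_DAYS = 180  # closed interval [start, start + 179]
OUTCOME_DAYS = 180  # outcome horizon after window end
MIN_RATINGS = 5  # per scale, within the window

#: exclusion reason codes
NO_WINDOW = "insufficient_measurements"
HOSP_TOO_EARLY = "hospitalisation_too_early"


@dataclass(frozen=True)
class MeasurementWindow:
    patient_id: str
    window_start: int
    window_end: int  # start + 179, inclusive
    n_cgi: int
    n_gaf: int


def select_window(
    cgi_days: np.ndarray,
    gaf_days: np.ndarray,
    first_hosp: int | None = None,
) -> tuple[int, int] | None:
    """Earliest qualifying 180-day window, or None.

    Candidate starts are restricted to observed rating days: any qualifying
    window can be slid left until its start coincides with an observation
    without losing observations, so the scan is linear in the number of
    visits. The window end must lie strictly before ``first_hosp``.
    """
    cgi_days = np.asarray(cgi_days)
    gaf_days = np.asarray(gaf_days)
    if cgi_days.size < MIN_RATINGS or gaf_days.size < MIN_RATINGS:
        return None
    starts = np.unique(np.concatenate([cgi_days, gaf_days]))
    ends = starts + WINDOW_DAYS - 1
    n_cgi = np.searchsorted(cgi_days, ends, side="right") - np.searchsorted(
        cgi_days, starts, side="left"
    )
    n_gaf = np.searchsorted(gaf_days, ends, side="right") - np.searchsorted(
        gaf_days, starts, side="left"
    )
    ok = (n_cgi >= MIN_RATINGS) & (n_gaf >= MIN_RATINGS)
    if first_hosp is not None:
        ok &= ends < first_hosp
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    i = idx[0]
    return int(starts[i]), int(ends[i])


def build_outcome(
    window_end: int,
    visit_days: np.ndarray,
    hosp_days: np.ndarray,
) -> tuple[float, bool]:
    """(time, event) for the 180 days after ``window_end``.

    Event time is days from window end to the first hospitalisation; the
    outcome clock starts the day after the window ends. Without an event the
    patient is censored at min(last visit, 180 days), floored at 0.
    """
    hosp_days = np.asarray(hosp_days)
    if hosp_days.size and hosp_days.min() <= window_end:
        raise ValueError(
            "hospitalisation on or before window end; window selection should "
            "have excluded this patient"
        )
    post = hosp_days[hosp_days > window_end]
    if post.size:
        t = int(post.min() - window_end)
        if t <= OUTCOME_DAYS:
            return float(t), True
    last_visit = int(np.asarray(visit_days).max())
    return float(min(max(last_visit - window_end, 0), OUTCOME_DAYS)), False


def build_cohort(ds: Dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per included patient, plus an exclusion log.

    Returns ``(cohort, exclusions)``. ``cohort`` columns: patient_id,
    window_start, window_end, n_cgi, n_gaf, time, event. ``exclusions``
    columns: patient_id, reason — ``insufficient_measurements`` when no
    180-day span ever holds 5+5 ratings, ``hospitalisation_too_early`` when
    one would, but not before the first hospitalisation.
    """
    visits = ds.visits.sort_values(["patient_id", "day"], kind="stable")
    hosp_by_pat = {
        pid: g["day"].to_numpy() for pid, g in ds.hospitalisations.groupby("patient_id")
    }
    rows, excluded = [], []
    for pid, g in visits.groupby("patient_id", sort=False):
        days = g["day"].to_numpy()
        cgi_days = days[g["cgi_s"].notna().to_numpy()]
        gaf_days = days[g["gaf"].notna().to_numpy()]
        hosp = hosp_by_pat.get(pid, np.empty(0, dtype=int))
        first_hosp = int(hosp.min()) if hosp.size else None
        win = select_window(cgi_days, gaf_days, first_hosp)
        if win is None:
            reason = (
                HOSP_TOO_EARLY
                if select_window(cgi_days, gaf_days, None) is not None
                else NO_WINDOW
            )
            excluded.append({"patient_id": pid, "reason": reason})
            continue
        start, end = win
        time, event = build_outcome(end, days, hosp)
        rows.append(
            {
                "patient_id": pid,
                "window_start": start,
                "window_end": end,
                "n_cgi": int(np.searchsorted(cgi_days, end, side="right")
                             - np.searchsorted(cgi_days, start, side="left")),
                "n_gaf": int(np.searchsorted(gaf_days, end, side="right")
                             - np.searchsorted(gaf_days, start, side="left")),
                "time": time,
                "event": event,
            }
        )
    # patients with no visits at all
    seen = set(visits["patient_id"])
    for pid in ds.patients["patient_id"]:
        if pid not in seen:
            excluded.append({"patient_id": pid, "reason": NO_WINDOW})
    cohort = pd.DataFrame(
        rows,
        columns=["patient_id", "window_start", "window_end", "n_cgi", "n_gaf", "time", "event"],
    )
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return cohort, exclusions
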