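"""Ethogram event-log processing.

Coded behaviour logs (one row per point or state event, times in seconds
from the start of the condition sequence) are converted into the two
analysis datasets:

* 5-s-interval records — wave counts plus social-context covariates,
  the observation stream of the signalling HMM; and
* per-condition burrow-use records — whether the male entered his
  burrow during each 5-min condition and, if so, the proportion of the
  condition he spent there — the observation unit of the hurdle model.

Intervals are half-open ``[start, start + 5)``, 0-based, anchored at the
condition-sequence start; interval boundaries never straddle condition
boundaries.  Intervals during which the male was ever out of view of
both cameras, or ever in his burrow, are discarded from the HMM stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import INTERVAL_S, ConditionSchedule

POINT_BEHAVIOURS = (
    "aggressive_stance",
    "wave",
    "female_enters",
    "female_exits",
    "rival_enters",
    "rival_exits",
    "out_of_view_start",
    "out_of_view_end",
    "robot_wave",
)
STATE_BEHAVIOURS = ("in_burrow", "out_of_burrow", "fight")
EVENT_COLUMNS = ("trial_id", "time_s", "behaviour", "event_type")


class EventLogError(ValueError):
    """Malformed ethogram event log."""


def validate_events(events: pd.DataFrame, schedule: ConditionSchedule) -> pd.DataFrame:
    """Check column layout, ordering and time range of one trial's log."""
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise EventLogError(f"event log missing column {col!r}")
    t = events["time_s"].to_numpy(dtype=float)
    if t.size and (np.any(t < 0) or np.any(t > schedule.end_s)):
        raise EventLogError("event times outside the condition schedule")
    if np.any(np.diff(t) < 0):
        raise EventLogError("event log is not sorted by time")
    return events


def _episodes(
    events: pd.DataFrame,
    start_name: str,
    end_name: str,
    end_s: float,
    *,
    paired_state: bool = False,
) -> list[tuple[float, float]]:
    """Pair start/end markers into half-open episodes ``[t0, t1)``.

    An episode still open at the schedule end is auto-closed there; an
    end marker with no matching start is a coding error.
    """
    sub = events[events["behaviour"].isin((start_name, end_name))]
    episodes: list[tuple[float, float]] = []
    open_t: float | None = None
    for row in sub.itertuples():
        if row.behaviour == start_name:
            if open_t is not None:
                raise EventLogError(f"nested {start_name!r} episode at t={row.time_s}")
            open_t = float(row.time_s)
        else:
            if open_t is None:
                raise EventLogError(f"{end_name!r} without matching {start_name!r}")
            episodes.append((open_t, float(row.time_s)))
            open_t = None
    if open_t is not None:
        episodes.append((open_t, end_s))
    return episodes


def burrow_episodes(events: pd.DataFrame, schedule: ConditionSchedule) -> list[tuple[float, float]]:
    """In-burrow episodes from paired in_burrow/out_of_burrow state events."""
    starts = events[
        (events["behaviour"] == "in_burrow") & (events["event_type"] == "state_start")
    ]
    stops = events[
        (events["behaviour"] == "in_burrow") & (events["event_type"] == "state_stop")
    ]
    merged = pd.concat([starts, stops]).sort_values("time_s", kind="stable")
    tagged = merged.assign(
        behaviour=np.where(merged["event_type"] == "state_start", "_open", "_close")
    )
    return _episodes(tagged, "_open", "_close", schedule.end_s)


def out_of_view_episodes(
    events: pd.DataFrame, schedule: ConditionSchedule
) -> list[tuple[float, float]]:
    return _episodes(events, "out_of_view_start", "out_of_view_end", schedule.end_s)


def _presence_episodes(
    events: pd.DataFrame, enter: str, exit_: str, end_s: float
) -> list[tuple[float, float]]:
    """Enter/exit point events -> presence episodes; multiple may overlap
    (two females can be in frame at once), so pair each exit with the
    earliest open enter."""
    sub = events[events["behaviour"].isin((enter, exit_))]
    open_times: list[float] = []
    episodes: list[tuple[float, float]] = []
    for row in sub.itertuples():
        if row.behaviour == enter:
            open_times.append(float(row.time_s))
        else:
            if not open_times:
                raise EventLogError(f"{exit_!r} without matching {enter!r}")
            episodes.append((open_times.pop(0), float(row.time_s)))
    episodes.extend((t, end_s) for t in open_times)
    return episodes


def _overlap_counts(
    episodes: list[tuple[float, float]], starts: np.ndarray, width: float
) -> np.ndarray:
    """Per interval: how many episodes overlap it at any moment.

    Episodes are half-open; an episode touches interval [a, a+w) iff
    t0 < a + w and t1 > a.  Zero-length episodes (enter and exit at the
    same instant) count for the interval containing that instant.
    """
    counts = np.zeros(starts.size, dtype=int)
    for t0, t1 in episodes:
        if t1 > t0:
            hit = (t0 < starts + width) & (t1 > starts)
        else:
            hit = (starts <= t0) & (t0 < starts + width)
        counts += hit.astype(int)
    return counts


def bin_events(
    events: pd.DataFrame, schedule: ConditionSchedule, width_s: float = INTERVAL_S
) -> pd.DataFrame:
    """Bin one trial's event log into half-open intervals.

    Returns one row per interval covering the whole schedule with
    columns: trial_id, interval_index, start_s, wave_count, n_females,
    rival_present, in_burrow_any, out_of_view_any, condition_label,
    wave_level.  ``n_females`` is the maximum number of females
    simultaneously in frame at any moment of the interval.
    """
    validate_events(events, schedule)
    n = int(round(schedule.end_s / width_s))
    starts = np.arange(n, dtype=float) * width_s
    trial_id = events["trial_id"].iloc[0] if len(events) else ""

    wave_t = events.loc[events["behaviour"] == "wave", "time_s"].to_numpy(dtype=float)
    idx = np.minimum((wave_t // width_s).astype(int), n - 1)
    wave_count = np.bincount(idx, minlength=n) if idx.size else np.zeros(n, dtype=int)

    fem = _presence_episodes(events, "female_enters", "female_exits", schedule.end_s)
    riv = _presence_episodes(events, "rival_enters", "rival_exits", schedule.end_s)
    burrow = burrow_episodes(events, schedule)
    oov = out_of_view_episodes(events, schedule)

    n_females = _overlap_counts(fem, starts, width_s)
    rival_present = (_overlap_counts(riv, starts, width_s) > 0).astype(int)
    in_burrow = (_overlap_counts(burrow, starts, width_s) > 0).astype(int)
    out_of_view = (_overlap_counts(oov, starts, width_s) > 0).astype(int)

    labels = [schedule.periods[schedule.condition_index_at(s)].condition_label for s in starts]
    levels = [schedule.periods[schedule.condition_index_at(s)].wave_level for s in starts]
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "interval_index": np.arange(n),
            "start_s": starts,
            "wave_count": wave_count,
            "n_females": n_females,
            "rival_present": rival_present,
            "in_burrow_any": in_burrow,
            "out_of_view_any": out_of_view,
            "condition_label": labels,
            "wave_level": levels,
        }
    )


def apply_retention_rule(records: pd.DataFrame) -> pd.DataFrame:
    """Flag the intervals that enter the HMM observation stream.

    An interval is retained only if the male was never out of view of
    both cameras and never in his burrow during it (partial burrow
    overlap also excludes: the male could not wave for part of it).
    """
    out = records.copy()
    out["retained"] = (out["out_of_view_any"] == 0) & (out["in_burrow_any"] == 0)
    return out


@dataclass(frozen=True)
class Segment:
    """Maximal run of consecutive retained intervals in one trial."""

    trial_id: str
    start_index: int
    length: int


def segment_sequences(records: pd.DataFrame) -> list[Segment]:
    """Split each trial's retained intervals into maximal consecutive runs.

    The HMM treats each segment as an independent sequence with its own
    initial state distribution.  A trial with no retained interval is
    excluded with a warning.
    """
    if "retained" not in records.columns:
        raise EventLogError("run apply_retention_rule before segmentation")
    segments: list[Segment] = []
    for trial_id, grp in records.groupby("trial_id", sort=False):
        grp = grp.sort_values("interval_index")
        kept = grp["retained"].to_numpy(dtype=bool)
        idx = grp["interval_index"].to_numpy()
        if not kept.any():
            warnings.warn(f"trial {trial_id!r}: no retained intervals; excluded from HMM")
            continue
        run_start = None
        for i, k in enumerate(kept):
            if k and run_start is None:
                run_start = i
            if (not k or i == len(kept) - 1) and run_start is not None:
                end = i + 1 if k else i
                segments.append(Segment(str(trial_id), int(idx[run_start]), end - run_start))
                run_start = None
    return segments


def _overlap_seconds(episodes: list[tuple[float, float]], a: float, b: float) -> float:
    return sum(max(0.0, min(t1, b) - max(t0, a)) for t0, t1 in episodes)


def summarize_burrow_use(events: pd.DataFrame, schedule: ConditionSchedule) -> pd.DataFrame:
    """Per-condition burrow use: did the male enter, and for what fraction.

    Episodes straddling a condition boundary are clipped, so each
    condition is credited only with the in-burrow seconds inside it.
    ``proportion_in_burrow`` is NaN when the male never entered.
    """
    validate_events(events, schedule)
    episodes = burrow_episodes(events, schedule)
    trial_id = events["trial_id"].iloc[0] if len(events) else ""
    rows = []
    for p in schedule.periods:
        secs = _overlap_seconds(episodes, p.start_s, p.end_s)
        entered = secs > 0
        rows.append(
            {
                "trial_id": trial_id,
                "condition_label": p.condition_label,
                "wave_level": p.wave_level,
                "entered": entered,
                "proportion_in_burrow": secs / (p.end_s - p.start_s) if entered else np.nan,
            }
        )
    return pd.DataFrame(rows)


def read_event_log(path) -> pd.DataFrame:
    """Read an event-log CSV (columns: trial_id, time_s, behaviour, event_type)."""
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise EventLogError(f"event log missing columns {sorted(missing)}")
    return df[list(EVENT_COLUMNS) + [c for c in df.columns if c not in EVENT_COLUMNS]]


def write_event_log(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)
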