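"""Experimental-design vocabulary: conditions, treatments, covariates.

A trial presents a focal male with a robotic rival through four abutting
5-minute conditions (no wave, one wave speed, no wave again, the other
wave speed).  The robot's claw size is fixed per trial.  This module
builds condition schedules, z-scores continuous covariates, and encodes
the dummy-coded design rows consumed by the signalling HMM and the
burrow-use hurdle model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITION_S = 300.0
TRIAL_S = 1200.0
INTERVAL_S = 5.0

CLAW_LEVELS = ("small", "large")
ORDER_LEVELS = ("fast_first", "slow_first")
WAVE_LEVELS = ("no_wave", "slow", "fast")
CONDITION_LABELS = ("no_wave_1", "slow_wave", "fast_wave", "no_wave_2")

#: continuous covariates that are z-scored before entering any model
CONTINUOUS_COVARIATES = ("temperature", "tide_time", "carapace_width", "claw_ratio")

#: design columns of the signalling HMM (reference cell: no wave, small claw);
#: the wave x claw interaction terms are appended only on request
HMM_COLUMNS = (
    "slow_wave",
    "fast_wave",
    "large_claw",
    "n_females",
    "rival_in_view",
    "temperature_z",
    "tide_z",
    "carapace_z",
    "ratio_z",
)
HMM_INTERACTION_COLUMNS = ("slow_x_large", "fast_x_large")

#: design columns of the burrow-use hurdle model
HURDLE_COLUMNS = (
    "slow_wave",
    "fast_wave",
    "large_claw",
    "slow_x_large",
    "fast_x_large",
    "fast_first",
    "temperature_z",
    "tide_z",
    "carapace_z",
    "ratio_z",
)


class DesignError(ValueError):
    """Invalid or incomplete design input."""


@dataclass(frozen=True)
class TrialMetadata:
    """Per-trial metadata for one focal male.

    ``tide_offset_min`` is the trial start time relative to the lowest
    tide point (signed, minutes; negative = before low tide).
    """

    male_id: str
    block_id: str
    claw_treatment: str
    order_treatment: str
    temperature_c: float
    tide_offset_min: float
    claw_length_mm: float
    carapace_width_mm: float

    def __post_init__(self) -> None:
        if self.claw_treatment not in CLAW_LEVELS:
            raise DesignError(f"unknown claw treatment {self.claw_treatment!r}")
        if self.order_treatment not in ORDER_LEVELS:
            raise DesignError(f"unknown order treatment {self.order_treatment!r}")
        if not (self.claw_length_mm > 0 and self.carapace_width_mm > 0):
            raise DesignError("morphometrics must be positive")

    @property
    def claw_ratio(self) -> float:
        return self.claw_length_mm / self.carapace_width_mm


@dataclass(frozen=True)
class ConditionPeriod:
    condition_label: str
    wave_level: str
    start_s: float
    end_s: float


@dataclass(frozen=True)
class ConditionSchedule:
    """Four abutting 300-s conditions partitioning [0, 1200) s."""

    periods: tuple[ConditionPeriod, ...]

    def __post_init__(self) -> None:
        if len(self.periods) != 4:
            raise DesignError("a schedule has exactly 4 conditions")
        t = 0.0
        for p in self.periods:
            if p.start_s != t or p.end_s - p.start_s != CONDITION_S:
                raise DesignError("conditions must abut in 300-s spans")
            t = p.end_s

    @property
    def end_s(self) -> float:
        return self.periods[-1].end_s

    def wave_level_at(self, time_s: float) -> str:
        return self.periods[self.condition_index_at(time_s)].wave_level

    def condition_index_at(self, time_s: float) -> int:
        if not (0 <= time_s < self.end_s):
            raise DesignError(f"time {time_s} outside schedule [0, {self.end_s})")
        return min(int(time_s // CONDITION_S), 3)

    def n_intervals(self, width_s: float = INTERVAL_S) -> int:
        return int(round(self.end_s / width_s))


def build_condition_schedule(order_treatment: str) -> ConditionSchedule:
    """Build the four-condition sequence for one trial.

    The focal male always sees no-wave first; the second condition is
    the wave speed named by ``order_treatment``; the third is another
    no-wave; the fourth is the speed he has not yet experienced.
    """
    if order_treatment not in ORDER_LEVELS:
        raise DesignError(f"unknown order treatment {order_treatment!r}")
    first = "fast" if order_treatment == "fast_first" else "slow"
    second = "slow" if first == "fast" else "fast"
    levels = ("no_wave", first, "no_wave", second)
    labels = (
        "no_wave_1",
        f"{first}_wave",
        "no_wave_2",
        f"{second}_wave",
    )
    periods = tuple(
        ConditionPeriod(label, level, i * CONDITION_S, (i + 1) * CONDITION_S)
        for i, (label, level) in enumerate(zip(labels, levels))
    )
    return ConditionSchedule(periods)


@dataclass(frozen=True)
class ZScoreSpec:
    """Standardisation constants for one covariate (sample sd, ddof=1)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sd) or self.sd <= 0:
            raise DesignError("z-score sd must be positive and finite")

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def z_score(values) -> tuple[np.ndarray, ZScoreSpec]:
    """Standardise to mean 0 / sample sd 1, returning the spec used.

    Raises on constant input (a degenerate covariate carries no
    information and would produce non-finite z-scores).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DesignError("z-scoring needs a 1-d array of at least 2 values")
    if not np.all(np.isfinite(x)):
        raise DesignError("non-finite covariate values")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DesignError("degenerate covariate: zero variance")
    spec = ZScoreSpec(float(np.mean(x)), sd)
    return spec.transform(x), spec


def compute_zscore_specs(frame: pd.DataFrame) -> dict[str, ZScoreSpec]:
    """Fit one :class:`ZScoreSpec` per continuous covariate column.

    ``frame`` must carry the raw-scale columns named in
    :data:`CONTINUOUS_COVARIATES`.  Specs are computed once per fitted
    dataset and persisted next to posteriors so that predictions on new
    data reuse the training standardisation.
    """
    specs: dict[str, ZScoreSpec] = {}
    for name in CONTINUOUS_COVARIATES:
        if name not in frame.columns:
            raise DesignError(f"missing covariate column {name!r}")
        col = frame[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise DesignError(f"missing values in covariate {name!r}")
        _, specs[name] = z_score(col)
    return specs


def _treatment_dummies(wave_level: str, claw_treatment: str) -> dict[str, float]:
    if wave_level not in WAVE_LEVELS:
        raise DesignError(f"unknown wave level {wave_level!r}")
    slow = float(wave_level == "slow")
    fast = float(wave_level == "fast")
    large = float(claw_treatment == "large")
    return {
        "slow_wave": slow,
        "fast_wave": fast,
        "large_claw": large,
        "slow_x_large": slow * large,
        "fast_x_large": fast * large,
    }


def _z(specs: dict[str, ZScoreSpec], name: str, value: float) -> float:
    if name not in specs:
        raise DesignError(f"no z-score spec for covariate {name!r}")
    if value is None or not np.isfinite(value):
        raise DesignError(f"missing covariate value for {name!r}")
    return float(specs[name].transform(value))


def hurdle_design_row(
    metadata: TrialMetadata, wave_level: str, specs: dict[str, ZScoreSpec]
) -> dict[str, float]:
    """One dummy-coded row of the hurdle design (unit = condition).

    The time covariate is the trial start relative to low tide.
    """
    row = _treatment_dummies(wave_level, metadata.claw_treatment)
    row["fast_first"] = float(metadata.order_treatment == "fast_first")
    row["temperature_z"] = _z(specs, "temperature", metadata.temperature_c)
    row["tide_z"] = _z(specs, "tide_time", metadata.tide_offset_min)
    row["carapace_z"] = _z(specs, "carapace_width", metadata.carapace_width_mm)
    row["ratio_z"] = _z(specs, "claw_ratio", metadata.claw_ratio)
    return {c: row[c] for c in HURDLE_COLUMNS}


def hmm_design_row(
    metadata: TrialMetadata,
    wave_level: str,
    interval_start_s: float,
    n_females: int,
    rival_in_view: int,
    specs: dict[str, ZScoreSpec],
    include_interaction: bool = False,
) -> dict[str, float]:
    """One dummy-coded row of the HMM design (unit = 5-s interval).

    The time covariate is the interval midpoint relative to low tide,
    in minutes; temperature is trial-level (measured at trial start).
    """
    row = _treatment_dummies(wave_level, metadata.claw_treatment)
    midpoint_min = metadata.tide_offset_min + (interval_start_s + INTERVAL_S / 2) / 60.0
    row["n_females"] = float(n_females)
    row["rival_in_view"] = float(bool(rival_in_view))
    row["temperature_z"] = _z(specs, "temperature", metadata.temperature_c)
    row["tide_z"] = _z(specs, "tide_time", midpoint_min)
    row["carapace_z"] = _z(specs, "carapace_width", metadata.carapace_width_mm)
    row["ratio_z"] = _z(specs, "claw_ratio", metadata.claw_ratio)
    cols = HMM_COLUMNS + (HMM_INTERACTION_COLUMNS if include_interaction else ())
    return {c: row[c] for c in cols}


def hmm_design_columns(include_interaction: bool = False) -> tuple[str, ...]:
    return HMM_COLUMNS + (HMM_INTERACTION_COLUMNS if include_interaction else ())


def metadata_frame(trials: list[TrialMetadata]) -> pd.DataFrame:
    """Tabulate trial metadata with raw-scale covariate columns attached."""
    rows = []
    for m in trials:
        rows.append(
            {
                "male_id": m.male_id,
                "block_id": m.block_id,
                "claw_treatment": m.claw_treatment,
                "order_treatment": m.order_treatment,
                "temperature_c": m.temperature_c,
                "tide_offset_min": m.tide_offset_min,
                "claw_length_mm": m.claw_length_mm,
                "carapace_width_mm": m.carapace_width_mm,
                "temperature": m.temperature_c,
                "tide_time": m.tide_offset_min,
                "carapace_width": m.carapace_width_mm,
                "claw_ratio": m.claw_ratio,
            }
        )
    return pd.DataFrame(rows)


def metadata_from_frame(frame: pd.DataFrame) -> list[TrialMetadata]:
    """Parse a metadata table (e.g. read from CSV) back into records."""
    required = [
        "male_id",
        "block_id",
        "claw_treatment",
        "order_treatment",
        "temperature_c",
        "tide_offset_min",
        "claw_length_mm",
        "carapace_width_mm",
    ]
    for col in required:
        if col not in frame.columns:
            raise DesignError(f"metadata table missing column {col!r}")
    return [
        TrialMetadata(
            male_id=str(r.male_id),
            block_id=str(r.block_id),
            claw_treatment=str(r.claw_treatment),
            order_treatment=str(r.order_treatment),
            temperature_c=float(r.temperature_c),
            tide_offset_min=float(r.tide_offset_min),
            claw_length_mm=float(r.claw_length_mm),
            carapace_width_mm=float(r.carapace_width_mm),
        )
        for r in frame.itertuples()
    ]
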