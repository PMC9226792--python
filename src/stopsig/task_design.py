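"""Selective stop-signal task schedules.

A session interleaves two conditions in a single pseudorandom sequence:

* **reactive** trials start with a non-informative cue;
* **proactive** trials start with an informative arrow cue pointing left or
  right, and on stop trials the cue always points to the side that will have
  to be stopped (cues are congruent).

Go trials require a bimanual response; on stop trials a stop signal (red
circle) appears on one side after a stop-signal delay (SSD) and only that
hand must be withheld.  The default design is 700 trials, half reactive and
half proactive, with a 60/40 go/stop split and stop trials balanced over
left and right within each condition.  SSDs are drawn uniformly at random
from a grid spanning 50-500 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "TrialSpec",
    "DesignParams",
    "TaskSchedule",
    "generate_schedule",
    "sample_ssd",
    "validate_schedule",
    "schedule_to_frame",
    "frame_to_schedule",
]

CONDITIONS = ("reactive", "proactive")
SSD_MIN_MS = 50.0
SSD_MAX_MS = 500.0


class ConfigurationError(ValueError):
    """A design parameter set that cannot produce a valid schedule."""


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the selective stop-signal task.

    ``cue_direction`` is ``"none"`` on reactive trials and ``"left"`` /
    ``"right"`` on proactive trials.  ``stop_direction`` and ``ssd_ms`` are
    ``"n/a"`` / ``nan`` on go trials.
    """

    index: int
    condition: str            # reactive | proactive
    trial_type: str           # go | stop
    cue_direction: str        # left | right | none
    stop_direction: str       # left | right | n/a
    ssd_ms: float             # nan on go trials
    cue_duration_ms: float = 200.0
    gap_duration_ms: float = 1300.0
    stimulus_duration_ms: float = 100.0

    @property
    def cue_onset_ms(self) -> float:
        """Cue onset relative to trial start (always 0)."""
        return 0.0

    @property
    def fixation_onset_ms(self) -> float:
        return self.cue_duration_ms

    @property
    def stimulus_onset_ms(self) -> float:
        """Go-stimulus onset relative to trial start."""
        return self.cue_duration_ms + self.gap_duration_ms

    @property
    def stop_onset_ms(self) -> float:
        """Stop-signal onset relative to trial start (nan on go trials)."""
        if self.trial_type != "stop":
            return float("nan")
        return self.stimulus_onset_ms + self.ssd_ms


@dataclass(frozen=True)
class DesignParams:
    """Counts, proportions and timings defining a session.

    Defaults reproduce the reference design: 700 trials, 350 per condition,
    go fraction 0.6, stop trials split evenly left/right within condition,
    cue 200 ms, fixation gap 1300 ms, go stimulus 100 ms, stop circle
    200 ms, SSD uniform on a 50 ms grid from 50 to 500 ms, and at most
    3 consecutive stop trials.
    """

    total_trials: int = 700
    go_fraction: float = 0.6
    ssd_grid_ms: tuple[float, ...] = tuple(float(v) for v in range(50, 501, 50))
    cue_duration_ms: float = 200.0
    gap_duration_ms: float = 1300.0
    stimulus_duration_ms: float = 100.0
    stop_duration_ms: float = 200.0
    max_consecutive_stops: int = 3
    # Inter-trial interval after stimulus offset; sets trial spacing when a
    # continuous EEG record is synthesized around the schedule.
    iti_ms: float = 1400.0

    @property
    def trial_duration_ms(self) -> float:
        return (self.cue_duration_ms + self.gap_duration_ms
                + self.stimulus_duration_ms + self.iti_ms)

    def cell_counts(self) -> dict[str, int]:
        """Integral per-cell counts; raises ConfigurationError if any split
        is non-integral."""
        n = self.total_trials
        if n % len(CONDITIONS):
            raise ConfigurationError(
                f"total_trials={n} not divisible into {len(CONDITIONS)} conditions")
        per_cond = n // len(CONDITIONS)
        go_per_cond = self.go_fraction * per_cond
        if abs(go_per_cond - round(go_per_cond)) > 1e-9:
            raise ConfigurationError(
                f"go_fraction={self.go_fraction} of {per_cond} trials per "
                f"condition is non-integral ({go_per_cond})")
        go_per_cond = round(go_per_cond)
        stop_per_cond = per_cond - go_per_cond
        if stop_per_cond % 2:
            raise ConfigurationError(
                f"stop trials per condition ({stop_per_cond}) cannot be "
                "split evenly over left/right")
        if go_per_cond % 2:
            raise ConfigurationError(
                f"go trials per condition ({go_per_cond}) cannot be split "
                "evenly over left/right proactive cues")
        return {
            "per_condition": per_cond,
            "go_per_condition": go_per_cond,
            "stop_per_condition": stop_per_cond,
            "stop_per_direction": stop_per_cond // 2,
        }


@dataclass
class TaskSchedule:
    trials: list[TrialSpec]
    seed: int
    design_params: DesignParams = field(default_factory=DesignParams)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


def sample_ssd(rng: np.random.Generator, grid: tuple[float, ...] | list[float]) -> float:
    """Draw one SSD uniformly from ``grid`` (values must lie in 50-500 ms)."""
    grid = tuple(grid)
    if not grid:
        raise ConfigurationError("SSD grid is empty")
    bad = [v for v in grid if not (SSD_MIN_MS <= v <= SSD_MAX_MS)]
    if bad:
        raise ConfigurationError(f"SSD grid values outside [50, 500] ms: {bad}")
    return float(grid[rng.integers(len(grid))])


def _enforce_run_length(order: np.ndarray, is_stop: np.ndarray,
                        max_run: int, rng: np.random.Generator) -> np.ndarray:
    """Repair a permutation so no more than max_run consecutive stop trials
    occur, by swapping offending stop positions with random go positions."""
    order = order.copy()
    for _ in range(10_000):
        stop_flags = is_stop[order]
        run = 0
        offender = -1
        for i, s in enumerate(stop_flags):
            run = run + 1 if s else 0
            if run > max_run:
                offender = i
                break
        if offender < 0:
            return order
        go_positions = np.flatnonzero(~stop_flags)
        j = int(rng.choice(go_positions))
        order[offender], order[j] = order[j], order[offender]
    raise ConfigurationError(
        "could not satisfy the consecutive-stop constraint; "
        f"max_consecutive_stops={max_run} too strict for this design")


def generate_schedule(design_params: DesignParams | None = None,
                      seed: int = 0) -> TaskSchedule:
    """Generate a full pseudorandom session schedule.

    The trial multiset is built deterministically from the design counts,
    then permuted with a seeded RNG subject to the run-length constraint.
    Identical ``(design_params, seed)`` give identical schedules.
    """
    params = design_params or DesignParams()
    counts = params.cell_counts()
    rng = np.random.default_rng(seed)

    protos: list[dict] = []
    for condition in CONDITIONS:
        n_go = counts["go_per_condition"]
        # Proactive go cues balanced left/right; reactive cues non-informative.
        for k in range(n_go):
            if condition == "proactive":
                cue = "left" if k < n_go // 2 else "right"
            else:
                cue = "none"
            protos.append(dict(condition=condition, trial_type="go",
                               cue_direction=cue, stop_direction="n/a"))
        for direction in ("left", "right"):
            for _ in range(counts["stop_per_direction"]):
                cue = direction if condition == "proactive" else "none"
                protos.append(dict(condition=condition, trial_type="stop",
                                   cue_direction=cue, stop_direction=direction))

    is_stop = np.array([p["trial_type"] == "stop" for p in protos])
    order = rng.permutation(len(protos))
    order = _enforce_run_length(order, is_stop, params.max_consecutive_stops, rng)

    trials = []
    for idx, src in enumerate(order):
        p = protos[src]
        ssd = (sample_ssd(rng, params.ssd_grid_ms)
               if p["trial_type"] == "stop" else float("nan"))
        trials.append(TrialSpec(
            index=idx, ssd_ms=ssd,
            cue_duration_ms=params.cue_duration_ms,
            gap_duration_ms=params.gap_duration_ms,
            stimulus_duration_ms=params.stimulus_duration_ms,
            **p))
    return TaskSchedule(trials=trials, seed=seed, design_params=params)


def validate_schedule(schedule: TaskSchedule) -> list[str]:
    """Check every trial- and schedule-level invariant.

    Returns a list of human-readable violations (empty when valid); never
    raises on bad content.
    """
    violations: list[str] = []
    params = schedule.design_params
    try:
        counts = params.cell_counts()
    except ConfigurationError as exc:
        return [f"design: {exc}"]

    for t in schedule.trials:
        where = f"trial {t.index}"
        if t.condition not in CONDITIONS:
            violations.append(f"{where}: unknown condition {t.condition!r}")
            continue
        if t.condition == "reactive" and t.cue_direction != "none":
            violations.append(f"{where}: reactive trial with informative cue "
                              f"{t.cue_direction!r}")
        if t.condition == "proactive" and t.cue_direction not in ("left", "right"):
            violations.append(f"{where}: proactive trial needs a left/right cue")
        if t.trial_type == "go":
            if t.stop_direction != "n/a":
                violations.append(f"{where}: go trial with stop_direction set")
            if not math.isnan(t.ssd_ms):
                violations.append(f"{where}: go trial with ssd_ms set")
        elif t.trial_type == "stop":
            if t.stop_direction not in ("left", "right"):
                violations.append(f"{where}: stop trial without stop direction")
            if not (SSD_MIN_MS <= t.ssd_ms <= SSD_MAX_MS):
                violations.append(f"{where}: ssd_ms={t.ssd_ms} outside [50, 500]")
            if (t.condition == "proactive"
                    and t.cue_direction != t.stop_direction):
                violations.append(f"{where}: proactive stop cue "
                                  f"{t.cue_direction!r} incongruent with stop "
                                  f"direction {t.stop_direction!r}")
        else:
            violations.append(f"{where}: unknown trial_type {t.trial_type!r}")

    n = len(schedule.trials)
    if n != params.total_trials:
        violations.append(f"schedule: {n} trials, expected {params.total_trials}")

    def count(**sel) -> int:
        return sum(all(getattr(t, k) == v for k, v in sel.items())
                   for t in schedule.trials)

    for condition in CONDITIONS:
        if count(condition=condition) != counts["per_condition"]:
            violations.append(f"schedule: condition {condition} count "
                              f"{count(condition=condition)} != {counts['per_condition']}")
        if count(condition=condition, trial_type="go") != counts["go_per_condition"]:
            violations.append(f"schedule: go count in {condition} is off")
        for direction in ("left", "right"):
            c = count(condition=condition, trial_type="stop",
                      stop_direction=direction)
            if c != counts["stop_per_direction"]:
                violations.append(
                    f"schedule: stop-{direction} count in {condition} is "
                    f"{c} != {counts['stop_per_direction']}")

    run = 0
    for t in schedule.trials:
        run = run + 1 if t.trial_type == "stop" else 0
        if run > params.max_consecutive_stops:
            violations.append(f"trial {t.index}: more than "
                              f"{params.max_consecutive_stops} consecutive stop trials")
            break
    return violations


def schedule_to_frame(schedule: TaskSchedule) -> pd.DataFrame:
    """Tabular view of a schedule (the on-disk TSV layout)."""
    rows = [{
        "index": t.index,
        "condition": t.condition,
        "trial_type": t.trial_type,
        "cue_direction": t.cue_direction,
        "stop_direction": t.stop_direction,
        "ssd_ms": t.ssd_ms,
        "cue_onset_ms": t.cue_onset_ms,
        "fixation_onset_ms": t.fixation_onset_ms,
        "stimulus_onset_ms": t.stimulus_onset_ms,
    } for t in schedule.trials]
    return pd.DataFrame(rows)


def frame_to_schedule(frame: pd.DataFrame, seed: int = -1,
                      design_params: DesignParams | None = None) -> TaskSchedule:
    """Rebuild a TaskSchedule from its tabular form.

    Timings are recovered from the onset columns; if design_params is not
    given, counts are inferred from the table so the validator can run.
    """
    trials = []
    for _, r in frame.iterrows():
        cue_dur = float(r["fixation_onset_ms"]) - float(r["cue_onset_ms"])
        gap_dur = float(r["stimulus_onset_ms"]) - float(r["fixation_onset_ms"])
        trials.append(TrialSpec(
            index=int(r["index"]),
            condition=str(r["condition"]),
            trial_type=str(r["trial_type"]),
            cue_direction=str(r["cue_direction"]),
            stop_direction=str(r["stop_direction"]),
            ssd_ms=float(r["ssd_ms"]),
            cue_duration_ms=cue_dur,
            gap_duration_ms=gap_dur,
        ))
    if design_params is None:
        n = len(trials)
        n_go = sum(t.trial_type == "go" for t in trials)
        design_params = replace(DesignParams(), total_trials=n,
                                go_fraction=n_go / n if n else 0.6)
    return TaskSchedule(trials=trials, seed=seed, design_params=design_params)
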