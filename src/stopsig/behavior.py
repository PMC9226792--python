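"""Behavioral scoring for the selective stop-signal task.

Covers trial classification, go-trial metrics (mean RT, omissions) and the
stop-signal reaction time (SSRT) by the integration method: the go-RT
distribution is integrated up to the quantile equal to p(respond | signal)
— i.e. the n-th ranked go RT with ``n = ceil(p * N)`` after omissions are
replaced with the maximum observed RT — and the mean stop-signal delay is
subtracted from that ranked RT.  Estimates are computed per condition and
stop direction, using the same-condition go RT distribution, mirroring how
selective stopping studies tabulate SSRT-LEFT / SSRT-RIGHT separately for
reactive and proactive trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import BehavioralTrial
from .task_design import TaskSchedule

__all__ = [
    "AlignmentError",
    "EmptyInputError",
    "UndefinedEstimateError",
    "SSRTEstimate",
    "classify_trials",
    "go_metrics",
    "estimate_ssrt_integration",
    "session_metrics",
    "study_metrics_table",
]

CLASSIFICATIONS = ("go_correct", "go_omission", "stop_success",
                   "stop_failed", "stop_choice_error")


class AlignmentError(ValueError):
    """Response log does not match the schedule it claims to score."""


class EmptyInputError(ValueError):
    """An operation received no usable trials."""


class UndefinedEstimateError(ValueError):
    """No finite SSRT exists (p(respond|signal) = 0: stopping never failed)."""


@dataclass(frozen=True)
class SSRTEstimate:
    """Integration-method SSRT for one condition x stop-direction stratum."""

    value_ms: float
    n_rank: int
    p_respond: float
    mean_ssd_ms: float
    n_go_rts: int
    condition: str
    direction: str


def classify_trials(raw: pd.DataFrame, schedule: TaskSchedule) -> list[BehavioralTrial]:
    """Classify raw per-trial responses against the schedule.

    ``raw`` needs one row per scheduled trial with columns ``index``,
    ``left_rt_ms`` and ``right_rt_ms`` (nan = no response).  Go trials are
    ``go_correct`` if at least one hand responded, else ``go_omission``.
    Stop trials (stop side d, responding side o): ``stop_success`` when
    hand d is withheld; ``stop_failed`` when hand d responds along with
    hand o; ``stop_choice_error`` when hand d responds alone — a wrong-hand
    response replacing the required one on an unsuccessful stop.
    """
    raw = raw.set_index("index") if "index" in raw.columns else raw
    out: list[BehavioralTrial] = []
    for t in schedule:
        if t.index not in raw.index:
            raise AlignmentError(f"trial {t.index} missing from response log")
        row = raw.loc[t.index]
        left = float(row["left_rt_ms"])
        right = float(row["right_rt_ms"])
        responded = {"left": not math.isnan(left), "right": not math.isnan(right)}
        if t.trial_type == "go":
            cls = "go_correct" if any(responded.values()) else "go_omission"
        else:
            cued = t.stop_direction
            other = "right" if cued == "left" else "left"
            if not responded[cued]:
                cls = "stop_success"
            elif responded[other]:
                cls = "stop_failed"
            else:
                cls = "stop_choice_error"
        out.append(BehavioralTrial(
            index=t.index, condition=t.condition, trial_type=t.trial_type,
            cue_direction=t.cue_direction, stop_direction=t.stop_direction,
            ssd_ms=t.ssd_ms, left_rt_ms=left, right_rt_ms=right,
            classification=cls))
    if len(out) != len(raw):
        extra = sorted(set(raw.index) - {t.index for t in schedule})
        raise AlignmentError(f"response log has unscheduled trials: {extra[:5]}")
    return out


def _trial_rt(b: BehavioralTrial) -> float:
    """Per-trial go RT: mean of the responding hands."""
    rts = [r for r in (b.left_rt_ms, b.right_rt_ms) if not math.isnan(r)]
    return float(np.mean(rts)) if rts else math.nan


def go_metrics(trials: list[BehavioralTrial],
               condition: str | None = None) -> dict[str, float]:
    """Mean go RT (over responded go trials) and omission count."""
    go = [b for b in trials if b.trial_type == "go"
          and (condition is None or b.condition == condition)]
    if not go:
        raise EmptyInputError(f"no go trials for condition={condition!r}")
    rts = [_trial_rt(b) for b in go if b.classification == "go_correct"]
    omissions = sum(b.classification == "go_omission" for b in go)
    mean_rt = float(np.mean(rts)) if rts else math.nan
    return {"mean_rt_ms": mean_rt, "omission_count": float(omissions),
            "n_go": float(len(go))}


def estimate_ssrt_integration(go_rts: list[float] | np.ndarray,
                              p_respond: float,
                              mean_ssd_ms: float,
                              omission_count: int = 0,
                              condition: str = "",
                              direction: str = "") -> SSRTEstimate:
    """Integration-method SSRT.

    Omitted go trials are appended as copies of the maximum observed RT
    (guarding against a downward-biased quantile), the list is sorted
    ascending, and the stop process is placed at the ``ceil(p * N)``-th
    ranked RT; SSRT is that RT minus the mean SSD of the stratum's stop
    trials.
    """
    go_rts = [float(r) for r in go_rts if not math.isnan(float(r))]
    if not go_rts:
        raise EmptyInputError("no go RTs")
    if not 0.0 <= p_respond <= 1.0:
        raise ValueError(f"p_respond={p_respond} outside [0, 1]")
    if p_respond == 0.0:
        raise UndefinedEstimateError(
            "p(respond|signal) = 0: stop process always won, no finite SSRT")
    rts = sorted(go_rts + [max(go_rts)] * int(omission_count))
    n = len(rts)
    n_rank = min(max(math.ceil(p_respond * n), 1), n)
    value = rts[n_rank - 1] - mean_ssd_ms
    return SSRTEstimate(value_ms=float(value), n_rank=n_rank,
                        p_respond=float(p_respond),
                        mean_ssd_ms=float(mean_ssd_ms), n_go_rts=n,
                        condition=condition, direction=direction)


def _stratum_ssrt(trials: list[BehavioralTrial], condition: str,
                  direction: str,
                  count_choice_errors_as_response: bool = True) -> SSRTEstimate:
    go = [b for b in trials if b.condition == condition and b.trial_type == "go"]
    stop = [b for b in trials if b.condition == condition
            and b.trial_type == "stop" and b.stop_direction == direction]
    if not go or not stop:
        raise EmptyInputError(
            f"stratum {condition}/{direction} has no go or stop trials")
    responded_classes = {"stop_failed"}
    if count_choice_errors_as_response:
        responded_classes.add("stop_choice_error")
    p_resp = float(np.mean([b.classification in responded_classes for b in stop]))
    mean_ssd = float(np.mean([b.ssd_ms for b in stop]))
    # The go distribution that races the stop process on stop-`direction`
    # trials is that hand's own finish-time distribution, so the quantile
    # is taken over the same-condition go RTs of the stopped hand.
    hand_attr = f"{direction}_rt_ms"
    go_rts = [getattr(b, hand_attr) for b in go
              if b.classification == "go_correct"
              and not math.isnan(getattr(b, hand_attr))]
    omissions = sum(b.classification == "go_omission" for b in go)
    return estimate_ssrt_integration(go_rts, p_resp, mean_ssd, omissions,
                                     condition=condition, direction=direction)


def session_metrics(trials: list[BehavioralTrial],
                    count_choice_errors_as_response: bool = True) -> pd.DataFrame:
    """Per-condition behavioral summary shaped like the study's tables.

    One row per condition with SSRT-RIGHT, SSRT-LEFT, choice-error counts
    per stop direction (CHE-STOPR / CHE-STOPL), go omission count and mean
    go RT.  A stratum where stopping never failed gets SSRT nan.
    """
    rows = []
    for condition in ("reactive", "proactive"):
        row: dict[str, float | str] = {"condition": condition}
        gm = go_metrics(trials, condition)
        row["rt_go_ms"] = gm["mean_rt_ms"]
        row["om_go"] = gm["omission_count"]
        for direction, key in (("right", "ssrt_right_ms"), ("left", "ssrt_left_ms")):
            try:
                est = _stratum_ssrt(trials, condition, direction,
                                    count_choice_errors_as_response)
                row[key] = est.value_ms
                row[f"p_respond_{direction}"] = est.p_respond
            except UndefinedEstimateError:
                row[key] = math.nan
                row[f"p_respond_{direction}"] = 0.0
        for direction, key in (("right", "che_stopr"), ("left", "che_stopl")):
            row[key] = float(sum(
                b.classification == "stop_choice_error"
                for b in trials if b.condition == condition
                and b.trial_type == "stop" and b.stop_direction == direction))
        rows.append(row)
    return pd.DataFrame(rows)


def study_metrics_table(sessions) -> pd.DataFrame:
    """Stack session_metrics over subjects with subject/group columns."""
    frames = []
    for sess in sessions:
        m = session_metrics(sess.behavior)
        m.insert(0, "subject", sess.subject_id)
        m.insert(1, "group", sess.group)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)
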