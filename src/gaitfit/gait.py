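"""Gait event detection and spatio-temporal gait parameters.

Heel-strike (HS) and toe-off (TO) are read off the anterior-posterior (AP)
distance of each foot from the camera: the foot is furthest from the camera at
heel-strike and closest at toe-off, so HS events are local maxima and TO
events local minima of the per-frame AP series.  Extrema are found with a
sliding detection window (default 19 frames); an extremum closer than
``delta_d_min`` frames to the adjacent opposite extremum is treated as noise.

Each pair of consecutive same-side heel-strikes with at least one interior
toe-off forms a gait cycle; with multiple TO candidates the one whose
stance-to-cycle ratio is closest to the ideal 60 % is kept.  Step length and
step width are computed from the displacement between the two feet at the
cycle-terminating heel-strike:

``step_length = |d_step · v_dir|``,  ``step_width = sqrt(‖d_step‖² − step_length²)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GaitEvent",
    "GaitCycle",
    "EventDetectorConfig",
    "detect_events",
    "pair_cycles",
    "spatial_parameters",
    "analyze_trajectory",
    "cycles_to_frame",
]

STANCE_RATIO_IDEAL = 0.60


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # "HS" | "TO"
    side: str  # "left" | "right"
    frame: int
    time: float


@dataclass
class GaitCycle:
    side: str
    hs_start: GaitEvent
    to: GaitEvent
    hs_end: GaitEvent
    step_length: float = np.nan  # mm
    step_width: float = np.nan  # mm

    @property
    def cycle_time(self) -> float:
        return self.hs_end.time - self.hs_start.time

    @property
    def stance_time(self) -> float:
        return self.to.time - self.hs_start.time

    @property
    def swing_time(self) -> float:
        return self.hs_end.time - self.to.time


@dataclass
class EventDetectorConfig:
    window: int = 19  # detection window, frames (odd, >= 3)
    delta_d_min: int = 5  # min frame gap to the adjacent opposite extremum
    v_dir: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )  # walking direction, camera frame (straight away from the camera)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.delta_d_min < 1:
            raise ValueError("delta_d_min must be >= 1")
        v = np.asarray(self.v_dir, dtype=float)
        self.v_dir = v / np.linalg.norm(v)


def _window_extrema(series: np.ndarray, window: int) -> List[Tuple[int, str]]:
    """Frames whose value is the strict max (HS) or min (TO) of the centered
    window; ties break toward the earlier frame (a later equal value loses)."""
    hw = window // 2
    out: List[Tuple[int, str]] = []
    n = len(series)
    for i in range(hw, n - hw):
        w = series[i - hw : i + hw + 1]
        v = series[i]
        if v >= w.max() and int(np.argmax(w)) == hw:
            out.append((i, "HS"))
        elif v <= w.min() and int(np.argmin(w)) == hw:
            out.append((i, "TO"))
    return out


def detect_events(
    ap_distance: np.ndarray,
    side: str,
    config: Optional[EventDetectorConfig] = None,
    times: Optional[np.ndarray] = None,
) -> List[GaitEvent]:
    """Sliding-window extremum detection on one side's AP-distance series.

    Candidates are accepted in time order with two rejection rules: a
    candidate of the same kind as the last accepted event replaces it only if
    more extreme (a glitch riding on the opposite phase is thereby dropped),
    and a candidate closer than ``delta_d_min`` frames to the last accepted
    opposite-kind event is rejected as noise.  A constant (or too short)
    series yields no events.
    """
    config = config or EventDetectorConfig()
    series = np.asarray(ap_distance, dtype=float)
    if len(series) < config.window:
        return []
    if times is None:
        times = np.arange(len(series), dtype=float)

    accepted: List[GaitEvent] = []
    for frame, kind in _window_extrema(series, config.window):
        ev = GaitEvent(kind=kind, side=side, frame=frame, time=float(times[frame]))
        if not accepted:
            accepted.append(ev)
            continue
        last = accepted[-1]
        if kind == last.kind:
            better = (
                series[frame] > series[last.frame]
                if kind == "HS"
                else series[frame] < series[last.frame]
            )
            if better:
                accepted[-1] = ev
        else:
            if frame - last.frame <= config.delta_d_min:
                continue
            accepted.append(ev)
    return accepted


def pair_cycles(
    events: Sequence[GaitEvent], stance_ratio_ideal: float = STANCE_RATIO_IDEAL
) -> List[GaitCycle]:
    """Form gait cycles from one side's time-sorted events.

    A cycle exists for each consecutive HS pair with at least one interior TO;
    with several, the TO whose stance-to-cycle ratio is closest to
    ``stance_ratio_ideal`` is selected.
    """
    hs = [e for e in events if e.kind == "HS"]
    tos = [e for e in events if e.kind == "TO"]
    cycles: List[GaitCycle] = []
    for a, b in zip(hs[:-1], hs[1:]):
        inner = [t for t in tos if a.time < t.time < b.time]
        if not inner:
            continue
        span = b.time - a.time
        best = min(inner, key=lambda t: abs((t.time - a.time) / span - stance_ratio_ideal))
        cycles.append(GaitCycle(side=a.side, hs_start=a, to=best, hs_end=b))
    return cycles


def spatial_parameters(
    t_left: np.ndarray, t_right: np.ndarray, v_dir: np.ndarray
) -> Tuple[float, float]:
    """Step length and step width (mm) from the two feet's origins at an HS.

    ``d_step`` is the displacement between the feet; its projection on the
    walking direction is the step length and the Pythagorean residual the step
    width (clamped at zero against rounding).
    """
    v = np.asarray(v_dir, dtype=float)
    v = v / np.linalg.norm(v)
    d = np.asarray(t_right, dtype=float) - np.asarray(t_left, dtype=float)
    length = abs(float(d @ v))
    width_sq = float(d @ d) - length**2
    return length, float(np.sqrt(max(width_sq, 0.0)))


def analyze_trajectory(
    trajectory: pd.DataFrame,
    config: Optional[EventDetectorConfig] = None,
) -> Tuple[List[GaitCycle], List[GaitEvent]]:
    """Full gait report from a tracked trajectory.

    ``trajectory`` is the tracker's output frame (columns frame, time_s, side,
    tx, ty, tz, ...).  Per side the AP distance is the projection of the foot
    translation on the walking direction; events are detected, paired into
    cycles, and the spatial parameters are evaluated at each cycle-terminating
    heel-strike.  A trajectory too short for the detection window yields an
    empty report.
    """
    config = config or EventDetectorConfig()
    events: List[GaitEvent] = []
    cycles: List[GaitCycle] = []
    by_side = {
        side: g.sort_values("frame").reset_index(drop=True)
        for side, g in trajectory.groupby("side")
    }
    translations = {
        side: g[["tx", "ty", "tz"]].to_numpy() for side, g in by_side.items()
    }
    for side, g in by_side.items():
        ap = translations[side] @ config.v_dir
        side_events = detect_events(ap, side, config, times=g["time_s"].to_numpy())
        # map series index back to the original frame numbers
        frames = g["frame"].to_numpy()
        side_events = [
            GaitEvent(e.kind, e.side, int(frames[e.frame]), e.time)
            for e in side_events
        ]
        events.extend(side_events)
        side_cycles = pair_cycles(side_events)
        other = "right" if side == "left" else "left"
        if other in by_side:
            og = by_side[other]
            frame_to_idx = {int(f): k for k, f in enumerate(og["frame"].to_numpy())}
            own_idx = {int(f): k for k, f in enumerate(frames)}
            for cyc in side_cycles:
                f = cyc.hs_end.frame
                if f in frame_to_idx and f in own_idx:
                    tl = translations[side][own_idx[f]]
                    to = translations[other][frame_to_idx[f]]
                    if side == "left":
                        length, width = spatial_parameters(tl, to, config.v_dir)
                    else:
                        length, width = spatial_parameters(to, tl, config.v_dir)
                    cyc.step_length, cyc.step_width = length, width
        cycles.extend(side_cycles)
    events.sort(key=lambda e: e.time)
    cycles.sort(key=lambda c: c.hs_start.time)
    return cycles, events


def cycles_to_frame(cycles: Sequence[GaitCycle]) -> pd.DataFrame:
    """Tabular gait report (one row per cycle)."""
    return pd.DataFrame(
        [
            {
                "side": c.side,
                "hs_start_time": c.hs_start.time,
                "to_time": c.to.time,
                "hs_end_time": c.hs_end.time,
                "step_length_mm": c.step_length,
                "step_width_mm": c.step_width,
                "cycle_time_s": c.cycle_time,
                "stance_time_s": c.stance_time,
                "swing_time_s": c.swing_time,
            }
            for c in cycles
        ]
    )
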