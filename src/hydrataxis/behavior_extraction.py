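"""Extraction of the three behavioral parameters from a pose track.

The analysis reduces *Hydra* phototaxis to three per-animal quantities:

* **head orientation** theta -- the unsigned angle between the foot-to-head
  vector and the foot-to-light vector, in [0, 180] degrees (a signed version
  in (-180, 180], positive toward +y, feeds the random-walk model);
* **jump distance** d -- the Euclidean displacement of the foot across a
  somersault, detected as a supra-threshold inter-sample foot displacement;
* **jump rate** lambda -- the Poisson rate N_h / T_h, where N_h is the
  animal's jump count and T_h its observation time in hours.

The phototaxis outcome is whether (and when) the foot crosses the
threshold distance from the light plane within the analysis horizon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from ._angles import wrap_deg
from .exceptions import UndefinedAngleError
from .trajectory_io import ChamberGeometry, PoseTrack

logger = logging.getLogger(__name__)

__all__ = [
    "JumpEvent",
    "BehavioralSummary",
    "ExtractionSettings",
    "head_orientation",
    "signed_heading",
    "heading_series",
    "detect_jumps",
    "jump_rate",
    "pooled_jump_rate",
    "classify_activity",
    "phototaxis_outcome",
    "summarize",
    "signed_heading_changes",
]


@dataclass(frozen=True)
class JumpEvent:
    """One somersault: the foot leaves ``from_xy`` at ``t_before`` (s) and is
    next seen attached at ``to_xy`` at ``t_after`` (s); ``distance`` is the
    Euclidean displacement in mm."""

    t_before: float
    t_after: float
    from_xy: tuple[float, float]
    to_xy: tuple[float, float]
    distance: float

    def __post_init__(self) -> None:
        if not self.t_after > self.t_before:
            raise ValueError("t_after must exceed t_before")
        d = math.dist(self.from_xy, self.to_xy)
        if not math.isclose(d, self.distance, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("distance inconsistent with from/to coordinates")
        if self.distance <= 0:
            raise ValueError("distance must be positive")


@dataclass
class ExtractionSettings:
    """Tunable knobs of the extraction stage (defaults documented in docs)."""

    epsilon_mm: float = 1.0
    min_dwell: int = 2
    activity_cutoff: int = 3
    horizon_h: float = 8.0
    pre_jump_only: bool = False


@dataclass
class BehavioralSummary:
    """Per-animal extracted features; the unit the model is fitted from."""

    animal_id: str
    theta_series: np.ndarray
    signed_heading_series: np.ndarray
    theta_times: np.ndarray
    jumps: list[JumpEvent]
    N_h: int
    T_h: float
    lambda_hat: float
    crossed: bool
    crossing_time: float | None
    activity_class: str
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.N_h != len(self.jumps):
            raise ValueError("N_h must equal the number of jump events")
        if not self.T_h > 0:
            raise ValueError("T_h must be positive")
        if not math.isclose(self.lambda_hat, self.N_h / self.T_h, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("lambda_hat must equal N_h / T_h")
        if self.crossed != (self.crossing_time is not None):
            raise ValueError("crossed must be true iff crossing_time is present")
        if self.activity_class not in ("active", "inactive"):
            raise ValueError("activity_class must be 'active' or 'inactive'")


# ---------------------------------------------------------------------------
# Head orientation
# ---------------------------------------------------------------------------

def signed_heading(foot, head, geometry: ChamberGeometry | None = None) -> float:
    """Signed heading in (-180, 180]: 0 = pointing straight at the light
    plane (-x direction), positive toward +y, 180 = directly away."""
    vx = head[0] - foot[0]
    vy = head[1] - foot[1]
    if vx == 0.0 and vy == 0.0:
        raise UndefinedAngleError("foot and head coincide; heading undefined")
    return float(wrap_deg(math.degrees(math.atan2(vy, -vx))))


def head_orientation(foot, head, geometry: ChamberGeometry | None = None) -> float:
    """Unsigned head orientation theta in [0, 180] degrees."""
    return abs(signed_heading(foot, head, geometry))


def heading_series(track: PoseTrack) -> tuple[np.ndarray, np.ndarray]:
    """Signed heading per sample; samples with a zero body vector are dropped.

    Returns ``(times, signed_heading_deg)``.
    """
    v = track.head - track.foot
    ok = ~np.all(v == 0.0, axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropping %d sample(s) with undefined heading for %s",
                    n_bad, track.animal_id)
    ang = wrap_deg(np.degrees(np.arctan2(v[ok, 1], -v[ok, 0])))
    return track.times[ok], np.atleast_1d(ang)


# ---------------------------------------------------------------------------
# Jumps
# ---------------------------------------------------------------------------

def detect_jumps(track: PoseTrack, epsilon: float = 1.0, min_dwell: int = 2) -> list[JumpEvent]:
    """Detect somersaults as supra-threshold foot displacements.

    Consecutive inter-sample displacements exceeding ``epsilon`` (mm) are
    merged into a single event spanning from the last pre-run sample to the
    first post-run sample; runs separated by fewer than ``min_dwell``
    sub-threshold samples are also merged (the foot has not settled). Events
    whose net from-to distance is at most ``epsilon`` are discarded.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = len(track)
    if n < 2:
        logger.warning("track %s shorter than 2 samples: no jumps detectable", track.animal_id)
        return []
    disp = np.linalg.norm(np.diff(track.foot, axis=0), axis=1)
    supra = disp > epsilon
    if not supra.any():
        return []
    idx = np.flatnonzero(supra)
    # maximal runs over displacement indices, merging gaps < min_dwell
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for k in idx[1:]:
        if int(k) - runs[-1][1] - 1 < min_dwell:
            runs[-1][1] = int(k)
        else:
            runs.append([int(k), int(k)])
    events: list[JumpEvent] = []
    for start, end in runs:
        frm = track.foot[start]
        to = track.foot[end + 1]
        d = float(np.linalg.norm(to - frm))
        if d <= epsilon:
            continue
        events.append(
            JumpEvent(
                t_before=float(track.times[start]),
                t_after=float(track.times[end + 1]),
                from_xy=(float(frm[0]), float(frm[1])),
                to_xy=(float(to[0]), float(to[1])),
                distance=d,
            )
        )
    return events


def jump_rate(N_h: int, T_h: float) -> float:
    """Poisson jump rate in jumps per hour: N_h / T_h."""
    if T_h <= 0:
        raise ValueError("T_h must be positive")
    if N_h < 0:
        raise ValueError("N_h must be non-negative")
    return N_h / T_h


def pooled_jump_rate(summaries: Iterable[BehavioralSummary]) -> float:
    """Pooled maximum-likelihood Poisson rate: sum N_h / sum T_h."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot pool an empty collection of summaries")
    total_n = sum(s.N_h for s in summaries)
    total_t = sum(s.T_h for s in summaries)
    if total_t <= 0:
        raise ValueError("total observation time must be positive")
    return total_n / total_t


def classify_activity(summary: BehavioralSummary, cutoff: int = 3) -> str:
    """'inactive' if the animal jumped at most ``cutoff`` times, else 'active'."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return "inactive" if summary.N_h <= cutoff else "active"


def phototaxis_outcome(
    track: PoseTrack, geometry: ChamberGeometry, horizon: float = 8.0
) -> tuple[bool, float | None]:
    """First threshold crossing within ``horizon`` hours, if any.

    Returns ``(crossed, crossing_time_h)``; times are measured from the
    track's first sample.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if len(track) == 0:
        return False, None
    rel_h = (track.times - track.times[0]) / 3600.0
    hit = np.flatnonzero((track.foot[:, 0] < geometry.phototaxis_threshold) & (rel_h <= horizon))
    if hit.size == 0:
        return False, None
    return True, float(rel_h[hit[0]])


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def summarize(
    track: PoseTrack,
    geometry: ChamberGeometry,
    settings: ExtractionSettings | None = None,
) -> BehavioralSummary:
    """Full per-animal extraction: heading series, jumps, rate, outcome.

    The analysis window is clipped to ``settings.horizon_h`` hours from the
    first sample; T_h is the elapsed time of that window.
    """
    settings = settings or ExtractionSettings()
    if len(track) < 2:
        raise ValueError(f"track {track.animal_id} too short to summarize")
    rel = track.times - track.times[0]
    keep = rel <= settings.horizon_h * 3600.0 + 1e-9
    import dataclasses as _dc

    clipped = _dc.replace(
        track,
        times=track.times[keep],
        foot=track.foot[keep],
        body=track.body[keep],
        head=track.head[keep],
        confidence=track.confidence[keep],
    )
    T_h = float((clipped.times[-1] - clipped.times[0]) / 3600.0)
    jumps = detect_jumps(clipped, epsilon=settings.epsilon_mm, min_dwell=settings.min_dwell)
    times, signed = heading_series(clipped)
    if settings.pre_jump_only and jumps:
        pre = np.isin(times, [j.t_before for j in jumps])
        times, signed = times[pre], signed[pre]
    crossed, crossing_time = phototaxis_outcome(clipped, geometry, settings.horizon_h)
    N_h = len(jumps)
    summary = BehavioralSummary(
        animal_id=track.animal_id,
        theta_series=np.abs(signed),
        signed_heading_series=signed,
        theta_times=times,
        jumps=jumps,
        N_h=N_h,
        T_h=T_h,
        lambda_hat=jump_rate(N_h, T_h),
        crossed=crossed,
        crossing_time=crossing_time,
        activity_class="inactive",  # placeholder, set below
        group_label=track.group_label,
    )
    summary.activity_class = classify_activity(summary, settings.activity_cutoff)
    return summary


def signed_heading_changes(summaries: Iterable[BehavioralSummary]) -> np.ndarray:
    """Pooled per-sample heading changes (deg, wrapped) across animals.

    The raw material for fitting the model's heading-noise terms.
    """
    out = []
    for s in summaries:
        if s.signed_heading_series.size >= 2:
            out.append(wrap_deg(np.diff(s.signed_heading_series)))
    if not out:
        return np.empty(0)
    return np.concatenate(out)
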