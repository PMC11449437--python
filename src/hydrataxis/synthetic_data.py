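"""Ground-truth synthetic cohorts rendered as pose-tracking files.

The generator runs the phototaxis model for starved and fed cohorts and
renders each simulated animal as a full-resolution pose track (1 frame per
second by default): the foot at the simulated location, the head one body
length away along the current heading, the body column at the midpoint, all
with isotropic Gaussian tracking jitter, plus an optional fraction of
corrupted low-confidence frames that emulate mislabelled tracker output.

The accompanying :class:`GroundTruth` records everything the generator knew
-- per-animal group, subclass, true rate, injected jump times/distances and
the heading series -- so every pipeline stage can be tested against it
without any external data.

Because real animals keep moving after reaching the light, the generator
does not terminate trajectories at the phototaxis threshold: each rendered
track spans the full horizon.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phototaxis_model import ModelParams, SimTrajectory, params_to_dict, simulate_cohort
from .trajectory_io import ChamberGeometry, PoseTrack, write_pose_csv

__all__ = [
    "TrackingNoise",
    "AnimalTruth",
    "GroundTruth",
    "generate_cohort",
    "generate_null_angles",
    "corrupt_frames",
]


@dataclass(frozen=True)
class TrackingNoise:
    """Rendering/tracking noise model for the synthetic pose output.

    ``jitter_sd`` is the isotropic per-point per-frame Gaussian tracking
    error (mm); ``body_length`` the foot-to-head distance (mm);
    ``corrupt_fraction`` the share of frames whose body point is teleported
    and flagged with low confidence.
    """

    jitter_sd: float = 0.05
    body_length: float = 3.0
    corrupt_fraction: float = 0.02
    high_confidence: tuple[float, float] = (0.9, 1.0)
    low_confidence: tuple[float, float] = (0.05, 0.4)

    def __post_init__(self) -> None:
        if self.jitter_sd < 0 or self.body_length <= 0:
            raise ValueError("jitter_sd must be >= 0 and body_length > 0")
        if not 0.0 <= self.corrupt_fraction <= 1.0:
            raise ValueError("corrupt_fraction must lie in [0, 1]")


@dataclass
class AnimalTruth:
    """Everything the generator knew about one synthetic animal."""

    animal_id: str
    group: str
    subclass: str | None
    true_lambda: float
    seed: int
    dt_s: float
    jump_times_s: list[float]
    jump_distances: list[float]
    jump_from: list[tuple[float, float]]
    jump_to: list[tuple[float, float]]
    heading_deg: list[float]
    crossed: bool
    crossing_time_h: float | None

    def __post_init__(self) -> None:
        if not (len(self.jump_times_s) == len(self.jump_distances)
                == len(self.jump_from) == len(self.jump_to)):
            raise ValueError("jump record lengths disagree")

    @property
    def n_jumps(self) -> int:
        return len(self.jump_times_s)

    def observable_events(self, min_dwell: int = 2, epsilon: float | None = None) -> list[dict]:
        """Injected jumps merged at the model's time resolution.

        Jumps closer together than ``min_dwell`` quiet steps cannot be told
        apart, at the step cadence, from a single somersault spanning them;
        they are merged into one event with the net displacement, exactly as
        a displacement-run detector sees them. With ``epsilon`` given, events
        whose net displacement is at most ``epsilon`` (mm) are dropped, again
        mirroring the detector. Each event dict has t_before_s, t_after_s,
        from_xy, to_xy and distance.
        """
        window = (min_dwell + 0.5) * self.dt_s
        events: list[dict] = []
        k = 0
        n = self.n_jumps
        while k < n:
            j = k
            while j + 1 < n and self.jump_times_s[j + 1] - self.jump_times_s[j] <= window:
                j += 1
            frm = self.jump_from[k]
            to = self.jump_to[j]
            d = math.dist(frm, to)
            if epsilon is None or d > epsilon:
                events.append(
                    {
                        "t_before_s": self.jump_times_s[k] - self.dt_s,
                        "t_after_s": self.jump_times_s[j],
                        "from_xy": tuple(frm),
                        "to_xy": tuple(to),
                        "distance": d,
                    }
                )
            k = j + 1
        return events


@dataclass
class GroundTruth:
    """Cohort-level ground truth: per-animal records plus generating settings."""

    animals: list[AnimalTruth]
    params: dict
    geometry: dict
    noise: dict
    seed: int

    def by_id(self) -> dict[str, AnimalTruth]:
        return {a.animal_id: a for a in self.animals}

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "params": self.params,
            "geometry": self.geometry,
            "noise": self.noise,
            "animals": [
                {
                    "animal_id": a.animal_id,
                    "group": a.group,
                    "subclass": a.subclass,
                    "true_lambda": a.true_lambda,
                    "seed": a.seed,
                    "dt_s": a.dt_s,
                    "jump_times_s": a.jump_times_s,
                    "jump_distances": a.jump_distances,
                    "jump_from": [list(p) for p in a.jump_from],
                    "jump_to": [list(p) for p in a.jump_to],
                    "heading_deg": a.heading_deg,
                    "crossed": a.crossed,
                    "crossing_time_h": a.crossing_time_h,
                }
                for a in self.animals
            ],
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        animals = [
            AnimalTruth(
                animal_id=a["animal_id"],
                group=a["group"],
                subclass=a["subclass"],
                true_lambda=a["true_lambda"],
                seed=a["seed"],
                dt_s=a["dt_s"],
                jump_times_s=a["jump_times_s"],
                jump_distances=a["jump_distances"],
                jump_from=[tuple(p) for p in a["jump_from"]],
                jump_to=[tuple(p) for p in a["jump_to"]],
                heading_deg=a["heading_deg"],
                crossed=a["crossed"],
                crossing_time_h=a["crossing_time_h"],
            )
            for a in payload["animals"]
        ]
        return cls(animals=animals, params=payload["params"], geometry=payload["geometry"],
                   noise=payload["noise"], seed=payload["seed"])


def _truth_from_trajectory(traj: SimTrajectory, params: ModelParams, n_rendered_states: int) -> AnimalTruth:
    """Record the jumps and headings that actually entered the rendered frames."""
    jump_idx = np.flatnonzero(traj.jump_flags[:n_rendered_states])
    return AnimalTruth(
        animal_id=traj.animal_id,
        group=traj.group,
        subclass=traj.subclass,
        true_lambda=params.rate_for(traj.group, traj.subclass),
        seed=traj.seed,
        dt_s=params.dt,
        jump_times_s=[float(traj.times[i]) for i in jump_idx],
        jump_distances=[float(np.linalg.norm(traj.foot_xy[i] - traj.foot_xy[i - 1])) for i in jump_idx],
        jump_from=[(float(traj.foot_xy[i - 1, 0]), float(traj.foot_xy[i - 1, 1])) for i in jump_idx],
        jump_to=[(float(traj.foot_xy[i, 0]), float(traj.foot_xy[i, 1])) for i in jump_idx],
        heading_deg=[float(h) for h in traj.heading[:n_rendered_states]],
        crossed=traj.crossed,
        crossing_time_h=traj.crossing_time,
    )


def _render_track(
    traj: SimTrajectory,
    params: ModelParams,
    geometry: ChamberGeometry,
    noise: TrackingNoise,
    rng: np.random.Generator,
    n_frames: int,
    frames_per_step: int,
) -> PoseTrack:
    step_idx = np.arange(n_frames) // frames_per_step
    foot = traj.foot_xy[step_idx]
    heading = traj.heading[step_idx]
    rad = np.radians(heading)
    u = np.column_stack([-np.cos(rad), np.sin(rad)])  # unit vector of the heading
    # A confined animal cannot extend its head through a wall: contract the
    # rendered body to what fits in the lane along the heading. The head
    # *direction* -- hence the extracted orientation -- is preserved exactly.
    with np.errstate(divide="ignore"):
        t_x = np.where(u[:, 0] < 0, foot[:, 0] / -u[:, 0],
                       np.where(u[:, 0] > 0, (geometry.lane_length - foot[:, 0]) / u[:, 0], np.inf))
        t_y = np.where(u[:, 1] < 0, foot[:, 1] / -u[:, 1],
                       np.where(u[:, 1] > 0, (geometry.lane_width - foot[:, 1]) / u[:, 1], np.inf))
    reach = np.clip(np.minimum(t_x, t_y), 0.0, noise.body_length)
    head = foot + reach[:, None] * u
    body = foot + 0.5 * reach[:, None] * u
    if noise.jitter_sd > 0:
        foot = foot + rng.normal(0.0, noise.jitter_sd, size=foot.shape)
        head = head + rng.normal(0.0, noise.jitter_sd, size=head.shape)
        body = body + rng.normal(0.0, noise.jitter_sd, size=body.shape)

    def _clip(pts: np.ndarray) -> np.ndarray:
        pts[:, 0] = np.clip(pts[:, 0], 0.0, geometry.lane_length)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, geometry.lane_width)
        return pts

    lo, hi = noise.high_confidence
    conf = rng.uniform(lo, hi, size=(n_frames, 3))
    times = np.arange(n_frames, dtype=float) * geometry.frame_interval
    return PoseTrack(
        animal_id=traj.animal_id,
        times=times,
        foot=_clip(foot),
        body=_clip(body),
        head=_clip(head),
        confidence=conf,
        group_label=traj.group,
    )


def generate_cohort(
    params: ModelParams,
    n_starved: int,
    n_fed: int,
    geometry: ChamberGeometry,
    seed: int,
    out_dir,
    *,
    noise: TrackingNoise | None = None,
) -> tuple[Path, Path, GroundTruth]:
    """Generate a pose-tracked cohort with known ground truth.

    Runs the phototaxis model for ``n_starved`` starved and ``n_fed`` fed
    animals (full horizon, no threshold termination) and renders each
    trajectory at the geometry's frame interval. Writes ``poses.csv`` and
    ``ground_truth.json`` into ``out_dir`` and returns their paths together
    with the in-memory :class:`GroundTruth`.
    """
    if n_starved < 0 or n_fed < 0 or n_starved + n_fed == 0:
        raise ValueError("need at least one animal")
    noise = noise or TrackingNoise()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    seed_starved, seed_fed, seed_render = (int(s) for s in ss.generate_state(3, dtype=np.uint32))
    render_rng = np.random.default_rng(seed_render)

    frames_per_step = int(round(params.dt / geometry.frame_interval))
    if frames_per_step < 1:
        raise ValueError("model dt must be at least one frame interval")
    n_steps = int(round(params.horizon * 3600.0 / params.dt))
    n_frames = n_steps * frames_per_step  # final model state falls just outside

    trajs: list[SimTrajectory] = []
    if n_starved:
        trajs += simulate_cohort(params, "starved", n_starved, geometry, seed_starved,
                                 terminate_on_cross=False, wall_mode="mirror")
    if n_fed:
        trajs += simulate_cohort(params, "fed", n_fed, geometry, seed_fed,
                                 terminate_on_cross=False, wall_mode="mirror")

    tracks: list[PoseTrack] = []
    animals: list[AnimalTruth] = []
    for traj in trajs:
        track = _render_track(traj, params, geometry, noise, render_rng, n_frames, frames_per_step)
        if noise.corrupt_fraction > 0:
            track = corrupt_frames(track, noise.corrupt_fraction, render_rng,
                                   geometry=geometry, low_confidence=noise.low_confidence)
        tracks.append(track)
        animals.append(_truth_from_trajectory(traj, params, n_rendered_states=n_steps))

    pose_path = write_pose_csv(tracks, out_dir / "poses.csv", frame_interval=geometry.frame_interval)
    truth = GroundTruth(
        animals=animals,
        params=params_to_dict(params),
        geometry={
            "lane_length": geometry.lane_length,
            "lane_width": geometry.lane_width,
            "phototaxis_threshold": geometry.phototaxis_threshold,
            "start_zone": list(geometry.start_zone),
            "frame_interval": geometry.frame_interval,
        },
        noise={
            "jitter_sd": noise.jitter_sd,
            "body_length": noise.body_length,
            "corrupt_fraction": noise.corrupt_fraction,
        },
        seed=int(seed),
    )
    truth_path = truth.to_json(out_dir / "ground_truth.json")
    return pose_path, truth_path, truth


def generate_null_angles(k: int, n: int, seed: int) -> list[np.ndarray]:
    """k independent samples of n uniform-circular angles in [0, 360) degrees."""
    if k < 1 or n < 5:
        raise ValueError("need k >= 1 groups of n >= 5 angles")
    rng = np.random.default_rng(seed)
    return [rng.uniform(0.0, 360.0, size=n) for _ in range(k)]


def corrupt_frames(
    track: PoseTrack,
    fraction: float,
    rng,
    *,
    geometry: ChamberGeometry | None = None,
    low_confidence: tuple[float, float] = (0.05, 0.4),
) -> PoseTrack:
    """Teleport one body point in a fraction of frames and mark it low-confidence.

    Emulates tracker mislabelling; the downstream confidence filter is
    expected to remove these frames. ``fraction = 0`` is the identity.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    n = len(track)
    n_corrupt = int(round(fraction * n))
    if n_corrupt == 0:
        return track
    lane_length = geometry.lane_length if geometry else float(np.max(track.foot[:, 0]) or 1.0)
    lane_width = geometry.lane_width if geometry else float(np.max(track.foot[:, 1]) or 1.0)
    frames = rng.choice(n, size=n_corrupt, replace=False)
    parts = rng.integers(0, 3, size=n_corrupt)
    foot = track.foot.copy()
    body = track.body.copy()
    head = track.head.copy()
    conf = track.confidence.copy()
    arrays = (foot, body, head)
    for f, p in zip(frames, parts):
        arrays[p][f, 0] = rng.uniform(0.0, lane_length)
        arrays[p][f, 1] = rng.uniform(0.0, lane_width)
        conf[f, p] = rng.uniform(*low_confidence)
    return PoseTrack(
        animal_id=track.animal_id,
        times=track.times.copy(),
        foot=foot,
        body=body,
        head=head,
        confidence=conf,
        group_label=track.group_label,
        n_dropped=track.n_dropped,
    )
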