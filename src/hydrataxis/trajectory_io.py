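"""Reading and writing pose-tracking files and experiment configuration.

The package consumes the output of markerless pose estimation: per-frame
(x, y, likelihood) triplets for three tracked body points of each animal --
the basal disk ("foot"), the centre of the body column ("body") and the
hypostome ("head"). The on-disk dialect follows the familiar pose-estimation
CSV layout of three header rows (scorer / bodyparts / coords) followed by one
row per frame; the animal id and experimental group travel in two extra
columns so that a single file can hold a whole device worth of animals as
consecutive row blocks. See the README for a worked example of the layout.

Coordinates are stored internally in millimetres, with the light source
modelled as the plane x = 0: the distance of a point to the light is simply
its x coordinate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ChamberGeometry",
    "PoseTrack",
    "RunConfig",
    "read_pose_csv",
    "write_pose_csv",
    "downsample",
    "load_config",
    "BODYPART_ALIASES",
]

GROUP_LABELS = ("starved", "fed", "unknown")

#: Accepted column names for each canonical body part (case-insensitive).
BODYPART_ALIASES: Mapping[str, tuple[str, ...]] = {
    "foot": ("foot", "basal_disk", "basaldisk", "basal disk"),
    "body": ("body", "body_column", "bodycolumn", "body column"),
    "head": ("head", "hypostome"),
}

_SCORER = "hydrataxis"


@dataclass(frozen=True)
class ChamberGeometry:
    """Geometry of one microfluidic lane and the experiment's coordinate frame.

    The light source sits at the plane ``x = 0``; ``lane_length`` is the lane
    extent along x (mm) and ``lane_width`` the extent along y (mm). An animal
    has performed phototaxis once its foot comes closer to the light plane
    than ``phototaxis_threshold`` (mm). Animals start inside ``start_zone``
    (distance interval from the light plane, mm). ``frame_interval`` is the
    video sampling period in seconds.
    """

    lane_length: float = 50.0
    lane_width: float = 5.0
    phototaxis_threshold: float = 10.0
    start_zone: tuple[float, float] = (23.0, 35.0)
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.start_zone
        if not (0.0 < self.phototaxis_threshold < lo <= hi <= self.lane_length):
            raise ValueError(
                "geometry requires 0 < phototaxis_threshold < start_zone min "
                f"<= start_zone max <= lane_length; got phototaxis_threshold="
                f"{self.phototaxis_threshold}, start_zone={self.start_zone}, "
                f"lane_length={self.lane_length}"
            )
        if self.lane_width <= 0.0:
            raise ValueError(f"lane_width must be > 0, got {self.lane_width}")
        if self.frame_interval <= 0.0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")


@dataclass
class PoseTrack:
    """Per-animal time series of tracked foot/body/head coordinates.

    ``times`` are in seconds and strictly increasing; ``foot``, ``body`` and
    ``head`` are (n, 2) arrays in mm; ``confidence`` is an (n, 3) array of
    tracker likelihoods in [0, 1] with columns in (foot, body, head) order.
    ``n_dropped`` records how many rows were removed by the confidence filter
    when the track was read from disk.
    """

    animal_id: str
    times: np.ndarray
    foot: np.ndarray
    body: np.ndarray
    head: np.ndarray
    confidence: np.ndarray
    group_label: str = "unknown"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("foot", "body", "head"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError(f"{name} must be an (n, 2) array")
            if arr.shape[0] != self.times.shape[0]:
                raise ValueError(f"{name} length {arr.shape[0]} != times length {self.times.shape[0]}")
            setattr(self, name, arr)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.confidence.shape != (self.times.shape[0], 3):
            raise ValueError("confidence must be an (n, 3) array")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.confidence.size and (self.confidence.min() < 0.0 or self.confidence.max() > 1.0):
            raise ValueError("confidences must lie in [0, 1]")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}")

    def __len__(self) -> int:
        return int(self.times.shape[0])


def _match_bodyparts(
    names: Sequence[str], aliases: Mapping[str, tuple[str, ...]]
) -> dict[str, str]:
    """Map canonical part -> column label actually present in the header."""
    lowered = {n.strip().lower(): n for n in names}
    out: dict[str, str] = {}
    for part, cands in aliases.items():
        for cand in cands:
            if cand in lowered:
                out[part] = lowered[cand]
                break
        else:
            raise FormatError(
                f"pose file lacks columns for body part {part!r} "
                f"(accepted names: {', '.join(cands)})"
            )
    return out


def read_pose_csv(
    path,
    geometry: ChamberGeometry,
    *,
    px_to_mm: float = 1.0,
    confidence_cutoff: float = 0.6,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
) -> list[PoseTrack]:
    """Read a pose CSV into one :class:`PoseTrack` per tracked animal.

    Coordinates are multiplied by ``px_to_mm`` and clipped into the lane
    bounding box. Rows in which any body-point likelihood falls below
    ``confidence_cutoff`` are dropped; the count is logged and recorded on
    each track's ``n_dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    aliases = dict(aliases or BODYPART_ALIASES)

    with open(path, "r", newline="") as fh:
        header_rows = [fh.readline().rstrip("\n").split(",") for _ in range(3)]
        labels = [row[0].strip().lower() for row in header_rows]
        if labels != ["scorer", "bodyparts", "coords"]:
            raise FormatError(
                "expected three header rows labelled scorer/bodyparts/coords, "
                f"got {labels}"
            )
        bodyparts_row = [c.strip() for c in header_rows[1][1:]]
        coords_row = [c.strip().lower() for c in header_rows[2][1:]]
        data = pd.read_csv(fh, header=None)
    if data.shape[1] != len(bodyparts_row) + 1:
        raise FormatError("header and data column counts disagree")

    colmap = _match_bodyparts(bodyparts_row, aliases)
    part_cols: dict[str, dict[str, int]] = {}
    for part, label in colmap.items():
        cols: dict[str, int] = {}
        for j, (bp, coord) in enumerate(zip(bodyparts_row, coords_row)):
            if bp == label and coord in ("x", "y", "likelihood"):
                cols[coord] = j + 1  # +1 for the frame column
        if set(cols) != {"x", "y", "likelihood"}:
            raise FormatError(
                f"body part {label!r} must have x, y and likelihood columns"
            )
        part_cols[part] = cols

    def _aux_col(name: str) -> int | None:
        for j, bp in enumerate(bodyparts_row):
            if bp.lower() == name:
                return j + 1
        return None

    ind_col = _aux_col("individual")
    grp_col = _aux_col("group")

    frames = pd.to_numeric(data.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    if ind_col is not None:
        ids = data.iloc[:, ind_col].astype(str).to_numpy()
    else:
        ids = np.full(len(data), path.stem, dtype=object)
    if grp_col is not None:
        groups = data.iloc[:, grp_col].astype(str).to_numpy()
    else:
        groups = np.full(len(data), "", dtype=object)

    tracks: list[PoseTrack] = []
    total_dropped = 0
    seen: list[str] = []
    for aid in ids:
        if aid not in seen:
            seen.append(aid)
    for aid in seen:
        sel = np.flatnonzero(ids == aid)
        f = frames[sel]
        if f.size > 1 and not np.all(np.diff(f) > 0):
            bad = sel[int(np.flatnonzero(np.diff(f) <= 0)[0]) + 1]
            raise FormatError(
                f"non-monotonic frame index for animal {aid!r} at data row {bad + 4}"
            )
        conf = np.column_stack(
            [
                pd.to_numeric(data.iloc[sel, part_cols[p]["likelihood"]]).to_numpy(dtype=float)
                for p in ("foot", "body", "head")
            ]
        )
        keep = np.all(conf >= confidence_cutoff, axis=1)
        n_dropped = int((~keep).sum())
        total_dropped += n_dropped

        def _xy(part: str) -> np.ndarray:
            x = pd.to_numeric(data.iloc[sel, part_cols[part]["x"]]).to_numpy(dtype=float)
            y = pd.to_numeric(data.iloc[sel, part_cols[part]["y"]]).to_numpy(dtype=float)
            pts = np.column_stack([x, y])[keep] * px_to_mm
            pts[:, 0] = np.clip(pts[:, 0], 0.0, geometry.lane_length)
            pts[:, 1] = np.clip(pts[:, 1], 0.0, geometry.lane_width)
            return pts

        raw_group = groups[sel[0]].strip().lower()
        if raw_group not in GROUP_LABELS:
            raw_group = next((g for g in ("starved", "fed") if g in str(aid).lower()), "unknown")
        tracks.append(
            PoseTrack(
                animal_id=str(aid),
                times=f[keep] * geometry.frame_interval,
                foot=_xy("foot"),
                body=_xy("body"),
                head=_xy("head"),
                confidence=np.clip(conf[keep], 0.0, 1.0),
                group_label=raw_group,
                n_dropped=n_dropped,
            )
        )
    logger.info(
        "read %d track(s) from %s; %d low-confidence row(s) dropped (cutoff %.2f)",
        len(tracks), path, total_dropped, confidence_cutoff,
    )
    return tracks


def write_pose_csv(tracks: Iterable[PoseTrack], path, *, frame_interval: float = 1.0):
    """Write tracks to a pose CSV; inverse of :func:`read_pose_csv`.

    Animals are written as consecutive row blocks in input order. The frame
    column holds ``time / frame_interval``, so re-reading with a geometry
    whose ``frame_interval`` matches reproduces the timestamps exactly.
    """
    tracks = list(tracks)
    if not tracks:
        raise ValueError("cannot write an empty collection of tracks")
    path = Path(path)
    parts = ("foot", "body", "head")
    with open(path, "w", newline="") as fh:
        ncols = 2 + 3 * len(parts)
        fh.write("scorer," + ",".join([_SCORER] * ncols) + "\n")
        fh.write(
            "bodyparts,individual,group,"
            + ",".join(",".join([p] * 3) for p in parts)
            + "\n"
        )
        fh.write("coords,id,label," + ",".join(["x,y,likelihood"] * len(parts)) + "\n")
        for tr in tracks:
            frames = tr.times / frame_interval
            cols = [frames]
            for i, p in enumerate(parts):
                arr = getattr(tr, p)
                cols.extend([arr[:, 0], arr[:, 1], tr.confidence[:, i]])
            block = np.column_stack(cols)
            df = pd.DataFrame(block)
            df.insert(1, "individual", tr.animal_id)
            df.insert(2, "group", tr.group_label)
            df.to_csv(fh, header=False, index=False, float_format="%.6f")
    return path


def downsample(track: PoseTrack, every_n: int) -> PoseTrack:
    """Keep every ``every_n``-th sample (indices 0, n, 2n, ...)."""
    if int(every_n) != every_n or every_n < 1:
        raise ValueError(f"every_n must be a positive integer, got {every_n!r}")
    every_n = int(every_n)
    sl = slice(None, None, every_n)
    return dataclasses.replace(
        track,
        times=track.times[sl].copy(),
        foot=track.foot[sl].copy(),
        body=track.body[sl].copy(),
        head=track.head[sl].copy(),
        confidence=track.confidence[sl].copy(),
        n_dropped=0,
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Defaults for the [extraction] section. px_to_mm is deliberately absent:
#: the pixel-to-mm scale must be stated explicitly in every config file.
EXTRACTION_DEFAULTS: dict = {
    "confidence_cutoff": 0.6,
    "downsample_every": 20,
    "epsilon_mm": 1.0,
    "min_dwell": 2,
    "activity_cutoff": 3,
    "horizon_h": 8.0,
    "pre_jump_only": False,
}

MODEL_DEFAULTS: dict = {
    "w": 0.8,
    "omega_t": 0.0,
    "phi_noise": {"mu": 0.0, "sigma": 30.0, "nu": 5.0, "lower": -180.0, "upper": 180.0},
    "delta_noise": {"mu": 0.0, "sigma": 10.0, "nu": 5.0, "lower": -180.0, "upper": 180.0},
    "lambda_starved": 2.0,
    "lambda_fed_active": 0.8,
    "lambda_fed_inactive": 0.1,
    "fed_active_fraction": 0.5,
    "jump_distances_mm": None,  # None -> built-in default sample
    "kde_bandwidth_mm": None,   # None -> Silverman's rule
    "dt_s": 20.0,
    "horizon_h": 8.0,
}

SIMULATION_DEFAULTS: dict = {
    "n_starved": 24,
    "n_fed": 31,
    "jitter_sd_mm": 0.05,
    "body_length_mm": 3.0,
    "corrupt_fraction": 0.02,
}

GEOMETRY_DEFAULTS: dict = {
    "lane_length": 50.0,
    "lane_width": 5.0,
    "phototaxis_threshold": 10.0,
    "start_zone": [23.0, 35.0],
    "frame_interval": 1.0,
}


@dataclass
class RunConfig:
    """Validated configuration: chamber geometry plus per-stage settings."""

    geometry: ChamberGeometry
    extraction: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        g = self.geometry
        return {
            "geometry": {
                "lane_length": g.lane_length,
                "lane_width": g.lane_width,
                "phototaxis_threshold": g.phototaxis_threshold,
                "start_zone": list(g.start_zone),
                "frame_interval": g.frame_interval,
            },
            "extraction": dict(self.extraction),
            "model": dict(self.model),
            "simulation": dict(self.simulation),
        }


def _merged(section: str, raw: Mapping, defaults: Mapping) -> dict:
    out = dict(defaults)
    unknown = set(raw) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    for key, dflt in defaults.items():
        if key in raw:
            out[key] = raw[key]
        else:
            logger.info("config: [%s] %s not set, using default %r", section, key, dflt)
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML configuration file.

    Sections: ``geometry``, ``extraction``, ``model``, ``simulation``.
    Every default applied for a missing optional key is echoed to the log;
    ``extraction.px_to_mm`` is mandatory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")
    known = {"geometry", "extraction", "model", "simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")

    geo_raw = _merged("geometry", raw.get("geometry") or {}, GEOMETRY_DEFAULTS)
    try:
        geometry = ChamberGeometry(
            lane_length=float(geo_raw["lane_length"]),
            lane_width=float(geo_raw["lane_width"]),
            phototaxis_threshold=float(geo_raw["phototaxis_threshold"]),
            start_zone=tuple(float(v) for v in geo_raw["start_zone"]),
            frame_interval=float(geo_raw["frame_interval"]),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid [geometry]: {exc}") from exc

    ex_raw = dict(raw.get("extraction") or {})
    if "px_to_mm" not in ex_raw:
        raise ConfigError("missing required key px_to_mm in [extraction]")
    px_to_mm = float(ex_raw.pop("px_to_mm"))
    if px_to_mm <= 0:
        raise ConfigError("extraction.px_to_mm must be > 0")
    extraction = _merged("extraction", ex_raw, EXTRACTION_DEFAULTS)
    extraction["px_to_mm"] = px_to_mm
    model = _merged("model", raw.get("model") or {}, MODEL_DEFAULTS)
    simulation = _merged("simulation", raw.get("simulation") or {}, SIMULATION_DEFAULTS)
    return RunConfig(geometry=geometry, extraction=extraction, model=model, simulation=simulation)
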