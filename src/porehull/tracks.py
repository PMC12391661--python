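"""Trajectory containers and delimited-text I/O.

A *localization* is one observation of one bead: elapsed time in seconds and
x/y/z position in micrometres.  A *track* is the time-ordered sequence of
localizations sharing one track id, and a :class:`TrackSet` bundles tracks
with the assay metadata (frame interval, bead diameter, pixel size) that all
downstream analyses need.  Units are fixed at micrometres and seconds
internally; readers convert on the way in.

Two CSV dialects are accepted: a minimal one (``track_id,t,x,y[,z]``) and a
tracking-software export style with named position/time columns
(``Track ID``, ``Position X`` ...).  Column names are normalized on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import TrackFormatError, TrackValidationError

__all__ = [
    "Localization",
    "Track",
    "TrackSet",
    "read_tracks",
    "write_tracks",
    "load_config",
]


@dataclass(frozen=True)
class Localization:
    """One observation: time since the first frame (s) and position (µm)."""

    t: float
    x: float
    y: float
    z: float = 0.0


@dataclass
class Track:
    """Time-ordered localizations of a single bead.

    ``t`` holds elapsed seconds, ``xyz`` the (n, 3) positions in µm.  For a
    planar assay z is identically zero.
    """

    track_id: object
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.t.ndim != 1 or self.xyz.shape != (self.t.size, 3):
            raise TrackValidationError(
                f"track {self.track_id!r}: t must be (n,) and xyz (n, 3)"
            )
        if self.t.size < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: needs at least 2 localizations"
            )
        if not np.all(np.isfinite(self.t)) or not np.all(np.isfinite(self.xyz)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite time or coordinate"
            )
        if np.any(self.t < 0):
            raise TrackValidationError(f"track {self.track_id!r}: negative time")
        if np.any(np.diff(self.t) <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: time is not strictly increasing"
            )

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def localizations(self) -> tuple[Localization, ...]:
        return tuple(
            Localization(float(t), float(x), float(y), float(z))
            for t, (x, y, z) in zip(self.t, self.xyz)
        )


@dataclass
class TrackSet:
    """A collection of tracks plus the assay metadata they were acquired with.

    Parameters
    ----------
    tracks
        The tracks, ids unique.
    frame_interval
        Acquisition interval in seconds.
    bead_diameter
        Tracer bead diameter in µm (used for the hull-diameter correction).
    pixel_size
        Camera pixel size in µm; metadata only.
    dims
        2 for planar assays (z identically 0), 3 otherwise.
    """

    tracks: list[Track] = field(default_factory=list)
    frame_interval: float = 1.0
    bead_diameter: float = 1.0
    pixel_size: float | None = None
    dims: int = 3

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise TrackValidationError("frame_interval must be > 0")
        if self.bead_diameter <= 0:
            raise TrackValidationError("bead_diameter must be > 0")
        if self.dims not in (2, 3):
            raise TrackValidationError("dims must be 2 or 3")
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise TrackValidationError("track ids are not unique")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


# -- column-name normalization ------------------------------------------------

_ID_NAMES = {"trackid", "track", "id", "particle", "trajectory", "spottrackid"}
_TIME_NAMES = {"t", "time", "times", "timesec", "posixtime"}
_FRAME_NAMES = {"frame", "frameindex", "framenumber", "spotframe"}
_X_NAMES = {"x", "positionx", "posx", "xum", "xpos"}
_Y_NAMES = {"y", "positiony", "posy", "yum", "ypos"}
_Z_NAMES = {"z", "positionz", "posz", "zum", "zpos"}


def _canon(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def _find_column(df: pd.DataFrame, names: set[str]) -> str | None:
    for col in df.columns:
        if _canon(col) in names:
            return col
    return None


def read_tracks(
    path,
    frame_interval: float = 1.0,
    bead_diameter: float = 1.0,
    pixel_size: float | None = None,
    validate_gaps: bool = False,
) -> TrackSet:
    """Read a delimited trajectory table into a :class:`TrackSet`.

    The table must carry a track-id column, x and y position columns, and
    either a time column (seconds) or a frame-index column; frame indices are
    converted to seconds via ``frame_interval``.  A missing z column yields a
    planar (dims = 2) set with z = 0.

    With ``validate_gaps`` the frame spacing within each track is checked
    against the linking convention used upstream: consecutive frames, with at
    most one single-frame gap per track.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    id_col = _find_column(df, _ID_NAMES)
    x_col = _find_column(df, _X_NAMES)
    y_col = _find_column(df, _Y_NAMES)
    z_col = _find_column(df, _Z_NAMES)
    t_col = _find_column(df, _TIME_NAMES)
    f_col = _find_column(df, _FRAME_NAMES)

    for col, label in ((id_col, "track id"), (x_col, "x"), (y_col, "y")):
        if col is None:
            raise TrackFormatError(f"missing required column: {label}")
    if t_col is None and f_col is None:
        raise TrackFormatError("missing required column: time (or frame index)")

    if t_col is not None:
        t_all = df[t_col].to_numpy(dtype=float)
    else:
        t_all = df[f_col].to_numpy(dtype=float) * frame_interval

    dims = 3 if z_col is not None else 2
    z_all = df[z_col].to_numpy(dtype=float) if z_col is not None else np.zeros(len(df))
    xyz_all = np.column_stack(
        [df[x_col].to_numpy(dtype=float), df[y_col].to_numpy(dtype=float), z_all]
    )

    tracks: list[Track] = []
    ids = df[id_col]
    for tid in sorted(pd.unique(ids), key=lambda v: (str(type(v)), v)):
        mask = (ids == tid).to_numpy()
        t = t_all[mask]
        order = np.argsort(t, kind="stable")
        track = Track(tid, t[order], xyz_all[mask][order])
        if validate_gaps:
            steps = np.rint(np.diff(track.t) / frame_interval).astype(int)
            if np.any((steps < 1) | (steps > 2)) or int(np.sum(steps == 2)) > 1:
                raise TrackValidationError(
                    f"track {tid!r}: more than one single-frame gap"
                )
        tracks.append(track)

    return TrackSet(
        tracks=tracks,
        frame_interval=frame_interval,
        bead_diameter=bead_diameter,
        pixel_size=pixel_size,
        dims=dims,
    )


def write_tracks(trackset: TrackSet, path) -> None:
    """Write a :class:`TrackSet` to CSV in the minimal dialect.

    Round-trips exactly: ``read_tracks(write_tracks(T))`` reproduces ids,
    times and coordinates to full double precision.  Planar sets are written
    without a z column.
    """
    cols = ["track_id", "t", "x", "y"] + (["z"] if trackset.dims == 3 else [])
    rows = []
    for track in trackset:
        for t, (x, y, z) in zip(track.t, track.xyz):
            row = [track.track_id, repr(float(t)), repr(float(x)), repr(float(y))]
            if trackset.dims == 3:
                row.append(repr(float(z)))
            rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False)


def load_config(path) -> dict:
    """Load an assay-metadata YAML (frame_interval_s, bead_diameter_um, ...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise TrackFormatError("config file must contain a YAML mapping")
    return cfg
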