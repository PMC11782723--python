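"""Reading and writing tag streams, rosters and sessions.

The raw unit of data is a *tag sample*: one timestamped (x, y) reading,
in meters, for one of the two tags (left / right shoulder) worn by one
person.  Streams arrive as CSV with columns ``person_id, tag_side, t, x, y``
(or a user-supplied column mapping).  Tracks are assembled onto a uniform
10 Hz grid per session; short dropouts are bridged by linear interpolation
and longer gaps are marked invalid rather than interpolated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TAG_COLUMNS = ["person_id", "tag_side", "t", "x", "y"]

_EPS = 1e-9


class FormatError(ValueError):
    """A file does not conform to the expected schema."""


@dataclass
class TagSample:
    """One timestamped reading for one tag of one person."""

    person_id: str
    tag_side: str  # 'L' or 'R'
    t: float  # seconds since session start
    x: float  # meters
    y: float  # meters


@dataclass(frozen=True)
class Person:
    """A roster entry: a tracked child or teacher.

    Children carry an eligibility group (``ASD``, ``DD`` or ``TD``);
    teachers do not.
    """

    person_id: str
    role: str  # 'child' | 'teacher'
    group: str | None = None  # children only
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.role == "child" and self.group not in ("ASD", "DD", "TD"):
            raise ValueError(
                f"child {self.person_id!r} must have group ASD/DD/TD, got {self.group!r}"
            )
        if self.role == "teacher" and self.group is not None:
            raise ValueError(f"teacher {self.person_id!r} must not have a group")
        if self.role not in ("child", "teacher"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class Session:
    """One observation occasion in one classroom."""

    session_id: str
    classroom_id: str
    room_width: float
    room_height: float
    roster: tuple[Person, ...] = ()
    sample_interval: float = 0.1  # seconds; canonical grid is 10 Hz
    start: float = 0.0
    end: float | None = None
    max_gap: float = 1.0  # seconds; longer dropouts are not interpolated

    def __post_init__(self) -> None:
        if self.room_width <= 0 or self.room_height <= 0:
            raise ValueError("room dimensions must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")

    def grid(self) -> np.ndarray:
        """The uniform time grid covering [start, end]."""
        if self.end is None:
            raise ValueError("session end time is not set")
        n = int(round((self.end - self.start) / self.sample_interval)) + 1
        return self.start + np.arange(n) * self.sample_interval


@dataclass
class PersonTrack:
    """Per-person tag positions resampled onto the session grid.

    ``valid[i]`` is True only when both tags have a usable position at
    grid step ``i`` (inside the sampled span and not inside a gap longer
    than ``max_gap``).
    """

    person_id: str
    times: np.ndarray  # (n,)
    left: np.ndarray  # (n, 2), NaN where invalid
    right: np.ndarray  # (n, 2)
    valid: np.ndarray  # (n,) bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "xL": self.left[:, 0],
                "yL": self.left[:, 1],
                "xR": self.right[:, 0],
                "yR": self.right[:, 1],
                "valid": self.valid,
            }
        )


@dataclass
class ParseResult:
    """Outcome of parsing a tag-stream file."""

    frame: pd.DataFrame  # columns TAG_COLUMNS, sorted
    n_rejected: int = 0

    @property
    def samples(self) -> list[TagSample]:
        return [
            TagSample(r.person_id, r.tag_side, r.t, r.x, r.y)
            for r in self.frame.itertuples(index=False)
        ]


def read_tag_stream(path: str | Path, schema: Mapping[str, str] | None = None) -> ParseResult:
    """Read a tag-stream CSV.

    Parameters
    ----------
    path
        CSV file with columns ``person_id, tag_side, t, x, y`` (any order).
    schema
        Optional mapping from canonical column name to the name used in
        the file, e.g. ``{"t": "time_s"}``.

    Returns
    -------
    ParseResult
        Samples sorted by (person_id, tag_side, t).  Rows with a
        non-numeric or missing coordinate/time, or an unrecognised tag
        side, are rejected, counted and logged — not raised.

    Raises
    ------
    FormatError
        If a required column is absent entirely.
    """
    df = pd.read_csv(path, dtype=str)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    missing = [c for c in TAG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    df = df[TAG_COLUMNS].copy()
    n_in = len(df)
    for col in ("t", "x", "y"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["tag_side"] = df["tag_side"].str.strip().str.upper()
    ok = (
        df["t"].notna()
        & df["x"].notna()
        & df["y"].notna()
        & np.isfinite(df["t"])
        & np.isfinite(df["x"])
        & np.isfinite(df["y"])
        & (df["t"] >= 0)
        & df["tag_side"].isin(["L", "R"])
        & df["person_id"].notna()
    )
    n_rejected = int(n_in - ok.sum())
    if n_rejected:
        logger.warning("%s: rejected %d malformed row(s) of %d", path, n_rejected, n_in)
    df = df[ok].sort_values(["person_id", "tag_side", "t"], kind="stable").reset_index(drop=True)
    return ParseResult(frame=df, n_rejected=n_rejected)


def write_tag_stream(data: ParseResult | pd.DataFrame | Iterable[TagSample], path: str | Path) -> None:
    """Write tag samples to CSV in the canonical column order."""
    if isinstance(data, ParseResult):
        df = data.frame
    elif isinstance(data, pd.DataFrame):
        df = data[TAG_COLUMNS]
    else:
        df = pd.DataFrame(
            [(s.person_id, s.tag_side, s.t, s.x, s.y) for s in data], columns=TAG_COLUMNS
        )
    # repr-precision floats so a read→write→read round trip is bit-exact
    df.to_csv(path, index=False, float_format="%.17g")


def read_roster(path: str | Path) -> tuple[Person, ...]:
    """Read a roster from JSON (list of objects) or CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"roster file not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    people = []
    for rec in records:
        group = rec.get("group")
        if group in ("", None) or (isinstance(group, float) and np.isnan(group)):
            group = None
        people.append(Person(str(rec["person_id"]), str(rec["role"]), group, rec.get("sex")))
    return tuple(people)


def write_roster(roster: Sequence[Person], path: str | Path) -> None:
    records = [
        {"person_id": p.person_id, "role": p.role, "group": p.group, "sex": p.sex}
        for p in roster
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_session_yaml(path: str | Path, roster: Sequence[Person] = ()) -> Session:
    """Read session metadata (room dimensions, grid, gap policy) from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return Session(
        session_id=str(cfg["session_id"]),
        classroom_id=str(cfg.get("classroom_id", cfg["session_id"])),
        room_width=float(cfg["room_width"]),
        room_height=float(cfg["room_height"]),
        roster=tuple(roster),
        sample_interval=float(cfg.get("sample_interval", 0.1)),
        start=float(cfg.get("start", 0.0)),
        end=(float(cfg["end"]) if cfg.get("end") is not None else None),
        max_gap=float(cfg.get("max_gap", 1.0)),
    )


def _resample_tag(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, grid: np.ndarray, max_gap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of one tag onto the grid, with gap masking.

    A grid step is valid when it lies within the sampled span and either
    coincides with a raw sample or sits between two samples no more than
    ``max_gap`` seconds apart.
    """
    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    # collapse duplicate timestamps (keep the mean reading)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        df = pd.DataFrame({"t": t, "x": x, "y": y}).groupby("t", as_index=False).mean()
        t, x, y = df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy()

    xi = np.interp(grid, t, x)
    yi = np.interp(grid, t, y)
    pos = np.column_stack([xi, yi])

    inside = (grid >= t[0] - _EPS) & (grid <= t[-1] + _EPS)
    idx = np.searchsorted(t, grid, side="right")
    prev = np.clip(idx - 1, 0, len(t) - 1)
    nxt = np.clip(idx, 0, len(t) - 1)
    gap = t[nxt] - t[prev]
    on_sample = np.abs(grid - t[prev]) <= _EPS
    if len(t) > 1:
        on_sample |= np.abs(grid - t[nxt]) <= _EPS
    valid = inside & (on_sample | (gap <= max_gap + _EPS))
    pos[~valid] = np.nan
    return pos, valid


def build_person_tracks(
    samples: ParseResult | pd.DataFrame,
    session: Session,
    max_gap: float | None = None,
    on_unknown: str = "warn",
) -> dict[str, PersonTrack]:
    """Resample raw tag samples onto the session's uniform grid.

    Parameters
    ----------
    samples
        Parsed tag stream (or a raw DataFrame in the canonical schema).
    session
        Supplies the grid ([start, end] at ``sample_interval``) and the
        roster.  If ``session.end`` is None it is taken from the data.
    max_gap
        Longest dropout, in seconds, bridged by linear interpolation
        (default: the session's policy).  Grid steps strictly inside
        longer gaps are marked invalid.
    on_unknown
        What to do with persons present in the stream but absent from
        the roster: ``"warn"`` (drop, default), ``"error"``, ``"keep"``.

    Returns
    -------
    dict
        person_id → PersonTrack; a person's timestep is valid only when
        both tags are valid there.
    """
    df = samples.frame if isinstance(samples, ParseResult) else samples
    if max_gap is None:
        max_gap = session.max_gap
    if session.end is None:
        session.end = float(df["t"].max()) if len(df) else session.start
    grid = session.grid()

    roster_ids = {p.person_id for p in session.roster}
    tracks: dict[str, PersonTrack] = {}
    for pid, sub in df.groupby("person_id", sort=True):
        if roster_ids and pid not in roster_ids:
            if on_unknown == "error":
                raise ValueError(f"person {pid!r} not in session roster")
            if on_unknown == "warn":
                logger.warning("person %r not in roster; dropped", pid)
                continue
        sides = {}
        ok = np.ones(len(grid), dtype=bool)
        for side in ("L", "R"):
            tag = sub[sub["tag_side"] == side]
            if len(tag) == 0:
                sides[side] = np.full((len(grid), 2), np.nan)
                ok[:] = False
                continue
            pos, v = _resample_tag(
                tag["t"].to_numpy(), tag["x"].to_numpy(), tag["y"].to_numpy(), grid, max_gap
            )
            sides[side] = pos
            ok &= v
        tracks[pid] = PersonTrack(pid, grid, sides["L"], sides["R"], ok)
    return tracks


def write_person_track(track: PersonTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, index=False, float_format="%.17g")
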