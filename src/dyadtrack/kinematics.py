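"""Per-person kinematics from the two shoulder tags.

A person's location at each timestep is the midpoint of the left and
right tag positions.  Linear velocity is the Euclidean displacement of
that midpoint over one 0.1 s grid step.  Heading is derived from the
shoulder geometry: the facing direction is the left→right shoulder
vector rotated 90° counterclockwise, i.e.

    theta = atan2(xR - xL, yL - yR)

in standard mathematical convention (radians, counterclockwise from +x).
Degrees appear only at criterion boundaries (the 45° mutual-orientation
rule and the cos² weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PersonTrack

__all__ = [
    "PersonStates",
    "midpoint_position",
    "linear_velocity",
    "heading",
    "angular_deviation",
    "person_states",
]


@dataclass
class PersonStates:
    """Vectorized per-timestep state for one person on the session grid.

    ``linvel[i]`` is the displacement over step i-1→i (meters per 0.1 s);
    it is NaN at the first step of each valid run (no predecessor).
    ``heading`` is NaN where undefined (coincident tags or invalid step).
    """

    person_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray  # radians in (-pi, pi], NaN if undefined
    linvel: np.ndarray  # meters per grid step, NaN if undefined
    valid: np.ndarray  # bool: both tags present at this step
    heading_valid: np.ndarray  # bool: valid and tags not coincident

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.x,
                "y": self.y,
                "heading_rad": self.heading,
                "linvel": self.linvel,
                "valid": self.valid,
            }
        )


def midpoint_position(left, right) -> np.ndarray:
    """Componentwise average of the two tag positions."""
    return (np.asarray(left, dtype=float) + np.asarray(right, dtype=float)) / 2.0


def linear_velocity(prev, curr) -> float | np.ndarray:
    """Euclidean displacement of the midpoint over one grid step."""
    d = np.asarray(curr, dtype=float) - np.asarray(prev, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


def heading(left, right) -> float | np.ndarray:
    """Facing angle from the shoulder tags.

    The facing unit vector is the shoulder vector L→R rotated 90°
    counterclockwise, (yL − yR, xR − xL) normalized; the returned angle
    is its standard math angle, atan2(xR − xL, yL − yR).  Undefined
    (NaN) when the tags coincide.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    fy = right[..., 0] - left[..., 0]  # xR - xL
    fx = left[..., 1] - right[..., 1]  # yL - yR
    ang = np.arctan2(fy, fx)
    coincident = (fy == 0) & (fx == 0)
    return np.where(coincident, np.nan, ang) if np.ndim(ang) else (np.nan if coincident else float(ang))


def angular_deviation(a, b) -> float | np.ndarray:
    """Smallest absolute difference between two directions, in degrees [0, 180]."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = np.mod(d + np.pi, 2.0 * np.pi) - np.pi
    out = np.degrees(np.abs(d))
    return float(out) if np.ndim(out) == 0 else out


def person_states(track: PersonTrack) -> PersonStates:
    """Compute midpoint, heading and linear velocity along a track."""
    mid = midpoint_position(track.left, track.right)
    x, y = mid[:, 0], mid[:, 1]

    with np.errstate(invalid="ignore"):
        hd = np.arctan2(
            track.right[:, 0] - track.left[:, 0],
            track.left[:, 1] - track.right[:, 1],
        )
    coincident = np.all(track.left == track.right, axis=1)
    heading_valid = track.valid & ~coincident
    hd = np.where(heading_valid, hd, np.nan)

    lv = np.full(len(x), np.nan)
    if len(x) > 1:
        step = np.sqrt(np.diff(x) ** 2 + np.diff(y) ** 2)
        pairwise = track.valid[1:] & track.valid[:-1]
        lv[1:] = np.where(pairwise, step, np.nan)

    return PersonStates(
        person_id=track.person_id,
        t=track.times,
        x=x,
        y=y,
        heading=hd,
        linvel=lv,
        valid=track.valid,
        heading_valid=heading_valid,
    )
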