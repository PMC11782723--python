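"""Dyadic quantities: approach distance, weighted social approach
velocity, social-contact detection, and per-dyad session summaries.

For an ordered dyad (A the approacher, B the partner) at grid step t:

* ``approach`` is how much closer A moved to B over the step.  Under the
  default ``initial_partner_position`` convention the reference is B's
  position at t−1, ``‖A[t−1]−B[t−1]‖ − ‖A[t]−B[t−1]‖``; the alternative
  ``current_partner_position`` uses B at t for the second term.
* the weighted social approach increment is
  ``approach · cos²(θo) · cos²(θm) / distance[t−1]`` — a dimensionless
  proportion of the initial dyad distance closed per 0.1 s — where θo is
  the deviation of A's heading at t−1 from the bearing A→B at t−1, and
  θm the deviation of A's movement vector over the step from that same
  bearing.  Only steps with positive approach are analyzed; moving away
  is excluded, not zero-clipped.
* *social contact* at a timestep requires the pair to be 0.2–2 m apart
  and mutually oriented within 45° (each partner's heading within 45° of
  the bearing to the other).  Contact is symmetric and instantaneous;
  no minimum episode duration is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Person, Session
from .kinematics import PersonStates, angular_deviation

__all__ = [
    "ContactParams",
    "DyadSteps",
    "approach_distance",
    "weighted_social_approach_increment",
    "mean_social_approach_velocity",
    "detect_social_contact",
    "contact_proportion",
    "dyad_steps",
    "summarize_session",
]

CONVENTIONS = ("initial_partner_position", "current_partner_position")


@dataclass(frozen=True)
class ContactParams:
    """Social-contact criterion: distance band and mutual-orientation cone."""

    d_min: float = 0.2  # meters
    d_max: float = 2.0  # meters
    max_mutual_angle: float = 45.0  # degrees

    def __post_init__(self) -> None:
        if not (0 <= self.d_min < self.d_max):
            raise ValueError("require 0 <= d_min < d_max")
        if not (0 < self.max_mutual_angle <= 180):
            raise ValueError("require 0 < max_mutual_angle <= 180")


@dataclass
class DyadSteps:
    """Per-timestep dyadic quantities for one ordered dyad (A → B).

    Arrays are aligned with the session grid.  Step-indexed quantities
    (distance_prev, approach, theta_o, theta_m, weighted) describe the
    transition (t−1 → t) and are NaN at index 0 and wherever undefined.
    """

    t: np.ndarray
    shared: np.ndarray  # both states valid at this step
    distance: np.ndarray  # ‖A[t]−B[t]‖ where shared
    distance_prev: np.ndarray
    approach: np.ndarray
    theta_o: np.ndarray  # degrees
    theta_m: np.ndarray  # degrees
    weighted: np.ndarray  # qualifying steps only, else NaN
    in_contact: np.ndarray  # bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "shared": self.shared,
                "distance": self.distance,
                "distance_prev": self.distance_prev,
                "approach": self.approach,
                "theta_o": self.theta_o,
                "theta_m": self.theta_m,
                "weighted_increment": self.weighted,
                "in_contact": self.in_contact,
            }
        )


def approach_distance(a_prev, a_curr, b_prev, b_curr, convention: str = "initial_partner_position") -> float:
    """Distance A closed toward B over one step (negative = moving away)."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    a_prev, a_curr = np.asarray(a_prev, float), np.asarray(a_curr, float)
    b_prev, b_curr = np.asarray(b_prev, float), np.asarray(b_curr, float)
    d_prev = float(np.hypot(*(a_prev - b_prev)))
    ref = b_prev if convention == "initial_partner_position" else b_curr
    d_next = float(np.hypot(*(a_curr - ref)))
    return d_prev - d_next


def weighted_social_approach_increment(
    approach: float, distance_prev: float, theta_o_deg: float, theta_m_deg: float
) -> float:
    """approach · cos²(θo) · cos²(θm) / distance_prev.

    Defined only for positive approach over a positive initial distance;
    returns NaN otherwise (such steps are excluded from the mean, per
    the convention that negative approach is not analyzed).
    """
    if not (distance_prev > 0 and approach > 0):
        return float("nan")
    if np.isnan(theta_o_deg) or np.isnan(theta_m_deg):
        return float("nan")
    co = np.cos(np.radians(theta_o_deg))
    cm = np.cos(np.radians(theta_m_deg))
    return float(approach * co * co * cm * cm / distance_prev)


def mean_social_approach_velocity(weighted: np.ndarray) -> tuple[float, int]:
    """Mean weighted increment over qualifying steps.

    Returns ``(mean, n_steps)``; the mean is NaN (missing, not zero)
    when no step qualifies.
    """
    w = np.asarray(weighted, dtype=float)
    w = w[~np.isnan(w)]
    if w.size == 0:
        return float("nan"), 0
    return float(w.mean()), int(w.size)


def detect_social_contact(
    pos_a, heading_a: float, pos_b, heading_b: float, params: ContactParams = ContactParams()
) -> bool:
    """Instantaneous social contact between two oriented positions.

    True iff the pair is within [d_min, d_max] and each partner's
    heading deviates from the bearing to the other by at most the
    mutual-angle limit.  Symmetric in (A, B).
    """
    pos_a, pos_b = np.asarray(pos_a, float), np.asarray(pos_b, float)
    if np.isnan(heading_a) or np.isnan(heading_b):
        return False
    d = float(np.hypot(*(pos_b - pos_a)))
    if not (params.d_min <= d <= params.d_max) or d == 0:
        return False
    bearing_ab = np.arctan2(pos_b[1] - pos_a[1], pos_b[0] - pos_a[0])
    bearing_ba = np.arctan2(pos_a[1] - pos_b[1], pos_a[0] - pos_b[0])
    return bool(
        angular_deviation(heading_a, bearing_ab) <= params.max_mutual_angle
        and angular_deviation(heading_b, bearing_ba) <= params.max_mutual_angle
    )


def contact_proportion(in_contact: np.ndarray, shared: np.ndarray) -> tuple[float, int, int]:
    """(#in-contact steps / #shared steps, n_contact, n_shared).

    The proportion is NaN when the dyad shares no valid time.
    """
    n_shared = int(np.count_nonzero(shared))
    n_contact = int(np.count_nonzero(in_contact & shared))
    if n_shared == 0:
        return float("nan"), 0, 0
    return n_contact / n_shared, n_contact, n_shared


def dyad_steps(
    a: PersonStates,
    b: PersonStates,
    params: ContactParams = ContactParams(),
    convention: str = "initial_partner_position",
) -> DyadSteps:
    """Vectorized per-timestep dyadic quantities for the ordered dyad A→B."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    n = len(a.t)
    shared = a.valid & b.valid

    dx, dy = b.x - a.x, b.y - a.y
    with np.errstate(invalid="ignore"):
        dist = np.hypot(dx, dy)
    dist = np.where(shared, dist, np.nan)

    nan = np.full(n, np.nan)
    distance_prev, approach = nan.copy(), nan.copy()
    theta_o, theta_m, weighted = nan.copy(), nan.copy(), nan.copy()

    if n > 1:
        pair = shared[1:] & shared[:-1]  # transition defined
        d_prev = dist[:-1]
        b_ref_x = b.x[:-1] if convention == "initial_partner_position" else b.x[1:]
        b_ref_y = b.y[:-1] if convention == "initial_partner_position" else b.y[1:]
        with np.errstate(invalid="ignore"):
            d_next = np.hypot(a.x[1:] - b_ref_x, a.y[1:] - b_ref_y)
            app = d_prev - d_next

            bearing = np.arctan2(dy[:-1], dx[:-1])  # A→B at t−1
            th_o = angular_deviation(a.heading[:-1], bearing)

            mx, my = a.x[1:] - a.x[:-1], a.y[1:] - a.y[:-1]
            moved = pair & ((mx != 0) | (my != 0))
            move_ang = np.arctan2(my, mx)
            th_m = np.where(moved, angular_deviation(move_ang, bearing), np.nan)

            qualify = (
                pair
                & (d_prev > 0)
                & (app > 0)
                & ~np.isnan(th_o)
                & ~np.isnan(th_m)
            )
            co, cm = np.cos(np.radians(th_o)), np.cos(np.radians(th_m))
            w = app * co * co * cm * cm / np.where(d_prev > 0, d_prev, np.nan)

        distance_prev[1:] = np.where(pair, d_prev, np.nan)
        approach[1:] = np.where(pair, app, np.nan)
        theta_o[1:] = np.where(pair, th_o, np.nan)
        theta_m[1:] = th_m
        weighted[1:] = np.where(qualify, w, np.nan)

    # instantaneous contact at each shared step
    in_contact = np.zeros(n, dtype=bool)
    ok = shared & a.heading_valid & b.heading_valid & (dist > 0)
    if np.any(ok):
        with np.errstate(invalid="ignore"):
            bearing_ab = np.arctan2(dy, dx)
            bearing_ba = np.arctan2(-dy, -dx)
            dev_a = angular_deviation(a.heading, bearing_ab)
            dev_b = angular_deviation(b.heading, bearing_ba)
            in_contact = (
                ok
                & (dist >= params.d_min)
                & (dist <= params.d_max)
                & (dev_a <= params.max_mutual_angle)
                & (dev_b <= params.max_mutual_angle)
            )

    return DyadSteps(
        t=a.t,
        shared=shared,
        distance=dist,
        distance_prev=distance_prev,
        approach=approach,
        theta_o=theta_o,
        theta_m=theta_m,
        weighted=weighted,
        in_contact=in_contact,
    )


def summarize_session(
    states: dict[str, PersonStates],
    session: Session,
    params: ContactParams = ContactParams(),
    convention: str = "initial_partner_position",
) -> pd.DataFrame:
    """Per-dyad summaries for every ordered pair in a session.

    Returns one row per ordered (agent, partner) pair with mean social
    approach velocity (agent as approacher), contact proportion, shared
    time, and role/group metadata from the session roster.
    """
    people: dict[str, Person] = {p.person_id: p for p in session.roster}
    ids = [pid for pid in sorted(states) if pid in people or not people]
    dt = session.sample_interval
    rows = []
    for i, ai in enumerate(ids):
        for bi in ids[i + 1 :]:
            ds_ab = dyad_steps(states[ai], states[bi], params, convention)
            ds_ba = dyad_steps(states[bi], states[ai], params, convention)
            cprop, n_contact, n_shared = contact_proportion(ds_ab.in_contact, ds_ab.shared)
            for agent, partner, ds in ((ai, bi, ds_ab), (bi, ai, ds_ba)):
                sav, n_steps = mean_social_approach_velocity(ds.weighted)
                pa, pb = people.get(agent), people.get(partner)
                rows.append(
                    {
                        "session_id": session.session_id,
                        "classroom_id": session.classroom_id,
                        "agent_id": agent,
                        "partner_id": partner,
                        "agent_role": pa.role if pa else None,
                        "partner_role": pb.role if pb else None,
                        "agent_group": pa.group if pa else None,
                        "partner_group": pb.group if pb else None,
                        "mean_sav": sav,
                        "n_approach_steps": n_steps,
                        "contact_prop": cprop,
                        "n_contact_steps": n_contact,
                        "shared_steps": n_shared,
                        "shared_seconds": n_shared * dt,
                    }
                )
    return pd.DataFrame(rows)
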