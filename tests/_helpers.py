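"""Shared test utilities: state construction and an independent,
pure-Python per-step reference implementation of the dyad metrics.

The naive reference deliberately avoids numpy and the package's own
vectorized code paths: it walks the timesteps one by one with ``math``
functions, so agreement with the pipeline is a genuine dual-route check.
"""

from __future__ import annotations

import math

import numpy as np

from dyadtrack.kinematics import PersonStates


def make_states(
    x,
    y,
    heading=None,
    valid=None,
    dt: float = 0.1,
    pid: str = "P",
) -> PersonStates:
    """Build a PersonStates directly from coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    t = np.arange(n) * dt
    if heading is None:
        heading = np.zeros(n)
    heading = np.asarray(heading, dtype=float)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    heading_valid = valid & ~np.isnan(heading)
    heading = np.where(heading_valid, heading, np.nan)
    linvel = np.full(n, np.nan)
    return PersonStates(pid, t, x, y, heading, linvel, valid, heading_valid)


def random_dyad(rng, n_steps: int, dt: float = 0.1):
    """Two correlated random-walk states with random dropouts and
    occasional undefined headings."""
    def walk(start):
        steps = rng.normal(0.0, 0.06, size=(n_steps, 2))
        return start + np.cumsum(steps, axis=0)

    pa = walk(rng.uniform(1, 8, size=2))
    pb = walk(rng.uniform(1, 8, size=2))
    ha = rng.uniform(-np.pi, np.pi, size=n_steps)
    hb = rng.uniform(-np.pi, np.pi, size=n_steps)
    ha[rng.random(n_steps) < 0.05] = np.nan  # coincident-tag steps
    hb[rng.random(n_steps) < 0.05] = np.nan
    va = rng.random(n_steps) > 0.1
    vb = rng.random(n_steps) > 0.1
    a = make_states(pa[:, 0], pa[:, 1], ha, va, dt, "A")
    b = make_states(pb[:, 0], pb[:, 1], hb, vb, dt, "B")
    return a, b


def _dev_deg(a: float, b: float) -> float:
    return math.degrees(abs(math.remainder(a - b, 2.0 * math.pi)))


def naive_dyad_summary(
    a: PersonStates,
    b: PersonStates,
    d_min: float = 0.2,
    d_max: float = 2.0,
    max_angle: float = 45.0,
    convention: str = "initial_partner_position",
):
    """Per-step reference: (mean SAV, n approach steps, contact prop, n shared)."""
    n = len(a.x)
    incs = []
    contact = shared = 0
    for t in range(n):
        if a.valid[t] and b.valid[t]:
            shared += 1
            d = math.dist((a.x[t], a.y[t]), (b.x[t], b.y[t]))
            if (
                not math.isnan(a.heading[t])
                and not math.isnan(b.heading[t])
                and d > 0
                and d_min <= d <= d_max
            ):
                bear_ab = math.atan2(b.y[t] - a.y[t], b.x[t] - a.x[t])
                bear_ba = math.atan2(a.y[t] - b.y[t], a.x[t] - b.x[t])
                if (
                    _dev_deg(a.heading[t], bear_ab) <= max_angle
                    and _dev_deg(b.heading[t], bear_ba) <= max_angle
                ):
                    contact += 1
        if t == 0:
            continue
        if not (a.valid[t] and a.valid[t - 1] and b.valid[t] and b.valid[t - 1]):
            continue
        d_prev = math.dist((a.x[t - 1], a.y[t - 1]), (b.x[t - 1], b.y[t - 1]))
        if convention == "initial_partner_position":
            ref = (b.x[t - 1], b.y[t - 1])
        else:
            ref = (b.x[t], b.y[t])
        app = d_prev - math.dist((a.x[t], a.y[t]), ref)
        if d_prev <= 0 or app <= 0 or math.isnan(a.heading[t - 1]):
            continue
        mx, my = a.x[t] - a.x[t - 1], a.y[t] - a.y[t - 1]
        if mx == 0 and my == 0:
            continue
        bearing = math.atan2(b.y[t - 1] - a.y[t - 1], b.x[t - 1] - a.x[t - 1])
        th_o = math.radians(_dev_deg(a.heading[t - 1], bearing))
        th_m = math.radians(_dev_deg(math.atan2(my, mx), bearing))
        incs.append(app * math.cos(th_o) ** 2 * math.cos(th_m) ** 2 / d_prev)
    mean = sum(incs) / len(incs) if incs else float("nan")
    prop = contact / shared if shared else float("nan")
    return mean, len(incs), prop, shared
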