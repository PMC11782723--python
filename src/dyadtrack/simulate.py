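"""Agent-based synthetic classroom: dual-tag movement streams with
programmable teacher/peer affinities.

The generator emulates the measurement conditions of UWB dual-tag
classroom tracking: a ~9 m square room, a 10 Hz sampling grid, two tags
per person at ±0.15 m from the body midline, isotropic Gaussian
positional noise with 0.15 m per-axis standard deviation, and random
per-tag dropouts.  Behavior follows a waypoint-plus-dwell model: each
agent alternates between walking to a chosen social partner (selected
with probability proportional to a role/group affinity), dwelling
face-to-face at 0.35–0.9 m, and walking to solo waypoints.  When an
agent reaches a partner who is not walking, the partner turns to face
the approacher for the dwell, so mutual-orientation contact episodes
exist by construction.

Group affinities are the programmed study conditions: children with ASD
prefer teachers over peers (3:1), children with DD mildly so (1.5:1),
and TD children prefer peers (1:2); teachers approach children rather
than each other.  These defaults encode the qualitative contrast the
pipeline is meant to recover and can be overridden per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Person, Session

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "StudyFixture",
    "DEFAULT_AFFINITY",
    "simulate_session",
    "make_study_fixture",
    "simulate_analysis_table",
]

# Programmed study conditions: row = agent's group (or 'teacher'),
# column = partner's role.  Children with ASD are teacher-biased, TD
# children peer-biased, DD intermediate.
DEFAULT_AFFINITY: dict[str, dict[str, float]] = {
    "ASD": {"teacher": 3.0, "child": 1.0},
    "DD": {"teacher": 1.5, "child": 1.0},
    "TD": {"teacher": 1.0, "child": 2.0},
    "teacher": {"teacher": 0.3, "child": 1.0},
}

# Full-scale study shape: 8 classrooms, 24/23/30 children with
# ASD/DD/TD, ~3 teachers per room, ~121-minute observations.
STUDY_N_CLASSROOMS = 8
STUDY_GROUP_TOTALS = {"ASD": 24, "DD": 23, "TD": 30}
STUDY_SESSION_MINUTES = 120.87
STUDY_TEACHERS_PER_CLASSROOM = 3
STUDY_OCCASIONS = 4  # children attend 3 or 4 of these


@dataclass
class SimConfig:
    """Generator parameters (defaults are the emulated study conditions)."""

    room_width: float = 9.0  # meters; study rooms ~8.4–9.6 m per side
    room_height: float = 9.0
    n_teachers: int = 3
    n_children: Mapping[str, int] = field(
        default_factory=lambda: {"ASD": 3, "DD": 3, "TD": 4}
    )
    session_length: float = 300.0  # seconds
    sample_rate: float = 10.0  # Hz
    affinity: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_AFFINITY.items()}
    )
    p_social: float = 0.7  # probability a new goal is a partner visit
    speed_range: tuple[float, float] = (0.3, 0.9)  # m/s, preschool walking pace
    dwell_range: tuple[float, float] = (4.0, 15.0)  # s face-to-face
    pause_range: tuple[float, float] = (0.5, 2.0)  # s at solo waypoints
    dwell_distance: tuple[float, float] = (0.35, 0.9)  # m, inside the contact band
    shoulder: float = 0.15  # half-width between tags, meters
    noise_sd: float = 0.15  # per-axis tag noise, meters
    dropout: float = 0.02  # per-tag per-step missing probability
    wall_margin: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if min(self.room_width, self.room_height, self.sample_rate, self.shoulder) <= 0:
            raise ValueError("dimensions, sample rate and shoulder width must be positive")
        if self.noise_sd < 0 or not (0 <= self.dropout < 1):
            raise ValueError("noise_sd >= 0 and 0 <= dropout < 1 required")
        for row in self.affinity.values():
            if any(w < 0 for w in row.values()):
                raise ValueError("affinities must be non-negative")
        n_agents = self.n_teachers + sum(self.n_children.values())
        capacity = (self.room_width * self.room_height) / (0.2 * 0.2)
        if n_agents > capacity:
            raise ValueError(
                f"{n_agents} agents exceed floor capacity ({capacity:.0f}) at 0.2 m separation"
            )


@dataclass
class GroundTruth:
    """Noise-free simulator state underlying the emitted tag stream."""

    ids: list[str]
    times: np.ndarray  # (n_steps,)
    positions: np.ndarray  # (n_steps, n_agents, 2)
    headings: np.ndarray  # (n_steps, n_agents)
    partner_log: pd.DataFrame  # columns: t, agent_id, partner_id
    affinity: dict  # the programmed preference ordering


@dataclass
class SimResult:
    session: Session
    tags: pd.DataFrame  # canonical tag-stream columns
    roster: tuple[Person, ...]
    truth: GroundTruth


@dataclass
class StudyFixture:
    """A multi-classroom, multi-occasion synthetic study."""

    sessions: list[SimResult]
    roster: tuple[Person, ...]  # all persons across classrooms
    scale: float
    seed: int


def _default_roster(config: SimConfig, prefix: str = "") -> tuple[Person, ...]:
    people = [Person(f"{prefix}T{i + 1}", "teacher") for i in range(config.n_teachers)]
    for group, n in config.n_children.items():
        people += [Person(f"{prefix}{group}{i + 1}", "child", group) for i in range(n)]
    return tuple(people)


def simulate_session(
    config: SimConfig,
    session_id: str = "S1",
    classroom_id: str = "C1",
    roster: Sequence[Person] | None = None,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Simulate one observation session; deterministic given the seed.

    Returns the emitted tag stream (noisy, with dropouts), the roster,
    and the noise-free ground truth.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    people = tuple(roster) if roster is not None else _default_roster(config)
    n = len(people)
    if n < 1:
        raise ValueError("empty roster")
    ids = [p.person_id for p in people]
    keys = [p.group if p.role == "child" else "teacher" for p in people]
    roles = np.array([p.role for p in people])

    # pairwise affinity weights: W[i, j] = weight of i choosing j
    W = np.zeros((n, n))
    for i, key in enumerate(keys):
        row = config.affinity.get(key, {"teacher": 1.0, "child": 1.0})
        for j in range(n):
            if j != i:
                W[i, j] = row.get(roles[j] if roles[j] == "teacher" else "child", 1.0)

    dt = 1.0 / config.sample_rate
    n_steps = int(round(config.session_length * config.sample_rate))
    m = config.wall_margin
    lo = np.array([m, m])
    hi = np.array([config.room_width - m, config.room_height - m])

    pos = rng.uniform(lo, hi, size=(n, 2))
    head = rng.uniform(-np.pi, np.pi, size=n)
    mode = np.ones(n, dtype=int)  # 0 walk, 1 dwell; start "dwelling" with 0 timer
    timer = np.zeros(n)
    partner = np.full(n, -1, dtype=int)
    target = pos.copy()
    arrive_r = np.full(n, 0.15)
    speed = rng.uniform(*config.speed_range, size=n)

    P = np.empty((n_steps, n, 2))
    H = np.empty((n_steps, n))
    log_t, log_a, log_p = [], [], []

    can_social = W.sum(axis=1) > 0

    for k in range(n_steps):
        # assign new goals to dwellers whose timer expired
        done = np.flatnonzero((mode == 1) & (timer <= 0))
        for i in done:
            speed[i] = rng.uniform(*config.speed_range)
            if can_social[i] and n > 1 and rng.random() < config.p_social:
                w = W[i] / W[i].sum()
                j = int(rng.choice(n, p=w))
                partner[i] = j
                arrive_r[i] = rng.uniform(*config.dwell_distance)
                log_t.append(k * dt)
                log_a.append(ids[i])
                log_p.append(ids[j])
            else:
                partner[i] = -1
                target[i] = rng.uniform(lo, hi)
                arrive_r[i] = 0.15
            mode[i] = 0

        walking = mode == 0
        if np.any(walking):
            wi = np.flatnonzero(walking)
            has_p = partner[wi] >= 0
            tgt = target[wi].copy()
            tgt[has_p] = pos[partner[wi[has_p]]]
            delta = tgt - pos[wi]
            dist = np.hypot(delta[:, 0], delta[:, 1])
            arrived = dist <= arrive_r[wi]
            # move the rest
            go = ~arrived
            if np.any(go):
                gi = wi[go]
                d = dist[go]
                step = np.minimum(speed[gi] * dt, d)
                unit = delta[go] / d[:, None]
                pos[gi] = pos[gi] + unit * step[:, None]
                head[gi] = np.arctan2(unit[:, 1], unit[:, 0])
            for idx in np.flatnonzero(arrived):
                i = wi[idx]
                mode[i] = 1
                if partner[i] >= 0:
                    tau = rng.uniform(*config.dwell_range)
                    timer[i] = tau
                    j = partner[i]
                    if mode[j] == 1:  # partner not walking: reciprocate
                        partner[j] = i
                        timer[j] = max(timer[j], tau)
                else:
                    timer[i] = rng.uniform(*config.pause_range)

        dwell = np.flatnonzero(mode == 1)
        if dwell.size:
            timer[dwell] -= dt
            facing = dwell[partner[dwell] >= 0]
            if facing.size:
                d = pos[partner[facing]] - pos[facing]
                nz = (d[:, 0] != 0) | (d[:, 1] != 0)
                head[facing[nz]] = np.arctan2(d[nz, 1], d[nz, 0])

        np.clip(pos, lo, hi, out=pos)
        P[k] = pos
        H[k] = head

    times = np.arange(n_steps) * dt

    # emit the two tags with noise and dropouts
    off = np.stack([np.sin(H), -np.cos(H)], axis=-1) * config.shoulder  # midline→R
    right = P + off
    left = P - off
    frames = []
    for side, arr in (("L", left), ("R", right)):
        noisy = arr + rng.normal(0.0, config.noise_sd, size=arr.shape)
        keep = rng.random((n_steps, n)) >= config.dropout
        step_idx, agent_idx = np.nonzero(keep)
        frames.append(
            pd.DataFrame(
                {
                    "person_id": np.asarray(ids, dtype=object)[agent_idx],
                    "tag_side": side,
                    "t": times[step_idx],
                    "x": noisy[step_idx, agent_idx, 0],
                    "y": noisy[step_idx, agent_idx, 1],
                }
            )
        )
    tags = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["person_id", "tag_side", "t"], kind="stable")
        .reset_index(drop=True)
    )

    session = Session(
        session_id=session_id,
        classroom_id=classroom_id,
        room_width=config.room_width,
        room_height=config.room_height,
        roster=people,
        sample_interval=dt,
        start=0.0,
        end=times[-1] if n_steps else 0.0,
    )
    truth = GroundTruth(
        ids=list(ids),
        times=times,
        positions=P,
        headings=H,
        partner_log=pd.DataFrame({"t": log_t, "agent_id": log_a, "partner_id": log_p}),
        affinity={k: dict(v) for k, v in config.affinity.items()},
    )
    return SimResult(session=session, tags=tags, roster=people, truth=truth)


def _split_counts(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def make_study_fixture(
    scale: float = 1.0,
    seed: int = 0,
    config: SimConfig | None = None,
    n_classrooms: int = STUDY_N_CLASSROOMS,
    occasions: int = STUDY_OCCASIONS,
) -> StudyFixture:
    """A study-shaped multi-session dataset.

    Eight classrooms share 24/23/30 children with ASD/DD/TD (split as
    evenly as possible), each with 3 teachers; every classroom is
    observed on ``occasions`` days and each child attends 3–4 of them.
    ``scale`` multiplies the ~121-minute session length only — the
    nesting structure is kept at full fidelity.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    base = config if config is not None else SimConfig()

    per_room = {g: _split_counts(t, n_classrooms) for g, t in STUDY_GROUP_TOTALS.items()}
    sessions: list[SimResult] = []
    all_people: list[Person] = []
    for c in range(n_classrooms):
        cid = f"C{c + 1}"
        members = [Person(f"{cid}-T{i + 1}", "teacher") for i in range(STUDY_TEACHERS_PER_CLASSROOM)]
        for g in ("ASD", "DD", "TD"):
            members += [
                Person(f"{cid}-{g}{i + 1}", "child", g) for i in range(per_room[g][c])
            ]
        all_people.extend(members)
        children = [p for p in members if p.role == "child"]
        teachers = [p for p in members if p.role == "teacher"]
        # each child misses at most one of the occasions
        missed = {p.person_id: (int(rng.integers(occasions)) if rng.random() < 0.5 else -1)
                  for p in children}
        cfg = replace(
            base,
            session_length=scale * STUDY_SESSION_MINUTES * 60.0,
            n_teachers=len(teachers),
        )
        for o in range(occasions):
            attending = teachers + [p for p in children if missed[p.person_id] != o]
            sessions.append(
                simulate_session(
                    cfg,
                    session_id=f"{cid}-O{o + 1}",
                    classroom_id=cid,
                    roster=attending,
                    rng=rng,
                )
            )
    return StudyFixture(sessions=sessions, roster=tuple(all_people), scale=scale, seed=seed)


def simulate_analysis_table(
    effects: Mapping[str, float],
    sd_child: float,
    sd_classroom: float,
    sd_residual: float,
    n_classrooms: int = 8,
    children_per_class: Mapping[str, int] | None = None,
    n_obs: tuple[int, int] = (3, 4),
    outcome: str = "y",
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a child × observation table from a known three-level model.

    ``y = intercept + B_ASD·[ASD] + B_DD·[DD] + u_classroom + u_child + e``
    with independent normal random intercepts.  Used for calibration and
    parameter-recovery checks of the statistical layer, where the
    generative fixed effects are known exactly.
    """
    rng = np.random.default_rng(seed)
    if children_per_class is None:
        children_per_class = {"ASD": 3, "DD": 3, "TD": 4}
    rows = []
    for c in range(n_classrooms):
        u_c = rng.normal(0.0, sd_classroom)
        for g, n in children_per_class.items():
            for i in range(n):
                child = f"C{c + 1}-{g}{i + 1}"
                u_k = rng.normal(0.0, sd_child)
                fixed = effects.get("intercept", 0.0) + effects.get(g, 0.0)
                for o in range(int(rng.integers(n_obs[0], n_obs[1] + 1))):
                    rows.append(
                        {
                            "child_id": child,
                            "classroom_id": f"C{c + 1}",
                            "group": g,
                            "obs": o + 1,
                            outcome: fixed + u_c + u_k + rng.normal(0.0, sd_residual),
                        }
                    )
    return pd.DataFrame(rows)
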