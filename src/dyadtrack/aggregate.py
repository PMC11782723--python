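"""Collapse dyad summaries to child × observation outcome variables.

Each child–session row carries six role-level means — social approach
velocity toward / from teachers and peers, and contact proportion with
teachers and peers — plus three teacher-over-peer preference indices
(teacher value minus peer value; positive means teacher preference):

* ``pref_approach_given``    = sav_to_teachers − sav_to_peers
* ``pref_approach_received`` = sav_from_teachers − sav_from_peers
* ``pref_contact``           = contact_teachers − contact_peers

Role-level means weight each partner dyad equally by default
(``equal_per_partner``); ``shared_time_weighted`` weights dyads by the
seconds both partners were present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "child_partner_role_mean",
    "preference_index",
    "build_analysis_table",
    "OUTCOME_COLUMNS",
]

WEIGHTINGS = ("equal_per_partner", "shared_time_weighted")

OUTCOME_COLUMNS = [
    "sav_to_teachers",
    "sav_to_peers",
    "sav_from_teachers",
    "sav_from_peers",
    "contact_teachers",
    "contact_peers",
    "pref_approach_given",
    "pref_approach_received",
    "pref_contact",
]


def child_partner_role_mean(
    values, weights=None, weighting: str = "equal_per_partner"
) -> float:
    """Mean of a per-dyad quantity over one child's partners of one role.

    NaN entries (dyads with no qualifying data) are ignored; if nothing
    remains the result is NaN (missing, never zero).
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    v = np.asarray(values, dtype=float)
    if weighting == "equal_per_partner" or weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
    ok = ~np.isnan(v) & (w > 0)
    if not np.any(ok):
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


def preference_index(teacher_value: float, peer_value: float) -> float:
    """teacher_value − peer_value; NaN if either side is missing."""
    return teacher_value - peer_value


def _role_mean(sub: pd.DataFrame, col: str, weighting: str) -> float:
    return child_partner_role_mean(sub[col], sub["shared_seconds"], weighting)


def build_analysis_table(
    summaries: pd.DataFrame, weighting: str = "equal_per_partner"
) -> pd.DataFrame:
    """One row per child × observation from ordered dyad summaries.

    Parameters
    ----------
    summaries
        Output of :func:`dyadtrack.dyads.summarize_session` (possibly
        concatenated over sessions): one row per ordered (agent,
        partner) dyad with role/group metadata.
    weighting
        How to average a child's dyads within a partner role.

    The observation index (``obs``) is the rank of the session within
    its classroom, making Level-1 the observation, Level-2 the child and
    Level-3 the classroom.
    """
    if weighting not in WEIGHTINGS:
        raise ValueError(f"unknown weighting {weighting!r}")
    need = {"session_id", "classroom_id", "agent_id", "partner_id", "agent_role",
            "partner_role", "agent_group", "mean_sav", "contact_prop", "shared_seconds"}
    missing = need - set(summaries.columns)
    if missing:
        raise ValueError(f"summaries missing columns {sorted(missing)}")

    rows = []
    given = summaries[summaries["agent_role"] == "child"]
    for (sid, child), sub in given.groupby(["session_id", "agent_id"], sort=True):
        received = summaries[
            (summaries["session_id"] == sid) & (summaries["partner_id"] == child)
        ]
        to_t = sub[sub["partner_role"] == "teacher"]
        to_p = sub[sub["partner_role"] == "child"]
        from_t = received[received["agent_role"] == "teacher"]
        from_p = received[(received["agent_role"] == "child")]

        rec = {
            "child_id": child,
            "session_id": sid,
            "classroom_id": sub["classroom_id"].iloc[0],
            "group": sub["agent_group"].iloc[0],
            "sav_to_teachers": _role_mean(to_t, "mean_sav", weighting),
            "sav_to_peers": _role_mean(to_p, "mean_sav", weighting),
            "sav_from_teachers": _role_mean(from_t, "mean_sav", weighting),
            "sav_from_peers": _role_mean(from_p, "mean_sav", weighting),
            "contact_teachers": _role_mean(to_t, "contact_prop", weighting),
            "contact_peers": _role_mean(to_p, "contact_prop", weighting),
        }
        rec["pref_approach_given"] = preference_index(
            rec["sav_to_teachers"], rec["sav_to_peers"]
        )
        rec["pref_approach_received"] = preference_index(
            rec["sav_from_teachers"], rec["sav_from_peers"]
        )
        rec["pref_contact"] = preference_index(
            rec["contact_teachers"], rec["contact_peers"]
        )
        rows.append(rec)

    table = pd.DataFrame(rows)
    if len(table):
        obs = (
            table[["classroom_id", "session_id"]]
            .drop_duplicates()
            .sort_values(["classroom_id", "session_id"])
        )
        obs["obs"] = obs.groupby("classroom_id").cumcount() + 1
        table = table.merge(obs, on=["classroom_id", "session_id"], how="left")
    return table
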