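"""Interpersonal features of a dyadic scene.

Twelve per-scene scalars describe proxemics, mutual orientation and
coordination between the two agents:

========= ============================================================ =====
name      definition                                                   units
========= ============================================================ =====
IPD       time-mean centroid-to-centroid distance                      mm
IPD_STD   time-SD of that distance                                     mm
PS        % of frames with separation below one arm length             %
IPO       mean of the two agents' facing-time percentages              %
IPO_BAL   1 - |t1 - t2| / (t1 + t2) over facing times                  [0,1]
DC_VEL    Pearson r between distance and agent-mean speed profile      r
DC_ACC    ... and the agent-mean |speed derivative| profile            r
DC_VOL    ... and the agent-mean bounding-box volume profile           r
DC_LC     ... and the agent-mean limb-contraction profile              r
SYNC_VEL  Pearson r between the two agents' speed profiles             r
SYNC_ACC  Pearson r between the two agents' acceleration profiles      r
ME_BAL    1 - |E1 - E2| / (E1 + E2) over total motion energy           [0,1]
========= ============================================================ =====

Centroids use the 13 anatomical markers.  An agent "faces" its partner when
the outward normal of its shoulder line (disambiguated by the forward head
offset) points within a configurable cone, 45 deg half-angle by default, of
the horizontal direction to the partner's centroid.  Balance indices use
``1 - |difference|/sum`` so that 1 means perfect balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dyadkin.scene_io import AgentTrajectory, Scene
from dyadkin.intra_features import (
    limb_contraction_series,
    speed_series,
    volume_series,
)

__all__ = [
    "DyadProfiles",
    "dyad_profiles",
    "interpersonal_distance",
    "personal_space",
    "orientation",
    "distance_correlation",
    "synchronization",
    "motion_energy_balance",
    "reduce_interpersonal",
    "INTER_FEATURES",
    "DEFAULT_CONE_HALF_ANGLE",
]

INTER_FEATURES = (
    "IPD",
    "IPD_STD",
    "PS",
    "IPO",
    "IPO_BAL",
    "DC_VEL",
    "DC_ACC",
    "DC_VOL",
    "DC_LC",
    "SYNC_VEL",
    "SYNC_ACC",
    "ME_BAL",
)

DEFAULT_CONE_HALF_ANGLE = 45.0


@dataclass
class DyadProfiles:
    """Per-frame profiles shared by the interpersonal features."""

    ipd_t: np.ndarray  # (frames,)
    facing: tuple[np.ndarray, np.ndarray]  # per agent, (frames,) bool
    speed_t: tuple[np.ndarray, np.ndarray]  # per agent, (frames-1,) mm/s
    acc_t: tuple[np.ndarray, np.ndarray]  # per agent, (frames-2,) mm/s^2
    vol_t: tuple[np.ndarray, np.ndarray]  # per agent, (frames,) m^3
    lc_t: tuple[np.ndarray, np.ndarray]  # per agent, (frames,) mm


def _centroids(agent: AgentTrajectory) -> np.ndarray:
    return agent.anatomical_coords().mean(axis=1)


def _facing_direction(agent: AgentTrajectory) -> np.ndarray:
    """(frames, 2) horizontal unit vector the agent's chest points along."""
    l_sh = agent.marker("l_shoulder")[:, :2]
    r_sh = agent.marker("r_shoulder")[:, :2]
    chord = r_sh - l_sh
    if np.any(np.linalg.norm(chord, axis=1) < 1e-9):
        raise ValueError("coincident shoulder markers: facing direction undefined")
    # two candidate normals of the shoulder line; pick the one on the side of
    # the forward head/sternum offset
    normal = np.stack([-chord[:, 1], chord[:, 0]], axis=1)
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    mid = 0.5 * (l_sh + r_sh)
    hint = 0.5 * (agent.marker("head")[:, :2] + agent.marker("sternum")[:, :2]) - mid
    sign = np.sign(np.einsum("fi,fi->f", normal, hint))
    sign[sign == 0] = 1.0
    return normal * sign[:, None]


def dyad_profiles(
    scene: Scene, cone_half_angle: float = DEFAULT_CONE_HALF_ANGLE
) -> DyadProfiles:
    """Compute every per-frame profile the interpersonal features rely on."""
    a1, a2 = scene.agents
    c1, c2 = _centroids(a1), _centroids(a2)
    ipd_t = np.linalg.norm(c1 - c2, axis=1)

    cos_thresh = np.cos(np.radians(cone_half_angle))
    facing = []
    for agent, own, other in ((a1, c1, c2), (a2, c2, c1)):
        to_partner = (other - own)[:, :2]
        norms = np.linalg.norm(to_partner, axis=1, keepdims=True)
        to_partner = np.divide(to_partner, norms, out=np.zeros_like(to_partner), where=norms > 0)
        face = _facing_direction(agent)
        facing.append(np.einsum("fi,fi->f", face, to_partner) > cos_thresh)

    speed_t = tuple(speed_series(a, scene.fps).mean(axis=1) for a in (a1, a2))
    acc_t = tuple(np.abs(np.diff(s)) * scene.fps for s in speed_t)
    vol_t = tuple(volume_series(a) for a in (a1, a2))
    lc_t = tuple(limb_contraction_series(a) for a in (a1, a2))
    return DyadProfiles(
        ipd_t=ipd_t,
        facing=(facing[0], facing[1]),
        speed_t=speed_t,
        acc_t=acc_t,
        vol_t=vol_t,
        lc_t=lc_t,
    )


def interpersonal_distance(scene: Scene) -> tuple[float, float, np.ndarray]:
    """(IPD mean, IPD SD, per-frame distance profile), all in mm."""
    ipd_t = dyad_profiles(scene).ipd_t
    return float(ipd_t.mean()), float(ipd_t.std()), ipd_t


def _arm_length(agent: AgentTrajectory) -> float:
    upper = [
        np.linalg.norm(agent.marker(f"{s}_elbow") - agent.marker(f"{s}_shoulder"), axis=1)
        for s in ("l", "r")
    ]
    lower = [
        np.linalg.norm(agent.marker(f"{s}_wrist") - agent.marker(f"{s}_elbow"), axis=1)
        for s in ("l", "r")
    ]
    return float(np.mean([u + l for u, l in zip(upper, lower)]))


def personal_space(scene: Scene) -> float:
    """Percentage of frames the dyad separation is below one arm length.

    The arm length is the time-mean shoulder-elbow-wrist chain length,
    averaged over both arms and both agents.
    """
    ipd_t = dyad_profiles(scene).ipd_t
    arm = float(np.mean([_arm_length(a) for a in scene.agents]))
    return float(100.0 * np.mean(ipd_t < arm))


def orientation(
    scene: Scene,
    cone_half_angle: float = DEFAULT_CONE_HALF_ANGLE,
    mutual_only: bool = False,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(IPO %, IPO_BAL, facing_1, facing_2).

    IPO defaults to the mean of the two agents' facing percentages, i.e.
    mutual facing plus half of the one-sided-only time; ``mutual_only``
    restricts it to frames in which both agents face each other.  IPO_BAL is
    ``1 - |t1 - t2|/(t1 + t2)`` over the agents' facing times (0 if neither
    agent ever faces the other).
    """
    prof = dyad_profiles(scene, cone_half_angle)
    f1, f2 = prof.facing
    t1, t2 = float(f1.sum()), float(f2.sum())
    if mutual_only:
        ipo = 100.0 * float(np.mean(f1 & f2))
    else:
        ipo = 50.0 * (float(np.mean(f1)) + float(np.mean(f2)))
    bal = 0.0 if t1 + t2 == 0 else 1.0 - abs(t1 - t2) / (t1 + t2)
    return ipo, bal, f1, f2


def _pearson(x: np.ndarray, y: np.ndarray, what: str) -> float:
    if len(x) != len(y):
        raise ValueError("profiles must be aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 aligned frames for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"{what}: zero-variance profile, correlation undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def distance_correlation(scene: Scene, profile: str) -> float:
    """Pearson r between the distance profile and an agent-averaged profile.

    ``profile`` is one of ``VEL``, ``ACC``, ``VOL``, ``LC``.  Differenced
    profiles are aligned by truncating the distance profile.
    """
    prof = dyad_profiles(scene)
    series = {
        "VEL": 0.5 * (prof.speed_t[0] + prof.speed_t[1]),
        "ACC": 0.5 * (prof.acc_t[0] + prof.acc_t[1]),
        "VOL": 0.5 * (prof.vol_t[0] + prof.vol_t[1]),
        "LC": 0.5 * (prof.lc_t[0] + prof.lc_t[1]),
    }
    try:
        y = series[profile]
    except KeyError:
        raise ValueError(f"unknown profile {profile!r}") from None
    return _pearson(prof.ipd_t[: len(y)], y, f"DC_{profile}")


def synchronization(scene: Scene, profile: str) -> float:
    """Pearson r between the two agents' speed (``VEL``) or acceleration
    (``ACC``) profiles."""
    prof = dyad_profiles(scene)
    if profile == "VEL":
        a, b = prof.speed_t
    elif profile == "ACC":
        a, b = prof.acc_t
    else:
        raise ValueError(f"unknown profile {profile!r}")
    return _pearson(a, b, f"SYNC_{profile}")


def motion_energy_balance(scene: Scene) -> float:
    """1 - |E1 - E2| / (E1 + E2) with E_i the summed mean marker displacement."""
    energies = []
    for agent in scene.agents:
        disp = np.linalg.norm(np.diff(agent.anatomical_coords(), axis=0), axis=2)
        energies.append(float(disp.mean(axis=1).sum()))
    e1, e2 = energies
    if e1 + e2 == 0:
        return 0.0
    return 1.0 - abs(e1 - e2) / (e1 + e2)


def reduce_interpersonal(
    scene: Scene, cone_half_angle: float = DEFAULT_CONE_HALF_ANGLE
) -> dict[str, float]:
    """All 12 interpersonal scalars; undefined correlations come back NaN."""
    prof = dyad_profiles(scene, cone_half_angle)
    ipd, ipd_std = float(prof.ipd_t.mean()), float(prof.ipd_t.std())
    ipo, ipo_bal, _, _ = orientation(scene, cone_half_angle)

    out = {
        "IPD": ipd,
        "IPD_STD": ipd_std,
        "PS": personal_space(scene),
        "IPO": ipo,
        "IPO_BAL": ipo_bal,
        "ME_BAL": motion_energy_balance(scene),
    }
    for name in ("VEL", "ACC", "VOL", "LC"):
        out[f"DC_{name}"] = distance_correlation(scene, name)
    for name in ("VEL", "ACC"):
        out[f"SYNC_{name}"] = synchronization(scene, name)
    return {k: out[k] for k in INTER_FEATURES}
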