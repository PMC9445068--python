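"""Intrapersonal kinematic and postural features.

Eight per-scene scalars are computed from each agent's 13 anatomical markers
(sternum and sacrum excluded) and averaged over the two agents:

======== =========================================================== ======
name     definition                                                  units
======== =========================================================== ======
VEL      mean per-step marker speed                                  mm/s
ACC      mean |d/dt| of per-marker speed                             mm/s^2
VM       cumulative |dz| path per marker, averaged over markers      mm
VOL      time-mean axis-aligned bounding-box volume                  m^3
VOL_STD  time-SD of the bounding-box volume                          m^3
SM       left/right asymmetry about the sagittal midline plane       mm
LA       mean interior angle at shoulder/elbow/hip/knee joints       deg
LC       mean head-to-extremity distance (wrists, ankles)            mm
======== =========================================================== ======

Velocity and acceleration use forward differences at the scene sampling
rate; their series are one and two samples shorter than the clip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dyadkin.scene_io import AgentTrajectory, Scene

__all__ = [
    "FrameSeries",
    "velocity",
    "acceleration",
    "vertical_movement",
    "volume",
    "volume_series",
    "symmetry",
    "symmetry_components",
    "limb_angles",
    "limb_angle_series",
    "limb_contraction",
    "limb_contraction_series",
    "speed_series",
    "reduce_intrapersonal",
    "INTRA_FEATURES",
]

INTRA_FEATURES = ("VEL", "ACC", "VM", "VOL", "VOL_STD", "SM", "LA", "LC")

MM3_TO_M3 = 1e-9

#: joints as (vertex, endpoint_a, endpoint_b); L/R expanded at call time
_JOINTS = (
    ("shoulder", "elbow", "hip"),
    ("elbow", "shoulder", "wrist"),
    ("hip", "shoulder", "knee"),
    ("knee", "hip", "ankle"),
)

_EXTREMITIES = ("l_wrist", "r_wrist", "l_ankle", "r_ankle")


@dataclass
class FrameSeries:
    """A per-frame (optionally per-marker) series with provenance."""

    values: np.ndarray
    feature_name: str
    agent_id: int | None = None

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def scalar(self) -> float:
        return float(np.mean(self.values))


def speed_series(agent: AgentTrajectory, fps: float) -> np.ndarray:
    """(frames-1, 13) per-step marker speeds in mm/s."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    pts = agent.anatomical_coords()
    disp = np.linalg.norm(np.diff(pts, axis=0), axis=2)
    return disp * fps


def velocity(agent: AgentTrajectory, fps: float) -> FrameSeries:
    """Per-marker speed series; the scene scalar is its overall mean."""
    return FrameSeries(speed_series(agent, fps), "VEL")


def acceleration(agent: AgentTrajectory, fps: float) -> FrameSeries:
    """Absolute rate of change of each marker's speed (mm/s^2)."""
    if agent.frames < 3:
        raise ValueError("acceleration needs at least 3 frames")
    spd = speed_series(agent, fps)
    return FrameSeries(np.abs(np.diff(spd, axis=0)) * fps, "ACC")


def vertical_movement(agent: AgentTrajectory) -> float:
    """Cumulative |dz| path over the clip, averaged over markers (mm)."""
    z = agent.anatomical_coords()[:, :, 2]
    return float(np.mean(np.sum(np.abs(np.diff(z, axis=0)), axis=0)))


def volume_series(agent: AgentTrajectory) -> np.ndarray:
    """(frames,) axis-aligned bounding-box volume of the 13 points, in m^3."""
    pts = agent.anatomical_coords()
    extent = pts.max(axis=1) - pts.min(axis=1)  # (frames, 3)
    return np.prod(extent, axis=1) * MM3_TO_M3


def volume(agent: AgentTrajectory) -> tuple[float, float]:
    """Time mean and time SD of the bounding-box volume (m^3)."""
    vols = volume_series(agent)
    return float(vols.mean()), float(vols.std())


def _midline_frame(agent: AgentTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame sagittal plane: (origin, unit normal), normal = L->R axis.

    The plane passes through the midpoint of the shoulder- and hip-pair
    midpoints and contains the vertical; its normal is the horizontal
    left-to-right shoulder direction, so mirrored postures score zero.
    """
    l_sh, r_sh = agent.marker("l_shoulder"), agent.marker("r_shoulder")
    l_hip, r_hip = agent.marker("l_hip"), agent.marker("r_hip")
    origin = (l_sh + r_sh + l_hip + r_hip) / 4.0
    lr = (r_sh - l_sh) + (r_hip - l_hip)
    lr = lr.copy()
    lr[:, 2] = 0.0  # keep the plane vertical
    norms = np.linalg.norm(lr, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ValueError("collapsed midline: left/right marker pairs coincide")
    return origin, lr / norms


def symmetry_components(agent: AgentTrajectory) -> dict[str, np.ndarray]:
    """Raw asymmetry components per frame and L/R pair.

    Returns arrays of shape (frames, 6):

    - ``height``: |z_L - z_R| in mm
    - ``distance``: |d_L + d_R| in mm, d being the signed perpendicular
      distance to the midline plane (symmetric postures have d_L = -d_R)
    - ``arc``: chord-to-normal angular offset converted to an arc length at
      the chord radius, in mm (0 when the chord is perpendicular to the plane)
    """
    origin, normal = _midline_frame(agent)
    heights = []
    dists = []
    arcs = []
    for l_name, r_name in agent.markers.pairs:
        p_l, p_r = agent.marker(l_name), agent.marker(r_name)
        heights.append(np.abs(p_l[:, 2] - p_r[:, 2]))
        d_l = np.einsum("fi,fi->f", p_l - origin, normal)
        d_r = np.einsum("fi,fi->f", p_r - origin, normal)
        dists.append(np.abs(d_l + d_r))
        chord = p_r - p_l
        chord_len = np.linalg.norm(chord, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.abs(np.einsum("fi,fi->f", chord, normal)) / chord_len
        cosang = np.where(chord_len < 1e-12, 1.0, np.clip(cosang, -1.0, 1.0))
        theta = np.arccos(cosang)  # 0 when chord aligned with the normal
        arcs.append(theta * chord_len)
    return {
        "height": np.stack(heights, axis=1),
        "distance": np.stack(dists, axis=1),
        "arc": np.stack(arcs, axis=1),
    }


def symmetry(agent: AgentTrajectory, weights: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Composite asymmetry scalar in mm (0 = perfectly mirrored posture).

    Weighted mean (equal weights by default) of the three components of
    :func:`symmetry_components`, averaged over pairs and frames.  All three
    components are lengths, so the composite scales linearly with the body.
    """
    comp = symmetry_components(agent)
    w = np.asarray(weights, dtype=float)
    means = np.array([comp["height"].mean(), comp["distance"].mean(), comp["arc"].mean()])
    return float(w @ means / w.sum())


def limb_angle_series(agent: AgentTrajectory) -> np.ndarray:
    """(frames, 8) interior joint angles in degrees (L/R shoulder, elbow, hip, knee)."""
    angles = []
    for side in ("l", "r"):
        for vertex, end_a, end_b in _JOINTS:
            p_v = agent.marker(f"{side}_{vertex}")
            v1 = agent.marker(f"{side}_{end_a}") - p_v
            v2 = agent.marker(f"{side}_{end_b}") - p_v
            n1 = np.linalg.norm(v1, axis=1)
            n2 = np.linalg.norm(v2, axis=1)
            bad = (n1 < 1e-12) | (n2 < 1e-12)
            if bad.any():
                raise ValueError(
                    f"zero-length segment at joint {side}_{vertex}, frame {int(np.flatnonzero(bad)[0])}"
                )
            cosang = np.einsum("fi,fi->f", v1, v2) / (n1 * n2)
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.stack(angles, axis=1)


def limb_angles(agent: AgentTrajectory) -> float:
    """Mean interior joint angle over the 8 joints and all frames (degrees)."""
    return float(limb_angle_series(agent).mean())


def limb_contraction_series(agent: AgentTrajectory) -> np.ndarray:
    """(frames,) mean head-to-extremity distance (mm); larger = more extended."""
    head = agent.marker("head")
    dists = [np.linalg.norm(agent.marker(m) - head, axis=1) for m in _EXTREMITIES]
    return np.mean(dists, axis=0)


def limb_contraction(agent: AgentTrajectory) -> float:
    return float(limb_contraction_series(agent).mean())


def reduce_intrapersonal(scene: Scene) -> dict[str, float]:
    """The 8 intrapersonal scalars of a scene, averaged over the two agents."""
    per_agent = []
    for agent in scene.agents:
        vol_mean, vol_std = volume(agent)
        per_agent.append(
            {
                "VEL": velocity(agent, scene.fps).scalar,
                "ACC": acceleration(agent, scene.fps).scalar,
                "VM": vertical_movement(agent),
                "VOL": vol_mean,
                "VOL_STD": vol_std,
                "SM": symmetry(agent),
                "LA": limb_angles(agent),
                "LC": limb_contraction(agent),
            }
        )
    return {k: 0.5 * (per_agent[0][k] + per_agent[1][k]) for k in INTRA_FEATURES}
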