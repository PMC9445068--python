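"""Data model and I/O for dyadic point-light scenes.

A scene holds two agents, each described by 15 markers tracked in 3-D
(millimetres, z vertical and up-positive) at a fixed sampling rate.  The
canonical on-disk representation is a long-form CSV with columns
``frame,agent,marker,x,y,z`` preceded by ``#``-comment header lines carrying
``fps``, ``emotion`` and ``scene_id``.  A thin C3D adapter is provided behind
the same contract for real motion-capture exports (requires ``ezc3d``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_NAMES",
    "MarkerSet",
    "AgentTrajectory",
    "Scene",
    "SceneFormatError",
    "read_scene",
    "write_scene",
    "read_dataset",
    "write_dataset",
]

#: Canonical marker roles, in fixed column order.
MARKER_NAMES: tuple[str, ...] = (
    "head",
    "sternum",
    "sacrum",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_wrist",
    "r_wrist",
    "l_hip",
    "r_hip",
    "l_knee",
    "r_knee",
    "l_ankle",
    "r_ankle",
)

_NON_ANATOMICAL = ("sternum", "sacrum")


class SceneFormatError(ValueError):
    """Raised when a file or array does not satisfy the scene contract."""


@dataclass(frozen=True)
class MarkerSet:
    """The 15 marker roles, the anatomical 13-subset and the 6 L/R pairs."""

    names: tuple[str, ...] = MARKER_NAMES

    def __post_init__(self) -> None:
        if len(self.names) != 15:
            raise SceneFormatError(f"expected 15 marker names, got {len(self.names)}")
        if len(set(self.names)) != 15:
            raise SceneFormatError("marker names must be unique")

    @property
    def anatomical_13(self) -> tuple[str, ...]:
        """All markers except sternum and sacrum."""
        return tuple(n for n in self.names if n not in _NON_ANATOMICAL)

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """Left/right marker correspondences (shoulder..ankle)."""
        out = []
        for n in self.names:
            if n.startswith("l_"):
                twin = "r_" + n[2:]
                if twin not in self.names:
                    raise SceneFormatError(f"missing right twin for {n}")
                out.append((n, twin))
        return tuple(out)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.names.index(n) for n in names], dtype=int)


DEFAULT_MARKERS = MarkerSet()

#: Accepted spelling variants for marker labels in input files.
DEFAULT_ALIASES: dict[str, str] = {}
for _n in MARKER_NAMES:
    DEFAULT_ALIASES[_n] = _n
    DEFAULT_ALIASES[_n.upper()] = _n
    DEFAULT_ALIASES[_n.replace("l_", "left_").replace("r_", "right_")] = _n
    DEFAULT_ALIASES[_n.replace("_", "")] = _n


@dataclass
class AgentTrajectory:
    """Marker positions of one agent: frames x 15 markers x 3 (mm)."""

    coords: np.ndarray
    markers: MarkerSet = field(default_factory=MarkerSet)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (15, 3):
            raise SceneFormatError(
                f"coords must be (frames, 15, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 2:
            raise SceneFormatError("an agent trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise SceneFormatError("non-finite coordinates after loading")

    @property
    def frames(self) -> int:
        return self.coords.shape[0]

    @property
    def marker_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.markers.names)}

    def marker(self, name: str) -> np.ndarray:
        """(frames, 3) positions of one marker."""
        return self.coords[:, self.markers.index(name), :]

    def anatomical_coords(self) -> np.ndarray:
        """(frames, 13, 3) positions of the anatomical subset."""
        idx = self.markers.indices(self.markers.anatomical_13)
        return self.coords[:, idx, :]


@dataclass
class Scene:
    """One dyadic interaction clip."""

    agents: tuple[AgentTrajectory, AgentTrajectory]
    fps: float = 100.0
    emotion: str | None = None
    scene_id: str = "scene"

    def __post_init__(self) -> None:
        if len(self.agents) != 2:
            raise SceneFormatError(f"a scene needs exactly 2 agents, got {len(self.agents)}")
        a, b = self.agents
        if a.frames != b.frames:
            raise SceneFormatError("both agents must share the frame count")
        if self.fps <= 0:
            raise SceneFormatError("fps must be positive")

    @property
    def frames(self) -> int:
        return self.agents[0].frames

    @property
    def duration(self) -> float:
        return self.frames / self.fps


def _fill_gaps(values: np.ndarray, max_gap: int, marker: str, agent: str) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; larger runs error."""
    out = values.copy()
    for axis in range(out.shape[1]):
        col = out[:, axis]
        bad = ~np.isfinite(col)
        if not bad.any():
            continue
        # locate runs of consecutive NaNs
        idx = np.flatnonzero(bad)
        runs: list[tuple[int, int]] = []
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                runs.append((start, prev))
                start = i
            prev = i
        runs.append((start, prev))
        for lo, hi in runs:
            length = hi - lo + 1
            if length > max_gap:
                raise SceneFormatError(
                    f"gap of {length} frames in marker '{marker}' of agent {agent} "
                    f"exceeds max_gap={max_gap}"
                )
            if lo == 0 or hi == len(col) - 1:
                raise SceneFormatError(
                    f"gap at clip boundary in marker '{marker}' of agent {agent} "
                    "cannot be interpolated"
                )
        good = np.flatnonzero(~bad)
        col[bad] = np.interp(np.flatnonzero(bad), good, col[good])
        out[:, axis] = col
    return out


def _parse_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    meta[key] = val
    return meta


def read_scene(
    path: str | Path,
    format: str = "tabular",
    *,
    fps: float | None = None,
    aliases: Mapping[str, str] | None = None,
    max_gap: int = 5,
    markers: MarkerSet = DEFAULT_MARKERS,
) -> Scene:
    """Read a two-agent scene from a tabular CSV or a C3D file.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tabular"`` (canonical CSV dialect) or ``"c3d"``.
    fps
        Overrides the sampling rate recorded in the file; defaults to the
        file header, else 100 Hz.
    aliases
        Mapping from file marker labels to canonical roles; merged over the
        built-in alias table.
    max_gap
        Longest run of missing samples (frames) repaired by linear
        interpolation; longer gaps raise :class:`SceneFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "c3d":
        return _read_c3d(path, fps=fps, aliases=aliases, max_gap=max_gap, markers=markers)
    if format != "tabular":
        raise ValueError(f"unknown format {format!r}")

    alias_table = dict(DEFAULT_ALIASES)
    if aliases:
        alias_table.update(aliases)

    meta = _parse_header(path)
    table = pd.read_csv(path, comment="#")
    required = {"frame", "agent", "marker", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise SceneFormatError(
            f"tabular scene needs columns {sorted(required)}, got {list(table.columns)}"
        )

    agent_ids = sorted(table["agent"].unique())
    if len(agent_ids) != 2:
        raise SceneFormatError(f"agent count must be 2, got {len(agent_ids)}")

    frames = np.sort(table["frame"].unique())
    n_frames = len(frames)
    frame_pos = {f: i for i, f in enumerate(frames)}

    agents = []
    for aid in agent_ids:
        sub = table[table["agent"] == aid]
        coords = np.full((n_frames, 15, 3), np.nan)
        seen: set[str] = set()
        for label, grp in sub.groupby("marker"):
            canon = alias_table.get(str(label))
            if canon is None:
                raise SceneFormatError(f"unknown marker label '{label}' for agent {aid}")
            seen.add(canon)
            col = markers.index(canon)
            rows = [frame_pos[f] for f in grp["frame"].to_numpy()]
            coords[rows, col, :] = grp[["x", "y", "z"]].to_numpy(dtype=float)
        missing = set(markers.names) - seen
        if missing:
            raise SceneFormatError(
                f"missing marker label(s) {sorted(missing)} for agent {aid}"
            )
        for col, name in enumerate(markers.names):
            coords[:, col, :] = _fill_gaps(coords[:, col, :], max_gap, name, str(aid))
        agents.append(AgentTrajectory(coords, markers))

    rate = fps if fps is not None else float(meta.get("fps", 100.0))
    return Scene(
        agents=(agents[0], agents[1]),
        fps=rate,
        emotion=meta.get("emotion") or None,
        scene_id=meta.get("scene_id", path.stem),
    )


def _read_c3d(
    path: Path,
    *,
    fps: float | None,
    aliases: Mapping[str, str] | None,
    max_gap: int,
    markers: MarkerSet,
) -> Scene:
    """C3D adapter: expects 30 point labels prefixed ``A1_``/``A2_``."""
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional dependency 'ezc3d'"
        ) from exc

    alias_table = dict(DEFAULT_ALIASES)
    if aliases:
        alias_table.update(aliases)

    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    rate = fps if fps is not None else float(c3d["parameters"]["POINT"]["RATE"]["value"][0])

    per_agent: dict[str, dict[str, np.ndarray]] = {"1": {}, "2": {}}
    for j, label in enumerate(labels):
        if "_" not in label:
            raise SceneFormatError(f"C3D label '{label}' lacks an agent prefix (A1_/A2_)")
        prefix, rest = label.split("_", 1)
        aid = prefix[-1]
        if aid not in per_agent:
            raise SceneFormatError(f"C3D label '{label}' has unknown agent prefix")
        canon = alias_table.get(rest)
        if canon is None:
            raise SceneFormatError(f"unknown marker label '{rest}' in C3D file")
        per_agent[aid][canon] = points[:3, j, :].T  # (frames, 3)

    agents = []
    for aid in ("1", "2"):
        got = per_agent[aid]
        missing = set(markers.names) - set(got)
        if missing:
            raise SceneFormatError(f"missing marker label(s) {sorted(missing)} for agent {aid}")
        n_frames = next(iter(got.values())).shape[0]
        coords = np.empty((n_frames, 15, 3))
        for col, name in enumerate(markers.names):
            coords[:, col, :] = _fill_gaps(got[name], max_gap, name, aid)
        agents.append(AgentTrajectory(coords, markers))
    return Scene(agents=(agents[0], agents[1]), fps=rate, scene_id=path.stem)


def write_scene(scene: Scene, path: str | Path) -> None:
    """Write a scene in the canonical tabular dialect (lossless to 1e-7 mm)."""
    path = Path(path)
    lines = [f"# fps={scene.fps:g} scene_id={scene.scene_id}"]
    if scene.emotion:
        lines[0] += f" emotion={scene.emotion}"
    lines.append("frame,agent,marker,x,y,z")
    for aid, agent in enumerate(scene.agents, start=1):
        for col, name in enumerate(agent.markers.names):
            xyz = agent.coords[:, col, :]
            for f in range(agent.frames):
                lines.append(
                    f"{f},{aid},{name},{xyz[f, 0]:.7f},{xyz[f, 1]:.7f},{xyz[f, 2]:.7f}"
                )
    path.write_text("\n".join(lines) + "\n")


def write_dataset(scenes: Sequence[Scene], out_dir: str | Path) -> Path:
    """Write one CSV per scene plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for scene in scenes:
        fname = f"{scene.scene_id}.csv"
        write_scene(scene, out_dir / fname)
        entries.append({"scene_id": scene.scene_id, "emotion": scene.emotion, "path": fname})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(entries, indent=1))
    return manifest


def read_dataset(manifest_path: str | Path, **kwargs) -> list[Scene]:
    """Read every scene listed in a manifest written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    entries = json.loads(manifest_path.read_text())
    scenes = []
    for entry in entries:
        scene = read_scene(manifest_path.parent / entry["path"], **kwargs)
        scene.scene_id = entry["scene_id"]
        scene.emotion = entry.get("emotion")
        scenes.append(scene)
    return scenes
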