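"""Independent brute-force reimplementations used as test oracles.

Everything here is written with explicit Python loops and scalar math,
deliberately avoiding the vectorized code paths of the package, so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

ANATOMICAL = [
    "head",
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
]
PAIRS = [
    ("l_shoulder", "r_shoulder"),
    ("l_elbow", "r_elbow"),
    ("l_wrist", "r_wrist"),
    ("l_hip", "r_hip"),
    ("l_knee", "r_knee"),
    ("l_ankle", "r_ankle"),
]
JOINTS = [
    ("shoulder", "elbow", "hip"),
    ("elbow", "shoulder", "wrist"),
    ("hip", "shoulder", "knee"),
    ("knee", "hip", "ankle"),
]


def _pos(agent, name, f):
    return agent.coords[f, agent.markers.index(name), :]


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def o_speed_matrix(agent, fps):
    """(frames-1, 13) per-step marker speeds, loop implementation."""
    out = []
    for f in range(agent.frames - 1):
        row = []
        for name in ANATOMICAL:
            row.append(_dist(_pos(agent, name, f + 1), _pos(agent, name, f)) * fps)
        out.append(row)
    return out


def o_velocity(agent, fps):
    mat = o_speed_matrix(agent, fps)
    return sum(sum(r) for r in mat) / (len(mat) * len(mat[0]))


def o_acceleration(agent, fps):
    mat = o_speed_matrix(agent, fps)
    total, count = 0.0, 0
    for f in range(len(mat) - 1):
        for m in range(len(ANATOMICAL)):
            total += abs(mat[f + 1][m] - mat[f][m]) * fps
            count += 1
    return total / count


def o_vertical_movement(agent):
    sums = []
    for name in ANATOMICAL:
        s = 0.0
        for f in range(agent.frames - 1):
            s += abs(_pos(agent, name, f + 1)[2] - _pos(agent, name, f)[2])
        sums.append(s)
    return sum(sums) / len(sums)


def o_volume(agent):
    vols = []
    for f in range(agent.frames):
        pts = [_pos(agent, n, f) for n in ANATOMICAL]
        v = 1.0
        for axis in range(3):
            coords = [p[axis] for p in pts]
            v *= max(coords) - min(coords)
        vols.append(v * 1e-9)
    mean = sum(vols) / len(vols)
    var = sum((v - mean) ** 2 for v in vols) / len(vols)
    return mean, math.sqrt(var)


def o_symmetry(agent):
    """Composite asymmetry per the documented midline-plane contract."""
    total, count = 0.0, 0
    for f in range(agent.frames):
        l_sh, r_sh = _pos(agent, "l_shoulder", f), _pos(agent, "r_shoulder", f)
        l_hip, r_hip = _pos(agent, "l_hip", f), _pos(agent, "r_hip", f)
        origin = [(l_sh[i] + r_sh[i] + l_hip[i] + r_hip[i]) / 4.0 for i in range(3)]
        lr = [
            (r_sh[0] - l_sh[0]) + (r_hip[0] - l_hip[0]),
            (r_sh[1] - l_sh[1]) + (r_hip[1] - l_hip[1]),
            0.0,
        ]
        nrm = math.sqrt(lr[0] ** 2 + lr[1] ** 2)
        normal = [lr[0] / nrm, lr[1] / nrm, 0.0]
        for l_name, r_name in PAIRS:
            p_l, p_r = _pos(agent, l_name, f), _pos(agent, r_name, f)
            height = abs(p_l[2] - p_r[2])
            d_l = sum((p_l[i] - origin[i]) * normal[i] for i in range(3))
            d_r = sum((p_r[i] - origin[i]) * normal[i] for i in range(3))
            distance = abs(d_l + d_r)
            chord = [p_r[i] - p_l[i] for i in range(3)]
            clen = math.sqrt(sum(c**2 for c in chord))
            if clen < 1e-12:
                arc = 0.0
            else:
                cosang = abs(sum(chord[i] * normal[i] for i in range(3))) / clen
                arc = math.acos(max(-1.0, min(1.0, cosang))) * clen
            total += (height + distance + arc) / 3.0
            count += 1
    return total / count


def o_limb_angles(agent):
    total, count = 0.0, 0
    for f in range(agent.frames):
        for side in ("l", "r"):
            for vertex, end_a, end_b in JOINTS:
                pv = _pos(agent, f"{side}_{vertex}", f)
                v1 = [a - b for a, b in zip(_pos(agent, f"{side}_{end_a}", f), pv)]
                v2 = [a - b for a, b in zip(_pos(agent, f"{side}_{end_b}", f), pv)]
                n1 = math.sqrt(sum(c**2 for c in v1))
                n2 = math.sqrt(sum(c**2 for c in v2))
                cosang = sum(a * b for a, b in zip(v1, v2)) / (n1 * n2)
                total += math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                count += 1
    return total / count


def o_limb_contraction(agent):
    total, count = 0.0, 0
    for f in range(agent.frames):
        head = _pos(agent, "head", f)
        for name in ("l_wrist", "r_wrist", "l_ankle", "r_ankle"):
            total += _dist(head, _pos(agent, name, f))
            count += 1
    return total / count


def o_centroid(agent, f):
    pts = [_pos(agent, n, f) for n in ANATOMICAL]
    return [sum(p[i] for p in pts) / len(pts) for i in range(3)]


def o_ipd_profile(scene):
    a1, a2 = scene.agents
    return [_dist(o_centroid(a1, f), o_centroid(a2, f)) for f in range(scene.frames)]


def o_arm_length(agent):
    total, count = 0.0, 0
    for f in range(agent.frames):
        for side in ("l", "r"):
            sh = _pos(agent, f"{side}_shoulder", f)
            el = _pos(agent, f"{side}_elbow", f)
            wr = _pos(agent, f"{side}_wrist", f)
            total += _dist(sh, el) + _dist(el, wr)
            count += 1
    return total / count


def o_personal_space(scene):
    ipd = o_ipd_profile(scene)
    arm = (o_arm_length(scene.agents[0]) + o_arm_length(scene.agents[1])) / 2.0
    return 100.0 * sum(1 for d in ipd if d < arm) / len(ipd)


def o_facing(scene, cone_deg=45.0):
    """Per-agent list of per-frame facing booleans."""
    out = []
    for idx, agent in enumerate(scene.agents):
        partner = scene.agents[1 - idx]
        flags = []
        for f in range(agent.frames):
            l_sh = _pos(agent, "l_shoulder", f)
            r_sh = _pos(agent, "r_shoulder", f)
            chord = [r_sh[0] - l_sh[0], r_sh[1] - l_sh[1]]
            normal = [-chord[1], chord[0]]
            nrm = math.sqrt(normal[0] ** 2 + normal[1] ** 2)
            normal = [normal[0] / nrm, normal[1] / nrm]
            mid = [(l_sh[0] + r_sh[0]) / 2.0, (l_sh[1] + r_sh[1]) / 2.0]
            head = _pos(agent, "head", f)
            stern = _pos(agent, "sternum", f)
            hint = [
                (head[0] + stern[0]) / 2.0 - mid[0],
                (head[1] + stern[1]) / 2.0 - mid[1],
            ]
            if normal[0] * hint[0] + normal[1] * hint[1] < 0:
                normal = [-normal[0], -normal[1]]
            own = o_centroid(agent, f)
            other = o_centroid(partner, f)
            to_p = [other[0] - own[0], other[1] - own[1]]
            tn = math.sqrt(to_p[0] ** 2 + to_p[1] ** 2)
            if tn == 0:
                flags.append(False)
                continue
            cosang = (normal[0] * to_p[0] + normal[1] * to_p[1]) / tn
            flags.append(cosang > math.cos(math.radians(cone_deg)))
        out.append(flags)
    return out


def o_orientation(scene, cone_deg=45.0):
    f1, f2 = o_facing(scene, cone_deg)
    ipo = 50.0 * (sum(f1) / len(f1) + sum(f2) / len(f2))
    t1, t2 = sum(f1), sum(f2)
    bal = 0.0 if t1 + t2 == 0 else 1.0 - abs(t1 - t2) / (t1 + t2)
    return ipo, bal


def o_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def o_mean_speed_profile(agent, fps):
    mat = o_speed_matrix(agent, fps)
    return [sum(r) / len(r) for r in mat]


def o_distance_correlation(scene, profile):
    a1, a2 = scene.agents
    fps = scene.fps
    if profile == "VEL":
        p1 = o_mean_speed_profile(a1, fps)
        p2 = o_mean_speed_profile(a2, fps)
    elif profile == "ACC":
        s1 = o_mean_speed_profile(a1, fps)
        s2 = o_mean_speed_profile(a2, fps)
        p1 = [abs(s1[i + 1] - s1[i]) * fps for i in range(len(s1) - 1)]
        p2 = [abs(s2[i + 1] - s2[i]) * fps for i in range(len(s2) - 1)]
    elif profile == "VOL":
        p1 = [o_frame_volume(a1, f) for f in range(a1.frames)]
        p2 = [o_frame_volume(a2, f) for f in range(a2.frames)]
    elif profile == "LC":
        p1 = [o_frame_lc(a1, f) for f in range(a1.frames)]
        p2 = [o_frame_lc(a2, f) for f in range(a2.frames)]
    else:
        raise ValueError(profile)
    avg = [(a + b) / 2.0 for a, b in zip(p1, p2)]
    ipd = o_ipd_profile(scene)[: len(avg)]
    return o_pearson(ipd, avg)


def o_frame_volume(agent, f):
    pts = [_pos(agent, n, f) for n in ANATOMICAL]
    v = 1.0
    for axis in range(3):
        coords = [p[axis] for p in pts]
        v *= max(coords) - min(coords)
    return v * 1e-9


def o_frame_lc(agent, f):
    head = _pos(agent, "head", f)
    return sum(
        _dist(head, _pos(agent, n, f)) for n in ("l_wrist", "r_wrist", "l_ankle", "r_ankle")
    ) / 4.0


def o_synchronization(scene, profile):
    a1, a2 = scene.agents
    s1 = o_mean_speed_profile(a1, scene.fps)
    s2 = o_mean_speed_profile(a2, scene.fps)
    if profile == "ACC":
        s1 = [abs(s1[i + 1] - s1[i]) * scene.fps for i in range(len(s1) - 1)]
        s2 = [abs(s2[i + 1] - s2[i]) * scene.fps for i in range(len(s2) - 1)]
    return o_pearson(s1, s2)


def o_motion_energy_balance(scene):
    energies = []
    for agent in scene.agents:
        e = 0.0
        for f in range(agent.frames - 1):
            step = sum(
                _dist(_pos(agent, n, f + 1), _pos(agent, n, f)) for n in ANATOMICAL
            ) / len(ANATOMICAL)
            e += step
        energies.append(e)
    e1, e2 = energies
    if e1 + e2 == 0:
        return 0.0
    return 1.0 - abs(e1 - e2) / (e1 + e2)


def o_tau_a(x, y):
    """Kendall tau-A by full pair enumeration (ties in denominator only)."""
    m = len(x)
    c = d = 0
    for i in range(m):
        for j in range(i + 1, m):
            s = (x[i] - x[j]) * (y[i] - y[j])
            if s > 0:
                c += 1
            elif s < 0:
                d += 1
    return (c - d) / (m * (m - 1) / 2.0)


def o_anova_f(groups):
    """One-way ANOVA F from explicit sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_b = sum(len(g) * ((sum(g) / len(g)) - grand) ** 2 for g in groups)
    ss_w = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_b / df_b) / (ss_w / df_w), ss_b / (ss_b + ss_w)
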