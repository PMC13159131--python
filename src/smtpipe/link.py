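"""Assemble per-frame detections into trajectories.

Frame-to-frame correspondences minimize the total squared displacement
over a bipartite matching (Hungarian algorithm) with a gate at ``r_max``
and birth/death costs of r_max², so a detection prefers staying
unmatched over an implausibly long link.  A second pass closes gaps:
track ends are matched to later track starts across up to ``gap_max``
missing frames, with the squared distance divided by the frame gap
(diffusive scaling) and a gate of r_max·√gap.  Tracks shorter than
``min_len`` are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .localize import SpotDetection
from .simulate import Trajectory

log = logging.getLogger(__name__)

#: above this many candidates in one frame pair, fall back to greedy matching
GREEDY_LIMIT = 500
_BIG = 1e12


@dataclass(frozen=True)
class LinkConfig:
    """Linker parameters: gate radius (µm), max closed gap (frames),
    minimum kept trajectory length (frames).

    The default gate 2.5 µm ≈ 4·√(4·D·dt) at D = 1 µm²/s, dt = 0.1 s,
    which keeps the per-step miss probability below 1e-3 over the D
    range of interest.
    """

    r_max: float = 2.5
    gap_max: int = 1
    min_len: int = 20

    def __post_init__(self) -> None:
        if not self.r_max > 0:
            raise ValueError(f"r_max must be > 0, got {self.r_max}")
        if self.gap_max < 0:
            raise ValueError(f"gap_max must be >= 0, got {self.gap_max}")
        if self.min_len < 2:
            raise ValueError(f"min_len must be >= 2, got {self.min_len}")


def _match_pair(p1: np.ndarray, p2: np.ndarray, gate: float,
                cost_scale: float = 1.0) -> list[tuple[int, int]]:
    """Gated min-total-squared-displacement assignment between two point sets.

    Returns (i, j) index pairs.  Uses the augmented square cost matrix
    with birth/death at gate² so unmatched points are allowed; falls
    back to greedy nearest-pair matching above GREEDY_LIMIT candidates.
    """
    n1, n2 = len(p1), len(p2)
    if n1 == 0 or n2 == 0:
        return []
    d2 = ((p1[:, None, :] - p2[None, :, :]) ** 2).sum(axis=2) * cost_scale
    gate2 = gate * gate * cost_scale

    if n1 + n2 > GREEDY_LIMIT:
        log.warning("frame pair with %d candidates: greedy fallback", n1 + n2)
        pairs = []
        order = np.argsort(d2, axis=None)
        used1: set[int] = set()
        used2: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), n2)
            if d2[i, j] > gate2:
                break
            if i in used1 or j in used2:
                continue
            pairs.append((i, j))
            used1.add(i)
            used2.add(j)
        return pairs

    cost = np.full((n1 + n2, n1 + n2), 0.0)
    block = np.where(d2 <= gate2, d2, _BIG)
    cost[:n1, :n2] = block
    cost[:n1, n2:] = _BIG
    cost[n1:, :n2] = _BIG
    np.fill_diagonal(cost[:n1, n2:], gate2)  # death
    np.fill_diagonal(cost[n1:, :n2], gate2)  # birth
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < n1 and j < n2 and d2[i, j] <= gate2
    ]


def link(
    detections_by_frame: dict[int, list[SpotDetection]],
    config: LinkConfig | None = None,
) -> list[Trajectory]:
    """Link detections into trajectories (empty input → empty output).

    Each detection belongs to at most one trajectory; per-step
    displacements respect the gate except across closed gaps, where the
    diffusive gate r_max·√gap applies.
    """
    if config is None:
        config = LinkConfig()
    frames = sorted(f for f, dets in detections_by_frame.items() if len(dets) > 0)
    if not frames:
        return []
    pts = {f: np.array([[d.x, d.y] for d in detections_by_frame[f]]) for f in frames}

    # pass 1: frame-to-frame segments
    segments: list[list[tuple[int, int]]] = []  # list of (frame, det_index)
    open_by_det: dict[tuple[int, int], int] = {}  # (frame, det_idx) -> segment id
    for k, f in enumerate(frames):
        for i in range(len(pts[f])):
            key = (f, i)
            if key not in open_by_det:
                segments.append([key])
                open_by_det[key] = len(segments) - 1
        if k + 1 >= len(frames):
            break
        f2 = frames[k + 1]
        if f2 != f + 1:
            continue  # not consecutive: left for the gap-closing pass
        for i, j in _match_pair(pts[f], pts[f2], config.r_max):
            sid = open_by_det[(f, i)]
            segments[sid].append((f2, j))
            open_by_det[(f2, j)] = sid

    # pass 2: close gaps between segment ends and starts
    if config.gap_max > 0 and len(segments) > 1:
        ends = np.array([s[-1][0] for s in segments])
        starts = np.array([s[0][0] for s in segments])
        end_pts = np.array([pts[s[-1][0]][s[-1][1]] for s in segments])
        start_pts = np.array([pts[s[0][0]][s[0][1]] for s in segments])
        n_seg = len(segments)
        cost = np.full((n_seg, n_seg), _BIG)
        for a in range(n_seg):
            gaps = starts - ends[a] - 1  # missing frames between a's end and b's start
            for b in range(n_seg):
                g = gaps[b]
                if a == b or g < 1 or g > config.gap_max:
                    continue
                d2 = float(((end_pts[a] - start_pts[b]) ** 2).sum())
                if d2 <= config.r_max**2 * (g + 1):
                    cost[a, b] = d2 / (g + 1)
        if (cost < _BIG).any():
            rows, cols = linear_sum_assignment(cost)
            merges = [(a, b) for a, b in zip(rows, cols) if cost[a, b] < _BIG]
            # apply merges end-to-start, chaining transitively
            target = {a: b for a, b in merges}
            merged_into: dict[int, int] = {}
            for a in sorted(target):
                root = a
                while root in merged_into:
                    root = merged_into[root]
                b = target[a]
                segments[root].extend(segments[b])
                merged_into[b] = root
            segments = [s for i, s in enumerate(segments) if i not in merged_into]

    out: list[Trajectory] = []
    tid = 0
    for seg in segments:
        if len(seg) < config.min_len:
            continue
        seg = sorted(seg)
        fr = np.array([f for f, _ in seg])
        xy = np.array([pts[f][i] for f, i in seg])
        out.append(Trajectory(traj_id=tid, frames=fr, x=xy[:, 0], y=xy[:, 1]))
        tid += 1
    return out
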