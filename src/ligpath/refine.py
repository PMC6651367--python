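"""Continuum refinement of discrete pathways with RRT-Connect.

A GA pathway samples the ligand pose at discrete frames; straight-line
interpolation between two consecutive frames may still sweep through a
steric bottleneck.  For frame pairs whose interpolation violates a clash
threshold, a bidirectional rapidly-exploring random tree (RRT-Connect) plans
a collision-free bridge in rigid-pose space (COM translation x rotation;
torsions are frozen at the linear interpolation between the endpoint genes).
Inserted frames carry interpolated receptor state and recomputed scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .scoring import Frame, Pathway

logger = logging.getLogger("ligpath")

__all__ = [
    "Pose",
    "RefinementStep",
    "rrt_connect",
    "refine_pathway",
    "continuum_valid",
]


@dataclass
class Pose:
    """Rigid ligand pose: COM position (A) and orientation quaternion."""

    position: np.ndarray
    quat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.quat = np.asarray(self.quat, dtype=float).reshape(4)
        self.quat = self.quat / np.linalg.norm(self.quat)


@dataclass
class RefinementStep:
    step_size: float = 0.25          # A, interpolation/extension resolution
    max_iterations: int = 2000
    collision_threshold: float = 50.0  # clash volume, A^3

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")


def pose_distance(a: Pose, b: Pose, rot_weight: float = 1.0) -> float:
    """COM distance plus weighted quaternion geodesic (A per radian)."""
    trans = float(np.linalg.norm(a.position - b.position))
    dot = abs(float(np.dot(a.quat, b.quat)))
    ang = 2.0 * np.arccos(min(1.0, dot))
    return trans + rot_weight * ang


def interpolate_pose(a: Pose, b: Pose, t: float) -> Pose:
    pos = (1 - t) * a.position + t * b.position
    qa, qb = a.quat, b.quat
    if np.dot(qa, qb) < 0:
        qb = -qb
    slerp = Slerp([0.0, 1.0], Rotation.from_quat(np.vstack([qa, qb])))
    return Pose(pos, slerp([t])[0].as_quat())


def _segment_clear(a: Pose, b: Pose, collision: Callable[[Pose], float],
                   cfg: RefinementStep) -> bool:
    n = max(1, int(np.ceil(pose_distance(a, b) / cfg.step_size)))
    for k in range(1, n + 1):
        if collision(interpolate_pose(a, b, k / n)) >= cfg.collision_threshold:
            return False
    return True


def _extend(tree: list[tuple[Pose, int]], target: Pose,
            collision: Callable[[Pose], float], cfg: RefinementStep) -> Optional[int]:
    """Greedy 'connect' extension of the nearest node toward ``target``.

    Returns the index of the node reaching ``target`` (exact), or None if the
    extension stalls before arriving.
    """
    near_idx = min(range(len(tree)), key=lambda i: pose_distance(tree[i][0], target))
    cur, parent = tree[near_idx][0], near_idx
    while True:
        d = pose_distance(cur, target)
        if d <= cfg.step_size:
            if collision(target) < cfg.collision_threshold and \
                    _segment_clear(cur, target, collision, cfg):
                tree.append((target, parent))
                return len(tree) - 1
            return None
        nxt = interpolate_pose(cur, target, cfg.step_size / d)
        if collision(nxt) >= cfg.collision_threshold:
            return None
        tree.append((nxt, parent))
        parent = len(tree) - 1
        cur = nxt


def _walk_back(tree: list[tuple[Pose, int]], idx: int) -> list[Pose]:
    out = []
    while idx != -1:
        out.append(tree[idx][0])
        idx = tree[idx][1]
    return out[::-1]


def rrt_connect(start: Pose, goal: Pose, collision: Callable[[Pose], float],
                cfg: RefinementStep, rng: np.random.Generator,
                sample_radius: float = 10.0) -> list[Pose]:
    """Plan a collision-free pose sequence from start to goal.

    Returns the intermediate poses (start and goal excluded); raises
    ``RuntimeError`` when ``max_iterations`` is exhausted.  Samples are drawn
    inside a ball of ``sample_radius`` A around the segment midpoint with
    uniformly random orientations.
    """
    if collision(start) >= cfg.collision_threshold or \
            collision(goal) >= cfg.collision_threshold:
        raise ValueError("start or goal pose already violates the collision threshold")
    if pose_distance(start, goal) < 1e-12:
        return []
    if _segment_clear(start, goal, collision, cfg):
        n = max(1, int(np.ceil(pose_distance(start, goal) / cfg.step_size)))
        return [interpolate_pose(start, goal, k / n) for k in range(1, n)]

    tree_a: list[tuple[Pose, int]] = [(start, -1)]
    tree_b: list[tuple[Pose, int]] = [(goal, -1)]
    mid = 0.5 * (start.position + goal.position)

    for it in range(cfg.max_iterations):
        # goal-biased random sample
        if rng.random() < 0.2:
            sample = tree_b[0][0] if it % 2 == 0 else tree_a[0][0]
        else:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = mid + u * sample_radius * rng.random() ** (1 / 3)
            quat = Rotation.random(random_state=np.random.RandomState(
                int(rng.integers(2 ** 31)))).as_quat()
            sample = Pose(pos, quat)

        grow, other = (tree_a, tree_b) if it % 2 == 0 else (tree_b, tree_a)
        # grow toward the sample (partial extension is fine)
        near_idx = min(range(len(grow)), key=lambda i: pose_distance(grow[i][0], sample))
        cur, parent = grow[near_idx][0], near_idx
        d = pose_distance(cur, sample)
        if d > 1e-9:
            nxt = interpolate_pose(cur, sample, min(1.0, cfg.step_size / d))
            if collision(nxt) < cfg.collision_threshold:
                grow.append((nxt, parent))
                # connect: drive the other tree toward the new node
                reached = _extend(other, nxt, collision, cfg)
                if reached is not None:
                    a_part = _walk_back(grow, len(grow) - 1)
                    b_part = _walk_back(other, reached)
                    if grow is tree_a:
                        seq = a_part + b_part[::-1][1:]
                    else:
                        seq = b_part + a_part[::-1][1:]
                    return seq[1:-1]
    raise RuntimeError(f"rrt_connect: no path within {cfg.max_iterations} iterations")


def continuum_valid(pathway: Pathway, cfg: RefinementStep) -> bool:
    """Check every consecutive frame pair by dense pose interpolation."""
    frames = pathway.frames
    for t in range(len(frames) - 1):
        a, b, collision = _pair_poses(pathway, t)
        if not _segment_clear(a, b, cfg=cfg, collision=collision):
            return False
    return True


def _pair_poses(pathway: Pathway, t: int):
    """Start/goal poses and a pose-collision closure for frame pair (t, t+1).

    The pose space is the rigid motion of the frame-t ligand conformation;
    the receptor is frozen at the frame-t state.
    """
    from .scoring import FrameScorer

    fa, fb = pathway.frames[t], pathway.frames[t + 1]
    m = pathway.ligand.masses[:, None]
    com_a = (fa.ligand_coords * m).sum(0) / m.sum()
    com_b = (fb.ligand_coords * m).sum(0) / m.sum()
    local = fa.ligand_coords - com_a
    # relative rotation taking frame-t local coords onto frame-t+1
    rot, _ = Rotation.align_vectors(fb.ligand_coords - com_b, local) \
        if len(local) >= 3 else (Rotation.identity(), None)
    start = Pose(com_a, Rotation.identity().as_quat())
    goal = Pose(com_b, rot.as_quat())

    scorer = pathway._scorer if hasattr(pathway, "_scorer") else \
        FrameScorer(pathway.ligand, pathway.receptor)
    rec = fa.receptor_coords

    def collision(p: Pose) -> float:
        xyz = Rotation.from_quat(p.quat).apply(local) + p.position
        return scorer.clash(xyz, rec)

    return start, goal, collision


def refine_pathway(pathway: Pathway, cfg: Optional[RefinementStep] = None,
                   rng: Optional[np.random.Generator] = None) -> Pathway:
    """Bridge every bottlenecked frame pair of a scored pathway.

    Original frames are kept in order; bridges are inserted between them.
    Inserted frames take the receptor state of the earlier frame and carry
    recomputed clash scores.  Pairs the planner cannot solve are annotated
    (``gap=True`` left in the frame's scores) and kept as-is.
    """
    from .scoring import FrameScorer

    cfg = RefinementStep() if cfg is None else cfg
    rng = np.random.default_rng() if rng is None else rng
    scorer = FrameScorer(pathway.ligand, pathway.receptor)

    new_frames: list[Frame] = []
    for t in range(len(pathway.frames) - 1):
        fa = pathway.frames[t]
        new_frames.append(fa)
        start, goal, collision = _pair_poses(pathway, t)
        if _segment_clear(start, goal, collision, cfg):
            continue
        m = pathway.ligand.masses[:, None]
        local = fa.ligand_coords - (fa.ligand_coords * m).sum(0) / m.sum()
        try:
            bridge = rrt_connect(start, goal, collision, cfg, rng)
        except (RuntimeError, ValueError) as exc:
            logger.warning("frame pair %d-%d not bridged: %s", t, t + 1, exc)
            fa.scores = dict(fa.scores or {}, gap=True)
            continue
        for pose in bridge:
            xyz = Rotation.from_quat(pose.quat).apply(local) + pose.position
            clash = scorer.clash(xyz, fa.receptor_coords)
            new_frames.append(Frame(xyz, fa.receptor_coords, fa.mutated_residues,
                                    scores={"clashes": clash, "vina": None,
                                            "smoothness": None, "inserted": True}))
    new_frames.append(pathway.frames[-1])
    return Pathway(pathway.ligand, pathway.receptor, new_frames,
                   pathway.objectives, pathway.objective_values)
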