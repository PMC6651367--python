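"""Generation, mutation and recombination of ligand translation paths.

A path is an ordered sequence of ligand centre-of-mass waypoints.  Two
geometric constraints shape it: the distance between consecutive waypoints
never exceeds ``max_step`` (set automatically from the ligand size unless the
user overrides it), and the distance from the origin must grow by at least
``min_increment`` per frame.  A positive increment (default 0.8 A) yields
outward-driving paths; zero or negative values permit curved "U"/"S" shapes
at the cost of more frames.

Three direction modes are supported: ``unbinding`` (origin known, walk until a
stop predicate declares bulk solvent reached), ``binding`` (destination known,
starts seeded at the six ends of the receptor's principal inertia axes) and
``two_point`` (both endpoints known).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .chem import Molecule

__all__ = [
    "PathPoints",
    "PathConfigError",
    "auto_max_step",
    "init_path",
    "mutate_path",
    "crossover_paths",
    "validate_path",
    "inertia_axis_starts",
    "default_stop_predicate",
]

MODES = ("unbinding", "binding", "two_point")


class PathConfigError(ValueError):
    """Infeasible or inconsistent path-gene configuration."""


@dataclass
class PathPoints:
    """Ordered ligand COM waypoints with their generating constraints."""

    origin: np.ndarray
    points: np.ndarray                      # (n, 3)
    min_increment: float = 0.8
    max_step: float = 1.0
    mode: str = "unbinding"
    destination: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.destination is not None:
            self.destination = np.asarray(self.destination, dtype=float).reshape(3)
        if self.mode not in MODES:
            raise PathConfigError(f"unknown mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.points)

    def copy(self) -> "PathPoints":
        return replace(self, points=self.points.copy())


def validate_path(path: PathPoints, atol: float = 1e-9) -> bool:
    """Check the step-length, origin-increment and destination invariants."""
    pts = np.vstack([path.origin[None], path.points])
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(steps > path.max_step + atol):
        return False
    d = np.linalg.norm(pts - path.origin, axis=1)
    if np.any(np.diff(d) < path.min_increment - atol):
        return False
    if path.mode in ("binding", "two_point"):
        if path.destination is None or len(path.points) == 0:
            return False
        if np.linalg.norm(path.points[-1] - path.destination) > path.max_step + atol:
            return False
    return True


def auto_max_step(ligand: Molecule) -> float:
    """Maximum inter-frame COM displacement, from the ligand size.

    A quarter of the ligand's bounding-sphere radius, clamped to [0.5, 1.0] A;
    a recipe value overrides this automatic choice exactly.
    """
    return float(np.clip(0.25 * ligand.bounding_radius(), 0.5, 1.0))


def inertia_axis_starts(receptor: Molecule, margin: float = 2.0) -> np.ndarray:
    """Six candidate start points: where the principal inertia axes pierce the
    receptor's bounding sphere (plus ``margin`` A of clearance)."""
    com = receptor.center_of_mass()
    x = receptor.coords - com
    m = receptor.masses
    inertia = np.einsum("i,ij,ik->jk", m, x, x)
    _, vecs = np.linalg.eigh(inertia)
    r = receptor.bounding_radius() + margin
    starts = [com + sign * r * vecs[:, k] for k in range(3) for sign in (+1.0, -1.0)]
    return np.array(starts)


def default_stop_predicate(receptor: Molecule, clearance: float = 5.0,
                           margin: float = 2.0) -> Callable[[np.ndarray], bool]:
    """Operational 'bulk solvent reached' test for unbinding walks.

    Fires when the ligand COM is beyond the receptor bounding sphere (+margin)
    and no receptor atom lies within ``clearance`` A of the waypoint.
    """
    from scipy.spatial import cKDTree

    com = receptor.center_of_mass()
    r_out = receptor.bounding_radius() + margin
    tree = cKDTree(receptor.coords)

    def stop(p: np.ndarray) -> bool:
        if np.linalg.norm(p - com) <= r_out:
            return False
        return tree.query(p, k=1)[0] > clearance

    return stop


def _sample_step(cur: np.ndarray, origin: np.ndarray, min_increment: float,
                 max_step: float, rng: np.random.Generator,
                 toward: Optional[np.ndarray] = None, n_cand: int = 16) -> np.ndarray:
    """One constrained random step from ``cur``.

    Rejection-samples candidate displacements inside the max_step sphere and
    keeps those meeting the origin-increment constraint; with a ``toward``
    goal, the feasible candidate closest to the goal wins.  Falls back to a
    radially outward step, which always satisfies min_increment <= max_step.
    """
    d_cur = np.linalg.norm(cur - origin)
    feasible = []
    for _ in range(8):
        v = rng.normal(size=(n_cand, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        lengths = max_step * rng.uniform(0.5, 1.0, size=n_cand) ** (1 / 3)
        cand = cur + v * lengths[:, None]
        ok = np.linalg.norm(cand - origin, axis=1) - d_cur >= min_increment
        feasible.extend(cand[ok])
        if feasible and toward is None:
            return feasible[int(rng.integers(len(feasible)))]
        if len(feasible) >= n_cand:
            break
    if feasible:
        arr = np.array(feasible)
        return arr[int(np.argmin(np.linalg.norm(arr - toward, axis=1)))]
    # radial fallback
    u = (cur - origin) / d_cur if d_cur > 1e-12 else _random_unit(rng)
    return cur + u * max_step


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def init_path(mode: str, origin: Optional[np.ndarray] = None,
              destination: Optional[np.ndarray] = None,
              min_increment: float = 0.8, max_step: float = 1.0,
              stop_predicate: Optional[Callable[[np.ndarray], bool]] = None,
              rng: Optional[np.random.Generator] = None,
              receptor: Optional[Molecule] = None,
              max_points: int = 500) -> PathPoints:
    """Random constrained walk in the requested direction mode.

    ``unbinding`` needs ``origin`` plus either ``stop_predicate`` or
    ``receptor`` (from which the default bulk-solvent predicate is built);
    ``binding`` needs ``destination`` (the origin is drawn from the six
    inertia-axis ends of ``receptor`` unless given); ``two_point`` needs both.
    """
    rng = np.random.default_rng() if rng is None else rng
    if min_increment > max_step:
        raise PathConfigError(
            f"min_increment ({min_increment}) > max_step ({max_step}): no step can satisfy both")
    if mode not in MODES:
        raise PathConfigError(f"unknown mode {mode!r}")

    if mode == "unbinding":
        if origin is None:
            raise PathConfigError("unbinding mode requires an origin")
        if stop_predicate is None:
            if receptor is None:
                raise PathConfigError("unbinding mode requires stop_predicate or receptor")
            stop_predicate = default_stop_predicate(receptor)
    elif mode == "binding":
        if destination is None:
            raise PathConfigError("binding mode requires a destination")
        if origin is None:
            if receptor is None:
                raise PathConfigError("binding mode requires receptor or explicit origin")
            starts = inertia_axis_starts(receptor)
            origin = starts[int(rng.integers(len(starts)))]
    else:  # two_point
        if origin is None or destination is None:
            raise PathConfigError("two_point mode requires origin and destination")

    origin = np.asarray(origin, dtype=float).reshape(3)
    toward = None if mode == "unbinding" else np.asarray(destination, dtype=float)
    pts: list[np.ndarray] = []
    cur = origin
    for _ in range(max_points):
        cur = _sample_step(cur, origin, min_increment, max_step, rng, toward=toward)
        pts.append(cur)
        if mode == "unbinding":
            if stop_predicate(cur):
                break
        elif np.linalg.norm(cur - toward) <= max_step:
            break
    else:
        if mode != "unbinding":
            raise PathConfigError(
                f"could not reach destination within {max_points} steps; "
                "check min_increment/max_step against the geometry")
    return PathPoints(origin, np.array(pts), min_increment, max_step, mode,
                      None if mode == "unbinding" else toward)


def _rewalk_tail(path: PathPoints, start_idx: int, n_tail: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Resample ``n_tail`` points continuing from points[start_idx - 1]."""
    cur = path.origin if start_idx == 0 else path.points[start_idx - 1]
    toward = path.destination if path.mode in ("binding", "two_point") else None
    tail = []
    for k in range(max(n_tail, 1) if toward is None else 4 * max(n_tail, 1)):
        cur = _sample_step(cur, path.origin, path.min_increment, path.max_step,
                           rng, toward=toward)
        tail.append(cur)
        if toward is None:
            if len(tail) >= n_tail:
                break
        elif np.linalg.norm(cur - toward) <= path.max_step:
            break
    return np.array(tail)


def mutate_path(path: PathPoints, rng: np.random.Generator) -> PathPoints:
    """Tail-resampling mutation: pick a random index and rewalk from there.

    The offspring satisfies the same constraints; in destination modes the
    tail is rewalked until it reaches the destination, so its length may
    change, while unbinding paths keep their frame count.
    """
    if len(path) == 0:
        return path.copy()
    k = int(rng.integers(len(path)))
    tail = _rewalk_tail(path, k, len(path) - k, rng)
    out = path.copy()
    out.points = np.vstack([path.points[:k], tail]) if len(tail) else path.points[:k].copy()
    return out


def perturb_waypoint(path: PathPoints, rng: np.random.Generator,
                     sigma: float = 0.3, tries: int = 20,
                     index: Optional[int] = None) -> PathPoints:
    """Local mutation: jitter one waypoint, keeping all constraints.

    Complements the tail-resampling mutation — it can polish a single frame
    (e.g. the one crossing a constriction) without rebuilding the remainder
    of the walk.  If no feasible jitter is found the path returns unchanged.
    """
    if len(path) == 0:
        return path.copy()
    out = path.copy()
    k = int(rng.integers(len(path))) if index is None else int(index) % len(path)
    for _ in range(tries):
        cand = out.points[k] + rng.normal(0, sigma, 3)
        saved = out.points[k].copy()
        out.points[k] = cand
        if validate_path(out):
            return out
        out.points[k] = saved
    return out


def crossover_paths(a: PathPoints, b: PathPoints,
                    rng: np.random.Generator) -> tuple[PathPoints, PathPoints]:
    """Nearest-point splice crossover.

    Finds the index pair (i in a, j in b) minimising the splice-point distance
    subject to the step and increment constraints holding across the joint,
    then exchanges tails.  If no feasible splice exists the parents are
    returned unchanged.  Offspring are re-validated; a broken offspring is
    repaired by resampling its tail from the splice.
    """
    if len(a) == 0 or len(b) == 0 or a.mode != b.mode:
        return a.copy(), b.copy()
    if len(a) == len(b) and np.allclose(a.points, b.points):
        return a.copy(), b.copy()

    da = np.linalg.norm(a.points - a.origin, axis=1)
    db = np.linalg.norm(b.points - b.origin, axis=1)
    dist = np.linalg.norm(a.points[:, None, :] - b.points[None, :, :], axis=2)
    step_ok = dist <= min(a.max_step, b.max_step) + 1e-9

    def build(head_path: PathPoints, head_pts: np.ndarray, tail_pts: np.ndarray) -> PathPoints:
        child = head_path.copy()
        child.points = np.vstack([head_pts, tail_pts]) if len(tail_pts) else head_pts.copy()
        if not validate_path(child):
            k = len(head_pts)
            tail = _rewalk_tail(child, k, max(len(child) - k, 1), rng)
            child.points = np.vstack([head_pts, tail]) if len(tail) else head_pts.copy()
        return child if validate_path(child) else head_path.copy()

    def splice(head: PathPoints, tail: PathPoints, feas: np.ndarray) -> PathPoints:
        # child = head[:i+1] + tail[j:]; the joint step i->j must satisfy both
        # the step bound and the origin-increment constraint
        if not feas.any():
            return head.copy()
        masked = np.where(feas, dist if head is a else dist.T, np.inf)
        i, j = np.unravel_index(int(np.argmin(masked)), masked.shape)
        return build(head, head.points[:i + 1], tail.points[j:])

    inc_ab = (db[None, :] - da[:, None]) >= a.min_increment - 1e-9
    inc_ba = (da[:, None] - db[None, :]) >= b.min_increment - 1e-9
    child1 = splice(a, b, step_ok & inc_ab)
    child2 = splice(b, a, (step_ok & inc_ba).T)
    return child1, child2
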