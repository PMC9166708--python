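"""Interhelical geometry of stacked-X junctions: helical axes and signed J_twist.

The two coaxially stacked arm pairs of a stacked-X junction form two
quasi-continuous helices.  Each helix axis is fit as the first principal
direction (total least squares) of the ordered base-pair reference points —
midpoints of the two C1' atoms of each pair — walked from the distal end of
the stack's first arm, through the branch point, to the distal end of its
second arm.  The interhelical angle (J_twist) is the dot angle of the two
unit axis directions under that orientation convention.

Handedness is resolved with a reference vector "perpendicular to" the
branch point: the vector from the centroid of stack 1's branch-pair C1'
atoms to stack 2's, orthogonalized against both axis directions.  Its dot
angle with ``cross(d1, d2)`` classifies the junction: below 90° is
right-handed, above is left-handed (equivalently, the sign of
``det[d1, d2, w]``).  Tying the reference vector to stack order makes the
sign invariant under exchanging the two stacks, while any improper (mirror)
operation flips it.  Left-handed angles are normalized by -1 to give the
signed J_twist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import AnnotationError, HJStructure, Trajectory

__all__ = [
    "HelicalAxis",
    "JTwistResult",
    "JTwistSeries",
    "AngleSummary",
    "GeometryError",
    "stack_basepair_points",
    "fit_axis",
    "jtwist",
    "jtwist_series",
    "summarize_angles",
]


class GeometryError(ValueError):
    """Axis fitting or angle computation failed."""


@dataclass(frozen=True)
class HelicalAxis:
    """A fitted helix axis: anchor point, unit direction, RMS fit residual (Å)."""

    anchor: np.ndarray
    direction: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-9):
            raise ValueError("direction must be a unit vector")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


@dataclass(frozen=True)
class JTwistResult:
    """Signed interhelical angle with handedness for one structure or frame."""

    angle: float
    handedness: str  # "right" or "left"
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        if not 0.0 <= self.angle < 180.0:
            raise ValueError("unsigned angle must lie in [0, 180)")

    @property
    def signed_angle(self) -> float:
        return self.angle if self.handedness == "right" else -self.angle


@dataclass
class JTwistSeries:
    """Per-frame J_twist results; failed frames are recorded, not fatal."""

    results: list[JTwistResult]
    failures: list[tuple[int, str]]

    @property
    def signed_angles(self) -> np.ndarray:
        return np.array([r.signed_angle for r in self.results], float)


@dataclass(frozen=True)
class AngleSummary:
    """Population summary of signed angles (degrees)."""

    n: int
    mean: float
    median: float
    std: float | None  # sample standard deviation (n-1); None when n < 2
    hist_edges: np.ndarray
    hist_counts: np.ndarray

    def __post_init__(self) -> None:
        if int(self.hist_counts.sum()) != self.n:
            raise ValueError("histogram counts must total n")


def _stack_arms(s: HJStructure, stack: int | tuple[int, int]) -> tuple[int, int]:
    if s.spec is None:
        raise AnnotationError("structure is not annotated")
    if isinstance(stack, int):
        return tuple(s.spec.stacks[stack])  # type: ignore[return-value]
    return tuple(stack)  # type: ignore[return-value]


def stack_basepair_points(
    s: HJStructure, stack: int | tuple[int, int], coords: np.ndarray | None = None
) -> np.ndarray:
    """Ordered C1' midpoints along one stack, first-arm distal to second-arm distal."""
    arm_a, arm_b = _stack_arms(s, stack)
    if coords is None:
        coords = s.coords
    pts = []
    walk = list(s.arm_residues(arm_a)) + list(reversed(s.arm_residues(arm_b)))
    for (ch_r, rn_r), (ch_p, rn_p) in walk:
        i = s.atom_index(ch_r, rn_r, "C1'")
        j = s.atom_index(ch_p, rn_p, "C1'")
        pts.append(0.5 * (coords[i] + coords[j]))
    return np.asarray(pts, float)


def fit_axis(
    s: HJStructure,
    stack: int | tuple[int, int],
    coords: np.ndarray | None = None,
) -> HelicalAxis:
    """Total-least-squares line through the stack's base-pair reference points.

    The direction is oriented from the first to the last base pair of the
    stack (first-listed arm's distal end toward the second arm's distal
    end), so it points consistently across frames.
    """
    pts = stack_basepair_points(s, stack, coords)
    if len(pts) < 4:
        raise GeometryError(
            f"stack needs >= 4 base pairs for an axis fit, got {len(pts)}"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0, atol=1e-9):
        raise GeometryError("zero spatial extent: all reference points coincide")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if d @ (pts[-1] - pts[0]) < 0:
        d = -d
    perp = centered - np.outer(centered @ d, d)
    residual = float(np.sqrt((perp**2).sum(axis=1).mean()))
    return HelicalAxis(anchor=centroid, direction=d / np.linalg.norm(d),
                       residual=residual)


def _branch_pair_c1_centroid(
    s: HJStructure, stack: tuple[int, int], coords: np.ndarray
) -> np.ndarray:
    pts = []
    for arm in stack:
        (ch_r, rn_r), (ch_p, rn_p) = s.arm_residues(arm)[-1]  # branch pair
        pts.append(coords[s.atom_index(ch_r, rn_r, "C1'")])
        pts.append(coords[s.atom_index(ch_p, rn_p, "C1'")])
    return np.mean(pts, axis=0)


def jtwist(
    s: HJStructure, coords: np.ndarray | None = None, frame: int | None = None
) -> JTwistResult:
    """Signed J_twist of one structure (or one trajectory frame's coordinates)."""
    if s.spec is None:
        raise AnnotationError("structure is not annotated")
    if coords is None:
        coords = s.coords
    ax1 = fit_axis(s, 0, coords)
    ax2 = fit_axis(s, 1, coords)
    d1, d2 = ax1.direction, ax2.direction
    cosang = float(np.clip(d1 @ d2, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    if angle >= 180.0:  # arccos(-1) exactly
        angle = np.nextafter(180.0, 0.0)

    w = _branch_pair_c1_centroid(
        s, tuple(s.spec.stacks[1]), coords
    ) - _branch_pair_c1_centroid(s, tuple(s.spec.stacks[0]), coords)
    # orthogonalize the branch reference vector against both axes
    w = w - (w @ d1) * d1
    w = w - (w @ d2) * d2
    x = np.cross(d1, d2)
    dot = float(w @ x)
    if dot == 0.0:
        warnings.warn(
            "handedness reference exactly perpendicular to the axis cross "
            "product; classifying as right-handed", stacklevel=2,
        )
        hand = "right"
    else:
        hand = "right" if dot > 0 else "left"
    return JTwistResult(angle=angle, handedness=hand, frame=frame)


def jtwist_series(t: Trajectory) -> JTwistSeries:
    """J_twist for every frame of an annotated trajectory, in frame order.

    Frames whose axis fit fails are recorded as ``(frame_index, message)``
    and the series continues.
    """
    if t.topology.spec is None:
        raise AnnotationError("trajectory topology is not annotated")
    results: list[JTwistResult] = []
    failures: list[tuple[int, str]] = []
    for i, frame in enumerate(t.frames):
        try:
            results.append(jtwist(t.topology, coords=frame, frame=i))
        except (GeometryError, KeyError) as e:
            failures.append((i, str(e)))
    return JTwistSeries(results, failures)


def summarize_angles(
    results: "JTwistSeries | list[JTwistResult] | np.ndarray",
    bins: int | np.ndarray = 36,
    range_: tuple[float, float] = (-180.0, 180.0),
) -> AngleSummary:
    """Mean / median / sample σ and histogram of signed angles."""
    if isinstance(results, JTwistSeries):
        angles = results.signed_angles
    elif len(results) and isinstance(results[0], JTwistResult):
        angles = np.array([r.signed_angle for r in results], float)
    else:
        angles = np.asarray(results, float)
    if angles.size == 0:
        raise GeometryError("cannot summarize an empty angle series")
    counts, edges = np.histogram(angles, bins=bins, range=range_)
    std = float(np.std(angles, ddof=1)) if angles.size > 1 else None
    return AngleSummary(
        n=int(angles.size),
        mean=float(angles.mean()),
        median=float(np.median(angles)),
        std=std,
        hist_edges=edges,
        hist_counts=counts,
    )
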