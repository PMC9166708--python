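"""Synthetic stacked-X junction structures and trajectories with known truth.

The generator builds an idealized stacked-X Holliday junction as two rigid,
straight B-form-like duplex stacks (constant helical rise and twist, planar
pseudo-pairs) whose axes cross near the branch point at a requested
interduplex angle and handedness.  Each stack spans two arms end-to-end
through the branch point; the four-strand topology follows the convention
of :mod:`hjkit.combinatorics` (strand ``i``: arm ``i`` reference half, then
arm ``i+1`` complementary half), so strands 2 and 4 cross between the
stacks and carry the Pos1/Pos2 bridging phosphates.

Atoms are a minimal per-residue set sufficient for every analysis in the
package: P, OP1, OP2 (backbone), C1' (axis reference) and the
identity-dependent base acceptors (N7/O6/O4/O2/N3).  The two C1' atoms of a
pair are placed diametrically so their midpoint lies exactly on the
construction axis: at zero noise the fitted axis reproduces the requested
geometry exactly, which is what makes the generator a ground-truth oracle
rather than a physical model.

Construction frame: the two stack centers sit at ±10 Å along z; the axes
lie in planes parallel to xy, at ±(angle/2) from x, with the sign pattern
chosen so that ``det[d1, d2, center2-center1]`` is positive for a
right-handed junction.  Mirror fixtures are produced by negating y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .combinatorics import JunctionSequenceSet, complement, realize_sequences
from .ions import ACCEPTOR_ATOMS, DEFAULT_CUTOFF, branch_point_sites
from .structure_io import (
    AtomRecord,
    HJStructure,
    JunctionSpec,
    StrandRun,
    Trajectory,
    write_structure,
    write_trajectory,
)

__all__ = [
    "SynthSpec",
    "IonPlan",
    "GroundTruth",
    "build_junction",
    "build_trajectory",
    "mirror_structure",
    "transform_structure",
    "write_bundle",
]

_LETTER_TO_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

# cylindrical placement of the per-residue atom set: name -> (radius Å,
# angle offset deg relative to the residue's C1' azimuth, z offset Å).
# OP2 is deliberately placed on the major-groove side so that each
# crossover phosphate has an anionic oxygen within bridging range of the
# adjacent base acceptors, as in the ion-bridging geometry under study.
_BASE_ATOMS = {
    "N7": (4.0, -35.0, 0.0),
    "O6": (4.0, -15.0, 0.0),
    "O4": (4.0, -15.0, 0.0),
    "N3": (3.2, 25.0, 0.0),
    "O2": (3.2, 40.0, 0.0),
}
_C1_RADIUS = 5.25
_P_ATOMS = {  # (radius, angle offset × backbone direction, z offset × dir)
    "P": (8.9, 55.0, -1.7),
    "OP1": (9.7, 63.0, -1.7),
}
_OP2 = (7.2, -30.0, -1.7)  # same azimuthal side as the base acceptors
_STACK_SEPARATION = 20.0
_UNBOUND_OFFSET = 60.0


@dataclass(frozen=True)
class IonPlan:
    """One planted ion: the frames in which it is bound, and where."""

    frames: frozenset[int]
    site: str = "Pos1"  # "Pos1" or "Pos2"
    radial_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.site not in ("Pos1", "Pos2"):
            raise ValueError("site must be 'Pos1' or 'Pos2'")
        object.__setattr__(self, "frames", frozenset(self.frames))


@dataclass
class SynthSpec:
    """Parameters of a synthetic stacked-X junction / trajectory.

    ``angle`` is the interduplex (J_twist) angle in degrees, exclusive of 0
    and 180 so the two axes stay distinguishable; ``rise``/``twist`` default
    to canonical B-DNA values; ``noise_sigma`` is the isotropic Gaussian
    displacement applied per atom per frame.
    """

    sequences: JunctionSequenceSet
    angle: float = 60.0
    handedness: str = "right"
    rise: float = 3.38
    twist: float = 34.3
    noise_sigma: float = 0.0
    n_frames: int = 1
    ion_plans: tuple[IonPlan, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.angle < 180.0:
            raise ValueError("angle must lie strictly in (0, 180) degrees")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for plan in self.ion_plans:
            bad = [f for f in plan.frames if not 0 <= f < self.n_frames]
            if bad:
                raise ValueError(
                    f"ion plan references frames outside 0..{self.n_frames - 1}: "
                    f"{sorted(bad)}"
                )

    @property
    def arm_length(self) -> int:
        return self.sequences.arm_length

    @classmethod
    def from_quartet(
        cls, quartet: str, arm_length: int = 8, stem_seed: int = 0, **kw
    ) -> "SynthSpec":
        from .combinatorics import BranchPointAssignment

        seqs = realize_sequences(
            BranchPointAssignment.from_refs(quartet), arm_length,
            stem_seed=stem_seed,
        )
        return cls(sequences=seqs, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """Machine-readable record of what the generator actually built."""

    angle: float
    handedness: str
    signed_angle: float
    axis1: tuple[float, float, float]
    axis2: tuple[float, float, float]
    arm_length: int
    n_frames: int
    bound_frames: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        d = {
            "angle": self.angle,
            "handedness": self.handedness,
            "signed_angle": self.signed_angle,
            "axis1": list(self.axis1),
            "axis2": list(self.axis2),
            "arm_length": self.arm_length,
            "n_frames": self.n_frames,
            "bound_frames": {k: sorted(v) for k, v in self.bound_frames.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, indent=1))


def _stack_frames(angle_deg: float, handedness: str):
    """Axis directions and centers of the two stacks in the build frame."""
    s = 1.0 if handedness == "right" else -1.0
    half = np.radians(angle_deg) / 2.0
    u1 = np.array([np.cos(half), -s * np.sin(half), 0.0])
    u2 = np.array([np.cos(half), +s * np.sin(half), 0.0])
    c1 = np.array([0.0, 0.0, -_STACK_SEPARATION / 2.0])
    c2 = np.array([0.0, 0.0, +_STACK_SEPARATION / 2.0])
    return u1, u2, c1, c2


def _perp_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ez = np.array([0.0, 0.0, 1.0])
    p = np.cross(ez, u)
    p /= np.linalg.norm(p)
    q = np.cross(u, p)
    return p, q


def _residue_atoms(
    base: str, azimuth_deg: float, z_along: float, backbone_dir: float,
    center: np.ndarray, u: np.ndarray, p: np.ndarray, q: np.ndarray,
) -> list[tuple[str, np.ndarray]]:
    def place(radius: float, ang_deg: float, dz: float) -> np.ndarray:
        a = np.radians(ang_deg)
        return (
            center
            + u * (z_along + dz)
            + p * radius * np.cos(a)
            + q * radius * np.sin(a)
        )

    out = [("P", place(*_P_ATOMS["P"][:1],
                       azimuth_deg + _P_ATOMS["P"][1] * backbone_dir,
                       _P_ATOMS["P"][2] * backbone_dir))]
    out.append(
        ("OP1", place(_P_ATOMS["OP1"][0],
                      azimuth_deg + _P_ATOMS["OP1"][1] * backbone_dir,
                      _P_ATOMS["OP1"][2] * backbone_dir))
    )
    out.append(
        ("OP2", place(_OP2[0], azimuth_deg + _OP2[1], _OP2[2] * backbone_dir))
    )
    out.append(("C1'", place(_C1_RADIUS, azimuth_deg, 0.0)))
    resname = _LETTER_TO_RESNAME[base]
    for name in ACCEPTOR_ATOMS[resname]:
        r, dphi, dz = _BASE_ATOMS[name]
        out.append((name, place(r, azimuth_deg + dphi, dz)))
    return out


def build_junction(spec: SynthSpec) -> tuple[HJStructure, GroundTruth]:
    """Idealized stacked-X junction coordinates plus the ground-truth record.

    Returns an annotated :class:`HJStructure` (strands A-D, branch residue
    ``arm_length`` on every strand, stacks ``((1, 2), (3, 4))``) together
    with the construction record the analyses can be checked against.
    """
    L = spec.arm_length
    strands = spec.sequences.strands
    u1, u2, c1, c2 = _stack_frames(spec.angle, spec.handedness)
    frames = {0: (u1, c1, *_perp_frame(u1)), 1: (u2, c2, *_perp_frame(u2))}

    # (chain, resnum) -> (stack, bp index, watson?, base letter)
    layout: dict[tuple[str, int], tuple[int, int, bool, str]] = {}
    n_bp = 2 * L
    for t in range(n_bp):
        layout[("A", t + 1)] = (0, t, True, strands[0][t])
        layout[("C", t + 1)] = (1, t, True, strands[2][t])
        crick_a = "D" if t < L else "B"
        crick_b = "B" if t < L else "D"
        layout[(crick_a, n_bp - t)] = (0, t, False, strands["ABCD".index(crick_a)][n_bp - t - 1])
        layout[(crick_b, n_bp - t)] = (1, t, False, strands["ABCD".index(crick_b)][n_bp - t - 1])

    # consistency of the strand model: every pair must be Watson-Crick
    for t in range(n_bp):
        for stack in (0, 1):
            w = [v[3] for v in layout.values() if v[:3] == (stack, t, True)][0]
            c = [v[3] for v in layout.values() if v[:3] == (stack, t, False)][0]
            assert complement(w) == c, "internal layout error"

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for chain in "ABCD":
        for resnum in range(1, n_bp + 1):
            stack, t, watson, base = layout[(chain, resnum)]
            u, c, p, q = frames[stack]
            z_along = (t - (n_bp - 1) / 2.0) * spec.rise
            azim = t * spec.twist + (0.0 if watson else 180.0)
            backbone_dir = 1.0 if watson else -1.0
            for name, xyz in _residue_atoms(
                base, azim, z_along, backbone_dir, c, u, p, q
            ):
                atoms.append(
                    AtomRecord(
                        chain=chain,
                        resnum=resnum,
                        resname=_LETTER_TO_RESNAME[base],
                        name=name,
                        element=name[0],
                    )
                )
                coords.append(xyz)

    jspec = JunctionSpec(
        strands=tuple(
            StrandRun(chain=ch, start=1, end=n_bp, branch=L) for ch in "ABCD"
        ),
        stacks=((1, 2), (3, 4)),
    )
    s = HJStructure(atoms, np.array(coords), None, jspec)
    truth = GroundTruth(
        angle=spec.angle,
        handedness=spec.handedness,
        signed_angle=spec.angle if spec.handedness == "right" else -spec.angle,
        axis1=tuple(u1),
        axis2=tuple(u2),
        arm_length=L,
        n_frames=spec.n_frames,
        seed=spec.seed,
    )
    return s, truth


def _bound_ion_position(
    s: HJStructure, coords: np.ndarray, site_label: str, radial_offset: float
) -> np.ndarray:
    """Midpoint of the closest (phosphate oxygen, base acceptor) pair of a site.

    Placing the ion at the midpoint guarantees both bridge contacts are
    below half the pair separation, well inside the default cutoff.
    """
    sites = {st.label: st for st in branch_point_sites(s)}
    site = sites[site_label]
    p_xyz = coords[list(site.phosphate_indices)]
    a_xyz = coords[list(site.acceptor_indices)]
    d = np.linalg.norm(p_xyz[:, None, :] - a_xyz[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    mid = 0.5 * (p_xyz[i] + a_xyz[j])
    if radial_offset:
        away = mid - coords.mean(axis=0)
        nrm = np.linalg.norm(away)
        if nrm > 0:
            mid = mid + radial_offset * away / nrm
    return mid


def build_trajectory(spec: SynthSpec) -> tuple[Trajectory, GroundTruth]:
    """Noisy multi-frame trajectory with ions planted per the ion plan.

    Every frame is the base structure plus seeded isotropic Gaussian noise.
    Each :class:`IonPlan` contributes one K+ ion present in all frames: in
    its bound frames it sits at the midpoint of the site's closest
    phosphate-oxygen/base-acceptor pair (computed from that frame's noisy
    coordinates, so the bridge contacts hold by construction); in unbound
    frames it is parked far (> 10 Å) from both sites.  Deterministic under
    ``spec.seed``.
    """
    base, truth = build_junction(spec)
    rng = np.random.default_rng(spec.seed)
    n_dna = len(base.atoms)

    atoms = list(base.atoms)
    ion_idx = []
    for k, _plan in enumerate(spec.ion_plans):
        atoms.append(
            AtomRecord(chain="I", resnum=k + 1, resname="K", name="K",
                       element="K")
        )
        ion_idx.append(n_dna + k)
    topo_coords = np.vstack(
        [base.coords]
        + [
            base.coords.mean(axis=0) + np.array([_UNBOUND_OFFSET, 0, 0]) * (k + 1)
            for k in range(len(spec.ion_plans))
        ]
    ) if spec.ion_plans else base.coords
    topo = HJStructure(atoms, topo_coords, None, base.spec,
                       np.array(ion_idx, int))

    frames: list[np.ndarray] = []
    bound: dict[str, set[int]] = {"Pos1": set(), "Pos2": set()}
    far = base.coords.mean(axis=0)
    for f in range(spec.n_frames):
        dna = base.coords + rng.normal(0.0, spec.noise_sigma, base.coords.shape) \
            if spec.noise_sigma > 0 else base.coords.copy()
        frame_s = base.with_coords(dna)
        ions = []
        for k, plan in enumerate(spec.ion_plans):
            if f in plan.frames:
                ions.append(
                    _bound_ion_position(frame_s, dna, plan.site,
                                        plan.radial_offset)
                )
                bound[plan.site].add(f)
            else:
                ions.append(far + np.array([_UNBOUND_OFFSET, 0, 0]) * (k + 1))
        frames.append(np.vstack([dna] + [i[None, :] for i in ions])
                      if ions else dna)
    truth = GroundTruth(
        angle=truth.angle,
        handedness=truth.handedness,
        signed_angle=truth.signed_angle,
        axis1=truth.axis1,
        axis2=truth.axis2,
        arm_length=truth.arm_length,
        n_frames=spec.n_frames,
        bound_frames={k: sorted(v) for k, v in bound.items() if v},
        seed=spec.seed,
    )
    return Trajectory(topo, frames), truth


def mirror_structure(s: HJStructure) -> HJStructure:
    """Reflection through the xz-plane: flips handedness, preserves |angle|."""
    m = s.coords.copy()
    m[:, 1] *= -1.0
    return s.with_coords(m)


def transform_structure(
    s: HJStructure, rotation: np.ndarray, translation: Sequence[float] = (0, 0, 0)
) -> HJStructure:
    """Apply a rigid (or improper) transform to all coordinates."""
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    return s.with_coords(s.coords @ R.T + t)


def write_bundle(spec: SynthSpec, out_dir) -> dict[str, Path]:
    """Write structure PDB, trajectory PDB, junction spec JSON and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    s, _ = build_junction(spec)
    traj, truth = build_trajectory(spec)
    paths = {
        "structure": out / "junction.pdb",
        "trajectory": out / "trajectory.pdb",
        "spec": out / "junction_spec.json",
        "truth": out / "ground_truth.json",
    }
    write_structure(s, paths["structure"])
    write_trajectory(traj, paths["trajectory"])
    s.spec.to_json(paths["spec"])
    truth.to_json(paths["truth"])
    return paths
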