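"""Branch-point ion bridging: site definition, per-frame detection, incidence.

In the stacked-X junction two strands cross between the helices.  Right at
each crossover sits a phosphate whose anionic oxygens, together with
hydrogen-bond-acceptor atoms of the adjacent branch-point base pairs, form
a cation-bridging site.  The two sites (labelled Pos1 and Pos2) lie on
opposite sides of the junction.  An ion counts as bound when it is
simultaneously within a distance cutoff of at least one phosphate oxygen
AND at least one base acceptor of the same site — a purely distance-based
operationalization of the phosphate-plus-base bridge.  The default cutoff
of 3.6 Å is a typical first coordination-shell distance for K+/Na+ to O/N
and applies to divalent ions as well.

The per-trajectory statistic is the *incidence*: the fraction of frames
containing at least one bridging event at either site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import AnnotationError, HJStructure, Trajectory

__all__ = [
    "ACCEPTOR_ATOMS",
    "DEFAULT_CUTOFF",
    "IonSite",
    "IonBindingEvent",
    "IncidenceSummary",
    "branch_point_sites",
    "detect_events",
    "incidence",
    "site_occupancy_table",
]

#: Hydrogen-bond-acceptor base atoms considered per residue identity
#: (purine N7/O6 and minor-groove N3; pyrimidine O2/O4/N3).
ACCEPTOR_ATOMS: dict[str, tuple[str, ...]] = {
    "DA": ("N7", "N3"),
    "DG": ("N7", "O6", "N3"),
    "DC": ("O2", "N3"),
    "DT": ("O2", "O4"),
    "A": ("N7", "N3"),
    "G": ("N7", "O6", "N3"),
    "C": ("O2", "N3"),
    "U": ("O2", "O4"),
}

#: First-shell coordination distance for monovalent cations to O/N, Å.
DEFAULT_CUTOFF = 3.6

_PHOSPHATE_OXYGENS = ("OP1", "OP2", "O1P", "O2P")


@dataclass(frozen=True)
class IonSite:
    """One branch-point bridging site: phosphate oxygens + base acceptors."""

    label: str  # "Pos1" or "Pos2"
    strand: int  # 1-based index of the crossover strand defining the site
    phosphate_indices: tuple[int, ...]
    acceptor_indices: tuple[int, ...]

    @property
    def atom_indices(self) -> tuple[int, ...]:
        return self.phosphate_indices + self.acceptor_indices


@dataclass(frozen=True)
class IonBindingEvent:
    """One ion bridging one site in one frame."""

    frame: int
    ion_index: int
    site: str
    phosphate_index: int
    acceptor_indices: tuple[int, ...]
    distances: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.acceptor_indices) <= 2:
            raise ValueError("an event bridges 1-2 base atoms")


@dataclass(frozen=True)
class IncidenceSummary:
    """Fraction of frames with at least one branch-point bridging event."""

    label: str
    frames_total: int
    frames_with_event: int

    def __post_init__(self) -> None:
        if not 0 <= self.frames_with_event <= self.frames_total:
            raise ValueError("frames_with_event must lie in [0, frames_total]")

    @property
    def incidence(self) -> float:
        return self.frames_with_event / self.frames_total


def branch_point_sites(s: HJStructure) -> tuple[IonSite, IonSite]:
    """The two crossover bridging sites (Pos1, Pos2) of an annotated junction.

    The crossover strands are those whose two halves lie in different
    declared stacks.  For crossover strand ``k`` the site comprises the
    anionic oxygens of the phosphate of residue ``branch+1`` (the first
    residue past the crossover) and the acceptor atoms of the two
    branch-point base pairs flanking that crossover: residues
    ``(k, branch)``, ``(k-1, branch+1)``, ``(k, branch+1)`` and
    ``(k+1, branch)``.  The two sites use disjoint atom sets on opposite
    sides of the junction.
    """
    if s.spec is None:
        raise AnnotationError("structure is not annotated")
    stacks = [frozenset(p) for p in s.spec.stacks]
    crossover = []
    for k in range(1, 5):
        arms = {k, k % 4 + 1}  # strand k spans arms k and k+1
        if not any(arms <= st for st in stacks):
            crossover.append(k)
    if len(crossover) != 2:
        raise AnnotationError(
            f"expected exactly 2 crossover strands, found {len(crossover)}; "
            "check the stack declaration"
        )
    sites = []
    for label, k in zip(("Pos1", "Pos2"), crossover):
        run = s.spec.strands[k - 1]
        p_res = run.branch + 1
        p_idx = []
        for name in _PHOSPHATE_OXYGENS:
            try:
                p_idx.append(s.atom_index(run.chain, p_res, name))
            except KeyError:
                pass
        if not p_idx:
            raise AnnotationError(
                f"strand {k}: crossover residue {run.chain}:{p_res} has no "
                "phosphate oxygens (OP1/OP2)"
            )
        acc_idx = []
        prev = s.spec.strands[k - 2]
        nxt = s.spec.strands[k % 4]
        flank = [
            (run.chain, run.branch),
            (prev.chain, prev.branch + 1),
            (run.chain, p_res),
            (nxt.chain, nxt.branch),
        ]
        for chain, resnum in flank:
            ridx = s.residue_atom_indices(chain, resnum)
            resname = s.atoms[ridx[0]].resname.upper()
            wanted = ACCEPTOR_ATOMS.get(resname, ())
            for i in ridx:
                if s.atoms[i].name in wanted:
                    acc_idx.append(i)
        if len(acc_idx) < 1:
            raise AnnotationError(
                f"strand {k}: no base acceptor atoms at the branch point"
            )
        sites.append(
            IonSite(label, k, tuple(p_idx), tuple(acc_idx))
        )
    return tuple(sites)  # type: ignore[return-value]


def _frame_events(
    frame_idx: int,
    coords: np.ndarray,
    ion_indices: np.ndarray,
    sites: tuple[IonSite, IonSite],
    cutoff: float,
) -> list[IonBindingEvent]:
    events = []
    ion_xyz = coords[ion_indices]
    per_site = []
    for site in sites:
        dp = cdist(ion_xyz, coords[list(site.phosphate_indices)])
        da = cdist(ion_xyz, coords[list(site.acceptor_indices)])
        per_site.append((dp, da))
    for j, ion in enumerate(ion_indices):
        qualified = []
        for site, (dp, da) in zip(sites, per_site):
            p_ok = dp[j].min() <= cutoff
            a_ok = da[j].min() <= cutoff
            if p_ok and a_ok:
                qualified.append((site, dp[j], da[j]))
        if not qualified:
            continue
        # nearest-site assignment when an ion satisfies both sites at once
        site, dp_j, da_j = min(
            qualified, key=lambda q: float(q[1].min() + q[2].min())
        )
        p_best = int(np.argmin(dp_j))
        a_order = np.argsort(da_j)
        a_keep = [int(a) for a in a_order[:2] if da_j[a] <= cutoff]
        acc = tuple(site.acceptor_indices[a] for a in a_keep)
        dists = (float(dp_j[p_best]),) + tuple(float(da_j[a]) for a in a_keep)
        events.append(
            IonBindingEvent(
                frame=frame_idx,
                ion_index=int(ion),
                site=site.label,
                phosphate_index=site.phosphate_indices[p_best],
                acceptor_indices=acc,
                distances=dists,
            )
        )
    return events


def detect_events(
    t: Trajectory, cutoff: float = DEFAULT_CUTOFF
) -> list[IonBindingEvent]:
    """All phosphate-plus-base bridging events, per frame and ion.

    An ion generates at most one event per frame: if it bridges both sites
    simultaneously it is assigned to the nearer site only.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    topo = t.topology
    sites = branch_point_sites(topo)
    if topo.ion_indices.size == 0:
        warnings.warn("no ions flagged in the topology; no events possible",
                      stacklevel=2)
        return []
    events: list[IonBindingEvent] = []
    for i, frame in enumerate(t.frames):
        events.extend(
            _frame_events(i, frame, topo.ion_indices, sites, cutoff)
        )
    return events


def incidence(
    t: Trajectory, cutoff: float = DEFAULT_CUTOFF, label: str = ""
) -> IncidenceSummary:
    """Fraction of frames with >= 1 bridging event at either site."""
    if t.n_frames == 0:
        raise ValueError("trajectory has zero frames")
    events = detect_events(t, cutoff)
    frames_hit = len({e.frame for e in events})
    return IncidenceSummary(
        label=label, frames_total=t.n_frames, frames_with_event=frames_hit
    )


def site_occupancy_table(
    summaries: list[IncidenceSummary],
    subset: list[str] | None = None,
) -> tuple[pd.DataFrame, float, float | None]:
    """Per-junction incidence table plus mean and sample σ over a subset.

    ``subset`` selects junction labels to include in the group statistic
    (e.g. excluding junctions declared fatal); default is all.  Returns
    ``(table, mean, sigma)`` with ``sigma=None`` when fewer than two
    summaries enter the group.
    """
    if not summaries:
        raise ValueError("need at least one incidence summary")
    table = pd.DataFrame(
        {
            "junction": [s.label for s in summaries],
            "frames_total": [s.frames_total for s in summaries],
            "frames_with_event": [s.frames_with_event for s in summaries],
            "incidence": [s.incidence for s in summaries],
        }
    )
    if subset is None:
        sel = table
    else:
        sel = table[table["junction"].isin(subset)]
        if sel.empty:
            raise ValueError("subset selects no junctions")
    mean = float(sel["incidence"].mean())
    sigma = float(sel["incidence"].std(ddof=1)) if len(sel) > 1 else None
    return table, mean, sigma
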