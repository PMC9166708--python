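"""Coordinate I/O and junction-topology annotation.

Structures are held in a lightweight container (:class:`HJStructure`):
per-atom metadata in file order plus an ``(n, 3)`` coordinate array in
angstroms. Reading and writing of PDB and mmCIF goes through gemmi;
trajectories use the multi-model PDB dialect (``MODEL``/``ENDMDL`` blocks
with an identical atom list in every model), the lowest-common-denominator
format that both the synthetic generator and real MD post-processing tools
can emit.

Junction annotation attaches the four-strand topology: four ordered residue
runs (one per strand), the per-strand crossover residue, and the two coaxial
stacks as pairs of arm indices. Arms are numbered as in
:mod:`hjkit.combinatorics`: strand ``i`` spans arm ``i`` (5' half, residues
``start..branch``) into arm ``i+1`` (3' half, residues ``branch+1..end``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "LatticeParams",
    "StrandRun",
    "JunctionSpec",
    "HJStructure",
    "Trajectory",
    "ParseError",
    "AnnotationError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "annotate_junction",
    "strand_sequences",
    "strands_to_fasta",
]

#: Residue names / elements recognized as ion (or ion-like) sites.  Cacodylate
#: (CAC/CAD) is treated as a single site at its arsenic atom.
ION_RESNAMES = {"K", "NA", "MG", "CL", "CA", "SR", "BA", "CS", "LI", "ZN",
                "MN", "CO", "NCO", "CAC", "CAD", "AS"}
ION_ELEMENTS = {"K", "NA", "MG", "CL", "CA", "SR", "BA", "CS", "LI", "ZN",
                "MN", "CO", "AS"}

_RESNAME_TO_LETTER = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
                      "A": "A", "C": "C", "G": "G", "T": "T", "U": "U"}


class ParseError(ValueError):
    """A coordinate file could not be interpreted."""


class AnnotationError(ValueError):
    """A junction declaration does not match the structure."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom as read from the file (author numbering preserved)."""

    chain: str
    resnum: int
    resname: str
    name: str
    element: str

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element must be non-empty")


@dataclass(frozen=True)
class LatticeParams:
    """Unit-cell constants (Å, degrees) and space-group label."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    spacegroup: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")


@dataclass(frozen=True)
class StrandRun:
    """One strand: a contiguous author-numbered residue run on one chain.

    ``branch`` is the crossover residue — the last residue of the strand's
    5'-half arm.
    """

    chain: str
    start: int
    end: int
    branch: int

    def __post_init__(self) -> None:
        if not self.start <= self.branch < self.end:
            raise ValueError(
                "branch residue must lie strictly inside the strand run"
            )


@dataclass(frozen=True)
class JunctionSpec:
    """Declaration of junction topology: four strands and two stacks.

    ``stacks`` are two pairs of 1-based arm indices declared coaxially
    stacked, e.g. ``((1, 2), (3, 4))``.
    """

    strands: tuple[StrandRun, StrandRun, StrandRun, StrandRun]
    stacks: tuple[tuple[int, int], tuple[int, int]] = ((1, 2), (3, 4))

    def __post_init__(self) -> None:
        if len(self.strands) != 4:
            raise AnnotationError("a junction has exactly four strands")
        flat = sorted(a for pair in self.stacks for a in pair)
        if flat != [1, 2, 3, 4]:
            raise AnnotationError("stacks must cover arms 1-4 exactly once")

    @classmethod
    def from_dict(cls, d: dict) -> "JunctionSpec":
        strands = tuple(StrandRun(**s) for s in d["strands"])
        stacks = tuple(tuple(p) for p in d.get("stacks", ((1, 2), (3, 4))))
        return cls(strands, stacks)  # type: ignore[arg-type]

    @classmethod
    def from_json(cls, path) -> "JunctionSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "strands": [
                {"chain": s.chain, "start": s.start, "end": s.end, "branch": s.branch}
                for s in self.strands
            ],
            "stacks": [list(p) for p in self.stacks],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class HJStructure:
    """Four-strand coordinate model with optional junction annotation."""

    atoms: list[AtomRecord]
    coords: np.ndarray
    cell: LatticeParams | None = None
    spec: JunctionSpec | None = None
    ion_indices: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    # ---- lookup helpers -------------------------------------------------
    def atom_index(self, chain: str, resnum: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.chain == chain and a.resnum == resnum and a.name == name:
                return i
        raise KeyError(f"no atom {name} in {chain}:{resnum}")

    def residue_atom_indices(self, chain: str, resnum: int) -> list[int]:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.chain == chain and a.resnum == resnum
        ]
        if not idx:
            raise KeyError(f"no residue {chain}:{resnum}")
        return idx

    @property
    def annotated(self) -> bool:
        return self.spec is not None

    def with_coords(self, coords: np.ndarray) -> "HJStructure":
        """Same topology/annotation with replaced coordinates."""
        return HJStructure(
            self.atoms, np.asarray(coords, float), self.cell, self.spec,
            self.ion_indices,
        )

    # ---- arm bookkeeping ------------------------------------------------
    def arm_residues(self, arm: int) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        """Ordered base pairs of one arm, distal -> branch.

        Each element is ``((chain, resnum)_ref, (chain, resnum)_partner)``:
        the reference residue on strand ``arm`` and its Watson-Crick partner
        on strand ``arm-1``'s 3' half, paired by antiparallel register.
        """
        if self.spec is None:
            raise AnnotationError("structure is not annotated")
        ref = self.spec.strands[arm - 1]
        partner = self.spec.strands[arm - 2]  # strand arm-1 (cyclic)
        n = ref.branch - ref.start + 1
        pairs = []
        for t in range(n):
            pairs.append(
                (
                    (ref.chain, ref.start + t),
                    (partner.chain, partner.end - t),
                )
            )
        return pairs


@dataclass
class Trajectory:
    """A topology plus an ordered list of congruent coordinate frames."""

    topology: HJStructure
    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.topology.atoms)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, float)
            if f.shape != (n, 3):
                raise ParseError(
                    f"frame {i}: expected {n} atoms, got {f.shape[0]}"
                )
            self.frames[i] = f

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, i: int) -> HJStructure:
        return self.topology.with_coords(self.frames[i])


# --------------------------------------------------------------------------
# reading / writing
# --------------------------------------------------------------------------

def _is_ion(resname: str, element: str, n_atoms_in_res: int) -> bool:
    rn = resname.strip().upper()
    if rn in ION_RESNAMES:
        return True
    return n_atoms_in_res == 1 and element.strip().upper() in ION_ELEMENTS


def _structure_from_gemmi_model(
    model: gemmi.Model, cell: LatticeParams | None
) -> HJStructure:
    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    ion_idx: list[int] = []
    for chain in model:
        for res in chain:
            res_is_ion = _is_ion(res.name, res[0].element.name if len(res) else "",
                                 len(res))
            for at in res:
                i = len(atoms)
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        resnum=res.seqid.num,
                        resname=res.name.strip(),
                        name=at.name,
                        element=at.element.name or "X",
                    )
                )
                coords.append((at.pos.x, at.pos.y, at.pos.z))
                if res_is_ion:
                    # cacodylate counts as one ion-like site at its As atom
                    if res.name.strip().upper() in {"CAC", "CAD"}:
                        if at.element.name.upper() == "AS":
                            ion_idx.append(i)
                    else:
                        ion_idx.append(i)
    if not atoms:
        raise ParseError("no atoms found")
    return HJStructure(
        atoms, np.array(coords, float), cell, None, np.array(ion_idx, int)
    )


def _cell_from_gemmi(st: gemmi.Structure) -> LatticeParams | None:
    c = st.cell
    if not c.is_crystal():
        return None
    return LatticeParams(
        c.a, c.b, c.c, c.alpha, c.beta, c.gamma, st.spacegroup_hm or ""
    )


def read_structure(path, fmt: str | None = None) -> HJStructure:
    """Read a single-model PDB or mmCIF file into an :class:`HJStructure`.

    Atoms are kept in file order; a CRYST1 / ``_cell`` block becomes
    :class:`LatticeParams` (absent cell is not an error); ions are
    auto-flagged by residue-name whitelist with a single-atom element
    fallback.
    """
    path = Path(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(
                str(path),
                format=gemmi.CoorFormat.Pdb
                if fmt.lower() == "pdb"
                else gemmi.CoorFormat.Mmcif,
            )
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"{path}: {e}") from e
    if len(st) == 0:
        raise ParseError(f"{path}: no models")
    return _structure_from_gemmi_model(st[0], _cell_from_gemmi(st))


def _gemmi_from_structure(s: HJStructure, coords: np.ndarray) -> gemmi.Structure:
    st = gemmi.Structure()
    if s.cell is not None:
        st.cell = gemmi.UnitCell(
            s.cell.a, s.cell.b, s.cell.c, s.cell.alpha, s.cell.beta, s.cell.gamma
        )
        st.spacegroup_hm = s.cell.spacegroup or "P 1"
    model = gemmi.Model("1")
    chain = None
    res = None
    key = None
    for a, xyz in zip(s.atoms, coords):
        if chain is None or chain.name != a.chain:
            chain = gemmi.Chain(a.chain)
            model.add_chain(chain)
            chain = model[-1]
            key = None
        if key != (a.resnum, a.resname):
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resnum, " ")
            chain.add_residue(res)
            res = chain[-1]
            key = (a.resnum, a.resname)
        at = gemmi.Atom()
        at.name = a.name
        at.element = gemmi.Element(a.element)
        at.pos = gemmi.Position(*map(float, xyz))
        res.add_atom(at)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: HJStructure, path) -> None:
    """Write a single-model PDB file (with CRYST1 when cell is present)."""
    _gemmi_from_structure(s, s.coords).write_pdb(str(path))


def write_trajectory(t: Trajectory, path) -> None:
    """Write a multi-model PDB: one MODEL/ENDMDL block per frame."""
    st = _gemmi_from_structure(t.topology, t.frames[0])
    for i, frame in enumerate(t.frames[1:], start=2):
        # re-fetch st[0]: add_model invalidates prior model references
        m = st[0].clone()
        m.num = i
        k = 0
        for chain in m:
            for res in chain:
                for at in res:
                    at.pos = gemmi.Position(*map(float, frame[k]))
                    k += 1
        st.add_model(m)
    st.write_pdb(str(path))


def read_trajectory(topology_path, frames_path=None) -> Trajectory:
    """Read a trajectory stored as a multi-model PDB.

    ``topology_path`` provides the atom list (its first model); frames come
    from all models of ``frames_path`` (defaulting to the topology file
    itself, so a single multi-model file is enough). Every frame must match
    the topology atom count; a mismatch raises naming the frame index.
    """
    topo = read_structure(topology_path)
    src = Path(frames_path) if frames_path is not None else Path(topology_path)
    try:
        st = gemmi.read_structure(str(src))
    except (RuntimeError, ValueError) as e:
        raise ParseError(f"{src}: {e}") from e
    n = len(topo.atoms)
    frames: list[np.ndarray] = []
    for i, model in enumerate(st):
        xyz = [
            (at.pos.x, at.pos.y, at.pos.z)
            for chain in model
            for res in chain
            for at in res
        ]
        if len(xyz) != n:
            raise ParseError(
                f"{src}: frame {i} has {len(xyz)} atoms, topology has {n}"
            )
        frames.append(np.array(xyz, float))
    if not frames:
        raise ParseError(f"{src}: no frames")
    return Trajectory(topo, frames)


# --------------------------------------------------------------------------
# annotation
# --------------------------------------------------------------------------

def _is_adjacent_pairing(stacks) -> bool:
    """True when the stacks are the coaxial (adjacent-arm) pairings.

    With strand ``i`` spanning arms ``i`` and ``i+1``, the two arms of a
    coaxial stack share a continuous strand and are adjacent in cyclic arm
    order: the valid pairings are {(1,2),(3,4)} and {(2,3),(4,1)}.  The
    opposite-arm pairing {(1,3),(2,4)} cannot form two continuous helices.
    """
    norm = {frozenset(p) for p in stacks}
    return norm in (
        {frozenset({1, 2}), frozenset({3, 4})},
        {frozenset({2, 3}), frozenset({4, 1})},
    )


def annotate_junction(s: HJStructure, spec: JunctionSpec | dict) -> HJStructure:
    """Attach and validate four-strand junction topology.

    Checks that every declared residue exists, that each strand's branch
    residue lies inside its run, and that the two halves pairing in each
    arm have equal length.  A stack declaration that does not pair adjacent
    arms is accepted but triggers a warning (it cannot describe a stacked-X
    coaxial arrangement).  Annotation is idempotent.
    """
    if isinstance(spec, dict):
        spec = JunctionSpec.from_dict(spec)
    present: dict[tuple[str, int], bool] = {}
    for a in s.atoms:
        present[(a.chain, a.resnum)] = True
    for k, run in enumerate(spec.strands, start=1):
        for r in range(run.start, run.end + 1):
            if (run.chain, r) not in present:
                raise AnnotationError(
                    f"strand {k}: residue {run.chain}:{r} absent from structure"
                )
    # arm pairing lengths: 5' half of strand i vs 3' half of strand i-1
    for arm in range(1, 5):
        ref = spec.strands[arm - 1]
        partner = spec.strands[arm - 2]
        n_ref = ref.branch - ref.start + 1
        n_par = partner.end - partner.branch
        if n_ref != n_par:
            raise AnnotationError(
                f"arm {arm}: reference half has {n_ref} residues but "
                f"partner half has {n_par}"
            )
    if not _is_adjacent_pairing(spec.stacks):
        warnings.warn(
            "declared stacks do not pair adjacent arms; a stacked-X junction "
            "stacks arms sharing a continuous strand (e.g. (1,2),(3,4))",
            stacklevel=2,
        )
    return replace_spec(s, spec)


def replace_spec(s: HJStructure, spec: JunctionSpec) -> HJStructure:
    return HJStructure(s.atoms, s.coords, s.cell, spec, s.ion_indices)


# --------------------------------------------------------------------------
# sequence export
# --------------------------------------------------------------------------

def strand_sequences(s: HJStructure) -> list[str]:
    """5'->3' sequences of the four annotated strands (one letter per residue)."""
    if s.spec is None:
        raise AnnotationError("structure is not annotated")
    seqs = []
    for run in s.spec.strands:
        letters = []
        for r in range(run.start, run.end + 1):
            idx = s.residue_atom_indices(run.chain, r)
            rn = s.atoms[idx[0]].resname.upper()
            letters.append(_RESNAME_TO_LETTER.get(rn, "N"))
        seqs.append("".join(letters))
    return seqs


def strands_to_fasta(s: HJStructure, path, prefix: str = "strand") -> None:
    """FASTA export of the annotated strands via biopython."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    recs = [
        SeqRecord(Seq(seq), id=f"{prefix}{i + 1}", description="")
        for i, seq in enumerate(strand_sequences(s))
    ]
    SeqIO.write(recs, str(path), "fasta")
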