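"""Branch-migration combinatorics of four-way (Holliday) junctions.

A four-way junction is built from four strands and four duplex arms. This
module fixes one explicit strand/arm convention and derives everything from
it:

* Arms are numbered 1-4 going around the junction; indices are cyclic
  (arm 5 == arm 1).
* Strand ``i`` runs 5'->3' from the distal end of arm ``i``, through the
  branch point, out to the distal end of arm ``i+1``.  Its 5' half is the
  reference strand of arm ``i``; its 3' half is the complementary strand of
  arm ``i+1``.
* The branch-point base pair of arm ``j`` therefore pairs the junction-
  proximal base of strand ``j`` (written ``a_j``) with the junction-proximal
  base of strand ``j-1``'s 3' half (written ``b_{j-1}``); Watson-Crick
  pairing forces ``b_i = complement(a_{i+1})``.

A branch-point assignment is the quartet ``(P1, P2, P3, P4)`` of reference
bases ``a_1..a_4``, so there are 4**4 = 256 assignments.  One-step branch
migration along an opposing-arm axis breaks the two branch-point pairs of
the shrinking arms and re-pairs each freed base with its new partner across
the junction; the junction is *immobile* when neither axis permits this.
Exhaustive enumeration plus collapse of cyclic strand relabelings yields the
36 immobile junction classes that underpin designed DNA crystals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "complement",
    "BasePair",
    "BranchPointAssignment",
    "JunctionClass",
    "JunctionSequenceSet",
    "Axis",
    "migrates_one_step",
    "is_immobile",
    "all_assignments",
    "enumerate_immobile_classes",
    "realize_sequences",
    "classes_table",
    "classes_to_fasta",
]

#: Alphabetical base order used for canonicalization and lexicographic labels.
BASES: tuple[str, ...] = ("A", "C", "G", "T")

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def complement(base: str) -> str:
    """Watson-Crick complement of a single DNA base symbol."""
    try:
        return _WC[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


@dataclass(frozen=True)
class BasePair:
    """A Watson-Crick pair identified by the base read on the reference strand."""

    ref: str

    def __post_init__(self) -> None:
        if self.ref not in _WC:
            raise ValueError(f"not a DNA base: {self.ref!r}")

    @property
    def partner(self) -> str:
        return _WC[self.ref]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ref}:{self.partner}"


@dataclass(frozen=True)
class BranchPointAssignment:
    """The quartet of branch-point base pairs (P1, P2, P3, P4), one per arm.

    ``pairs[j-1].ref`` is the base ``a_j`` read on the reference strand of
    arm ``j`` under the module-level strand convention.
    """

    pairs: tuple[BasePair, BasePair, BasePair, BasePair]

    def __post_init__(self) -> None:
        if len(self.pairs) != 4:
            raise ValueError("a branch-point assignment has exactly 4 pairs")

    @classmethod
    def from_refs(cls, refs: str | Sequence[str]) -> "BranchPointAssignment":
        refs = tuple(refs)
        if len(refs) != 4:
            raise ValueError("need exactly 4 reference bases")
        return cls(tuple(BasePair(r) for r in refs))  # type: ignore[arg-type]

    @property
    def refs(self) -> str:
        return "".join(p.ref for p in self.pairs)

    def rotated(self, k: int) -> "BranchPointAssignment":
        """Cyclic relabeling of the arms by ``k`` positions (arm 1 -> arm 1+k)."""
        k %= 4
        return BranchPointAssignment(self.pairs[k:] + self.pairs[:k])

    def flanking_bases(self) -> dict[str, str]:
        """The eight junction-proximal bases ``a_1..a_4`` and ``b_1..b_4``.

        ``a_i`` is the last base of strand ``i``'s 5' half, ``b_i`` the first
        base of its 3' half; complementarity of the arm branch pairs fixes
        ``b_i = complement(a_{i+1})``.
        """
        a = {f"a{i + 1}": p.ref for i, p in enumerate(self.pairs)}
        b = {f"b{i + 1}": complement(self.pairs[(i + 1) % 4].ref) for i in range(4)}
        return {**a, **b}


class Axis:
    """The two opposing-arm migration axes."""

    ARMS_1_3 = "axis(1,3)"
    ARMS_2_4 = "axis(2,4)"

    ALL = (ARMS_1_3, ARMS_2_4)


def migrates_one_step(a: BranchPointAssignment, axis: str) -> bool:
    """Whether one step of branch migration along ``axis`` is Watson-Crick legal.

    Explicit re-pairing model over the eight flanking bases: the two
    branch-point pairs of the shrinking arms (the arms named by ``axis``)
    are broken, and each freed base re-pairs with its new partner across
    the junction — the adjacent junction-proximal base of the strand it
    meets when the crossover moves one step.  The step is allowed iff both
    new pairs are Watson-Crick.
    """
    if axis == Axis.ARMS_1_3:
        shrink = (1, 3)
    elif axis == Axis.ARMS_2_4:
        shrink = (2, 4)
    else:
        raise ValueError(f"invalid axis identifier: {axis!r}")

    bases = a.flanking_bases()
    j, k = shrink  # k = j + 2
    # Branch pair of arm m is (a_m on strand m, b_{m-1} on strand m-1).
    # Breaking arms j and j+2 frees a_j, b_{j-1}, a_{j+2}, b_{j+1}.
    # Moving the crossover one step extends the two growing arms:
    #   arm j-1 gains the pair (b_{j-1}, a_{j+2})  [strand j-1 meets strand j+2-1's ref... ]
    #   arm j+1 gains the pair (b_{j+1}, a_j)
    # i.e. each freed 3'-side base pairs the freed 5'-side base of the
    # strand two arms away.
    def wrap(m: int) -> int:
        return ((m - 1) % 4) + 1

    freed_b_prev = bases[f"b{wrap(j - 1)}"]
    freed_b_next = bases[f"b{wrap(j + 1)}"]
    freed_a_j = bases[f"a{j}"]
    freed_a_k = bases[f"a{k}"]
    new_pairs = [(freed_b_prev, freed_a_k), (freed_b_next, freed_a_j)]
    return all(complement(x) == y for x, y in new_pairs)


def is_immobile(a: BranchPointAssignment) -> bool:
    """True when one-step migration is Watson-Crick forbidden on both axes."""
    return not migrates_one_step(a, Axis.ARMS_1_3) and not migrates_one_step(
        a, Axis.ARMS_2_4
    )


def all_assignments() -> list[BranchPointAssignment]:
    """All 4**4 = 256 branch-point assignments, in lexicographic order."""
    return [
        BranchPointAssignment.from_refs("".join(t))
        for t in itertools.product(BASES, repeat=4)
    ]


@dataclass(frozen=True)
class JunctionClass:
    """An orbit of immobile branch-point assignments under cyclic relabeling."""

    canonical: BranchPointAssignment
    members: frozenset[BranchPointAssignment]
    label: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 4:
            raise ValueError("orbit size must be between 1 and 4")

    @property
    def orbit_size(self) -> int:
        return len(self.members)


def enumerate_immobile_classes(
    labels: Mapping[str, str] | None = None,
) -> list[JunctionClass]:
    """Enumerate the rotational equivalence classes of immobile junctions.

    All 256 assignments are generated, filtered with :func:`is_immobile`
    (each call running the explicit re-pairing oracle on both axes), and
    partitioned into orbits under cyclic rotation of the four arms.  One
    class per orbit is returned, ordered by the canonical member
    (lexicographic minimum of the orbit under alphabetical base order).

    Parameters
    ----------
    labels
        Optional mapping from canonical quartet string (e.g. ``"AACG"``) to
        a display label, for users who want to attach the literature's
        J1..J36 numbering.  Default labels are ``"J1".."J36"`` in canonical
        order; correspondence with any published numbering is not implied.
    """
    seen: set[str] = set()
    classes: list[JunctionClass] = []
    for a in all_assignments():
        if a.refs in seen or not is_immobile(a):
            continue
        orbit = {a.rotated(k) for k in range(4)}
        seen.update(m.refs for m in orbit)
        canonical = min(orbit, key=lambda m: m.refs)
        classes.append(JunctionClass(canonical=canonical, members=frozenset(orbit)))
    classes.sort(key=lambda c: c.canonical.refs)
    out = []
    for i, c in enumerate(classes):
        default = f"J{i + 1}"
        label = labels.get(c.canonical.refs, default) if labels else default
        out.append(JunctionClass(c.canonical, c.members, label))
    return out


@dataclass(frozen=True)
class JunctionSequenceSet:
    """Four strand sequences (5'->3'), each spanning two adjacent arms."""

    strands: tuple[str, str, str, str]
    arm_length: int
    branch_point: BranchPointAssignment

    def __post_init__(self) -> None:
        L = self.arm_length
        if L < 2:
            raise ValueError("arm_length must be >= 2")
        if any(len(s) != 2 * L for s in self.strands):
            raise ValueError("each strand must span two arms (length 2*arm_length)")
        readback = self.branch_point_from_strands(self.strands, L)
        if readback != self.branch_point:
            raise ValueError(
                "strand sequences do not realize the declared branch point"
            )
        # full Watson-Crick complementarity of every arm
        for i in range(4):
            ref_half = self.strands[i][:L]
            partner_half = self.strands[(i - 1) % 4][L:]
            if any(
                complement(x) != y for x, y in zip(ref_half, reversed(partner_half))
            ):
                raise ValueError(f"arm {i + 1} is not Watson-Crick complementary")

    @staticmethod
    def branch_point_from_strands(
        strands: Sequence[str], arm_length: int
    ) -> BranchPointAssignment:
        """Read the branch-point quartet back from four strand sequences."""
        return BranchPointAssignment.from_refs(
            "".join(s[arm_length - 1] for s in strands)
        )


def realize_sequences(
    c: JunctionClass | BranchPointAssignment,
    arm_length: int,
    stem_seed: int | None = None,
    stems: Sequence[str] | None = None,
) -> JunctionSequenceSet:
    """Concrete four-strand sequences realizing a junction class.

    Each arm gets ``arm_length - 1`` stem pairs (distal of the branch pair)
    whose reference-strand bases are either drawn from a seeded RNG or
    supplied explicitly (``stems``, four strings read 5'->3' toward the
    branch on the reference strand of each arm).  Strand ``i`` is assembled
    per the module convention: its arm-``i`` reference half followed by the
    complementary half of arm ``i+1``.
    """
    if arm_length < 2:
        raise ValueError("arm_length must be >= 2")
    bp = c.canonical if isinstance(c, JunctionClass) else c
    refs = bp.refs
    n_stem = arm_length - 1
    if stems is not None:
        stems = [str(s).upper() for s in stems]
        if len(stems) != 4 or any(len(s) != n_stem for s in stems):
            raise ValueError(f"stems must be 4 strings of length {n_stem}")
        for s in stems:
            for ch in s:
                complement(ch)  # validates alphabet
    else:
        rng = np.random.default_rng(stem_seed)
        stems = [
            "".join(rng.choice(BASES, size=n_stem)) if n_stem else ""
            for _ in range(4)
        ]
    strands = []
    for i in range(4):
        ref_half = stems[i] + refs[i]
        nxt = (i + 1) % 4
        partner_half = complement(refs[nxt]) + "".join(
            complement(x) for x in reversed(stems[nxt])
        )
        strands.append(ref_half + partner_half)
    return JunctionSequenceSet(tuple(strands), arm_length, bp)


def classes_table(classes: Iterable[JunctionClass]) -> pd.DataFrame:
    """Tidy table of classes: label, canonical quartet, pairs, orbit size."""
    rows = [
        {
            "label": c.label,
            "quartet": c.canonical.refs,
            "pairs": " ".join(str(p) for p in c.canonical.pairs),
            "orbit_size": c.orbit_size,
        }
        for c in classes
    ]
    return pd.DataFrame(rows)


def classes_to_fasta(
    classes: Iterable[JunctionClass],
    path,
    arm_length: int = 8,
    stem_seed: int | None = 0,
) -> None:
    """Write realized strands of each class as FASTA (4 records per class)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for c in classes:
        seqs = realize_sequences(c, arm_length, stem_seed=stem_seed)
        for i, s in enumerate(seqs.strands):
            records.append(
                SeqRecord(
                    Seq(s),
                    id=f"{c.label}_strand{i + 1}",
                    description=f"quartet={c.canonical.refs} arm_length={arm_length}",
                )
            )
    SeqIO.write(records, str(path), "fasta")
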