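"""PDB/mmCIF round trips, junction annotation, trajectory dialect."""

import numpy as np
import pytest

from hjkit.structure_io import (
    AnnotationError,
    JunctionSpec,
    LatticeParams,
    ParseError,
    StrandRun,
    Trajectory,
    annotate_junction,
    read_structure,
    read_trajectory,
    strand_sequences,
    strands_to_fasta,
    write_structure,
    write_trajectory,
)
from hjkit.synth import IonPlan, SynthSpec, build_junction, build_trajectory


def test_pdb_round_trip(junction_60, tmp_path):
    s, _ = junction_60
    p = tmp_path / "j.pdb"
    write_structure(s, p)
    s2 = read_structure(p)
    assert len(s2.atoms) == len(s.atoms)
    assert np.allclose(s2.coords, s.coords, atol=1e-3)
    assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]
    assert [a.resnum for a in s2.atoms] == [a.resnum for a in s.atoms]


def test_cryst1_maps_to_lattice_params(junction_60, tmp_path):
    # representative trigonal cell of a 4x5-type lattice
    s, _ = junction_60
    s.cell = LatticeParams(68.85, 68.85, 60.09, 90.0, 90.0, 120.0, "P 32 2 1")
    p = tmp_path / "cell.pdb"
    write_structure(s, p)
    s2 = read_structure(p)
    assert s2.cell is not None
    assert s2.cell.a == pytest.approx(68.85, abs=1e-2)
    assert s2.cell.c == pytest.approx(60.09, abs=1e-2)
    assert s2.cell.gamma == pytest.approx(120.0)
    assert "32" in s2.cell.spacegroup.replace(" ", "")


def test_missing_cell_is_not_an_error(junction_60, tmp_path):
    s, _ = junction_60
    p = tmp_path / "nocell.pdb"
    write_structure(s, p)
    assert read_structure(p).cell is None


def test_empty_file_raises(tmp_path):
    p = tmp_path / "empty.pdb"
    p.write_text("")
    with pytest.raises(ParseError):
        read_structure(p)


def test_ion_autoflagging(tmp_path, make_trajectory):
    traj, _ = make_trajectory(n_frames=2, bound_frames={0})
    p = tmp_path / "t.pdb"
    write_trajectory(traj, p)
    s = read_structure(p)
    assert s.ion_indices.size == 1
    assert s.atoms[int(s.ion_indices[0])].resname == "K"


class TestAnnotation:
    def test_generator_spec_annotates(self, junction_60):
        s, _ = junction_60
        assert s.annotated
        for arm in range(1, 5):
            assert len(s.arm_residues(arm)) == 8

    def test_annotation_idempotent(self, junction_60):
        s, _ = junction_60
        again = annotate_junction(s, s.spec)
        assert again.spec == s.spec

    def test_three_strands_rejected(self):
        runs = tuple(StrandRun("A", 1, 16, 8) for _ in range(3))
        with pytest.raises(AnnotationError):
            JunctionSpec(strands=runs)  # type: ignore[arg-type]

    def test_absent_residue_rejected(self, junction_60):
        s, _ = junction_60
        bad = JunctionSpec(
            strands=(
                StrandRun("A", 1, 16, 8),
                StrandRun("B", 1, 16, 8),
                StrandRun("C", 1, 16, 8),
                StrandRun("Z", 1, 16, 8),
            )
        )
        with pytest.raises(AnnotationError, match="absent"):
            annotate_junction(s, bad)

    def test_unequal_arm_halves_rejected(self, junction_60):
        s, _ = junction_60
        bad = JunctionSpec(
            strands=(
                StrandRun("A", 1, 16, 7),  # shifts arm-1/arm-2 half lengths
                StrandRun("B", 1, 16, 8),
                StrandRun("C", 1, 16, 8),
                StrandRun("D", 1, 16, 8),
            )
        )
        with pytest.raises(AnnotationError, match="arm"):
            annotate_junction(s, bad)

    def test_non_coaxial_stack_declaration_warns(self, junction_60):
        s, _ = junction_60
        spec = JunctionSpec(strands=s.spec.strands, stacks=((1, 3), (2, 4)))
        with pytest.warns(UserWarning, match="adjacent"):
            annotated = annotate_junction(s, spec)
        assert annotated.spec.stacks == ((1, 3), (2, 4))

    def test_alternative_coaxial_pairing_accepted_silently(
        self, junction_60, recwarn
    ):
        s, _ = junction_60
        spec = JunctionSpec(strands=s.spec.strands, stacks=((2, 3), (4, 1)))
        annotate_junction(s, spec)
        assert not [w for w in recwarn if "adjacent" in str(w.message)]

    def test_spec_json_round_trip(self, junction_60, tmp_path):
        s, _ = junction_60
        p = tmp_path / "spec.json"
        s.spec.to_json(p)
        assert JunctionSpec.from_json(p) == s.spec


class TestTrajectoryIO:
    def test_multi_model_round_trip(self, make_trajectory, tmp_path):
        traj, _ = make_trajectory(n_frames=10, bound_frames={0, 3})
        p = tmp_path / "traj.pdb"
        write_trajectory(traj, p)
        back = read_trajectory(p)
        assert back.n_frames == 10
        for a, b in zip(back.frames, traj.frames):
            assert np.allclose(a, b, atol=1e-3)

    def test_frame_atom_mismatch_names_frame(self, make_trajectory, tmp_path):
        traj, _ = make_trajectory(n_frames=5, bound_frames={0})
        p = tmp_path / "traj.pdb"
        write_trajectory(traj, p)
        lines = p.read_text().splitlines(keepends=True)
        # drop one ATOM line from the 4th MODEL block (frame index 3)
        model_seen = 0
        for i, ln in enumerate(lines):
            if ln.startswith("MODEL"):
                model_seen += 1
            elif ln.startswith("ATOM") and model_seen == 4:
                del lines[i]
                break
        bad = tmp_path / "bad.pdb"
        bad.write_text("".join(lines))
        with pytest.raises(ParseError, match="frame 3"):
            read_trajectory(bad)

    def test_single_model_file_is_one_frame(self, junction_60, tmp_path):
        s, _ = junction_60
        p = tmp_path / "one.pdb"
        write_structure(s, p)
        assert read_trajectory(p).n_frames == 1

    def test_congruence_enforced_in_memory(self, junction_60):
        s, _ = junction_60
        with pytest.raises(ParseError, match="frame 1"):
            Trajectory(s, [s.coords, s.coords[:-1]])


def test_strand_sequences_round_trip(quartet, tmp_path):
    spec = SynthSpec.from_quartet(quartet, arm_length=8, stem_seed=5)
    s, _ = build_junction(spec)
    assert tuple(strand_sequences(s)) == spec.sequences.strands
    fa = tmp_path / "strands.fasta"
    strands_to_fasta(s, fa)
    text = fa.read_text()
    assert text.count(">") == 4
    assert spec.sequences.strands[0] in text.replace("\n", "")


def test_lattice_params_validation():
    with pytest.raises(ValueError):
        LatticeParams(0.0, 10.0, 10.0, 90.0, 90.0, 90.0)
    with pytest.raises(ValueError):
        LatticeParams(10.0, 10.0, 10.0, 90.0, 90.0, 180.0)


def test_mmcif_read_matches_pdb(junction_60, tmp_path):
    s, _ = junction_60
    pdb = tmp_path / "j.pdb"
    write_structure(s, pdb)
    import gemmi

    st = gemmi.read_structure(str(pdb))
    st.setup_entities()
    cif = tmp_path / "j.cif"
    st.make_mmcif_document().write_file(str(cif))
    s2 = read_structure(cif)
    assert len(s2.atoms) == len(s.atoms)
    assert np.allclose(s2.coords, s.coords, atol=1e-3)
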