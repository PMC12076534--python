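"""Octahedral orientation search, constrained closure, whole-chain repair."""

import numpy as np
import pytest

from pdbmend.errors import ChainTooLargeError
from pdbmend.fixtures import (
    AblationPlan,
    ablate,
    make_ideal_peptide,
    random_sequence,
    roundtrip,
)
from pdbmend.gap_repair import (
    RepairConfig,
    close_gap,
    octahedral_directions,
    place_fragment,
    repair_chain,
)
from pdbmend.geometry import bond_length, dihedral, rotation_about_axis
from pdbmend.pdbio import Chain, Residue, StructureModel
from pdbmend.residue_builder import build_alltrans, expected_atom_count
from pdbmend.sequence_gaps import chain_gaps

from conftest import damaged_helix

FAST = RepairConfig(closure_max_iter=200, minimize_final=False)


def _anchor():
    return build_alltrans(["ALA"]).residues[0]


class TestOctahedralDirections:
    def test_orthonormal_pm_axes(self):
        dirs = octahedral_directions(_anchor())
        assert dirs.shape == (6, 3)
        assert np.allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-10)
        dots = dirs @ dirs.T
        off = dots[~np.eye(6, dtype=bool)]
        assert set(np.round(off, 9)) <= {-1.0, 0.0}

    def test_minimum_pairwise_angle_90_degrees(self):
        dirs = octahedral_directions(_anchor())
        angles = []
        for i in range(6):
            for j in range(i + 1, 6):
                angles.append(np.degrees(np.arccos(np.clip(dirs[i] @ dirs[j], -1, 1))))
        assert min(angles) == pytest.approx(90.0, abs=1e-7)

    def test_rigid_rotation_equivariance(self):
        anchor = _anchor()
        dirs = octahedral_directions(anchor)
        rot = rotation_about_axis(np.array([1.0, -2.0, 0.5]), 1.234)
        rotated = Residue(anchor.name, anchor.number, "", [
            type(a)(a.serial, a.name, a.altloc, a.element, rot @ a.coords)
            for a in anchor.atoms
        ])
        dirs2 = octahedral_directions(rotated)
        assert np.allclose(dirs2, dirs @ rot.T, atol=1e-9)

    def test_degenerate_anchor_rejected(self):
        res = Residue("GLY", 1, "", [])
        from pdbmend.pdbio import AtomRecord

        for i, name in enumerate(["N", "CA", "C"]):
            res.atoms.append(AtomRecord(i, name, "", name[0], np.array([float(i), 0, 0])))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            octahedral_directions(res)


class TestPlaceFragment:
    def _fragment(self, n=5):
        anchor = _anchor()
        frame = (anchor.coord("N"), anchor.coord("CA"), anchor.coord("C"))
        return anchor, build_alltrans(random_sequence(n, np.random.default_rng(1)),
                                      attach_frame=frame)

    def test_axis_aligned_with_direction(self):
        anchor, frag = self._fragment()
        for direction in octahedral_directions(anchor):
            placed = place_fragment(frag, direction)
            axis = placed.c_term.coord("CA") - placed.n_term_n
            cosang = axis @ direction / np.linalg.norm(axis)
            assert np.arccos(np.clip(cosang, -1, 1)) < 1e-6

    def test_attachment_bond_preserved(self):
        anchor, frag = self._fragment()
        d0 = bond_length(anchor.coord("C"), frag.n_term_n)
        for direction in octahedral_directions(anchor):
            placed = place_fragment(frag, direction)
            assert bond_length(anchor.coord("C"), placed.n_term_n) == pytest.approx(
                d0, abs=1e-9
            )

    def test_six_distinct_tips(self):
        anchor, frag = self._fragment()
        tips = [place_fragment(frag, d).c_term.coord("CA")
                for d in octahedral_directions(anchor)]
        for i in range(6):
            for j in range(i + 1, 6):
                assert np.linalg.norm(tips[i] - tips[j]) > 1.0

    def test_single_residue_fragment_uses_nc_axis(self):
        anchor = _anchor()
        frame = (anchor.coord("N"), anchor.coord("CA"), anchor.coord("C"))
        frag = build_alltrans(["GLY"], attach_frame=frame)
        direction = octahedral_directions(anchor)[2]
        placed = place_fragment(frag, direction)
        axis = placed.c_term.coord("C") - placed.n_term_n
        cosang = axis @ direction / np.linalg.norm(axis)
        assert np.arccos(np.clip(cosang, -1, 1)) < 1e-6


class TestCloseGap:
    def test_single_gly_between_ideal_anchors(self):
        """A 1-residue gap at ideal spacing closes with a sane peptide bond."""
        model = make_ideal_peptide(["ALA"] * 9, "alltrans", with_hydrogens=False)
        damaged, _ = ablate(model, AblationPlan(deleted_runs=[(5, 5)]))
        chain = roundtrip(damaged).chains[0]
        up, down = chain.residue(4), chain.residue(6)
        frame = (up.coord("N"), up.coord("CA"), up.coord("C"))
        frag = build_alltrans(["GLY"], attach_frame=frame, numbers=[5])
        closed, trial = close_gap(frag, up, down)
        assert not trial.failed
        assert abs(trial.closure_bond - 1.329) <= 0.1
        res = closed.residues[0]
        omega = dihedral(res.coord("CA"), res.coord("C"), down.coord("N"),
                         down.coord("CA"))
        assert abs(abs(omega) - 180.0) <= 30.0

    def test_anchor_coordinates_bit_identical(self):
        model = make_ideal_peptide(["ALA"] * 9, "alltrans", with_hydrogens=False)
        damaged, _ = ablate(model, AblationPlan(deleted_runs=[(5, 5)]))
        chain = roundtrip(damaged).chains[0]
        up, down = chain.residue(4), chain.residue(6)
        before_up = [a.coords.copy() for a in up.atoms]
        before_down = [a.coords.copy() for a in down.atoms]
        frame = (up.coord("N"), up.coord("CA"), up.coord("C"))
        frag = build_alltrans(["GLY"], attach_frame=frame, numbers=[5])
        close_gap(frag, up, down)
        assert all(np.array_equal(a.coords, b) for a, b in zip(up.atoms, before_up))
        assert all(np.array_equal(a.coords, b) for a, b in zip(down.atoms, before_down))

    def test_overcrowded_gap_reported_not_crashed(self):
        """Anchors 2 Å apart with a 10-residue gap: a pathological request."""
        a = build_alltrans(["ALA"], numbers=[1]).residues[0]
        b = build_alltrans(["ALA"], numbers=[12]).residues[0]
        for atom in b.atoms:
            atom.coords = atom.coords + np.array([2.0, 0.5, 0.5])
        chain = Chain("A", residues=[a, b], seqres=["ALA"] + ["GLY"] * 10 + ["ALA"])
        model = StructureModel(chains=[chain])
        _, report = repair_chain(
            model, "A", config=RepairConfig(minimize_final=False, closure_max_iter=100)
        )
        g = report.gap_results[0]
        # either it crumples in (finite clash trials) or every trial fails
        assert g.closed or g.reason == "all orientations failed"


class TestRepairChain:
    def test_helix_deletion_census_and_rmsd(self, helix60):
        model, seq = helix60
        damaged, truth = ablate(model, AblationPlan(deleted_runs=[(25, 30)]))
        damaged = roundtrip(damaged)
        repaired, report = repair_chain(
            damaged, "A", config=RepairConfig(final_max_iter=150)
        )
        assert report.success
        assert chain_gaps(repaired.chains[0]) == []
        assert (report.n_atoms, report.n_hydrogens) == expected_atom_count(
            seq, nterm="charged", cterm="charged"
        )
        assert report.backbone_rmsd < 1.5

    def test_gap_free_chain_passthrough(self):
        model = roundtrip(make_ideal_peptide(
            random_sequence(15, np.random.default_rng(2)), "helix",
            with_hydrogens=False))
        _, report = repair_chain(model, "A", config=FAST)
        assert report.n_gaps == 0
        assert report.gap_results == []

    def test_heavy_atom_limit_refusal(self):
        model = roundtrip(make_ideal_peptide("AAAA", with_hydrogens=False))
        with pytest.raises(ChainTooLargeError):
            repair_chain(model, "A", config=RepairConfig(max_heavy_atoms=10))

    def test_anchor_atoms_move_only_in_final_stage(self):
        """Anchors are immobile during closure; the final unconstrained
        minimization is allowed to move them."""
        damaged, truth, seq = damaged_helix(21)
        frozen = roundtrip(damaged)
        start, end = truth.runs[0]
        anchor_before = frozen.chains[0].residue(start - 1).coord("CA").copy()
        _, rep_nofinal = repair_chain(roundtrip(damaged), "A", config=FAST)
        m2 = roundtrip(damaged)
        repair_chain(m2, "A", config=FAST)
        after_closure = m2.chains[0].residue(start - 1).coord("CA")
        assert np.allclose(after_closure, anchor_before, atol=1e-9)
        m3 = roundtrip(damaged)
        _, rep_final = repair_chain(
            m3, "A", config=RepairConfig(closure_max_iter=200, final_max_iter=80)
        )
        moved = np.linalg.norm(m3.chains[0].residue(start - 1).coord("CA") - anchor_before)
        assert moved > 0  # unconstrained final stage relaxes everything

    @pytest.mark.parametrize("seed", [31, 32])
    def test_census_conservation_two_code_paths(self, seed):
        """Repaired atom count equals the pure template census, per fixture."""
        damaged, truth, seq = damaged_helix(seed, n_res=25, max_run=4)
        repaired, report = repair_chain(damaged, "A", config=FAST)
        assert all(g.closed for g in report.gap_results)
        assert (report.n_atoms, report.n_hydrogens) == expected_atom_count(
            seq, nterm="charged", cterm="charged"
        )

    def test_report_serialization(self):
        damaged, truth, seq = damaged_helix(33, n_res=20, max_run=3)
        _, report = repair_chain(damaged, "A", config=FAST)
        assert '"census"' in report.to_json()
        assert "Repair report" in report.to_text()
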