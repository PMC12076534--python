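"""Fragment building, side-chain completion, hydrogen addition, censuses."""

import numpy as np
import pytest

from pdbmend.errors import PdbmendError
from pdbmend.fixtures import make_ideal_peptide, random_sequence, roundtrip
from pdbmend.geometry import bond_length, dihedral, place_atom
from pdbmend.pdbio import Chain, StructureModel
from pdbmend.residue_builder import (
    add_hydrogens,
    build_alltrans,
    complete_sidechains,
    expected_atom_count,
)
from pdbmend.templates import UntemplatedResidueError, get_template


def _nerf_oracle_ca_distance(n: int) -> float:
    """Independent minimal NeRF chain builder for an all-trans poly-ALA
    backbone; returns the CA(1)-CA(n) distance."""
    geo = dict(n_ca=1.458, ca_c=1.525, c_n=1.329, c_o=1.231)
    ang = dict(n_ca_c=111.2, ca_c_n=116.2, c_n_ca=121.7)
    N = np.zeros(3)
    CA = np.array([geo["n_ca"], 0.0, 0.0])
    C = place_atom(CA, N, np.array([0.0, 1.0, 0.0]), geo["ca_c"], ang["n_ca_c"], 0.0)
    cas = [CA]
    for _ in range(n - 1):
        N2 = place_atom(C, CA, N, geo["c_n"], ang["ca_c_n"], 180.0)
        CA2 = place_atom(N2, C, CA, geo["n_ca"], ang["c_n_ca"], 180.0)
        C2 = place_atom(CA2, N2, C, geo["ca_c"], ang["n_ca_c"], 180.0)
        N, CA, C = N2, CA2, C2
        cas.append(CA)
    return float(np.linalg.norm(cas[-1] - cas[0]))


class TestBuildAlltrans:
    def test_glycine_heavy_atoms(self):
        frag = build_alltrans(["GLY"])
        names = {a.name for a in frag.residues[0].atoms}
        assert names == {"N", "CA", "C", "O"}

    def test_ca_span_matches_independent_nerf_oracle(self):
        frag = build_alltrans(["ALA"] * 10)
        d = bond_length(frag.residues[0].coord("CA"), frag.residues[9].coord("CA"))
        assert d == pytest.approx(_nerf_oracle_ca_distance(10), abs=1e-6)

    def test_omega_and_peptide_bonds_by_construction(self):
        frag = build_alltrans(random_sequence(8, np.random.default_rng(0)))
        for a, b in zip(frag.residues, frag.residues[1:]):
            omega = dihedral(a.coord("CA"), a.coord("C"), b.coord("N"), b.coord("CA"))
            assert abs(abs(omega) - 180.0) < 1e-6
            assert bond_length(a.coord("C"), b.coord("N")) == pytest.approx(1.329, abs=1e-6)

    def test_attachment_to_anchor_frame(self):
        anchor = build_alltrans(["ALA"]).residues[0]
        frame = (anchor.coord("N"), anchor.coord("CA"), anchor.coord("C"))
        frag = build_alltrans(["GLY", "SER"], attach_frame=frame)
        assert bond_length(anchor.coord("C"), frag.residues[0].coord("N")) == pytest.approx(
            1.329, abs=1e-9
        )

    def test_untemplated_code_listed(self):
        with pytest.raises(UntemplatedResidueError, match="PTR"):
            build_alltrans(["ALA", "PTR"])

    def test_template_bond_lengths_on_random_builds(self, rng):
        """All template-placed bonds within 0.05 Å of their template lengths."""
        for _ in range(5):
            seq = random_sequence(6, rng)
            frag = build_alltrans(seq)
            for res in frag.residues:
                tpl = get_template(res.name)
                for entry in tpl.heavy_ics:
                    d = bond_length(res.coord(entry.name), res.coord(entry.refs[0]))
                    assert abs(d - entry.r) < 0.05


class TestCompleteSidechains:
    def test_truncated_lysine_completed(self):
        model = make_ideal_peptide(["ALA", "LYS", "ALA"], with_hydrogens=False)
        res = model.chains[0].residue(2)
        keep = {"N", "CA", "C", "O", "CB"}
        res.atoms = [a for a in res.atoms if a.name in keep]
        _, added = complete_sidechains(model)
        assert added[("A", 2, "")] == ["CG", "CD", "CE", "NZ"]
        assert len(res.heavy_atoms()) == 9

    def test_complete_model_untouched(self):
        model = make_ideal_peptide(random_sequence(8, np.random.default_rng(1)),
                                   with_hydrogens=False)
        before = model.all_coords().copy()
        _, added = complete_sidechains(model)
        assert added == {}
        assert np.array_equal(model.all_coords(), before)

    def test_random_truncations_restore_template_counts(self, rng):
        seq = random_sequence(20, rng)
        model = make_ideal_peptide(seq, with_hydrogens=False)
        chain = model.chains[0]
        for num in rng.choice(np.arange(2, 20), size=5, replace=False):
            res = chain.residue(int(num))
            res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "CB")]
        complete_sidechains(model)
        for res in chain.residues:
            assert len(res.heavy_atoms()) == get_template(res.name).n_heavy

    def test_missing_backbone_skipped_with_warning(self):
        model = make_ideal_peptide(["ALA", "LYS", "ALA"], with_hydrogens=False)
        res = model.chains[0].residue(2)
        res.atoms = [a for a in res.atoms if a.name in ("N", "CB")]
        complete_sidechains(model)
        assert any("incomplete backbone" in w for w in model.warnings)
        assert res.atom("CG") is None


class TestAddHydrogens:
    def test_internal_ala_five_hydrogens(self):
        model = make_ideal_peptide(["GLY", "ALA", "GLY"], with_hydrogens=False)
        add_hydrogens(model)
        names = {a.name for a in model.chains[0].residue(2).atoms if a.element == "H"}
        assert names == {"H", "HA", "HB1", "HB2", "HB3"}

    @pytest.mark.parametrize(
        "variant,present,absent",
        [("HIE", "HE2", "HD1"), ("HID", "HD1", "HE2")],
    )
    def test_histidine_tautomers(self, variant, present, absent):
        model = make_ideal_peptide(["GLY", "HIS", "GLY"], with_hydrogens=False)
        add_hydrogens(model, states={("A", 2, ""): variant})
        names = {a.name for a in model.chains[0].residue(2).atoms}
        assert present in names and absent not in names

    def test_metal_coordinating_cysteine_has_no_hg(self):
        model = make_ideal_peptide(["GLY", "CYS", "GLY"], with_hydrogens=False)
        add_hydrogens(model, states={("A", 2, ""): "CYM"})
        assert model.chains[0].residue(2).atom("HG") is None
        add_hydrogens(model)  # default: protonated
        assert model.chains[0].residue(2).atom("HG") is not None

    def test_idempotence(self):
        model = make_ideal_peptide(random_sequence(10, np.random.default_rng(2)),
                                   with_hydrogens=False)
        add_hydrogens(model)
        first = model.all_coords().copy()
        add_hydrogens(model)
        assert np.array_equal(model.all_coords(), first)

    def test_charged_termini_geometry_matches_census(self):
        seq = random_sequence(6, np.random.default_rng(3))
        model = make_ideal_peptide(seq, with_hydrogens=False)
        add_hydrogens(model, termini={"A": ("charged", "charged")})
        total = model.chains[0].n_atoms
        nh = sum(1 for r in model.chains[0].residues for a in r.atoms if a.element == "H")
        assert (total, nh) == expected_atom_count(seq, nterm="charged", cterm="charged")


class TestCensusGeometryConsistency:
    @pytest.mark.parametrize("seed", [10, 11, 12, 13])
    def test_census_equals_built_model(self, seed):
        """Two independent code paths: table census vs geometric construction."""
        rng = np.random.default_rng(seed)
        seq = random_sequence(int(rng.integers(5, 15)), rng)
        model = make_ideal_peptide(seq)  # build + sidechains + hydrogens
        total = model.chains[0].n_atoms
        nh = sum(1 for r in model.chains[0].residues for a in r.atoms if a.element == "H")
        assert (total, nh) == expected_atom_count(seq)

    def test_roundtripped_model_same_census(self):
        seq = random_sequence(8, np.random.default_rng(14))
        model = roundtrip(make_ideal_peptide(seq))
        assert model.n_atoms == expected_atom_count(seq)[0]
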