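"""Reduced force field: topology, energies, gradients, clashes, minimizer."""

import numpy as np
import pytest

from pdbmend.energy_min import (
    EnergyTopology,
    NeighborList,
    build_topology,
    clash_score,
    energy_and_gradient,
    minimize,
)
from pdbmend.errors import TopologyError
from pdbmend.fixtures import make_ideal_peptide, random_sequence
from pdbmend.geometry import rotation_about_axis
from pdbmend.pdbio import AtomRecord, Chain, Residue, StructureModel
from pdbmend.residue_builder import add_hydrogens, build_alltrans


def _dimer(k=1000.0, r0=1.5, exclude_lj=True):
    n = 2
    return EnergyTopology(
        n_atoms=n, elements=["C", "C"],
        bonds=np.array([[0, 1]]), bond_k=np.array([k]), bond_r0=np.array([r0]),
        angles=np.empty((0, 3), int), angle_k=np.empty(0), angle_t0=np.empty(0),
        torsions=np.empty((0, 4), int), torsion_k=np.empty(0),
        torsion_n=np.empty(0, int), torsion_phase=np.empty(0),
        lj_sigma=np.full(n, 3.4), lj_eps=np.full(n, 0.36),
        vdw_radii=np.full(n, 1.7),
        excluded_keys=np.array([1], dtype=np.int64) if exclude_lj else np.empty(0, np.int64),
        pair14_keys=np.empty(0, dtype=np.int64),
        fixed=np.zeros(n, bool),
    )


def _peptide_topology(seq=None, seed=0):
    seq = seq or random_sequence(3, np.random.default_rng(seed))
    model = StructureModel(chains=[Chain("A", residues=build_alltrans(seq).residues)])
    add_hydrogens(model)
    return model, build_topology(model)


class TestEnergy:
    def test_bond_at_minimum_zero(self):
        e, g, _ = energy_and_gradient(np.array([[0, 0, 0], [1.5, 0, 0.0]]), _dimer())
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.max(np.abs(g)) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_closed_form(self):
        # E = 1/2 k d^2 = 0.5 * 1000 * 0.01 = 5.0 kJ/mol
        e, _, _ = energy_and_gradient(np.array([[0, 0, 0], [1.6, 0, 0.0]]), _dimer())
        assert e == pytest.approx(5.0, abs=1e-9)

    def test_overlapping_nonbonded_pair_raises(self):
        top = _dimer(exclude_lj=False)
        top.bonds = np.empty((0, 2), int)
        top.bond_k = np.empty(0)
        top.bond_r0 = np.empty(0)
        with pytest.raises(ValueError, match="overlap"):
            energy_and_gradient(np.array([[0, 0, 0], [0, 0, 1e-8]]), top)

    def test_analytic_gradient_matches_finite_differences(self):
        """Central finite differences agree to 1e-6 relative on a peptide."""
        model, top = _peptide_topology(seed=3)
        rng = np.random.default_rng(5)
        x = model.all_coords() + 0.05 * rng.normal(size=(top.n_atoms, 3))
        _, g, _ = energy_and_gradient(x, top, NeighborList(top.cutoff))
        h = 1e-6
        gfd = np.zeros_like(x)
        for i in range(top.n_atoms):
            for k in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, k] += h
                xm[i, k] -= h
                ep, _, _ = energy_and_gradient(xp, top, NeighborList(top.cutoff))
                em, _, _ = energy_and_gradient(xm, top, NeighborList(top.cutoff))
                gfd[i, k] = (ep - em) / (2 * h)
        rel = np.max(np.abs(g - gfd)) / max(1.0, np.max(np.abs(gfd)))
        assert rel < 1e-6

    def test_rigid_motion_invariance(self):
        model, top = _peptide_topology(seed=4)
        x = model.all_coords()
        e1, _, _ = energy_and_gradient(x, top, NeighborList(top.cutoff))
        rot = rotation_about_axis(np.array([0.2, 0.7, -0.4]), 0.9)
        x2 = (x - x.mean(0)) @ rot.T + np.array([7.0, -2.0, 3.0])
        e2, _, _ = energy_and_gradient(x2, top, NeighborList(top.cutoff))
        assert abs(e1 - e2) < 1e-8


class TestTopology:
    def test_ala_dipeptide_bond_count(self):
        """Heavy+H bonds: 2x ALA template bonds (10 each) + 1 peptide bond."""
        model = StructureModel(
            chains=[Chain("A", residues=build_alltrans(["ALA", "ALA"]).residues)]
        )
        add_hydrogens(model)
        top = build_topology(model)
        # per ALA: N-CA, CA-C, C-O, CA-CB, N-H, CA-HA, CB-HB1/2/3 = 9 bonds
        assert len(top.bonds) == 2 * 9 + 1

    def test_bridged_pair_has_one_ss_bond(self):
        from pdbmend.chem_states import ChemState

        model = make_ideal_peptide(["CYS", "GLY", "CYS"], with_hydrogens=False)
        state = ChemState(
            variants={("A", 1, ""): "CYX", ("A", 3, ""): "CYX"},
            disulfides=[(("A", 1, ""), ("A", 3, ""))],
        )
        top = build_topology(model, states=state)
        ss = [
            b for b, r0 in zip(top.bonds, top.bond_r0)
            if abs(r0 - 2.05) < 1e-9
        ]
        assert len(ss) == 1

    def test_single_isolated_atom_no_bonded_terms(self):
        model = StructureModel(metals=[AtomRecord(1, "ZN", "", "ZN", np.zeros(3))])
        top = build_topology(model)
        assert len(top.bonds) == 0 and len(top.angles) == 0 and len(top.torsions) == 0

    def test_variant_mismatch_raises(self):
        model = make_ideal_peptide(["GLY", "CYS", "GLY"], with_hydrogens=False)
        add_hydrogens(model)  # protonated: HG present
        from pdbmend.chem_states import ChemState

        state = ChemState(variants={("A", 2, ""): "CYM"})  # defines no HG
        with pytest.raises(TopologyError, match="CYS 2"):
            build_topology(model, states=state)


class TestClashScore:
    def test_far_apart_no_clash(self):
        n, ov = clash_score(np.zeros((1, 3)), np.array([1.7]),
                            np.array([[20.0, 0, 0]]), np.array([1.7]))
        assert (n, ov) == (0, 0.0)

    def test_two_carbons_at_one_angstrom(self):
        n, ov = clash_score(np.zeros((1, 3)), np.array([1.7]),
                            np.array([[1.0, 0, 0]]), np.array([1.7]))
        assert n == 1
        assert ov == pytest.approx(0.6 * 3.4 - 1.0)  # 1.04 Å

    def test_matches_brute_force_on_random_configurations(self, rng):
        for _ in range(20):
            nf, ne = rng.integers(3, 12, size=2)
            fc = rng.uniform(0, 8, size=(nf, 3))
            ec = rng.uniform(0, 8, size=(ne, 3))
            fr = rng.uniform(1.2, 1.9, size=nf)
            er = rng.uniform(1.2, 1.9, size=ne)
            got = clash_score(fc, fr, ec, er)
            n = ov = 0
            for i in range(nf):
                for j in range(ne):
                    thr = 0.6 * (fr[i] + er[j])
                    d = np.linalg.norm(fc[i] - ec[j])
                    if d < thr:
                        n += 1
                        ov += thr - d
            assert got[0] == n
            assert got[1] == pytest.approx(ov)


class TestMinimize:
    def test_start_at_minimum_zero_iterations(self):
        x0 = np.array([[0, 0, 0], [1.5, 0, 0.0]])
        res = minimize(x0, _dimer(), gtol=1e-6)
        assert res.iterations == 0
        assert np.array_equal(res.coords, x0)
        assert res.converged

    def test_stretched_dimer_converges_to_r0(self):
        res = minimize(np.array([[0, 0, 0], [2.5, 0, 0.0]]), _dimer(), gtol=1e-4)
        assert res.converged
        assert np.linalg.norm(res.coords[1] - res.coords[0]) == pytest.approx(1.5, abs=1e-4)

    def test_all_atoms_fixed_contract(self):
        top = _dimer()
        top.fixed = np.ones(2, bool)
        x0 = np.array([[0, 0, 0], [2.5, 0, 0.0]])
        res = minimize(x0, top)
        assert np.array_equal(res.coords, x0)
        assert res.converged  # nothing movable: trivially done

    def test_fixed_atom_immobile_in_mixed_system(self):
        top = _dimer()
        top.fixed = np.array([True, False])
        x0 = np.array([[0.25, -1.0, 3.0], [2.75, -1.0, 3.0]])
        res = minimize(x0, top, gtol=1e-4)
        assert np.array_equal(res.coords[0], x0[0])  # bit-identical
        assert np.linalg.norm(res.coords[1] - res.coords[0]) == pytest.approx(1.5, abs=1e-4)

    def test_energy_trajectory_monotone_on_peptide(self):
        model, top = _peptide_topology(seed=8)
        rng = np.random.default_rng(9)
        x = model.all_coords() + 0.15 * rng.normal(size=(top.n_atoms, 3))
        res = minimize(x, top, max_iter=150)
        assert all(b <= a + 1e-9 for a, b in zip(res.energies, res.energies[1:]))
        assert res.energy <= res.energies[0]


def test_neighbor_list_matches_brute_force_lj(rng):
    """Cell-list style LJ sum equals the O(n^2) oracle on random configs."""
    for _ in range(10):
        n = int(rng.integers(10, 40))
        coords = rng.uniform(0, 18, size=(n, 3))
        # enforce a minimum separation so LJ stays finite
        coords += np.arange(n)[:, None] * 1e-3
        top = EnergyTopology(
            n_atoms=n, elements=["C"] * n,
            bonds=np.empty((0, 2), int), bond_k=np.empty(0), bond_r0=np.empty(0),
            angles=np.empty((0, 3), int), angle_k=np.empty(0), angle_t0=np.empty(0),
            torsions=np.empty((0, 4), int), torsion_k=np.empty(0),
            torsion_n=np.empty(0, int), torsion_phase=np.empty(0),
            lj_sigma=np.full(n, 3.4), lj_eps=np.full(n, 0.36),
            vdw_radii=np.full(n, 1.7),
            excluded_keys=np.empty(0, np.int64), pair14_keys=np.empty(0, np.int64),
            fixed=np.zeros(n, bool),
        )
        e, _, _ = energy_and_gradient(coords, top, NeighborList(top.cutoff))
        brute = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                r = np.linalg.norm(coords[i] - coords[j])
                if r < top.cutoff:
                    sr6 = (3.4 / r) ** 6
                    src6 = (3.4 / top.cutoff) ** 6
                    brute += 4 * 0.36 * (sr6**2 - sr6) - 4 * 0.36 * (src6**2 - src6)
        assert e == pytest.approx(brute, rel=1e-9, abs=1e-9)
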