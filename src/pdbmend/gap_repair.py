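"""Per-gap divide-and-conquer repair.

Each internal gap is processed independently, in chain order:

1. the missing subsequence is built fully extended (all-trans) with its
   N-terminus bonded to the residue upstream of the gap;
2. the fragment is rigidly rotated about its attachment nitrogen so that its
   free end points, in turn, toward the six vertices of an octahedron (the
   ±axes of an orthonormal frame anchored on the upstream residue);
3. orientations with too many hard steric clashes against the atoms present
   are discarded; the survivors are closed by constrained minimization — a
   harmonic restraint pulls the fragment's C-terminal carbon onto the
   downstream anchor nitrogen while both anchor residues stay fixed;
4. the lowest-energy successful closure is inserted into the chain.

After every gap is closed: side-chain completion, a fresh chemical-state
assignment (inserted residues may coordinate metals), hydrogen addition, and
an unconstrained minimization of the whole chain with ligands and metals as
rigid/nonbonded participants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .chem_states import ChemState, assign_states
from .errors import ChainTooLargeError, GapRepairError
from .geometry import bond_length, dihedral, place_atom, rotation_aligning
from .pdbio import Chain, Residue, StructureModel
from .residue_builder import (
    BACKBONE,
    Fragment,
    add_hydrogens,
    build_alltrans,
    complete_sidechains,
    expected_atom_count,
)
from .sequence_gaps import GapRecord, chain_gaps, match_seqres
from .energy_min import (
    NeighborList,
    build_topology,
    clash_score,
    energy_and_gradient,
    load_params,
    minimize,
)

__all__ = [
    "RepairConfig",
    "OrientationTrial",
    "GapResult",
    "RepairReport",
    "octahedral_directions",
    "place_fragment",
    "close_gap",
    "repair_chain",
]


@dataclass
class RepairConfig:
    max_heavy_atoms: int = 9000  # chains above this limit are refused
    clash_threshold: int = 5  # hard clashes allowed before a trial is discarded
    closure_max_iter: int = 300
    final_max_iter: int = 300
    gtol: float = 10.0  # kJ/mol/A per atom
    closure_bond_tol: float = 0.1  # closure C-N within 1.329 +/- tol (A)
    env_margin: float = 12.0  # environment inclusion radius around the gap
    minimize_final: bool = True


@dataclass
class OrientationTrial:
    direction_index: int  # 1..6
    direction: np.ndarray
    n_clashes: int = 0
    overlap: float = 0.0
    closure_energy: float = float("nan")
    closure_converged: bool = False
    closure_bond: float = float("nan")
    failed: bool = True
    reason: str = ""


@dataclass
class GapResult:
    gap: GapRecord
    trials: list[OrientationTrial] = field(default_factory=list)
    chosen: int | None = None  # direction index of the accepted trial
    closed: bool = False
    reason: str = ""


@dataclass
class RepairReport:
    chain_id: str
    gap_results: list[GapResult]
    n_atoms: int = 0  # chain atoms incl. hydrogens after repair
    n_hydrogens: int = 0
    n_ligand_atoms: int = 0
    n_gaps: int = 0
    pre_energy: float = float("nan")
    post_energy: float = float("nan")
    energy_per_residue: float = float("nan")
    backbone_rmsd: float = float("nan")
    final_converged: bool = False
    final_max_gradient: float = float("nan")
    success: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "chain": self.chain_id,
                "n_gaps": self.n_gaps,
                "gaps": [
                    {
                        "span": g.gap.span,
                        "length": len(g.gap),
                        "closed": g.closed,
                        "chosen_direction": g.chosen,
                        "reason": g.reason,
                        "trials": [
                            {
                                "direction": t.direction_index,
                                "n_clashes": t.n_clashes,
                                "closure_energy": None
                                if np.isnan(t.closure_energy)
                                else round(t.closure_energy, 2),
                                "closure_bond": None
                                if np.isnan(t.closure_bond)
                                else round(t.closure_bond, 3),
                                "converged": t.closure_converged,
                                "failed": t.failed,
                                "reason": t.reason,
                            }
                            for t in g.trials
                        ],
                    }
                    for g in self.gap_results
                ],
                "census": {
                    "N": self.n_atoms,
                    "Nh": self.n_hydrogens,
                    "NL": self.n_ligand_atoms,
                },
                "pre_energy": None if np.isnan(self.pre_energy) else round(self.pre_energy, 2),
                "post_energy": None if np.isnan(self.post_energy) else round(self.post_energy, 2),
                "energy_per_residue": None
                if np.isnan(self.energy_per_residue)
                else round(self.energy_per_residue, 2),
                "backbone_rmsd": None
                if np.isnan(self.backbone_rmsd)
                else round(self.backbone_rmsd, 3),
                "final_converged": self.final_converged,
                "success": self.success,
            },
            indent=2,
        )

    def to_text(self) -> str:
        rows = [f"Repair report, chain {self.chain_id}: {self.n_gaps} gap(s)"]
        for g in self.gap_results:
            status = f"closed via direction {g.chosen}" if g.closed else f"FAILED ({g.reason})"
            rows.append(f"  gap {g.gap.span[0]}-{g.gap.span[1]} ({len(g.gap)} res): {status}")
            for t in g.trials:
                e = "-" if np.isnan(t.closure_energy) else f"{t.closure_energy:.1f}"
                rows.append(
                    f"    dir {t.direction_index}: clashes {t.n_clashes}, "
                    f"E {e}, bond "
                    + ("-" if np.isnan(t.closure_bond) else f"{t.closure_bond:.3f}")
                    + ("" if t.failed else "  <- ok")
                )
        rows.append(
            f"  census: N={self.n_atoms} Nh={self.n_hydrogens} NL={self.n_ligand_atoms}"
        )
        rows.append(
            f"  energy: {self.post_energy:.1f} kJ/mol"
            f" ({self.energy_per_residue:.1f} per residue),"
            f" max gradient {self.final_max_gradient:.2f}"
        )
        rows.append(f"  backbone RMSD (observed atoms): {self.backbone_rmsd:.3f} A")
        rows.append(f"  success: {self.success}")
        return "\n".join(rows)


# --- geometry of the orientation search --------------------------------------


def octahedral_directions(anchor: Residue) -> np.ndarray:
    """Six unit vectors (±3 orthonormal axes) anchored on the upstream residue.

    e1 points along the ideal next-peptide-bond direction from the anchor C;
    e2 lies in the anchor N-CA-C plane; e3 completes the right-handed frame.
    """
    n, ca, c = anchor.coord("N"), anchor.coord("CA"), anchor.coord("C")
    return _octahedral_from_frame(n, ca, c)


def _octahedral_from_frame(n, ca, c) -> np.ndarray:
    if n is None or ca is None or c is None:
        raise ValueError("anchor residue lacks N/CA/C")
    virtual_n = place_atom(c, ca, n, BACKBONE["c_n"], BACKBONE["ang_ca_c_n"], 180.0)
    e1 = virtual_n - c
    norm = np.linalg.norm(e1)
    plane = np.cross(ca - n, c - ca)
    if norm < 1e-8 or np.linalg.norm(plane) < 1e-8:
        raise ValueError("degenerate (collinear) anchor atoms")
    e1 /= norm
    plane /= np.linalg.norm(plane)
    e2 = np.cross(plane, e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return np.array([e1, e2, e3, -e1, -e2, -e3])


def place_fragment(fragment: Fragment, direction: np.ndarray) -> Fragment:
    """Rigidly rotate the fragment about its attachment N onto ``direction``.

    The fragment axis is N(first) -> CA(last); for a single-residue fragment
    it degenerates to N -> C of that residue. The attachment bond geometry is
    preserved (the pivot is the bonded atom itself).
    """
    pivot = fragment.n_term_n
    if len(fragment.residues) > 1:
        tip = fragment.c_term.coord("CA")
    else:
        tip = fragment.c_term.coord("C")
    axis = tip - pivot
    rot = rotation_aligning(axis, direction)
    out = []
    for res in fragment.residues:
        atoms = [
            type(a)(a.serial, a.name, a.altloc, a.element,
                    pivot + rot @ (a.coords - pivot), a.occupancy, a.bfactor, a.is_het)
            for a in res.atoms
        ]
        out.append(Residue(res.name, res.number, res.icode, atoms))
    return Fragment(residues=out, anchor_frame=fragment.anchor_frame)


# --- closure ------------------------------------------------------------------


def close_gap(
    fragment: Fragment,
    upstream: Residue,
    downstream: Residue,
    environment: list | None = None,
    config: RepairConfig | None = None,
) -> tuple[Fragment, OrientationTrial]:
    """Minimize the fragment onto the downstream anchor under a closure restraint.

    Both anchor residues (and any environment atoms) are held fixed; only
    fragment atoms move. On success the closure C-N bond is within
    1.329 ± tolerance Å.
    """
    config = config or RepairConfig()
    mini = StructureModel()
    chain = Chain("_")
    up_copy = Residue(upstream.name, upstream.number, upstream.icode,
                      [a for a in upstream.atoms if a.element != "H"])
    down_copy = Residue(downstream.name, downstream.number, downstream.icode,
                        [a for a in downstream.atoms if a.element != "H"])
    chain.residues = [up_copy] + fragment.residues + [down_copy]
    mini.chains = [chain]
    if environment:
        env_res = Residue("ENV", 1, "", list(environment))
        mini.het_groups.append(("E", env_res))

    fixed = {("_", up_copy.number, up_copy.icode), ("_", down_copy.number, down_copy.icode),
             ("E", 1, "")}
    top = build_topology(mini, fixed_keys=fixed)

    # during closure the fragment must fold; the generic 3-fold torsion
    # barriers only hinder that, so keep just the peptide-planarity terms
    keep = top.torsion_n == 2
    top.torsions = top.torsions[keep]
    top.torsion_k = top.torsion_k[keep]
    top.torsion_n = top.torsion_n[keep]
    top.torsion_phase = top.torsion_phase[keep]

    # indices of the closure partners
    frag_last = fragment.residues[-1]
    meta = top.atom_meta
    idx_c = meta.index(("chain", "_", frag_last.number, frag_last.icode, "C"))
    idx_ca = meta.index(("chain", "_", frag_last.number, frag_last.icode, "CA"))
    idx_o = meta.index(("chain", "_", frag_last.number, frag_last.icode, "O"))
    idx_n = meta.index(("chain", "_", down_copy.number, down_copy.icode, "N"))
    idx_nca = meta.index(("chain", "_", down_copy.number, down_copy.icode, "CA"))

    params = load_params()
    k_base = params.constants["bond_k"]
    top.bonds = np.vstack([top.bonds, [idx_c, idx_n]])
    top.bond_k = np.append(top.bond_k, k_base)
    top.bond_r0 = np.append(top.bond_r0, BACKBONE["c_n"])
    top.angles = np.vstack([
        top.angles,
        [idx_ca, idx_c, idx_n], [idx_c, idx_n, idx_nca], [idx_o, idx_c, idx_n],
    ])
    top.angle_k = np.append(top.angle_k, [params.constants["angle_k"]] * 3)
    top.angle_t0 = np.append(
        top.angle_t0,
        [np.radians(BACKBONE["ang_ca_c_n"]), np.radians(BACKBONE["ang_c_n_ca"]),
         np.radians(123.3)],
    )
    top.torsions = np.vstack([top.torsions, [idx_ca, idx_c, idx_n, idx_nca]]) \
        if len(top.torsions) else np.array([[idx_ca, idx_c, idx_n, idx_nca]])
    top.torsion_k = np.append(top.torsion_k, params.constants["omega_k"])
    top.torsion_n = np.append(top.torsion_n, 2)
    top.torsion_phase = np.append(top.torsion_phase, np.pi)
    # the restrained pair must feel the restraint, not LJ repulsion
    top.excluded_keys = np.sort(np.append(top.excluded_keys, top.key(
        np.array([idx_c]), np.array([idx_n]))))

    # restraint-stiffness continuation: minimize, and if the bond has not
    # sealed, stiffen the closure restraint and continue from where we are
    x0 = mini.all_coords()
    result = None
    for mult in (1.0, 4.0, 16.0, 64.0):
        top.bond_k[-1] = k_base * mult
        result = minimize(x0, top, max_iter=config.closure_max_iter, gtol=config.gtol)
        x0 = result.coords
        if abs(bond_length(x0[idx_c], x0[idx_n]) - BACKBONE["c_n"]) <= config.closure_bond_tol:
            break
    # report the energy on the base-stiffness surface so trials stay comparable
    top.bond_k[-1] = k_base
    final_energy, _, _ = energy_and_gradient(result.coords, top, NeighborList(top.cutoff))

    closed = []
    cursor = len(up_copy.atoms)
    for res in fragment.residues:
        atoms = []
        for a in res.atoms:
            atoms.append(type(a)(a.serial, a.name, a.altloc, a.element,
                                 result.coords[cursor].copy(), a.occupancy,
                                 a.bfactor, a.is_het))
            cursor += 1
        closed.append(Residue(res.name, res.number, res.icode, atoms))

    bond = bond_length(result.coords[idx_c], result.coords[idx_n])
    trial = OrientationTrial(
        direction_index=0,
        direction=np.zeros(3),
        closure_energy=final_energy,
        closure_converged=result.converged,
        closure_bond=bond,
        failed=abs(bond - BACKBONE["c_n"]) > config.closure_bond_tol,
        reason="" if abs(bond - BACKBONE["c_n"]) <= config.closure_bond_tol
        else f"closure bond {bond:.2f} A outside tolerance",
    )
    return Fragment(residues=closed, anchor_frame=fragment.anchor_frame), trial


# --- whole-chain repair --------------------------------------------------------


def _gather_environment(model: StructureModel, chain_id: str, center: np.ndarray,
                        radius: float, exclude_numbers: set[int]) -> list:
    out = []
    for chain in model.chains:
        for res in chain.residues:
            if chain.id == chain_id and res.number in exclude_numbers:
                continue
            for a in res.atoms:
                if a.element != "H" and np.linalg.norm(a.coords - center) < radius:
                    out.append(a)
    for _, res in model.het_groups:
        out.extend(a for a in res.atoms
                   if a.element != "H" and np.linalg.norm(a.coords - center) < radius)
    for a in model.metals:
        if np.linalg.norm(a.coords - center) < radius:
            out.append(a)
    return out


def _observed_backbone(chain: Chain) -> dict[tuple, np.ndarray]:
    out = {}
    for res in chain.residues:
        for name in ("N", "CA", "C", "O"):
            pos = res.coord(name)
            if pos is not None:
                out[(res.number, res.icode, name)] = pos.copy()
    return out


def repair_chain(
    model: StructureModel,
    chain_id: str,
    gaps: list[GapRecord] | None = None,
    states: ChemState | None = None,
    config: RepairConfig | None = None,
) -> tuple[StructureModel, RepairReport]:
    """Repair every internal gap of one chain, then finish the chemistry.

    Returns the modified model and a :class:`RepairReport`. Raises
    :class:`ChainTooLargeError` above the heavy-atom limit and
    :class:`GapRepairError` only for a missing chain; per-gap failures are
    recorded in the report with ``success = False``.
    """
    config = config or RepairConfig()
    chain = model.chain(chain_id)
    if chain is None:
        raise GapRepairError(f"no chain {chain_id!r} in model")
    if chain.n_heavy_atoms > config.max_heavy_atoms:
        raise ChainTooLargeError(
            f"chain {chain_id}: {chain.n_heavy_atoms} heavy atoms exceeds the"
            f" {config.max_heavy_atoms}-atom limit"
        )
    if gaps is None:
        gaps = chain_gaps(chain)

    deposited = _observed_backbone(chain)
    report = RepairReport(chain_id=chain_id, gap_results=[], n_gaps=len(gaps))

    for gap in gaps:
        result = GapResult(gap=gap)
        report.gap_results.append(result)
        if not gap.repairable:
            result.reason = "gap contains non-standard residues"
            continue
        upstream = chain.residue(*_anchor_key(gap.start_anchor))
        downstream = chain.residue(*_anchor_key(gap.end_anchor))
        if upstream is None or downstream is None or not upstream.has_backbone \
                or not downstream.has_backbone:
            result.reason = "anchor residue missing backbone"
            continue
        numbers = list(range(gap.span[0], gap.span[1] + 1))
        frame = (upstream.coord("N"), upstream.coord("CA"), upstream.coord("C"))
        fragment = build_alltrans(gap.missing_seq, attach_frame=frame, numbers=numbers)
        directions = _octahedral_from_frame(*frame)

        center = 0.5 * (upstream.coord("CA") + downstream.coord("CA"))
        span_reach = 3.8 * (len(gap) + 2)
        exclude = {upstream.number, downstream.number}
        environment = _gather_environment(
            model, chain_id, center, span_reach + config.env_margin, exclude
        )
        env_coords = np.array([a.coords for a in environment]).reshape(-1, 3)
        params = load_params()
        env_radii = np.array([params.vdw_for(a.element) for a in environment])

        placements = []
        for d_index, direction in enumerate(directions, start=1):
            placed = place_fragment(fragment, direction)
            fcoords = placed.coords(heavy_only=True)
            fradii = np.array([
                params.vdw_for(a.element)
                for r in placed.residues for a in r.atoms if a.element != "H"
            ])
            n_clash, overlap = clash_score(fcoords, fradii, env_coords, env_radii)
            trial = OrientationTrial(d_index, direction, n_clash, overlap)
            result.trials.append(trial)
            placements.append((trial, placed))
        survivors = [p for p in placements if p[0].n_clashes <= config.clash_threshold]
        if not survivors:
            # tight gaps (1-residue in a helix) may clash in every orientation;
            # minimization is exactly the tool that relieves overlap, so let the
            # two least-clashing orientations through rather than giving up
            ranked = sorted(placements,
                            key=lambda p: (p[0].n_clashes, p[0].overlap,
                                           p[0].direction_index))
            survivors = ranked[:2]
            for t, _ in survivors:
                t.reason = "clash screen bypassed: no clash-free orientation"
        else:
            for t, _ in placements:
                if t not in [s[0] for s in survivors]:
                    t.reason = (f"{t.n_clashes} clashes > threshold"
                                f" {config.clash_threshold}")
        best: tuple | None = None
        for trial, placed in survivors:
            closed, ct = close_gap(placed, upstream, downstream, environment, config)
            trial.closure_energy = ct.closure_energy
            trial.closure_converged = ct.closure_converged
            trial.closure_bond = ct.closure_bond
            trial.failed = ct.failed
            if ct.reason:
                trial.reason = ct.reason
            if not trial.failed:
                key = (trial.closure_energy, trial.direction_index)
                if best is None or key < best[0]:
                    best = (key, closed, trial.direction_index)
        if best is None:
            result.reason = "all orientations failed"
            continue
        _, closed, d_index = best
        result.chosen = d_index
        result.closed = True
        chain.residues.extend(closed.residues)
        chain.sort_residues()

    # --- final stage: chemistry, hydrogens, unconstrained minimization -------
    complete_sidechains(model)
    states = assign_states(model)
    model.disulfides = [
        ((a[0], a[1], a[2]), (b[0], b[1], b[2])) for a, b in states.disulfides
    ]

    termini = {}
    for ch in model.chains:
        if not ch.is_protein:
            continue
        try:
            m = match_seqres(ch)
            termini[ch.id] = (
                "charged" if m.n_missing_nterm == 0 else "cut",
                "charged" if m.n_missing_cterm == 0 else "cut",
            )
        except Exception:
            termini[ch.id] = ("cut", "cut")
    add_hydrogens(model, states=states, termini=termini)

    fixed = {("het", cid, r.number, r.icode) for cid, r in model.het_groups}
    fixed |= {("metal", a.serial) for a in model.metals}
    top = build_topology(model, states=states, fixed_keys=fixed)
    x0 = model.all_coords()
    nbl = NeighborList(top.cutoff)
    e0, _, _ = energy_and_gradient(x0, top, nbl)
    report.pre_energy = e0
    if config.minimize_final:
        mres = minimize(x0, top, max_iter=config.final_max_iter, gtol=config.gtol)
        _write_back_coords(model, mres.coords)
        report.post_energy = mres.energy
        report.final_converged = mres.converged
        report.final_max_gradient = mres.max_gradient
    else:
        report.post_energy = e0
        report.final_converged = False

    # census and RMSD
    report.n_atoms = chain.n_atoms
    report.n_hydrogens = sum(
        1 for r in chain.residues for a in r.atoms if a.element == "H"
    )
    report.n_ligand_atoms = sum(len(r.atoms) for _, r in model.het_groups)
    n_res = len(chain.residues)
    report.energy_per_residue = report.post_energy / n_res if n_res else float("nan")

    devs = []
    for (num, icode, name), old in deposited.items():
        res = chain.residue(num, icode)
        if res is None:
            continue
        new = res.coord(name)
        if new is not None:
            devs.append(np.sum((new - old) ** 2))
    report.backbone_rmsd = float(np.sqrt(np.mean(devs))) if devs else float("nan")
    report.success = all(g.closed or not g.gap.repairable for g in report.gap_results) \
        and all(g.closed for g in report.gap_results if g.gap.repairable) \
        and (report.final_converged or not config.minimize_final)
    return model, report


def _write_back_coords(model: StructureModel, coords: np.ndarray) -> None:
    i = 0
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                a.coords = coords[i].copy()
                i += 1
    for _, res in model.het_groups:
        for a in res.atoms:
            a.coords = coords[i].copy()
            i += 1
    for res in model.waters:
        for a in res.atoms:
            a.coords = coords[i].copy()
            i += 1
    for a in model.metals:
        a.coords = coords[i].copy()
        i += 1


def _anchor_key(anchor: tuple[int, str]) -> tuple[int, str]:
    return (anchor[0], "")
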