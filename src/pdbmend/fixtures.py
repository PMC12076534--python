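"""Synthetic defective structures with known ground truth.

Every stage of the pipeline is testable offline: fixtures are ideal peptides
(extended or helical) built from the template library, optionally damaged by
an :class:`AblationPlan` (internal residue deletions, side-chain truncations,
hydrogen stripping) whose truth record suffices to verify the repair.

Fixtures are meant to be written to disk as genuine PDB files and re-parsed
(:func:`roundtrip`), so format handling stays on the test path.

The ``synthetic_*`` constructors build stand-ins for two published reference
entries that cannot be redistributed here; they reproduce the *published
properties* (chain sizes, gap spans, zinc-site chemistry, entity counts) on
synthetic coordinates and are labelled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import rotation_about_axis
from .pdbio import (
    AtomRecord,
    Chain,
    Residue,
    StructureModel,
    parse_structure,
    write_structure,
)
from .residue_builder import add_hydrogens, build_alltrans, declash_sidechains
from .templates import STANDARD_AA

__all__ = [
    "AblationPlan",
    "make_ideal_peptide",
    "ablate",
    "make_zinc_site",
    "random_sequence",
    "random_ablation_plan",
    "make_corpus",
    "roundtrip",
    "synthetic_helicase_like",
    "synthetic_two_chain_complex",
]

HELIX_PHI, HELIX_PSI = -57.0, -47.0

# residues drawn for random fixture sequences; CYS excluded so that no
# accidental disulfide or metal chemistry sneaks into a fixture
_POOL = sorted(STANDARD_AA - {"CYS"})


def make_ideal_peptide(
    seq: list[str] | str,
    conformation: str = "alltrans",
    chain_id: str = "A",
    with_hydrogens: bool = True,
    with_sidechains: bool = True,
    numbers: list[int] | None = None,
) -> StructureModel:
    """Complete ideal peptide as a single-chain model with consistent SEQRES.

    ``seq`` may be 3-letter codes or a 1-letter string; ``conformation`` is
    "alltrans" (phi = psi = 180) or "helix" (phi = -57, psi = -47).
    ``with_sidechains=False`` builds backbone-only residues (fast path for
    sequence-level fixtures).
    """
    from .templates import ONE_TO_THREE

    if isinstance(seq, str):
        seq = [ONE_TO_THREE[c] for c in seq]
    if conformation == "helix":
        phi, psi = HELIX_PHI, HELIX_PSI
    elif conformation == "alltrans":
        phi, psi = 180.0, 180.0
    else:
        raise ValueError(f"unknown conformation {conformation!r}")
    if numbers is None:
        numbers = list(range(1, len(seq) + 1))
    if with_sidechains:
        frag = build_alltrans(seq, numbers=numbers, phi=phi, psi=psi)
        residues = frag.residues
    else:
        from .residue_builder import build_backbone

        phis = [-75.0 if c == "PRO" and phi == 180.0 else phi for c in seq]
        bb = build_backbone(len(seq), phi=phis, psi=psi)
        residues = [
            Residue(code, num, "",
                    [AtomRecord(0, n, "", n[0], x) for n, x in atoms.items()])
            for code, num, atoms in zip(seq, numbers, bb)
        ]
    model = StructureModel(
        chains=[Chain(chain_id, residues=residues, seqres=list(seq))]
    )
    if with_sidechains:
        declash_sidechains(model)
    if with_hydrogens and with_sidechains:
        add_hydrogens(model)
    return model


@dataclass
class AblationPlan:
    """A reproducible damage plan; deletions must be strictly internal."""

    deleted_runs: list[tuple[int, int]] = field(default_factory=list)  # inclusive numbers
    truncations: dict[int, str] = field(default_factory=dict)  # number -> last kept atom
    strip_hydrogens: bool = False
    seed: int | None = None


@dataclass
class AblationTruth:
    plan: AblationPlan
    deleted: dict[int, Residue]  # residue number -> the removed residue (with coords)

    @property
    def deleted_numbers(self) -> set[int]:
        return set(self.deleted)

    @property
    def runs(self) -> list[tuple[int, int]]:
        return sorted(self.plan.deleted_runs)


# template heavy-atom placement order per residue, for truncation validation
def _truncate_residue(res: Residue, last_kept: str) -> None:
    from .templates import get_template

    tpl = get_template(res.name)
    order = ["N", "CA", "C", "O"] + [e.name for e in tpl.heavy_ics]
    if last_kept not in order:
        raise ValueError(f"{last_kept} not a heavy atom of {res.name}")
    keep = set(order[: order.index(last_kept) + 1])
    res.atoms = [a for a in res.atoms if a.element == "H" or a.name in keep]


def ablate(model: StructureModel, plan: AblationPlan) -> tuple[StructureModel, AblationTruth]:
    """Apply a damage plan to (a copy of) a single-chain fixture.

    SEQRES is left intact so deletions remain detectable. Raises ``ValueError``
    for a plan touching the terminal residues.
    """
    text = write_structure(model)
    damaged = parse_structure(text)
    chain = damaged.chains[0]
    numbers = [r.number for r in chain.residues]
    first, last = numbers[0], numbers[-1]
    deleted: dict[int, Residue] = {}
    for start, end in plan.deleted_runs:
        if start <= first or end >= last:
            raise ValueError(f"deleted run {start}-{end} touches a terminal residue")
        if start > end:
            raise ValueError(f"bad run {start}-{end}")
        for num in range(start, end + 1):
            res = chain.residue(num)
            if res is None:
                raise ValueError(f"run {start}-{end}: residue {num} absent")
            deleted[num] = res
        chain.residues = [r for r in chain.residues if not (start <= r.number <= end)]
    for num, last_kept in plan.truncations.items():
        res = chain.residue(num)
        if res is None:
            raise ValueError(f"truncation target {num} absent")
        _truncate_residue(res, last_kept)
    if plan.strip_hydrogens:
        for res in chain.residues:
            res.strip_hydrogens()
    return damaged, AblationTruth(plan=plan, deleted=deleted)


TETRAHEDRAL = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


def make_zinc_site(n_cys: int = 4, geometry: str = "tetrahedral") -> StructureModel:
    """A zinc ion at the origin with ``n_cys`` cysteine SG atoms at 2.3 Å.

    Each cysteine comes with its own backbone scaffold, rigidly placed so the
    SG sits on a tetrahedral vertex and the side chain points outward.
    """
    if geometry != "tetrahedral":
        raise ValueError("only tetrahedral geometry is implemented")
    if not 2 <= n_cys <= 4:
        raise ValueError("n_cys must be in 2..4")
    chain = Chain("A")
    for i in range(n_cys):
        direction = TETRAHEDRAL[i]
        frag = build_alltrans(["CYS"], numbers=[10 * (i + 1)])
        res = frag.residues[0]
        sg = res.coord("SG")
        cb = res.coord("CB")
        from .geometry import rotation_aligning

        rot = rotation_aligning(cb - sg, direction)  # S->C axis points outward
        target = 2.3 * direction
        for a in res.atoms:
            a.coords = target + rot @ (a.coords - sg)
        chain.residues.append(res)
    chain.seqres = [r.name for r in chain.residues]
    zn = AtomRecord(9001, "ZN", "", "ZN", np.zeros(3), is_het=True)
    return StructureModel(chains=[chain], metals=[zn])


def random_sequence(n: int, rng: np.random.Generator) -> list[str]:
    return [_POOL[i] for i in rng.integers(0, len(_POOL), size=n)]


def random_ablation_plan(
    n_residues: int,
    rng: np.random.Generator,
    n_runs: int = 1,
    max_run: int = 6,
) -> AblationPlan:
    """Non-adjacent internal deletion runs (never touching residues 1 and n)."""
    runs: list[tuple[int, int]] = []
    # candidate start positions, kept >= 2 apart from existing runs so two
    # deletions never merge into one gap
    for _ in range(200):
        if len(runs) == n_runs:
            break
        length = int(rng.integers(1, max_run + 1))
        start = int(rng.integers(2, n_residues - length))
        end = start + length - 1
        if all(end < s - 1 or start > e + 1 for s, e in runs):
            runs.append((start, end))
    return AblationPlan(deleted_runs=sorted(runs))


def roundtrip(model: StructureModel) -> StructureModel:
    """Serialize to PDB text and re-parse: fixtures always cross the format."""
    return parse_structure(write_structure(model))


def make_corpus(
    directory,
    n_entries: int,
    seed: int = 0,
    gap_fraction: float = 0.4,
    max_run: int = 6,
):
    """Write a synthetic PDB corpus with a known gap plan; returns the truth.

    Each entry holds 1-3 protein chains; a chain carries one internal deletion
    run with probability ``gap_fraction``. The returned truth lists, per file,
    each chain's gap runs and lengths.
    """
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth = []
    for k in range(n_entries):
        n_chains = int(rng.integers(1, 4))
        model = StructureModel()
        entry_truth = []
        for ci in range(n_chains):
            cid = "ABC"[ci]
            n = int(rng.integers(20, 45))
            single = make_ideal_peptide(
                random_sequence(n, rng), "alltrans", chain_id=cid, with_hydrogens=False
            )
            gaps: list[tuple[int, int]] = []
            if rng.random() < gap_fraction:
                plan = random_ablation_plan(n, rng, n_runs=1, max_run=max_run)
                single, tr = ablate(single, plan)
                gaps = tr.runs
            ch = single.chains[0]
            # offset chains so they do not overlap in space
            shift = np.array([0.0, 12.0 * ci, 0.0])
            for r in ch.residues:
                for a in r.atoms:
                    a.coords = a.coords + shift
            model.chains.append(ch)
            entry_truth.append({"chain": cid, "gaps": gaps})
        path = directory / f"fixture_{k:04d}.pdb"
        path.write_text(write_structure(model))
        truth.append({"path": str(path), "chains": entry_truth})
    return truth


# --- synthetic stand-ins for the two published reference entries ---------------


def _sequence_with_heavy_count(n_residues: int, n_heavy: int) -> list[str]:
    """A sequence of ``n_residues`` whose template heavy-atom total is exact."""
    from .templates import get_template

    counts = {aa: get_template(aa).n_heavy for aa in STANDARD_AA}
    base = counts["LYS"]  # 9
    seq = ["LYS"] * n_residues
    deficit = n_heavy - base * n_residues
    if deficit < 0:
        # swap LYS (9) down to GLY (4) / ALA (5)
        i = 0
        while deficit < 0 and i < n_residues:
            step = min(5, -deficit)
            swap = {5: "GLY", 4: "ALA", 3: "SER", 2: "VAL", 1: "ASP"}[step]
            seq[i] = swap
            deficit += base - counts[swap]
            i += 1
    else:
        i = 0
        while deficit > 0 and i < n_residues:
            step = min(5, deficit)
            swap = {5: "TRP", 3: "TYR", 2: "PHE", 1: "HIS", 4: "TRP"}.get(step)
            if swap is None or counts[swap] - base > deficit:
                swap = "HIS"
            seq[i] = swap
            deficit -= counts[swap] - base
            i += 1
    if deficit != 0:
        raise ValueError("cannot hit requested heavy-atom count")
    return seq


def _strip_hydrogens(model: StructureModel) -> None:
    for chain in model.chains:
        for r in chain.residues:
            r.strip_hydrogens()


def synthetic_two_chain_complex() -> StructureModel:
    """SYNTHETIC stand-in for a two-chain protease/cofactor complex entry.

    Reproduces the published report-level properties on synthetic coordinates:
    two protein chains of exactly 2310 and 899 heavy ATOM-record atoms, one
    1-residue internal gap in each chain, 338 SEQRES residues in total, two
    ligands and 415 water molecules. Coordinates are ideal extended peptides,
    not the real fold.
    """
    # chain C: 249 SEQRES, 248 observed, 2310 heavy atoms
    seq_c_obs = _sequence_with_heavy_count(248, 2310)
    seq_l_obs = _sequence_with_heavy_count(88, 899)
    gap_c, gap_l = 125, 45  # positions (1-based) of the unobserved residue

    def build(cid, obs_seq, gap_pos, shift):
        seqres = obs_seq[: gap_pos - 1] + ["ALA"] + obs_seq[gap_pos - 1 :]
        numbers = [i + 1 for i in range(len(seqres)) if i + 1 != gap_pos]
        m = make_ideal_peptide(obs_seq, "alltrans", chain_id=cid,
                               with_hydrogens=False, numbers=numbers)
        ch = m.chains[0]
        ch.seqres = seqres
        for r in ch.residues:
            for a in r.atoms:
                a.coords = a.coords + shift
        return ch

    model = StructureModel(source_id="SYN1")
    model.chains.append(build("C", seq_c_obs, gap_c, np.zeros(3)))
    model.chains.append(build("L", seq_l_obs, gap_l, np.array([0.0, 18.0, 0.0])))

    rng = np.random.default_rng(7)
    for li in range(2):
        atoms = [
            AtomRecord(0, f"C{j+1}", "", "C",
                       np.array([-10.0 - 5 * li, -10.0, 3.0 * j]), is_het=True)
            for j in range(6)
        ]
        model.het_groups.append(("C", Residue("LIG", 900 + li, "", atoms)))
    for w in range(415):
        pos = np.array([-30.0, 0.0, 0.0]) + rng.uniform(-25, 25, size=3)
        model.waters.append(
            Residue("HOH", 1000 + w, "", [AtomRecord(0, "O", "", "O", pos, is_het=True)])
        )
    return model


def synthetic_helicase_like(with_chain_b: bool = True) -> StructureModel:
    """SYNTHETIC stand-in for a two-chain viral helicase entry with zinc sites.

    Reproduces the published gap layout and zinc chemistry on synthetic
    coordinates: chain A has internal gaps 95-102, 186-192 and 203-207
    (20 missing residues), chain B has 204-207 and 337-339 (7 missing);
    each chain carries three zinc ions, two of them tetrahedrally coordinated
    by four cysteine SG atoms and one sitting on a histidine NE2. The zinc-
    site SG atoms are displaced onto ideal coordination vertices, so their
    CB-SG bonds are strained; state assignment, gap detection and censuses
    are exact, geometry around the zincs is not meaningful.
    """
    rng = np.random.default_rng(42)
    model = StructureModel(source_id="SYN2")
    serial = 9000

    def build_chain(cid, n_seqres, gap_runs, cys_groups, his_pos, shift):
        nonlocal serial
        seq = random_sequence(n_seqres, rng)
        for grp in cys_groups:
            for p in grp:
                seq[p - 1] = "CYS"
        seq[his_pos - 1] = "HIS"
        missing = {n for s, e in gap_runs for n in range(s, e + 1)}
        numbers = [i for i in range(1, n_seqres + 1) if i not in missing]
        obs_seq = [seq[n - 1] for n in numbers]
        m = make_ideal_peptide(obs_seq, "alltrans", chain_id=cid,
                               with_hydrogens=False, numbers=numbers)
        ch = m.chains[0]
        ch.seqres = seq
        for r in ch.residues:
            for a in r.atoms:
                a.coords = a.coords + shift
        model.chains.append(ch)
        # zinc sites: move the SG of each group onto tetrahedral vertices
        for grp in cys_groups:
            cas = np.array([ch.residue(p).coord("CA") for p in grp])
            zn_pos = cas.mean(axis=0) + np.array([0.0, 0.0, 8.0])
            serial += 1
            model.metals.append(AtomRecord(serial, "ZN", "", "ZN", zn_pos, is_het=True))
            for p, vertex in zip(grp, TETRAHEDRAL):
                ch.residue(p).atom("SG").coords = zn_pos + 2.3 * vertex
        his = ch.residue(his_pos)
        ne2, ce1, cd2 = his.coord("NE2"), his.coord("CE1"), his.coord("CD2")
        lone_pair = ne2 - 0.5 * (ce1 + cd2)
        lone_pair /= np.linalg.norm(lone_pair)
        serial += 1
        model.metals.append(
            AtomRecord(serial, "ZN", "", "ZN", ne2 + 2.1 * lone_pair, is_het=True)
        )

    build_chain("A", 250, [(95, 102), (186, 192), (203, 207)],
                [(10, 13, 30, 33), (50, 53, 70, 73)], 120, np.zeros(3))
    if with_chain_b:
        build_chain("B", 350, [(204, 207), (337, 339)],
                    [(10, 13, 30, 33), (50, 53, 70, 73)], 120,
                    np.array([0.0, 30.0, 0.0]))

    # one ligand of 23 heavy atoms, far from both chains
    atoms = []
    for j in range(23):
        ring = rotation_about_axis(np.array([0, 0, 1.0]), 2 * np.pi * j / 23)
        pos = np.array([-25.0, -25.0, 0.0]) + ring @ np.array([4.0, 0.0, 0.1 * j])
        atoms.append(AtomRecord(0, f"C{j+1}", "", "C", pos, is_het=True))
    model.het_groups.append(("A", Residue("LIG", 901, "", atoms)))
    return model
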