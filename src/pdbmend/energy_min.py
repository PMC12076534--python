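"""Reduced molecular-mechanics energy, clash scoring, and conjugate-gradient
minimization with fixed-atom constraints.

The energy is a transferable stand-in for a real protein force field,
sufficient for relieving steric clashes and closing gaps but NOT for
absolute energetics:

* harmonic bonds and angles, equilibrium values measured once from the
  template reference geometry of each residue variant;
* a 2-fold cosine term keeping peptide bonds planar, plus a generic 3-fold
  barrier on acyclic heavy-atom torsions;
* element-based Lennard-Jones (Lorentz-Berthelot mixing, 10 Å cutoff,
  Verlet neighbor list), 1-2/1-3 pairs excluded and 1-4 pairs scaled;
* no electrostatics (an optional per-atom charge hook accepts externally
  supplied charges and adds a plain Coulomb term).

Consequently absolute energies are NOT comparable to published force-field
values; convergence is judged on the maximum per-atom gradient instead
(default threshold 10 kJ/mol/Å).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import TopologyError
from .geometry import bond_angle, bond_length
from .pdbio import Residue, StructureModel
from .residue_builder import add_hydrogens, build_alltrans
from .templates import get_template, load_templates, resolve_variant

__all__ = [
    "ForceFieldParams",
    "EnergyTopology",
    "MinimizationResult",
    "load_params",
    "build_topology",
    "energy_and_gradient",
    "clash_score",
    "minimize",
]

COULOMB_K = 138.935458  # kJ/mol * A / e^2


# --- parameters ---------------------------------------------------------------


@dataclass(frozen=True)
class ForceFieldParams:
    constants: dict[str, float]
    lj: dict[str, tuple[float, float]]  # element -> (sigma, epsilon)
    vdw: dict[str, float]  # element -> clash radius

    def lj_for(self, element: str) -> tuple[float, float]:
        return self.lj.get(element, self.lj["X"])

    def vdw_for(self, element: str) -> float:
        return self.vdw.get(element, self.vdw["X"])


_PARAMS: ForceFieldParams | None = None


def load_params() -> ForceFieldParams:
    global _PARAMS
    if _PARAMS is None:
        text = (
            importlib.resources.files("pdbmend")
            .joinpath("data/reduced_ff.dat")
            .read_text()
        )
        constants: dict[str, float] = {}
        lj: dict[str, tuple[float, float]] = {}
        vdw: dict[str, float] = {}
        for raw in text.splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tok = line.split()
            if tok[0] == "CONST":
                constants[tok[1]] = float(tok[2])
            elif tok[0] == "LJ":
                lj[tok[1]] = (float(tok[2]), float(tok[3]))
                vdw[tok[1]] = float(tok[4])
        _PARAMS = ForceFieldParams(constants, lj, vdw)
    return _PARAMS


# --- reference geometry for equilibrium values ---------------------------------

_REFERENCE: dict[str, Residue] = {}

# angles that span the peptide junction (or involve OXT), by atom-name triple
_JUNCTION_ANGLES = {
    ("CA", "C", "N"): 116.2,
    ("O", "C", "N"): 123.3,
    ("C", "N", "CA"): 121.7,
    ("C", "N", "H"): 119.5,
    ("C", "N", "CD"): 125.0,
    ("CA", "C", "OXT"): 117.0,
    ("O", "C", "OXT"): 126.0,
    ("CB", "SG", "SG"): 104.0,
}


def _reference_residue(variant: str) -> Residue:
    """A single residue built in vacuum from its template; geometry cache."""
    if variant not in _REFERENCE:
        frag = build_alltrans([_parent_name(variant)])
        res = frag.residues[0]
        res.name = variant
        from .pdbio import Chain, StructureModel as _SM

        add_hydrogens(_SM(chains=[Chain("_", residues=[res])]),
                      states={("_", res.number, res.icode): variant})
        _REFERENCE[variant] = res
    return _REFERENCE[variant]


def _parent_name(variant: str) -> str:
    from .templates import VARIANT_PARENT

    return VARIANT_PARENT.get(variant, variant)


def _ref_bond(variant: str, a: str, b: str) -> float | None:
    res = _reference_residue(variant)
    pa, pb = res.coord(a), res.coord(b)
    if pa is None or pb is None:
        return None
    return bond_length(pa, pb)


def _ref_angle(variant: str, a: str, b: str, c: str) -> float | None:
    res = _reference_residue(variant)
    pa, pb, pc = res.coord(a), res.coord(b), res.coord(c)
    if pa is None or pb is None or pc is None:
        return None
    return bond_angle(pa, pb, pc)


# --- topology -------------------------------------------------------------------


@dataclass
class EnergyTopology:
    n_atoms: int
    elements: list[str]
    bonds: np.ndarray  # (m, 2) int
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray  # (m, 3) int
    angle_k: np.ndarray
    angle_t0: np.ndarray  # radians
    torsions: np.ndarray  # (m, 4) int
    torsion_k: np.ndarray
    torsion_n: np.ndarray
    torsion_phase: np.ndarray  # radians
    lj_sigma: np.ndarray
    lj_eps: np.ndarray
    vdw_radii: np.ndarray
    excluded_keys: np.ndarray  # sorted i*n+j (i<j), 1-2 and 1-3 (and ligand-internal)
    pair14_keys: np.ndarray  # sorted, scaled pairs
    fixed: np.ndarray  # bool mask
    charges: np.ndarray | None = None
    cutoff: float = 10.0
    atom_meta: list[tuple] = field(default_factory=list)  # (kind, chain, resnum, icode, name)

    def key(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        lo = np.minimum(i, j).astype(np.int64)
        hi = np.maximum(i, j).astype(np.int64)
        return lo * self.n_atoms + hi


def _enumerate_angles(bonds: list[tuple[int, int]], n: int):
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    torsions = []
    for j, k in bonds:
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                torsions.append((i, j, k, l))
    return adj, angles, torsions


def _cycle_edges(bonds: list[tuple[int, int]], n: int) -> set[tuple[int, int]]:
    """Edges that belong to at least one cycle (ring bonds)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(bonds)
    out: set[tuple[int, int]] = set()
    for cyc in nx.cycle_basis(g):
        for a, b in zip(cyc, cyc[1:] + [cyc[0]]):
            out.add((min(a, b), max(a, b)))
    return out


def build_topology(
    model: StructureModel,
    states=None,
    fixed_keys: set | None = None,
    charges: dict | None = None,
) -> EnergyTopology:
    """Build the reduced-force-field topology over every atom in the model.

    Bonds come from the per-variant template bond lists plus inter-residue
    peptide bonds (C-N pairs closer than 2 Å), SG-SG bonds for disulfide
    pairs registered in ``states``, and rigid-water bonds. Ligand (het)
    groups contribute no bonded terms; their internal atom pairs are excluded
    from the nonbonded sum. Metals interact through Lennard-Jones only.

    Raises :class:`TopologyError` when a residue holds atoms its assigned
    variant does not define.
    """
    params = load_params()
    fixed_keys = fixed_keys or set()

    index: dict[tuple, int] = {}
    elements: list[str] = []
    meta: list[tuple] = []
    fixed_list: list[bool] = []

    def _add_atom(kind: str, chain_id: str, res: Residue, atom) -> int:
        idx = len(elements)
        index[(kind, chain_id, res.number, res.icode, atom.name)] = idx
        elements.append(atom.element)
        meta.append((kind, chain_id, res.number, res.icode, atom.name))
        fixed_list.append((chain_id, res.number, res.icode) in fixed_keys
                          or (kind, chain_id, res.number, res.icode) in fixed_keys)
        return idx

    bonds: list[tuple[int, int]] = []
    bond_r0: list[float] = []
    excl_extra: list[tuple[int, int]] = []
    templatable = set(load_templates()) | {"HIS"}

    bond_k_const = params.constants["bond_k"]

    for chain in model.chains:
        prev_res: Residue | None = None
        prev_c: int | None = None
        for res in chain.residues:
            key3 = (chain.id, res.number, res.icode)
            variant = None
            if states is not None:
                variant = states.get(key3)
            try:
                variant = resolve_variant(res.name, variant)
            except KeyError:
                variant = None
            for atom in res.atoms:
                _add_atom("chain", chain.id, res, atom)
            if variant is not None:
                tpl = load_templates()[variant]
                allowed = set(tpl.heavy_atoms) | set(tpl.hydrogen_atoms) | {
                    "OXT", "H1", "H2", "H3"}
                extras = [a.name for a in res.atoms if a.name not in allowed]
                if extras:
                    raise TopologyError(
                        f"chain {chain.id} {res.name} {res.number}: atoms"
                        f" {extras} not defined by variant {variant}"
                    )
                for a, b in tpl.bonds():
                    if a.startswith("-") or b.startswith("-"):
                        continue
                    ia = index.get(("chain", chain.id, res.number, res.icode, a))
                    ib = index.get(("chain", chain.id, res.number, res.icode, b))
                    if ia is None or ib is None:
                        continue
                    bonds.append((ia, ib))
                    bond_r0.append(_ref_bond(variant, a, b) or 1.5)
                # terminal extras
                for extra, parent, r0 in (("OXT", "C", 1.249), ("H1", "N", 1.01),
                                          ("H2", "N", 1.01), ("H3", "N", 1.01)):
                    ia = index.get(("chain", chain.id, res.number, res.icode, extra))
                    ib = index.get(("chain", chain.id, res.number, res.icode, parent))
                    if ia is not None and ib is not None:
                        bonds.append((ia, ib))
                        bond_r0.append(r0)
            # peptide bond to previous residue
            c_idx = index.get(("chain", chain.id, res.number, res.icode, "C"))
            n_idx = index.get(("chain", chain.id, res.number, res.icode, "N"))
            if prev_c is not None and n_idx is not None and prev_res is not None:
                cpos = prev_res.coord("C")
                npos = res.coord("N")
                if cpos is not None and npos is not None and np.linalg.norm(cpos - npos) < 2.0:
                    bonds.append((prev_c, n_idx))
                    bond_r0.append(1.329)
            prev_res, prev_c = res, c_idx

    # disulfide SG-SG bonds
    if states is not None and getattr(states, "disulfides", None):
        for ka, kb in states.disulfides:
            ia = index.get(("chain", ka[0], ka[1], ka[2], "SG"))
            ib = index.get(("chain", kb[0], kb[1], kb[2], "SG"))
            if ia is not None and ib is not None:
                bonds.append((ia, ib))
                bond_r0.append(2.05)

    # het groups: atoms present, no bonded terms, internal pairs excluded
    for chain_id, res in model.het_groups:
        idxs = [_add_atom("het", chain_id, res, a) for a in res.atoms]
        for x in range(len(idxs)):
            for y in range(x + 1, len(idxs)):
                excl_extra.append((idxs[x], idxs[y]))

    # waters: rigid 3-site bonded terms
    water_angles: list[tuple[int, int, int]] = []
    for res in model.waters:
        o = h1 = h2 = None
        for a in res.atoms:
            i = _add_atom("water", "W", res, a)
            if a.element == "O":
                o = i
            elif h1 is None:
                h1 = i
            else:
                h2 = i
        if o is not None and h1 is not None:
            bonds.append((o, h1))
            bond_r0.append(params.constants["water_oh"])
        if o is not None and h2 is not None:
            bonds.append((o, h2))
            bond_r0.append(params.constants["water_oh"])
        if o is not None and h1 is not None and h2 is not None:
            water_angles.append((h1, o, h2))

    for m in model.metals:
        idx = len(elements)
        index[("metal", "M", m.serial, "", m.name)] = idx
        elements.append(m.element)
        meta.append(("metal", "M", m.serial, "", m.name))
        fixed_list.append(("metal", m.serial) in fixed_keys)

    n = len(elements)
    adj, angle_triples, torsion_quads = _enumerate_angles(bonds, n)

    # angle equilibrium values
    by_residue: dict[tuple, str] = {}
    variant_of: dict[int, str] = {}
    name_of = [m[4] for m in meta]
    res_of = [m[:4] for m in meta]
    for i, m in enumerate(meta):
        if m[0] != "chain":
            continue
        rk = (m[1], m[2], m[3])
        if rk not in by_residue:
            v = states.get(rk) if states is not None else None
            try:
                by_residue[rk] = resolve_variant(
                    next(r.name for c in model.chains if c.id == m[1]
                         for r in c.residues if (r.number, r.icode) == (m[2], m[3])),
                    v,
                )
            except (KeyError, StopIteration):
                by_residue[rk] = ""
        variant_of[i] = by_residue[rk]

    angle_t0 = []
    angles_kept = []
    for i, j, k in angle_triples:
        t0 = None
        if res_of[i] == res_of[j] == res_of[k]:
            if meta[j][0] == "water":
                t0 = params.constants["water_hoh"]
            elif variant_of.get(j):
                t0 = _ref_angle(variant_of[j], name_of[i], name_of[j], name_of[k])
        if t0 is None:
            names = (name_of[i], name_of[j], name_of[k])
            t0 = _JUNCTION_ANGLES.get(names) or _JUNCTION_ANGLES.get(names[::-1])
        if t0 is None:
            t0 = 111.0  # generic sp3 fallback
        angles_kept.append((i, j, k))
        angle_t0.append(np.radians(t0))

    # torsions: omega planarity on peptide bonds, plus a generic 3-fold
    # barrier on acyclic torsions between saturated (4-neighbor) centers;
    # torsions about sp2 bonds and within rings carry no term
    ring = _cycle_edges(bonds, n)
    degree = np.array([len(a) for a in adj])
    tors, tk, tn, tphase = [], [], [], []
    hydro = np.array([e == "H" for e in elements])
    for i, j, k, l in torsion_quads:
        if hydro[i] or hydro[l]:
            continue
        jk = (min(j, k), max(j, k))
        inter_res = res_of[j] != res_of[k]
        if inter_res and {name_of[j], name_of[k]} == {"C", "N"}:
            if (name_of[i], name_of[l]) in (("CA", "CA"),):
                tors.append((i, j, k, l))
                tk.append(params.constants["omega_k"])
                tn.append(2)
                tphase.append(np.pi)
            continue
        if jk in ring or degree[j] < 4 or degree[k] < 4:
            continue
        tors.append((i, j, k, l))
        tk.append(params.constants["torsion_v"] / 2.0)
        tn.append(3)
        tphase.append(0.0)

    # exclusions: 1-2 and 1-3; 1-4 scaled
    excl: set[tuple[int, int]] = set()
    for i, j in bonds:
        excl.add((min(i, j), max(i, j)))
    for i, j, k in angle_triples:
        excl.add((min(i, k), max(i, k)))
    excl.update(excl_extra)
    p14: set[tuple[int, int]] = set()
    for i, j, k, l in torsion_quads:
        p = (min(i, l), max(i, l))
        if p not in excl:
            p14.add(p)

    def _keys(pairs):
        if not pairs:
            return np.empty(0, dtype=np.int64)
        arr = np.array(sorted(pairs), dtype=np.int64)
        return arr[:, 0] * n + arr[:, 1]

    lj_sigma = np.array([params.lj_for(e)[0] for e in elements])
    lj_eps = np.array([params.lj_for(e)[1] for e in elements])
    vdw = np.array([params.vdw_for(e) for e in elements])

    q = None
    if charges:
        q = np.zeros(n)
        for i, m in enumerate(meta):
            q[i] = charges.get(m, 0.0)

    return EnergyTopology(
        n_atoms=n,
        elements=elements,
        bonds=np.array(bonds, dtype=int).reshape(-1, 2),
        bond_k=np.full(len(bonds), bond_k_const),
        bond_r0=np.array(bond_r0),
        angles=np.array(angles_kept, dtype=int).reshape(-1, 3),
        angle_k=np.full(len(angles_kept), params.constants["angle_k"]),
        angle_t0=np.array(angle_t0),
        torsions=np.array(tors, dtype=int).reshape(-1, 4),
        torsion_k=np.array(tk),
        torsion_n=np.array(tn, dtype=int),
        torsion_phase=np.array(tphase),
        lj_sigma=lj_sigma,
        lj_eps=lj_eps,
        vdw_radii=vdw,
        excluded_keys=np.sort(_keys(excl)),
        pair14_keys=np.sort(_keys(p14)),
        fixed=np.array(fixed_list + [False] * (n - len(fixed_list)), dtype=bool)[:n],
        charges=q,
        cutoff=params.constants["lj_cutoff"],
        atom_meta=meta,
    )


# --- energy and gradient --------------------------------------------------------


class NeighborList:
    """Verlet list over non-excluded pairs; rebuilt on large displacements."""

    def __init__(self, cutoff: float, skin: float = 2.0):
        self.cutoff = cutoff
        self.skin = skin
        self._ref: np.ndarray | None = None
        self._pairs: np.ndarray | None = None
        self._scale: np.ndarray | None = None

    def pairs(self, coords: np.ndarray, top: EnergyTopology):
        if (
            self._ref is None
            or len(self._ref) != len(coords)
            or np.max(np.linalg.norm(coords - self._ref, axis=1)) > self.skin / 2.0
        ):
            tree = cKDTree(coords)
            raw = tree.query_pairs(self.cutoff + self.skin, output_type="ndarray")
            if raw.size:
                # pairs between two fixed atoms are a constant: skip them
                both_fixed = top.fixed[raw[:, 0]] & top.fixed[raw[:, 1]]
                raw = raw[~both_fixed]
                keys = top.key(raw[:, 0], raw[:, 1])
                keep = ~np.isin(keys, top.excluded_keys)
                raw = raw[keep]
                keys = keys[keep]
                scale = np.where(np.isin(keys, top.pair14_keys), 0.5, 1.0)
            else:
                raw = raw.reshape(0, 2)
                scale = np.empty(0)
            self._pairs = raw
            self._scale = scale
            self._ref = coords.copy()
        return self._pairs, self._scale


def energy_and_gradient(
    coords: np.ndarray,
    top: EnergyTopology,
    nbl: NeighborList | None = None,
) -> tuple[float, np.ndarray, dict[str, float]]:
    """Total energy (kJ/mol), analytic gradient (kJ/mol/Å), per-term energies."""
    x = np.asarray(coords, float).reshape(-1, 3)
    if not np.isfinite(x).all():
        raise ValueError("non-finite coordinates")
    grad = np.zeros_like(x)
    terms: dict[str, float] = {}

    # bonds
    e_bond = 0.0
    if len(top.bonds):
        bi, bj = top.bonds[:, 0], top.bonds[:, 1]
        d = x[bi] - x[bj]
        r = np.linalg.norm(d, axis=1)
        dr = r - top.bond_r0
        e_bond = float(np.sum(0.5 * top.bond_k * dr**2))
        f = (top.bond_k * dr / r)[:, None] * d
        np.add.at(grad, bi, f)
        np.add.at(grad, bj, -f)
    terms["bond"] = e_bond

    # angles
    e_angle = 0.0
    if len(top.angles):
        ai, aj, ak = top.angles[:, 0], top.angles[:, 1], top.angles[:, 2]
        u = x[ai] - x[aj]
        v = x[ak] - x[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cost = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0 + 1e-12, 1.0 - 1e-12)
        theta = np.arccos(cost)
        dt = theta - top.angle_t0
        e_angle = float(np.sum(0.5 * top.angle_k * dt**2))
        sint = np.sqrt(1.0 - cost**2)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        dthe_di = (cost[:, None] * uh - vh) / (nu * sint)[:, None]
        dthe_dk = (cost[:, None] * vh - uh) / (nv * sint)[:, None]
        coef = (top.angle_k * dt)[:, None]
        np.add.at(grad, ai, coef * dthe_di)
        np.add.at(grad, ak, coef * dthe_dk)
        np.add.at(grad, aj, -coef * (dthe_di + dthe_dk))
    terms["angle"] = e_angle

    # torsions: E = k (1 + cos(n*phi - phase))
    e_tors = 0.0
    if len(top.torsions):
        ti, tj, tk_, tl = (top.torsions[:, c] for c in range(4))
        b1 = x[tj] - x[ti]
        b2 = x[tk_] - x[tj]
        b3 = x[tl] - x[tk_]
        m = np.cross(b1, b2)
        nvec = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        mm = np.sum(m * m, axis=1)
        nn = np.sum(nvec * nvec, axis=1)
        cosphi = np.sum(m * nvec, axis=1)
        sinphi = np.sum(np.cross(m, nvec) * (b2 / nb2[:, None]), axis=1)
        phi = np.arctan2(sinphi, cosphi)
        arg = top.torsion_n * phi - top.torsion_phase
        e_tors = float(np.sum(top.torsion_k * (1.0 + np.cos(arg))))
        dV = -top.torsion_k * top.torsion_n * np.sin(arg)
        gi = (-nb2 / mm)[:, None] * m
        gl = (nb2 / nn)[:, None] * nvec
        s12 = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
        s32 = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
        gj = -(1.0 + s12) * gi + s32 * gl
        gk = s12 * gi - (1.0 + s32) * gl
        np.add.at(grad, ti, dV[:, None] * gi)
        np.add.at(grad, tj, dV[:, None] * gj)
        np.add.at(grad, tk_, dV[:, None] * gk)
        np.add.at(grad, tl, dV[:, None] * gl)
    terms["torsion"] = e_tors

    # nonbonded
    if nbl is None:
        nbl = NeighborList(top.cutoff)
    pairs, scale = nbl.pairs(x, top)
    e_lj = 0.0
    e_coul = 0.0
    if len(pairs):
        pi, pj = pairs[:, 0], pairs[:, 1]
        d = x[pi] - x[pj]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-6):
            raise ValueError("overlapping atoms in nonbonded pair")
        within = r < top.cutoff
        pi, pj, d, r, sc = pi[within], pj[within], d[within], r[within], scale[within]
        sig = 0.5 * (top.lj_sigma[pi] + top.lj_sigma[pj])
        eps = np.sqrt(top.lj_eps[pi] * top.lj_eps[pj]) * sc
        sr6 = (sig / r) ** 6
        src6 = (sig / top.cutoff) ** 6  # potential shift: E continuous at cutoff
        e_lj = float(np.sum(4.0 * eps * (sr6**2 - sr6) - 4.0 * eps * (src6**2 - src6)))
        fmag = 24.0 * eps * (2.0 * sr6**2 - sr6) / r**2
        f = fmag[:, None] * d
        np.add.at(grad, pi, -f)
        np.add.at(grad, pj, f)
        if top.charges is not None:
            qq = COULOMB_K * top.charges[pi] * top.charges[pj] * sc
            e_coul = float(np.sum(qq / r))
            fc = (qq / r**3)[:, None] * d
            np.add.at(grad, pi, -fc)
            np.add.at(grad, pj, fc)
    terms["lj"] = e_lj
    if top.charges is not None:
        terms["coulomb"] = e_coul

    total = sum(terms.values())
    return total, grad, terms


# --- clash scoring ---------------------------------------------------------------

CLASH_FACTOR = 0.6


def clash_score(
    frag_coords: np.ndarray,
    frag_radii: np.ndarray,
    env_coords: np.ndarray,
    env_radii: np.ndarray,
    exclude: set[tuple[int, int]] | None = None,
) -> tuple[int, float]:
    """Hard steric clashes between a fragment and its environment.

    A clash is a (non-excluded) heavy-atom pair closer than
    ``0.6 * (r_vdw_i + r_vdw_j)``; the second return value is the summed
    distance deficit in Å. ``exclude`` holds (fragment index, environment
    index) pairs that are covalently connected.
    """
    frag_coords = np.asarray(frag_coords, float).reshape(-1, 3)
    env_coords = np.asarray(env_coords, float).reshape(-1, 3)
    if len(frag_coords) == 0 or len(env_coords) == 0:
        return 0, 0.0
    exclude = exclude or set()
    rmax = CLASH_FACTOR * (np.max(frag_radii) + np.max(env_radii))
    tree = cKDTree(env_coords)
    n_clash = 0
    overlap = 0.0
    for fi, (p, rf) in enumerate(zip(frag_coords, frag_radii)):
        for ej in tree.query_ball_point(p, rmax):
            if (fi, ej) in exclude:
                continue
            thr = CLASH_FACTOR * (rf + env_radii[ej])
            dist = float(np.linalg.norm(p - env_coords[ej]))
            if dist < thr:
                n_clash += 1
                overlap += thr - dist
    return n_clash, overlap


# --- minimization ------------------------------------------------------------------


@dataclass
class MinimizationResult:
    coords: np.ndarray
    energy: float
    terms: dict[str, float]
    max_gradient: float
    rms_gradient: float
    iterations: int
    converged: bool
    energies: list[float]  # accepted-step trajectory (non-increasing)
    energy_per_residue: float | None = None


def minimize(
    coords: np.ndarray,
    top: EnergyTopology,
    max_iter: int = 500,
    gtol: float = 10.0,
    max_step: float = 0.5,
) -> MinimizationResult:
    """Polak-Ribière conjugate gradient with backtracking line search.

    Atoms flagged in ``top.fixed`` do not move (their coordinates are
    bit-identical on return). Convergence: maximum per-atom gradient norm of
    the free atoms <= ``gtol`` (kJ/mol/Å).
    """
    x = np.array(coords, float).reshape(-1, 3).copy()
    free = ~top.fixed
    nbl = NeighborList(top.cutoff)

    def eg(xx):
        e, g, t = energy_and_gradient(xx, top, nbl)
        g[top.fixed] = 0.0
        return e, g, t

    e, g, terms = eg(x)
    energies = [e]
    d = -g
    it = 0
    converged = _converged(g, free, gtol)
    g_old = g
    while not converged and it < max_iter:
        it += 1
        dmax = np.max(np.linalg.norm(d, axis=1))
        if dmax < 1e-14:
            break
        alpha = min(1.0, max_step / dmax)
        gd = float(np.sum(g * d))
        if gd >= 0:  # not a descent direction: restart
            d = -g
            gd = float(np.sum(g * d))
            alpha = min(1.0, max_step / np.max(np.linalg.norm(d, axis=1)))
        accepted = False
        for _ in range(30):
            x_new = x + alpha * d
            try:
                e_new, g_new, terms_new = eg(x_new)
            except ValueError:
                alpha *= 0.5
                continue
            if e_new <= e + 1e-4 * alpha * gd:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            break
        x, e, terms = x_new, e_new, terms_new
        g_old, g = g, g_new
        energies.append(e)
        beta = max(0.0, float(np.sum(g * (g - g_old)) / max(np.sum(g_old * g_old), 1e-30)))
        d = -g + beta * d
        converged = _converged(g, free, gtol)

    gn = np.linalg.norm(g, axis=1)
    free_gn = gn[free] if free.any() else gn
    return MinimizationResult(
        coords=x,
        energy=e,
        terms=terms,
        max_gradient=float(free_gn.max()) if len(free_gn) else 0.0,
        rms_gradient=float(np.sqrt(np.mean(free_gn**2))) if len(free_gn) else 0.0,
        iterations=it,
        converged=bool(converged),
        energies=energies,
    )


def _converged(g: np.ndarray, free: np.ndarray, gtol: float) -> bool:
    if not free.any():
        return True
    return bool(np.max(np.linalg.norm(g[free], axis=1)) <= gtol)
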