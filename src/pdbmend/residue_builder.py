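"""Peptide construction from templates: all-trans fragments, side-chain
completion, and hydrogen addition under pH-7 rules.

Backbone geometry is a fixed standard single-conformer set (Engh–Huber-like):

====================  ======
N-CA                  1.458 Å
CA-C                  1.525 Å
C-N (peptide)         1.329 Å
C=O                   1.231 Å
N-CA-C                111.2°
CA-C-N                116.2°
C-N-CA                121.7°
CA-C-O                120.5°
====================  ======

Gap fragments are built maximally extended (phi = psi = omega = 180°) and
oriented/closed downstream by the gap-repair module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PdbmendError
from .geometry import dihedral, place_atom
from .pdbio import AtomRecord, Residue, StructureModel
from .templates import (
    ICEntry,
    UntemplatedResidueError,
    expected_atom_count,  # noqa: F401  (census lives with the templates, re-exported here)
    get_template,
    resolve_variant,
)

__all__ = [
    "Fragment",
    "build_alltrans",
    "build_backbone",
    "complete_sidechains",
    "add_hydrogens",
    "declash_sidechains",
    "expected_atom_count",
    "BACKBONE",
]

BACKBONE = {
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.5,
}


@dataclass
class Fragment:
    """A built peptide fragment; residue 0's N is bonded to the anchor C."""

    residues: list[Residue]
    anchor_frame: tuple[np.ndarray, np.ndarray, np.ndarray] | None  # (N, CA, C)

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        xs = []
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.element == "H":
                    continue
                xs.append(a.coords)
        return np.array(xs)

    @property
    def n_term_n(self) -> np.ndarray:
        return self.residues[0].coord("N")

    @property
    def c_term(self) -> Residue:
        return self.residues[-1]


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _mkatom(name: str, coords: np.ndarray, element: str | None = None) -> AtomRecord:
    return AtomRecord(0, name, "", element or _element_of(name), np.asarray(coords, float))


def _resolve_ref(ref: str, res: Residue, prev: Residue | None) -> np.ndarray | None:
    if ref.startswith("-"):
        return None if prev is None else prev.coord(ref[1:])
    return res.coord(ref)


def _place_ic(entry: ICEntry, res: Residue, prev: Residue | None) -> np.ndarray | None:
    refs = [_resolve_ref(r, res, prev) for r in entry.refs]
    if any(r is None for r in refs):
        return None
    return place_atom(refs[0], refs[1], refs[2], entry.r, entry.theta, entry.phi)


def _place_sidechain(res: Residue, template) -> None:
    for entry in template.heavy_ics:
        if res.atom(entry.name) is None:
            pos = _place_ic(entry, res, None)
            if pos is None:
                raise PdbmendError(
                    f"cannot place {entry.name} of {res.name} {res.number}:"
                    " reference atoms missing"
                )
            res.atoms.append(_mkatom(entry.name, pos))


def build_backbone(
    n: int,
    phi: float | list[float] = 180.0,
    psi: float | list[float] = 180.0,
    omega: float = 180.0,
    attach_frame: tuple | None = None,
) -> list[dict[str, np.ndarray]]:
    """Backbone heavy-atom positions (N, CA, C, O) for ``n`` residues.

    ``phi``/``psi`` may be scalars or per-residue lists. When
    ``attach_frame`` = (N, CA, C) of an upstream anchor residue is given,
    residue 0's N is bonded to the anchor C at the standard peptide geometry.
    """
    g = BACKBONE
    phis = [phi] * n if np.isscalar(phi) else list(phi)
    psis = [psi] * n if np.isscalar(psi) else list(psi)
    out: list[dict[str, np.ndarray]] = []
    if attach_frame is not None:
        na, caa, ca = (np.asarray(x, float) for x in attach_frame)
        nn = place_atom(ca, caa, na, g["c_n"], g["ang_ca_c_n"], psis[0])
        cca = place_atom(nn, ca, caa, g["n_ca"], g["ang_c_n_ca"], omega)
        cc = place_atom(cca, nn, ca, g["ca_c"], g["ang_n_ca_c"], phis[0])
    else:
        nn = np.zeros(3)
        cca = np.array([g["n_ca"], 0.0, 0.0])
        cc = place_atom(cca, nn, np.array([0.0, 1.0, 0.0]), g["ca_c"], g["ang_n_ca_c"], 0.0)
    out.append({"N": nn, "CA": cca, "C": cc})
    for i in range(1, n):
        prev = out[-1]
        nn = place_atom(prev["C"], prev["CA"], prev["N"], g["c_n"], g["ang_ca_c_n"], psis[i - 1])
        prev["O"] = place_atom(prev["C"], prev["CA"], prev["N"], g["c_o"],
                               g["ang_ca_c_o"], psis[i - 1] + 180.0)
        cca = place_atom(nn, prev["C"], prev["CA"], g["n_ca"], g["ang_c_n_ca"], omega)
        cc = place_atom(cca, nn, prev["C"], g["ca_c"], g["ang_n_ca_c"], phis[i])
        out.append({"N": nn, "CA": cca, "C": cc})
    last = out[-1]
    last["O"] = place_atom(last["C"], last["CA"], last["N"], g["c_o"],
                           g["ang_ca_c_o"], psis[-1] + 180.0)
    return out


def build_alltrans(
    seq: list[str],
    attach_frame: tuple | None = None,
    numbers: list[int] | None = None,
    phi: float = 180.0,
    psi: float = 180.0,
    omega: float = 180.0,
) -> Fragment:
    """Build a maximally extended peptide for ``seq`` (3-letter codes).

    All backbone dihedrals default to 180°; side chains come from template
    internal coordinates. Raises :class:`UntemplatedResidueError` listing the
    offending code when the sequence contains a residue with no template.
    """
    if not seq:
        raise ValueError("empty sequence")
    bad = [c for c in seq if c not in _templatable()]
    if bad:
        raise UntemplatedResidueError(f"untemplated residue code(s): {', '.join(bad)}")
    if numbers is None:
        numbers = list(range(1, len(seq) + 1))
    # proline's ring constrains phi; 180 deg would fold CD onto the previous O
    if np.isscalar(phi):
        phis = [-75.0 if code == "PRO" and float(phi) == 180.0 else float(phi) for code in seq]
    else:
        phis = list(phi)
    bb = build_backbone(len(seq), phi=phis, psi=psi, omega=omega, attach_frame=attach_frame)
    residues = []
    for code, num, atoms in zip(seq, numbers, bb):
        res = Residue(code, num, "", [_mkatom(n, x) for n, x in atoms.items()])
        _place_sidechain(res, get_template(code))
        residues.append(res)
    return Fragment(residues=residues, anchor_frame=attach_frame)


def _templatable() -> set[str]:
    from .templates import DEFAULT_VARIANTS, load_templates

    return set(DEFAULT_VARIANTS) | set(load_templates())


def complete_sidechains(model: StructureModel) -> tuple[StructureModel, dict]:
    """Add missing side-chain (and carbonyl O) heavy atoms from templates.

    Existing atoms are never moved. Residues with an incomplete backbone or a
    non-standard name are skipped with a warning. Returns the model and a map
    ``(chain id, number, icode) -> [added atom names]``.
    """
    added: dict[tuple, list[str]] = {}
    templatable = _templatable()
    for chain in model.chains:
        for i, res in enumerate(chain.residues):
            if res.name not in templatable:
                model.warnings.append(
                    f"chain {chain.id} {res.name} {res.number}: non-standard residue skipped"
                )
                continue
            if not res.has_backbone:
                model.warnings.append(
                    f"chain {chain.id} {res.name} {res.number}: incomplete backbone, skipped"
                )
                continue
            names: list[str] = []
            if res.atom("O") is None:
                res.atoms.append(_mkatom("O", _carbonyl_o(chain.residues, i)))
                names.append("O")
            template = get_template(res.name)
            for entry in template.heavy_ics:
                if res.atom(entry.name) is None:
                    pos = _place_ic(entry, res, None)
                    if pos is None:  # parent atom itself unresolved upstream
                        continue
                    res.atoms.append(_mkatom(entry.name, pos))
                    names.append(entry.name)
            if names:
                added[(chain.id, res.number, res.icode)] = names
    return model, added


def _carbonyl_o(residues: list[Residue], i: int) -> np.ndarray:
    res = residues[i]
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    psi = 180.0
    if i + 1 < len(residues):
        nn = residues[i + 1].coord("N")
        if nn is not None and np.linalg.norm(nn - c) < 2.0:
            psi = dihedral(n, ca, c, nn)
    return place_atom(c, ca, n, BACKBONE["c_o"], BACKBONE["ang_ca_c_o"], psi + 180.0)


def _bonded(prev: Residue | None, res: Residue) -> bool:
    if prev is None:
        return False
    c, n = prev.coord("C"), res.coord("N")
    return c is not None and n is not None and np.linalg.norm(c - n) < 2.0


def _variant_for(states, chain_id: str, res: Residue) -> str:
    if states is not None:
        tag = states.get((chain_id, res.number, res.icode))
        if tag is not None:
            return tag
    return resolve_variant(res.name)


def _amide_h_fallback(res: Residue) -> np.ndarray:
    # chain-start (cut) amide hydrogen: anti to C about the N-CA bond
    return place_atom(res.coord("N"), res.coord("CA"), res.coord("C"), 1.010, 114.0, 180.0)


def _charged_nterm_h(res: Residue) -> list[tuple[str, np.ndarray]]:
    n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
    if res.name == "PRO":
        cd = res.coord("CD")
        d = dihedral(cd, n, ca, c) if cd is not None else 60.0
        return [
            ("H2", place_atom(n, ca, c, 1.010, 109.5, d + 120.0)),
            ("H3", place_atom(n, ca, c, 1.010, 109.5, d - 120.0)),
        ]
    return [
        ("H1", place_atom(n, ca, c, 1.010, 109.5, 60.0)),
        ("H2", place_atom(n, ca, c, 1.010, 109.5, 180.0)),
        ("H3", place_atom(n, ca, c, 1.010, 109.5, -60.0)),
    ]


_BACKBONE_SET = {"N", "CA", "C", "O", "OXT", "H", "HA", "HA2", "HA3", "H1", "H2", "H3"}


def _sidechain_clashes(res: Residue, others: list[np.ndarray], threshold: float = 2.3):
    """(count, overlap) of side-chain heavy atoms closer than threshold to others."""
    count, overlap = 0, 0.0
    for a in res.atoms:
        if a.element == "H" or a.name in _BACKBONE_SET:
            continue
        for p in others:
            d = float(np.linalg.norm(a.coords - p))
            if d < threshold:
                count += 1
                overlap += threshold - d
    return count, overlap


def declash_sidechains(model: StructureModel, threshold: float = 2.3) -> int:
    """Resolve template-rotamer clashes by rotating whole side chains about CA-CB.

    The template chi values are chosen for clash-free *extended* building; in
    other backbone conformations (e.g. helices) a side chain can fold onto a
    neighbour. This deterministic pass tries the three staggered chi1
    rotations per clashing residue and keeps the least-clashing one. Returns
    the number of residues rotated. Only heavy-atom geometry is considered;
    call before :func:`add_hydrogens`.
    """
    from .geometry import rotation_about_axis

    n_rotated = 0
    for chain in model.chains:
        if not chain.is_protein:
            continue
        for i, res in enumerate(chain.residues):
            ca, cb = res.coord("CA"), res.coord("CB")
            if ca is None or cb is None:
                continue
            others: list[np.ndarray] = []
            for j, other in enumerate(chain.residues):
                if abs(j - i) < 1:
                    continue
                for a in other.atoms:
                    if a.element != "H" and np.linalg.norm(a.coords - cb) < 12.0:
                        others.append(a.coords)
            if not others:
                continue
            base = _sidechain_clashes(res, others, threshold)
            if base[0] == 0:
                continue
            axis = cb - ca
            side = [a for a in res.atoms
                    if a.element != "H" and a.name not in _BACKBONE_SET and a.name != "CB"]
            best = (base, 0.0)
            for angle in (2 * np.pi / 3, -2 * np.pi / 3):
                rot = rotation_about_axis(axis, angle)
                saved = [a.coords.copy() for a in side]
                for a in side:
                    a.coords = cb + rot @ (a.coords - cb)
                score = _sidechain_clashes(res, others, threshold)
                if score < best[0]:
                    best = (score, angle)
                for a, s in zip(side, saved):
                    a.coords = s
            if best[1]:
                rot = rotation_about_axis(axis, best[1])
                for a in side:
                    a.coords = cb + rot @ (a.coords - cb)
                n_rotated += 1
    return n_rotated


def add_hydrogens(
    model: StructureModel,
    states=None,
    termini: dict[str, tuple[str, str]] | None = None,
) -> StructureModel:
    """Discard and rebuild all protein hydrogens from template geometry.

    ``states`` maps ``(chain id, residue number, icode)`` to a variant tag
    (a :class:`~pdbmend.chem_states.ChemState` works directly); unassigned
    residues take the pH-7 defaults (HIS -> epsilon tautomer, CYS protonated,
    ASP/GLU deprotonated, LYS/ARG protonated). ``termini`` maps chain id to
    ("charged"|"cut", "charged"|"cut"); the default is neutral cut ends,
    appropriate for chains whose true termini are unresolved.
    """
    termini = termini or {}
    templatable = _templatable()
    for chain in model.chains:
        if not chain.is_protein:
            continue
        nterm, cterm = termini.get(chain.id, ("cut", "cut"))
        for i, res in enumerate(chain.residues):
            if res.name not in templatable or not res.has_backbone:
                continue
            res.strip_hydrogens()
            is_first = i == 0
            is_last = i == len(chain.residues) - 1
            # OXT bookkeeping so geometry always matches the census
            oxt = res.atom("OXT")
            if is_last and cterm == "charged":
                if oxt is None and res.atom("O") is not None:
                    res.atoms.append(
                        _mkatom("OXT", place_atom(res.coord("C"), res.coord("CA"),
                                                  res.coord("O"), 1.249, 117.0, 180.0))
                    )
            elif oxt is not None:
                res.atoms.remove(oxt)
            template = get_template(res.name, _variant_for(states, chain.id, res))
            prev = chain.residues[i - 1] if i > 0 else None
            if not _bonded(prev, res):
                prev = None
            for entry in template.hydrogen_ics:
                if entry.name == "H" and is_first and nterm == "charged":
                    continue  # replaced by the NH3+ set below
                pos = _place_ic(entry, res, prev)
                if pos is None and entry.name == "H":
                    pos = _amide_h_fallback(res)
                if pos is not None:
                    res.atoms.append(_mkatom(entry.name, pos, "H"))
            if is_first and nterm == "charged":
                for name, pos in _charged_nterm_h(res):
                    res.atoms.append(_mkatom(name, pos, "H"))
    return model
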