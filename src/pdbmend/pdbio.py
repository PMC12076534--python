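"""PDB v3.x fixed-column reading/writing and the structural report.

The in-memory currency of the whole pipeline is :class:`StructureModel`, a
plain chains -> residues -> atoms hierarchy plus the SEQRES sequences,
non-water het groups ("ligands"), waters and single-atom metal ions.

Parsing policy (see package docs for rationale):

* only the first MODEL of a multi-model (NMR) entry is kept;
* alternate locations are collapsed to the highest-occupancy conformer,
  ties broken toward altloc ``A`` and then first-seen;
* the element is inferred from the atom-name columns when the element field
  is blank (old PDB dialects);
* malformed fixed-width lines are skipped with a recorded warning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateOverflowError, EmptyStructureError

__all__ = [
    "AtomRecord",
    "Residue",
    "Chain",
    "StructureModel",
    "StructureReport",
    "parse_structure",
    "write_structure",
    "summarize",
    "METAL_ELEMENTS",
    "WATER_NAMES",
]

METAL_ELEMENTS = frozenset({"ZN", "CU", "FE", "MG", "MN", "CA", "NA", "K", "NI", "CO"})
WATER_NAMES = frozenset({"HOH", "WAT"})


@dataclass
class AtomRecord:
    serial: int
    name: str
    altloc: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_het: bool = False

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Residue:
    name: str
    number: int
    icode: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.coords

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.element != "H"]

    def strip_hydrogens(self) -> None:
        self.atoms = [a for a in self.atoms if a.element != "H"]


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    seqres: list[str] = field(default_factory=list)

    @property
    def is_protein(self) -> bool:
        return any(r.has_backbone for r in self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def n_heavy_atoms(self) -> int:
        return sum(len(r.heavy_atoms()) for r in self.residues)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def sort_residues(self) -> None:
        self.residues.sort(key=lambda r: (r.number, r.icode))


@dataclass
class StructureModel:
    chains: list[Chain] = field(default_factory=list)
    het_groups: list[tuple[str, Residue]] = field(default_factory=list)
    waters: list[Residue] = field(default_factory=list)
    metals: list[AtomRecord] = field(default_factory=list)
    source_id: str | None = None
    disulfides: list[tuple[tuple[str, int, str], tuple[str, int, str]]] = field(
        default_factory=list
    )
    warnings: list[str] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain | None:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    @property
    def n_atoms(self) -> int:
        return (
            sum(c.n_atoms for c in self.chains)
            + sum(len(r.atoms) for _, r in self.het_groups)
            + sum(len(r.atoms) for r in self.waters)
            + len(self.metals)
        )

    def all_coords(self) -> np.ndarray:
        """(n, 3) array over every atom in the model, partition order."""
        xs = []
        for c in self.chains:
            for r in c.residues:
                xs.extend(a.coords for a in r.atoms)
        for _, r in self.het_groups:
            xs.extend(a.coords for a in r.atoms)
        for r in self.waters:
            xs.extend(a.coords for a in r.atoms)
        xs.extend(a.coords for a in self.metals)
        return np.array(xs).reshape(-1, 3)


# --- parsing ------------------------------------------------------------------


def _infer_element(name_field: str, resname: str) -> str:
    """Element from PDB atom-name columns 13-16 when the element field is blank."""
    if len(name_field) >= 2 and name_field[0] != " " and name_field[:2].strip().isalpha():
        two = name_field[:2].strip().upper()
        # two-character elements occupy column 13; hydrogens like "HG21" do not
        if two in METAL_ELEMENTS or two in {"FE", "CL", "BR", "SE"}:
            return two
    stripped = name_field.strip()
    for ch in stripped:
        if ch.isalpha():
            # leading digits (e.g. "1HB2") belong to hydrogen naming
            return ch.upper()
    return "X"


def _parse_atom_line(line: str) -> tuple | None:
    try:
        serial = int(line[6:11])
        name = line[12:16]
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21]
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if len(line) > 60 and line[60:66].strip() else 0.0
        element = line[76:78].strip().upper() if len(line) > 76 else ""
    except (ValueError, IndexError):
        return None
    if not element:
        element = _infer_element(name, resname)
    if not np.isfinite([x, y, z]).all():
        return None
    return (serial, name.strip(), altloc, resname, chain_id, resseq, icode,
            np.array([x, y, z]), occ, bfac, element)


def _collapse_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties -> 'A', then first."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for a in atoms:
        prev = best.get(a.name)
        if prev is None:
            best[a.name] = a
            order.append(a.name)
        elif (a.occupancy, a.altloc == "A") > (prev.occupancy, prev.altloc == "A"):
            best[a.name] = a
    for a in best.values():
        a.altloc = ""
    return [best[n] for n in order]


def parse_structure(text: str, source_id: str | None = None) -> StructureModel:
    """Parse a PDB-format character stream into a :class:`StructureModel`.

    Raises :class:`EmptyStructureError` when no ATOM/HETATM record parses.
    """
    model = StructureModel(source_id=source_id)
    seqres: dict[str, list[str]] = {}
    # (chain, resseq, icode, resname, is_het) -> raw atom list
    groups: dict[tuple, list[AtomRecord]] = {}
    group_order: list[tuple] = []
    in_first_model = True
    seen_model = False
    n_parsed = 0

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "MODEL ":
            if seen_model:
                in_first_model = False
            seen_model = True
            continue
        if rec == "ENDMDL":
            in_first_model = False
            continue
        if rec == "SEQRES":
            chain_id = line[11] if len(line) > 11 else " "
            seqres.setdefault(chain_id, []).extend(line[19:].split())
            continue
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if not in_first_model:
            continue
        parsed = _parse_atom_line(line)
        if parsed is None:
            model.warnings.append(f"line {lineno}: malformed record skipped")
            continue
        (serial, name, altloc, resname, chain_id, resseq, icode,
         coords, occ, bfac, element) = parsed
        atom = AtomRecord(serial, name, altloc, element, coords, occ, bfac,
                          is_het=(rec == "HETATM"))
        key = (chain_id, resseq, icode, resname, rec == "HETATM")
        if key not in groups:
            groups[key] = []
            group_order.append(key)
        groups[key].append(atom)
        n_parsed += 1

    if n_parsed == 0:
        raise EmptyStructureError("empty structure: no parsable ATOM/HETATM records")

    chain_map: dict[str, Chain] = {}
    chain_order: list[str] = []
    for key in group_order:
        chain_id, resseq, icode, resname, is_het = key
        atoms = _collapse_altlocs(groups[key])
        residue = Residue(resname, resseq, icode, atoms)
        if resname in WATER_NAMES:
            model.waters.append(residue)
            continue
        if is_het:
            heavies = [a for a in atoms if a.element != "H"]
            if len(heavies) == 1 and heavies[0].element in METAL_ELEMENTS:
                model.metals.append(heavies[0])
                continue
            model.het_groups.append((chain_id, residue))
            continue
        if chain_id not in chain_map:
            chain_map[chain_id] = Chain(chain_id, seqres=seqres.get(chain_id, []))
            chain_order.append(chain_id)
        chain_map[chain_id].residues.append(residue)

    for cid in chain_order:
        chain_map[cid].sort_residues()
        model.chains.append(chain_map[cid])
    # SEQRES-only chains (fully unobserved) are dropped with a warning
    for cid in seqres:
        if cid not in chain_map:
            model.warnings.append(f"chain {cid}: SEQRES without coordinates ignored")
    return model


# --- writing ------------------------------------------------------------------


def _format_atom_name(name: str, element: str) -> str:
    # one/two-char elements start in column 14/13 respectively (PDB v3)
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2 or (name[:1].isdigit()):
        return f"{name:<4s}"
    return f" {name:<3s}"


def _atom_line(rec: str, serial: int, a: AtomRecord, resname: str,
               chain_id: str, resseq: int, icode: str) -> str:
    x, y, z = a.coords
    if max(abs(x), abs(y), abs(z)) >= 10000.0:
        raise CoordinateOverflowError(
            f"coordinate overflow on atom {a.name} of {resname} {resseq}"
        )
    return (
        f"{rec:<6s}{serial:>5d} {_format_atom_name(a.name, a.element)}"
        f"{'':1s}{resname:>3s} {chain_id:1s}{resseq:>4d}{icode:<1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.bfactor:6.2f}"
        f"          {a.element:>2s}"
    )


def write_structure(
    model: StructureModel,
    include_seqres: bool = True,
    include_ssbond: bool = True,
    cryst1: float | None = None,
) -> str:
    """Serialize a model to PDB format; ``cryst1`` adds a cubic cell record."""
    lines: list[str] = []
    if cryst1 is not None:
        lines.append(
            f"CRYST1{cryst1:9.3f}{cryst1:9.3f}{cryst1:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    if include_ssbond:
        for i, (a, b) in enumerate(model.disulfides, start=1):
            lines.append(
                f"SSBOND {i:3d} CYS {a[0]:1s} {a[1]:4d}{a[2]:<1s}   "
                f"CYS {b[0]:1s} {b[1]:4d}{b[2]:<1s}"
            )
    if include_seqres:
        for chain in model.chains:
            for i in range(0, len(chain.seqres), 13):
                chunk = chain.seqres[i : i + 13]
                lines.append(
                    f"SEQRES {i // 13 + 1:3d} {chain.id:1s} {len(chain.seqres):4d}  "
                    + " ".join(f"{r:>3s}" for r in chunk)
                )
    serial = 0
    for chain in model.chains:
        last = None
        for res in chain.residues:
            for a in res.atoms:
                serial += 1
                lines.append(_atom_line("ATOM", serial, a, res.name, chain.id,
                                        res.number, res.icode))
            last = res
        if last is not None:
            serial += 1
            lines.append(
                f"TER   {serial:>5d}      {last.name:>3s} {chain.id:1s}"
                f"{last.number:>4d}{last.icode:<1s}"
            )
    for chain_id, res in model.het_groups:
        for a in res.atoms:
            serial += 1
            lines.append(_atom_line("HETATM", serial, a, res.name, chain_id,
                                    res.number, res.icode))
    for res in model.waters:
        for a in res.atoms:
            serial += 1
            # large boxes overflow the 4-digit residue field; wrap like the PDB does
            lines.append(_atom_line("HETATM", serial, a, res.name, "W",
                                    res.number % 10000, res.icode))
    for a in model.metals:
        serial += 1
        lines.append(_atom_line("HETATM", serial, a, a.element[:3], "M",
                                serial % 10000, ""))
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- structural report --------------------------------------------------------


@dataclass
class ChainSummary:
    id: str
    n_atoms: int
    n_residues: int
    n_seqres: int
    n_internal_gaps: int
    n_missing_internal: int
    n_missing_nterm: int
    n_missing_cterm: int


@dataclass
class StructureReport:
    source_id: str | None
    chains: list[ChainSummary]
    n_ligands: int
    n_waters: int
    n_metals: int

    @property
    def total_residues(self) -> int:
        return sum(c.n_residues for c in self.chains)

    @property
    def total_seqres_residues(self) -> int:
        return sum(c.n_seqres for c in self.chains)

    def to_json(self) -> str:
        return json.dumps(
            {
                "source_id": self.source_id,
                "chains": [vars(c) for c in self.chains],
                "n_ligands": self.n_ligands,
                "n_waters": self.n_waters,
                "n_metals": self.n_metals,
                "total_residues": self.total_residues,
                "total_seqres_residues": self.total_seqres_residues,
            },
            indent=2,
        )

    def to_text(self) -> str:
        rows = [
            f"Structure {self.source_id or '(local file)'}",
            f"  protein chains : {len(self.chains)}",
        ]
        for c in self.chains:
            rows.append(
                f"    chain {c.id}: {c.n_atoms} atoms, {c.n_residues} residues"
                f" ({c.n_seqres} in SEQRES), {c.n_internal_gaps} internal gap(s)"
                f" missing {c.n_missing_internal} residue(s),"
                f" termini missing {c.n_missing_nterm}+{c.n_missing_cterm}"
            )
        rows.append(f"  ligands        : {self.n_ligands}")
        rows.append(f"  waters         : {self.n_waters}")
        rows.append(f"  metals         : {self.n_metals}")
        rows.append(
            f"  residues       : {self.total_residues} observed,"
            f" {self.total_seqres_residues} in SEQRES"
        )
        return "\n".join(rows)


def summarize(
    model: StructureModel,
    gaps: dict[str, list] | None = None,
    matches: dict[str, object] | None = None,
) -> StructureReport:
    """Build the structural report.

    ``gaps`` maps chain id -> list of GapRecord and ``matches`` maps chain id
    -> SequenceMatch (both from the sequence_gaps module; either may be
    omitted). Atom counts are the ATOM-record atoms as parsed; nothing is
    added.
    """
    gaps = gaps or {}
    matches = matches or {}
    chains = []
    for chain in model.chains:
        if not chain.is_protein:
            continue
        chain_gaps = gaps.get(chain.id, [])
        n_missing = sum(len(g.missing_seq) for g in chain_gaps)
        match = matches.get(chain.id)
        n_nterm = match.n_missing_nterm if match is not None else 0
        n_cterm = match.n_missing_cterm if match is not None else 0
        chains.append(
            ChainSummary(
                id=chain.id,
                n_atoms=chain.n_atoms,
                n_residues=len(chain.residues),
                n_seqres=len(chain.seqres),
                n_internal_gaps=len(chain_gaps),
                n_missing_internal=n_missing,
                n_missing_nterm=n_nterm,
                n_missing_cterm=n_cterm,
            )
        )
    return StructureReport(
        source_id=model.source_id,
        chains=chains,
        n_ligands=len(model.het_groups),
        n_waters=len(model.waters),
        n_metals=len(model.metals),
    )
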