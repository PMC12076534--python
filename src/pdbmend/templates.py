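"""Residue template library.

Templates are read from the versioned, human-readable data file
``data/residue_templates.dat``. A template describes one protonation /
tautomer / bridging variant of an amino acid: its side-chain heavy atoms and
all hydrogens as NeRF internal coordinates, plus the intra-residue bond list.
Backbone heavy atoms (N, CA, C, O) are implicit in every template and are
placed by the chain builder.

Variant tags follow the AMBER-style naming used across the package:

========  =======================================================
tag       meaning
========  =======================================================
``HIE``   neutral histidine, hydrogen on NE2 (epsilon; default)
``HID``   neutral histidine, hydrogen on ND1 (delta)
``HIP``   protonated histidinium (+1)
``CYS``   protonated cysteine thiol (default)
``CYX``   disulfide-bridged cysteine (no HG, SG-SG bond)
``CYM``   deprotonated thiolate cysteine (metal-coordinating)
``ASH``/``GLH``/``LYN``  neutral acid / neutral lysine (non-default)
========  =======================================================
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "ICEntry",
    "ResidueTemplate",
    "load_templates",
    "get_template",
    "resolve_variant",
    "residue_census",
    "expected_atom_count",
    "UntemplatedResidueError",
    "STANDARD_AA",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "DEFAULT_VARIANTS",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# template name used for each standard residue when no chemical state is assigned
DEFAULT_VARIANTS = {
    "HIS": "HIE",
    **{aa: aa for aa in STANDARD_AA if aa != "HIS"},
}

# variant tag -> parent 3-letter residue name
VARIANT_PARENT = {
    "HIE": "HIS", "HID": "HIS", "HIP": "HIS",
    "CYX": "CYS", "CYM": "CYS",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
    **{aa: aa for aa in STANDARD_AA if aa != "HIS"},
}


class UntemplatedResidueError(KeyError):
    """Raised when a residue code has no template (non-standard residue)."""


class ICEntry(NamedTuple):
    name: str
    refs: tuple[str, str, str]  # may include "-C" / "-O" (previous residue)
    r: float
    theta: float
    phi: float


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    charge: int
    heavy_ics: tuple[ICEntry, ...]
    hydrogen_ics: tuple[ICEntry, ...]
    extra_bonds: tuple[tuple[str, str], ...] = field(default=())

    @property
    def heavy_atoms(self) -> tuple[str, ...]:
        return BACKBONE_ATOMS + tuple(e.name for e in self.heavy_ics)

    @property
    def hydrogen_atoms(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.hydrogen_ics)

    @property
    def n_heavy(self) -> int:
        return 4 + len(self.heavy_ics)

    @property
    def n_hydrogens(self) -> int:
        return len(self.hydrogen_ics)

    def bonds(self) -> list[tuple[str, str]]:
        """Intra-residue bonds: implied backbone + IC parent bonds + ring closures."""
        out = [("N", "CA"), ("CA", "C"), ("C", "O")]
        for e in self.heavy_ics:
            out.append((e.name, e.refs[0]))
        for e in self.hydrogen_ics:
            if not e.refs[0].startswith("-"):
                out.append((e.name, e.refs[0]))
        out.extend(self.extra_bonds)
        return out


def _parse(text: str) -> dict[str, ResidueTemplate]:
    templates: dict[str, ResidueTemplate] = {}
    name = None
    charge = 0
    heavy: list[ICEntry] = []
    hydro: list[ICEntry] = []
    bonds: list[tuple[str, str]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        kind = tok[0]
        if kind == "RESI":
            name, charge = tok[1], int(tok[2])
            heavy, hydro, bonds = [], [], []
        elif kind == "IC":
            heavy.append(ICEntry(tok[1], (tok[2], tok[3], tok[4]),
                                 float(tok[5]), float(tok[6]), float(tok[7])))
        elif kind == "H":
            hydro.append(ICEntry(tok[1], (tok[2], tok[3], tok[4]),
                                 float(tok[5]), float(tok[6]), float(tok[7])))
        elif kind == "BOND":
            bonds.append((tok[1], tok[2]))
        elif kind == "END":
            assert name is not None
            templates[name] = ResidueTemplate(
                name, charge, tuple(heavy), tuple(hydro), tuple(bonds)
            )
            name = None
        else:
            raise ValueError(f"unrecognised template line: {raw!r}")
    return templates


_TEMPLATES: dict[str, ResidueTemplate] | None = None


def load_templates() -> dict[str, ResidueTemplate]:
    global _TEMPLATES
    if _TEMPLATES is None:
        text = (
            importlib.resources.files("pdbmend")
            .joinpath("data/residue_templates.dat")
            .read_text()
        )
        _TEMPLATES = _parse(text)
    return _TEMPLATES


def resolve_variant(resname: str, variant: str | None = None) -> str:
    """Template name for a residue, honouring an optional variant tag."""
    if variant is not None:
        if variant not in load_templates():
            raise UntemplatedResidueError(variant)
        return variant
    if resname in load_templates() and resname in VARIANT_PARENT:
        return resname
    if resname in DEFAULT_VARIANTS:
        return DEFAULT_VARIANTS[resname]
    raise UntemplatedResidueError(resname)


def get_template(resname: str, variant: str | None = None) -> ResidueTemplate:
    return load_templates()[resolve_variant(resname, variant)]


# --- census -----------------------------------------------------------------

def residue_census(
    template: ResidueTemplate,
    nterm: str | None = None,
    cterm: str | None = None,
) -> tuple[int, int]:
    """(heavy atoms, hydrogens) for one residue.

    nterm / cterm: None (internal), "cut" (neutral unresolved end, as left by
    an unmodelled terminal gap) or "charged" (true sequence terminus,
    NH3+ / COO-).
    """
    heavy = template.n_heavy
    nh = template.n_hydrogens
    if nterm == "charged":
        nh += 2  # NH -> NH3+ (PRO: N-H absent internally, NH2+ at terminus)
    if cterm == "charged":
        heavy += 1  # OXT
    return heavy, nh


def expected_atom_count(
    seq: list[str],
    states: dict[int, str] | None = None,
    nterm: str = "cut",
    cterm: str = "cut",
) -> tuple[int, int]:
    """Pure template census of a chain: (n_total, n_hydrogens).

    ``seq`` is the full modelled sequence (3-letter codes); ``states`` maps a
    0-based sequence index to a variant tag (e.g. ``{12: "CYM"}``); unlisted
    residues take the pH-7 defaults. n_total includes hydrogens.
    """
    if not seq:
        return (0, 0)
    states = states or {}
    heavy = nh = 0
    last = len(seq) - 1
    for i, code in enumerate(seq):
        tpl = get_template(code, states.get(i))
        h, x = residue_census(
            tpl,
            nterm=nterm if i == 0 else None,
            cterm=cterm if i == last else None,
        )
        heavy += h
        nh += x
    return heavy + nh, nh
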