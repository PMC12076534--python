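"""Disulfide and metal-site detection; per-residue protonation assignment.

The pH-7 rule set: histidine neutral (epsilon tautomer unless a metal
coordinates one of its ring nitrogens), arginine and lysine protonated,
aspartate and glutamate deprotonated, cysteine protonated unless it is
disulfide-bridged (CYX) or its sulfur coordinates a metal (CYM, thiolate).

Metals are never bonded: they remain nonbonded particles throughout, and
their only chemical effect here is on the protonation of their coordinating
residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pdbio import AtomRecord, StructureModel

__all__ = [
    "ChemState",
    "MetalSite",
    "detect_disulfides",
    "find_metal_sites",
    "assign_states",
    "DISULFIDE_CUTOFF",
    "METAL_CUTOFF",
]

DISULFIDE_CUTOFF = 2.5  # Å, SG-SG (typical bond 2.05 Å)
METAL_CUTOFF = 3.0  # Å, metal to protein N/O/S

ResidueKey = tuple[str, int, str]  # (chain id, residue number, icode)


@dataclass
class MetalSite:
    metal: AtomRecord
    # (residue key, residue name, atom name, distance Å)
    coordinators: list[tuple[ResidueKey, str, str, float]]


@dataclass
class ChemState:
    variants: dict[ResidueKey, str] = field(default_factory=dict)
    disulfides: list[tuple[ResidueKey, ResidueKey]] = field(default_factory=list)
    metal_sites: list[MetalSite] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def get(self, key: ResidueKey, default: str | None = None) -> str | None:
        return self.variants.get(key, default)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variants": {"/".join(map(str, k)): v for k, v in self.variants.items()},
                "disulfides": [
                    ["/".join(map(str, a)), "/".join(map(str, b))]
                    for a, b in self.disulfides
                ],
                "metal_sites": [
                    {
                        "metal": s.metal.element,
                        "coordinators": [
                            {"residue": "/".join(map(str, k)), "name": n,
                             "atom": a, "distance": round(d, 3)}
                            for k, n, a, d in s.coordinators
                        ],
                    }
                    for s in self.metal_sites
                ],
            },
            indent=2,
        )


def _cys_sg_atoms(model: StructureModel) -> list[tuple[ResidueKey, np.ndarray]]:
    out = []
    for chain in model.chains:
        for res in chain.residues:
            if res.name in ("CYS", "CYX", "CYM"):
                sg = res.coord("SG")
                if sg is not None:
                    out.append(((chain.id, res.number, res.icode), sg))
    return out


def detect_disulfides(
    model: StructureModel, cutoff: float = DISULFIDE_CUTOFF
) -> list[tuple[ResidueKey, ResidueKey]]:
    """CYS pairs with SG-SG distance <= cutoff, greedy nearest-pair matching.

    Each SG joins at most one bridge; candidate pairs are consumed in order of
    increasing distance, so the geometrically best bridge wins when an SG has
    several partners within the cutoff. The pair set is independent of residue
    order in the model.
    """
    sgs = _cys_sg_atoms(model)
    candidates = []
    for i in range(len(sgs)):
        for j in range(i + 1, len(sgs)):
            d = float(np.linalg.norm(sgs[i][1] - sgs[j][1]))
            if d <= cutoff:
                candidates.append((d, sgs[i][0], sgs[j][0]))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set[ResidueKey] = set()
    pairs = []
    for _, a, b in candidates:
        if a in used or b in used:
            continue
        pairs.append((a, b) if a <= b else (b, a))
        used.update((a, b))
    pairs.sort()
    return pairs


def find_metal_sites(
    model: StructureModel, cutoff: float = METAL_CUTOFF
) -> list[MetalSite]:
    """For each metal ion, the protein N/O/S atoms within the cutoff."""
    sites = []
    for metal in model.metals:
        coordinators = []
        for chain in model.chains:
            for res in chain.residues:
                for atom in res.atoms:
                    if atom.element not in ("N", "O", "S"):
                        continue
                    d = float(np.linalg.norm(atom.coords - metal.coords))
                    if d <= cutoff:
                        coordinators.append(
                            ((chain.id, res.number, res.icode), res.name, atom.name, d)
                        )
        coordinators.sort(key=lambda t: t[3])
        sites.append(MetalSite(metal=metal, coordinators=coordinators))
    return sites


def assign_states(
    model: StructureModel,
    disulfides: list[tuple[ResidueKey, ResidueKey]] | None = None,
    metal_sites: list[MetalSite] | None = None,
) -> ChemState:
    """Assign per-residue protonation variants from detection results.

    Priority for cysteine: a disulfide bridge wins over metal coordination
    (with a warning); otherwise metal-coordinating SG -> CYM, else protonated
    CYS. Histidine tautomer: the metal-coordinating ring nitrogen is left
    unprotonated (NE2 coordinates -> delta tautomer HID; ND1 -> epsilon HIE);
    both nitrogens coordinating is flagged and the epsilon default kept.
    """
    if disulfides is None:
        disulfides = detect_disulfides(model)
    if metal_sites is None:
        metal_sites = find_metal_sites(model)
    state = ChemState(disulfides=disulfides, metal_sites=metal_sites)

    bridged: set[ResidueKey] = set()
    for a, b in disulfides:
        bridged.update((a, b))
        state.variants[a] = "CYX"
        state.variants[b] = "CYX"

    # metal-driven assignments
    cys_coord: set[ResidueKey] = set()
    his_coord: dict[ResidueKey, set[str]] = {}
    for site in metal_sites:
        for key, resname, atom_name, _ in site.coordinators:
            if resname in ("CYS", "CYX", "CYM") and atom_name == "SG":
                cys_coord.add(key)
            if resname in ("HIS", "HIE", "HID", "HIP") and atom_name in ("ND1", "NE2"):
                his_coord.setdefault(key, set()).add(atom_name)

    for key in sorted(cys_coord):
        if key in bridged:
            state.warnings.append(
                f"CYS {key}: both disulfide-bridged and metal-coordinating; bridge wins"
            )
        else:
            state.variants[key] = "CYM"

    for key, nitrogens in sorted(his_coord.items()):
        if nitrogens == {"ND1", "NE2"}:
            state.warnings.append(
                f"HIS {key}: both ring nitrogens within metal cutoff; keeping epsilon"
            )
            state.variants[key] = "HIE"
        elif "NE2" in nitrogens:
            state.variants[key] = "HID"
        else:
            state.variants[key] = "HIE"
    return state
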