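"""Minimal PDB reading boundary.

Wraps Bio.PDB into a light structure representation: an ordered list of
residues, each holding heavy-atom coordinates in Angstrom keyed by atom name.
First model and first altLoc only by default; HETATM records are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning


# force-field naming variants -> standard residue names
RESNAME_ALIASES = {
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
    "CYX": "CYS", "MSE": "MET",
}


@dataclass
class ResidueRecord:
    name: str
    index: int              # 1-based ordinal along the chain
    resseq: int             # author residue number
    icode: str              # insertion code, "" if none
    chain_id: str
    atoms: dict = field(default_factory=dict)  # name -> (3,) Angstrom array
    elements: dict = field(default_factory=dict)  # name -> element symbol


@dataclass
class StructureRecord:
    name: str
    residues: list

    def sequence(self):
        return [r.name for r in self.residues]


def read_structure(path, model_index: int = 0, chain_id: str | None = None,
                   include_het: bool = False) -> StructureRecord:
    """Parse a PDB file into a StructureRecord (first model, first altLoc)."""
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("s", str(path))
    models = list(structure)
    if model_index >= len(models):
        raise ValueError(f"model {model_index} not present ({len(models)} models)")
    model = models[model_index]
    chains = list(model)
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found")
    else:
        chains = chains[:1]

    residues = []
    ordinal = 0
    for chain in chains:
        for res in chain:
            het, resseq, icode = res.id
            if het.strip() and not include_het:
                continue
            ordinal += 1
            resname = res.get_resname().strip()
            rec = ResidueRecord(name=RESNAME_ALIASES.get(resname, resname),
                                index=ordinal,
                                resseq=resseq, icode=icode.strip(), chain_id=chain.id)
            for atom in res:
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]  # first altLoc
                name = atom.get_name().strip()
                if name in rec.atoms:
                    continue
                elem = _guess_element(name, (atom.element or "").strip())
                if elem == "H":
                    continue  # heavy atoms only; hydrogens handled implicitly
                rec.atoms[name] = np.asarray(atom.get_coord(), dtype=float)
                rec.elements[name] = elem
            if rec.atoms:
                residues.append(rec)
    return StructureRecord(name=str(path), residues=residues)


def _guess_element(name: str, parsed: str = "") -> str:
    """Element for a protein atom.

    Name-based rules win over the parser's guess: files without an element
    column make Bio.PDB read 'CA' as calcium, 'HE' as helium, etc., while in
    standard amino acids only H/C/N/O/S occur.
    """
    stripped = name.strip().lstrip("0123456789")
    if stripped and stripped[0].upper() in "HCNOS":
        return stripped[0].upper()
    if parsed:
        return parsed.capitalize()
    return "C"
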