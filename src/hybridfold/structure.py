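"""Minimal protein-chain container and PDB-format I/O.

A :class:`StructureChain` is an ordered list of residues, each holding its
named heavy atoms with coordinates.  It is the input to Protein Blocks
assignment (backbone dihedrals) and to solvent-accessibility calculation,
and it is what the synthetic-backbone generators produce.

Parsing and writing of PDB-format files is delegated to Biopython; alternate
atom locations are collapsed to the highest-occupancy conformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser, PDBIO, StructureBuilder
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from Bio.SeqUtils import seq1

__all__ = ["Atom", "Residue", "StructureChain", "read_pdb_chain", "write_pdb"]


@dataclass
class Atom:
    name: str
    coord: np.ndarray  # shape (3,), Angstrom
    element: str
    occupancy: float = 1.0


@dataclass
class Residue:
    name: str  # three-letter code, e.g. "ALA"
    seq_id: int
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        code = seq1(self.name.capitalize())
        return code if code and code != "X" and len(code) == 1 else "X"

    def get(self, atom_name: str) -> Atom | None:
        return self.atoms.get(atom_name)

    def has_backbone(self) -> bool:
        return all(n in self.atoms for n in ("N", "CA", "C"))


@dataclass
class StructureChain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def heavy_atoms(self):
        """Yield (residue_index, Atom) for all non-hydrogen atoms."""
        for i, res in enumerate(self.residues):
            for atom in res.atoms.values():
                if atom.element.upper() != "H":
                    yield i, atom


def _pick_conformer(bio_atom):
    """Highest-occupancy conformer of a possibly disordered Biopython atom."""
    if bio_atom.is_disordered():
        children = bio_atom.disordered_get_list()
        return max(children, key=lambda a: (a.get_occupancy() or 0.0))
    return bio_atom


def read_pdb_chain(path, chain_id: str | None = None, model_index: int = 0) -> StructureChain:
    """Read one chain of a PDB-format file into a :class:`StructureChain`.

    Only the first model is used by default; water and other hetero residues
    without backbone atoms are kept as-is (downstream code treats residues
    lacking N/CA/C as undefined positions) except waters, which are dropped.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {path}")
    model = models[model_index]
    chains = {c.id: c for c in model}
    if chain_id is None:
        chain_id = next(iter(chains))
    if chain_id not in chains:
        raise KeyError(f"chain {chain_id!r} not found in {path}; have {sorted(chains)}")
    out = StructureChain(chain_id=chain_id)
    for res in chains[chain_id]:
        if res.get_resname().strip() == "HOH":
            continue
        atoms: dict[str, Atom] = {}
        for bio_atom in res.get_unpacked_list():
            a = _pick_conformer(bio_atom)
            name = a.get_name()
            if name in atoms:  # keep first (highest occupancy already chosen)
                continue
            atoms[name] = Atom(
                name=name,
                coord=np.asarray(a.get_coord(), dtype=float),
                element=(a.element or name[0]).strip().upper(),
                occupancy=a.get_occupancy() or 1.0,
            )
        out.residues.append(Residue(name=res.get_resname().strip(), seq_id=res.id[1], atoms=atoms))
    if not out.residues:
        raise ValueError("empty structure")
    return out


def write_pdb(chain: StructureChain, path) -> None:
    """Write a chain as a single-model PDB file (via Biopython)."""
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("s")
    builder.init_model(0)
    builder.init_chain(chain.chain_id or "A")
    builder.init_seg("    ")
    serial = 1
    for res in chain.residues:
        builder.init_residue(res.name, " ", res.seq_id, " ")
        for atom in res.atoms.values():
            builder.init_atom(
                atom.name,
                np.asarray(atom.coord, dtype=float),
                0.0,
                atom.occupancy,
                " ",
                f" {atom.name:<3s}"[:4],
                serial,
                element=atom.element,
            )
            serial += 1
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))
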