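"""Solvent accessibility: Shrake–Rupley SASA, relative accessibility, 10 classes.

Absolute solvent-accessible surface area is computed with the Shrake–Rupley
method on a deterministic spherical quadrature (golden-section lattice), so
results are reproducible bit-for-bit for a fixed point count.  Relative
accessibility divides a residue's SASA by its residue-type maximum (the
NACCESS-compatible Hubbard–Thornton tripeptide values by default), and the
resulting percentage is discretised into ten equal-width classes from
buried (1) to exposed (10).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure import StructureChain

__all__ = [
    "VDW_RADII",
    "ResidueSASA",
    "sphere_points",
    "sasa",
    "max_asa_table",
    "relative_accessibility",
    "sa_class",
    "sa_classes",
]

#: element van der Waals radii (Angstrom); fallback is the carbon radius
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4
N_SA_CLASSES = 10

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class ResidueSASA:
    """Per-residue absolute SASA (A^2) and relative accessibility (%)."""

    absolute: np.ndarray
    relative: np.ndarray

    def __len__(self) -> int:
        return len(self.absolute)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section lattice of ``n`` points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k  # golden angle increments
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(chain: StructureChain, probe: float = PROBE_RADIUS, n_points: int = 960) -> ResidueSASA:
    """Shrake–Rupley solvent-accessible surface area per residue.

    Hydrogens are ignored.  Each heavy atom is given ``n_points`` quadrature
    points on its solvent-expanded sphere; a point is accessible when it lies
    outside every neighbouring atom's expanded sphere.  The accessible
    fraction times the sphere area is summed per residue.
    """
    atoms = list(chain.heavy_atoms())
    if not atoms:
        raise ValueError("no atoms")
    coords = np.array([a.coord for _, a in atoms], dtype=float)
    radii = np.array(
        [VDW_RADII.get(a.element.upper(), DEFAULT_RADIUS) + probe for _, a in atoms]
    )
    res_index = np.array([i for i, _ in atoms], dtype=int)
    unit = sphere_points(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    absolute = np.zeros(len(chain))
    for k in range(len(atoms)):
        pts = coords[k] + radii[k] * unit
        neighbours = [j for j in tree.query_ball_point(coords[k], max_reach) if j != k]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= radii[j] ** 2
        area = 4.0 * np.pi * radii[k] ** 2 * accessible.sum() / n_points
        absolute[res_index[k]] += area

    rel = np.array(
        [
            relative_accessibility(absolute[i], chain.residues[i].name)
            for i in range(len(chain))
        ]
    )
    return ResidueSASA(absolute=absolute, relative=rel)


def max_asa_table(which: str = "hubbard") -> dict[str, float]:
    """Residue-type maximum ASA table: ``hubbard`` (default) or ``tien2013``."""
    text = resources.files("hybridfold.data").joinpath("max_asa.tsv").read_text()
    table: dict[str, float] = {}
    col = {"hubbard": 1, "tien2013": 2}[which]
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue\t"):
            continue
        parts = line.split("\t")
        table[parts[0]] = float(parts[col])
    return table


def relative_accessibility(abs_sasa: float, residue_type: str, table: str = "hubbard") -> float:
    """Relative accessibility in percent: 100 * SASA / maxASA(residue type).

    ``residue_type`` may be a one- or three-letter code.  Unknown types fall
    back to the glycine maximum with a warning (may exceed 100 before any
    clamping; classes clamp at the top bin).
    """
    maxasa = max_asa_table(table)
    name = residue_type.upper()
    if len(name) == 1:
        name = _ONE_TO_THREE.get(name, name)
    if name not in maxasa:
        warnings.warn(f"unknown residue type {residue_type!r}; normalising by glycine maximum")
        name = "GLY"
    return 100.0 * abs_sasa / maxasa[name]


def sa_class(rel_acc: float) -> int:
    """Ten equal-width accessibility classes on [0, 100], clamped above 100.

    Class 1 is fully buried (<10%), class 10 the most exposed (>=90%).
    """
    if rel_acc < 0:
        raise ValueError("relative accessibility must be non-negative")
    return min(int(rel_acc // 10.0), N_SA_CLASSES - 1) + 1


def sa_classes(chain: StructureChain, probe: float = PROBE_RADIUS, n_points: int = 960) -> list[int]:
    """Convenience: per-residue SA class (1..10) straight from coordinates."""
    rs = sasa(chain, probe=probe, n_points=n_points)
    return [sa_class(max(0.0, r)) for r in rs.relative]
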