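"""Protein Blocks: backbone dihedrals, 16-letter assignment, and SS mapping.

Protein Blocks (PBs) are a structural alphabet of 16 pentapeptide backbone
conformations, labelled ``a``–``p``.  Each letter is defined by a reference
vector of 8 dihedral angles (the psi/phi angles of a five-residue window
centred on the assigned position).  A residue is assigned the letter whose
reference vector is nearest in RMSDA — root mean square deviation over
angular values, with differences wrapped to [0, 180] degrees.

Letters map onto three secondary-structure states for display: ``m`` is the
core alpha-helix block (with caps f, k, l, n, o, p), ``d`` the core
beta-strand block (with caps b, c, e), and a, g, h, i, j are coil/turn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .structure import StructureChain

__all__ = [
    "PB_ALPHABET",
    "UNDEFINED_PB",
    "DihedralSeries",
    "load_pb_reference_table",
    "backbone_dihedrals",
    "rmsda",
    "assign_pb",
    "pb_to_ss",
    "pb_string_to_ss",
]

PB_ALPHABET = "abcdefghijklmnop"
UNDEFINED_PB = "Z"

#: default C(i)-N(i+1) distance above which a chain break is declared
CHAIN_BREAK_THRESHOLD = 2.5

_HELIX = set("mfklnop")
_STRAND = set("dbce")
_COIL = set("aghij")


@dataclass
class DihedralSeries:
    """Per-residue (phi, psi) in degrees; ``nan`` marks undefined angles."""

    phi: np.ndarray
    psi: np.ndarray

    def __len__(self) -> int:
        return len(self.phi)


def load_pb_reference_table() -> dict[str, np.ndarray]:
    """The canonical 16x8 PB reference dihedral table (degrees).

    Row order of the 8 angles: psi(i-2), phi(i-1), psi(i-1), phi(i), psi(i),
    phi(i+1), psi(i+1), phi(i+2).
    """
    table: dict[str, np.ndarray] = {}
    text = resources.files("hybridfold.data").joinpath("pb_reference_angles.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pb\t"):
            continue
        parts = line.split("\t")
        table[parts[0]] = np.array([float(x) for x in parts[1:]], dtype=float)
        if table[parts[0]].shape != (8,):
            raise ValueError(f"bad reference row for PB {parts[0]!r}")
    if sorted(table) != list(PB_ALPHABET):
        raise ValueError("PB reference table must contain exactly letters a..p")
    return table


def _dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points, in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def backbone_dihedrals(
    chain: StructureChain, break_threshold: float = CHAIN_BREAK_THRESHOLD
) -> DihedralSeries:
    """Compute per-residue phi/psi angles.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1).
    Angles are undefined (nan) at chain termini, where backbone atoms are
    missing, and across chain breaks (consecutive C-N distance above
    ``break_threshold`` Angstrom).
    """
    n = len(chain)
    if n == 0:
        raise ValueError("empty structure")
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)

    def atom(i: int, name: str):
        a = chain.residues[i].atoms.get(name)
        return None if a is None else a.coord

    def linked(i: int) -> bool:
        """True if the peptide bond C(i)-N(i+1) exists and is unbroken."""
        c, nn = atom(i, "C"), atom(i + 1, "N")
        if c is None or nn is None:
            return False
        return float(np.linalg.norm(nn - c)) <= break_threshold

    for i in range(n):
        if not chain.residues[i].has_backbone():
            continue
        cur = (atom(i, "N"), atom(i, "CA"), atom(i, "C"))
        if i > 0 and linked(i - 1):
            phi[i] = _dihedral(atom(i - 1, "C"), cur[0], cur[1], cur[2])
        if i < n - 1 and linked(i):
            psi[i] = _dihedral(cur[0], cur[1], cur[2], atom(i + 1, "N"))
    return DihedralSeries(phi=phi, psi=psi)


def rmsda(a, b) -> float:
    """Root mean square deviation over 8 angular values, degrees.

    Differences are wrapped to [0, 180]; raises on any undefined angle.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != (8,) or b.shape != (8,):
        raise ValueError("rmsda expects two 8-angle vectors")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("incomplete window")
    d = np.abs(a - b) % 360.0
    d = np.minimum(d, 360.0 - d)
    return float(np.sqrt(np.mean(d**2)))


def _window(d: DihedralSeries, i: int) -> np.ndarray | None:
    n = len(d)
    if i < 2 or i > n - 3:
        return None
    w = np.array(
        [
            d.psi[i - 2],
            d.phi[i - 1],
            d.psi[i - 1],
            d.phi[i],
            d.psi[i],
            d.phi[i + 1],
            d.psi[i + 1],
            d.phi[i + 2],
        ]
    )
    return None if np.isnan(w).any() else w


def assign_pb(d: DihedralSeries, refs: dict[str, np.ndarray] | None = None) -> str:
    """Assign the nearest PB letter at every position with a complete window.

    Positions whose pentapeptide window is incomplete (the two first/last
    residues, or any window containing an undefined angle) get ``Z``.  Ties
    in RMSDA break to the alphabetically first letter.
    """
    if len(d) == 0:
        raise ValueError("empty dihedral series")
    if refs is None:
        refs = load_pb_reference_table()
    letters = sorted(refs)
    out = []
    for i in range(len(d)):
        w = _window(d, i)
        if w is None:
            out.append(UNDEFINED_PB)
            continue
        best_letter, best_dist = UNDEFINED_PB, math.inf
        for letter in letters:
            dist = rmsda(w, refs[letter])
            if dist < best_dist:
                best_letter, best_dist = letter, dist
        out.append(best_letter)
    return "".join(out)


def pb_to_ss(pb: str) -> str:
    """Map a PB letter to a 3-state secondary structure code (H/E/C, '-' for Z)."""
    if pb in _HELIX:
        return "H"
    if pb in _STRAND:
        return "E"
    if pb in _COIL:
        return "C"
    if pb == UNDEFINED_PB:
        return "-"
    raise ValueError(f"unknown PB letter {pb!r}")


def pb_string_to_ss(pbs: str) -> str:
    return "".join(pb_to_ss(p) for p in pbs)
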