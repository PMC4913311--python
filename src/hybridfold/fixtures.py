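"""Deterministic synthetic fixtures: toy backbones, mutated MSAs, toy databanks.

Everything here is a pure function of its arguments (and an explicit seed),
so tests and benchmarks are reproducible bit-for-bit without downloading any
structure or sequence data.

Backbones are grown in internal coordinates with ideal peptide geometry
(bond lengths/angles below, omega fixed at 180 degrees), so a chain built
from prescribed (phi, psi) dihedrals returns those dihedrals on
recomputation.  A chain realising a requested Protein Blocks string gives
every residue the central (phi, psi) pair of its letter's reference vector;
on homogeneous five-residue windows the nearest-letter assignment then
recovers the letter exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .databank import FamilySpec, TemplateDatabank, build_databank
from .pb_alphabet import assign_pb, backbone_dihedrals, load_pb_reference_table
from .profiles import (
    AA_ALPHABET,
    AA_BACKGROUND,
    HybridProfile,
    build_aa_profile,
    build_pb_profile_from_structures,
    build_sa_profile_from_structures,
    concat_hybrid,
    sa_classes_to_string,
)
from . import accessibility
from .structure import Atom, Residue, StructureChain

__all__ = [
    "ToySpec",
    "make_backbone",
    "make_pb_backbone",
    "stable_pb_letters",
    "mutate_sequence",
    "mutate_msa",
    "make_toy_databank",
    "make_query_profile",
    "random_profile",
]

# ideal peptide geometry (Angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class ToySpec:
    """Plan for one synthetic fold: PB segments, sequence source, noise, seed."""

    fold_id: str
    segments: list[tuple[str, int]]  # (PB letter, length)
    sequence: str
    mutation_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        total = sum(n for _, n in self.segments)
        if total < 15:
            raise ValueError("toy folds must be at least 15 residues long")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")

    @property
    def pb_string(self) -> str:
        return "".join(letter * n for letter, n in self.segments)


def _place(a, b, c, length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: point d with |cd|=length, angle(b,c,d), torsion(a,b,c,d)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    d_local = np.array(
        [-length * np.cos(theta), length * np.sin(theta) * np.cos(chi), length * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_backbone(
    segments: list[tuple[float, float, int]],
    sequence: str | None = None,
    chain_id: str = "A",
    with_oxygen: bool = True,
    with_cb: bool = True,
) -> StructureChain:
    """Grow an ideal-geometry backbone from (phi, psi, length) segments.

    Residue i takes phi/psi from its segment; phi of the first residue and
    psi of the last are geometrically unused.  Residue types follow
    ``sequence`` (default poly-alanine); glycines get no CB.
    """
    plan = [(phi, psi) for phi, psi, n in segments for _ in range(int(n))]
    if not plan:
        raise ValueError("empty segment plan")
    n_res = len(plan)
    if sequence is None:
        sequence = "A" * n_res
    if len(sequence) != n_res:
        raise ValueError("sequence length does not match segment plan")

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed frame for residue 0
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    t = np.radians(180.0 - ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(t), np.sin(t), 0.0])
    for i in range(1, n_res):
        psi_prev = plan[i - 1][1]
        N[i] = _place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA[i] = _place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = _place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, plan[i][0])

    chain = StructureChain(chain_id=chain_id)
    for i in range(n_res):
        res = Residue(name=_THREE.get(sequence[i].upper(), "ALA"), seq_id=i + 1)
        res.atoms["N"] = Atom("N", N[i].copy(), "N")
        res.atoms["CA"] = Atom("CA", CA[i].copy(), "C")
        res.atoms["C"] = Atom("C", C[i].copy(), "C")
        if with_oxygen:
            res.atoms["O"] = Atom("O", _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, plan[i][1] + 180.0), "O")
        if with_cb and res.name != "GLY":
            res.atoms["CB"] = Atom("CB", _place(N[i], C[i], CA[i], BOND_CA_CB, 110.6, 122.7), "C")
        chain.residues.append(res)
    return chain


def make_pb_backbone(pb_string: str, sequence: str | None = None, refs=None) -> StructureChain:
    """Backbone whose residues carry the central (phi, psi) of their PB letter."""
    if refs is None:
        refs = load_pb_reference_table()
    segments = []
    for letter in pb_string:
        if letter not in refs:
            raise ValueError(f"cannot build geometry for PB letter {letter!r}")
        row = refs[letter]
        segments.append((float(row[3]), float(row[4]), 1))  # phi(i), psi(i)
    return make_backbone(segments, sequence=sequence)


@lru_cache(maxsize=1)
def stable_pb_letters() -> str:
    """PB letters that a constant central-dihedral backbone assigns back to itself.

    Used by the toy-fold generator so fold PB strings are realisable.
    """
    refs = load_pb_reference_table()
    stable = []
    for letter in sorted(refs):
        chain = make_backbone([(float(refs[letter][3]), float(refs[letter][4]), 9)])
        assigned = assign_pb(backbone_dihedrals(chain), refs)
        if assigned[4] == letter:
            stable.append(letter)
    return "".join(stable)


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate``, uniformly over 19 others."""
    out = []
    for c in sequence:
        if rng.random() < rate and c in AA_ALPHABET:
            alternatives = AA_ALPHABET.replace(c, "")
            out.append(alternatives[rng.integers(len(alternatives))])
        else:
            out.append(c)
    return "".join(out)


def mutate_msa(
    master_sequence: str,
    n_rows: int,
    rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> list[str]:
    """Aligned rows derived from the master by substitutions and deletions.

    Each row applies per-site substitutions at ``rate``; with probability
    ``indel_rate`` a site starts a geometric-length (mean 2) gap run.
    Indels are deletions only (gap characters in the row), so the alignment
    stays in master coordinates.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    L = len(master_sequence)
    rows = []
    for _ in range(n_rows):
        chars = list(mutate_sequence(master_sequence, rate, rng))
        i = 0
        while i < L:
            if rng.random() < indel_rate:
                run = 1 + rng.geometric(0.5)
                for k in range(i, min(i + run, L)):
                    chars[k] = "-"
                i += run
            else:
                i += 1
        rows.append("".join(chars))
    return rows


def _hamming_fraction(a: str, b: str) -> float:
    n = min(len(a), len(b))
    diff = sum(1 for x, y in zip(a, b) if x != y) + abs(len(a) - len(b))
    return diff / max(len(a), len(b)) if n else 1.0


def _random_fold_plan(length: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Random PB segment plan; diversity comes from the realised assignment."""
    letters = "abcdefghijklmnop"
    segments: list[tuple[str, int]] = []
    total = 0
    prev = None
    while total < length:
        letter = letters[rng.integers(len(letters))]
        if letter == prev:
            continue
        seg_len = int(min(3 + rng.integers(6), length - total))
        segments.append((letter, seg_len))
        total += seg_len
        prev = letter
    return segments


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AA_ALPHABET), size=length, p=AA_BACKGROUND)
    return "".join(AA_ALPHABET[i] for i in idx)


@dataclass
class ToyDatabank:
    """A built toy databank plus the fold truth needed for evaluation."""

    databank: TemplateDatabank
    fold_map: dict[str, str]  # template id -> fold id
    folds: dict[str, ToySpec] = field(default_factory=dict)


def make_toy_databank(
    n_folds: int = 5,
    members_per_fold: int = 2,
    length: int = 40,
    seed: int = 0,
    member_mutation_rate: float = 0.3,
    out_path=None,
) -> ToyDatabank:
    """Build a databank of distinct toy folds with sequence-diverged members.

    Folds get random PB segment plans whose strings differ pairwise by at
    least 30% of positions; members of a fold share the fold backbone but
    carry sequences mutated from the fold master at ``member_mutation_rate``.
    Each member becomes one template record; the fold map labels records for
    benchmark evaluation.
    """
    rng = np.random.default_rng(seed)
    folds: dict[str, ToySpec] = {}
    plans: list[str] = []
    attempts = 0
    while len(folds) < n_folds:
        attempts += 1
        if attempts > 200 * n_folds:
            raise RuntimeError("could not draw sufficiently distinct fold plans")
        plan = _random_fold_plan(length, rng)
        # distinctness is judged on the PB string the backbone actually realises
        probe = make_backbone([(phi, psi, n) for phi, psi, n in _plan_to_segments(plan)])
        realised = assign_pb(backbone_dihedrals(probe))
        if any(_hamming_fraction(realised, p) < 0.30 for p in plans):
            continue
        fold_id = f"fold{len(folds) + 1:02d}"
        folds[fold_id] = ToySpec(
            fold_id=fold_id,
            segments=plan,
            sequence=_random_sequence(length, rng),
            mutation_rate=member_mutation_rate,
            seed=seed,
        )
        plans.append(realised)

    specs = []
    fold_map: dict[str, str] = {}
    for fold_id, fold in folds.items():
        for k in range(members_per_fold):
            member_seq = mutate_sequence(fold.sequence, fold.mutation_rate, rng)
            chain = make_backbone(
                [(phi, psi, 1) for phi, psi, _ in _per_residue_plan(fold)], sequence=member_seq
            )
            tid = f"{fold_id}_m{k + 1}"
            specs.append(FamilySpec(identifier=tid, members=[(chain, tid)], description=f"toy {fold_id}"))
            fold_map[tid] = fold_id
    db = build_databank(specs, out_path=out_path)
    return ToyDatabank(databank=db, fold_map=fold_map, folds=folds)


def _plan_to_segments(segments: list[tuple[str, int]]) -> list[tuple[float, float, int]]:
    refs = load_pb_reference_table()
    return [(float(refs[c][3]), float(refs[c][4]), int(n)) for c, n in segments]


def _per_residue_plan(fold: ToySpec) -> list[tuple[float, float, int]]:
    plan = []
    for phi, psi, n in _plan_to_segments(fold.segments):
        plan.extend((phi, psi, 1) for _ in range(n))
    return plan


def make_query_profile(
    fold: ToySpec,
    seed: int,
    mutation_rate: float = 0.3,
    n_msa_rows: int = 8,
    indel_rate: float = 0.05,
    identifier: str = "query",
) -> HybridProfile:
    """Hybrid profile of a held-out member of ``fold``.

    The member's sequence is a fresh mutation of the fold master; its MSA is
    generated around that sequence, and PB/SA tracks are computed from the
    member's own structure (standing in for an external predictor).
    """
    rng = np.random.default_rng(seed)
    member_seq = mutate_sequence(fold.sequence, mutation_rate, rng)
    msa = [member_seq] + mutate_msa(
        member_seq, n_msa_rows, mutation_rate, indel_rate, seed=int(rng.integers(2**31))
    )
    aa = build_aa_profile(msa, master_index=0)
    chain = make_backbone([(p, s, n) for p, s, n in _per_residue_plan(fold)], sequence=member_seq)
    pb_string = assign_pb(backbone_dihedrals(chain))
    sa_cls = accessibility.sa_classes(chain)
    pb = build_pb_profile_from_structures([pb_string])
    sa = build_sa_profile_from_structures([sa_cls])
    return concat_hybrid(
        aa, pb, sa,
        identifier=identifier,
        pb_string=pb_string,
        sa_string=sa_classes_to_string(sa_cls),
    )


def random_profile(length: int, seed: int, identifier: str = "rand") -> HybridProfile:
    """A random but valid hybrid profile (Dirichlet columns); for DP testing."""
    rng = np.random.default_rng(seed)
    aa = rng.dirichlet(np.ones(20), size=length)
    pb = rng.dirichlet(np.ones(16), size=length)
    sa = rng.dirichlet(np.ones(10), size=length)
    gap = rng.uniform(0.0, 0.5, size=length)
    seq = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
    hp = HybridProfile(
        identifier=identifier, sequence=seq, aa=aa, gap=gap, pb=pb, sa=sa
    )
    hp.validate()
    return hp
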