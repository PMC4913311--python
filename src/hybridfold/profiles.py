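"""Position-specific probability profiles and the hybrid profile container.

A hybrid profile concatenates, per query position, three probability
columns: 20 amino-acid probabilities plus a gap probability (from the
multiple sequence alignment of homologs), 16 Protein Block probabilities,
and 10 solvent-accessibility class probabilities.  For templates the PB and
SA columns come from the 3D coordinates; for queries they come from an
external predictor or, in synthetic settings, from a known structure.

Amino-acid profiles use position-based Henikoff sequence weighting and
BLOSUM62 conditional-probability pseudocounts mixed by an admixture
parameter beta:  p' = (N_eff * f_obs + beta * f_pc) / (N_eff + beta), with
N_eff the inverse-Simpson effective sequence count of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AA_ALPHABET",
    "AA_BACKGROUND",
    "PB_BACKGROUND",
    "AAProfile",
    "PBProfile",
    "SAProfile",
    "HybridProfile",
    "read_alignment_fasta",
    "henikoff_weights",
    "build_aa_profile",
    "build_pb_profile_from_structures",
    "build_sa_profile_from_structures",
    "concat_hybrid",
    "write_profile",
    "read_profile",
    "sa_classes_to_string",
    "sa_string_to_classes",
]

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
GAP_CHARS = {"-", "."}
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

# Robinson & Robinson amino-acid background frequencies (renormalised).
_AA_BG = {
    "A": 0.078047, "R": 0.051269, "N": 0.044873, "D": 0.053640, "C": 0.019246,
    "Q": 0.042644, "E": 0.062949, "G": 0.073772, "H": 0.021992, "I": 0.051420,
    "L": 0.090191, "K": 0.057438, "M": 0.022425, "F": 0.038556, "P": 0.052028,
    "S": 0.071198, "T": 0.058413, "W": 0.013298, "Y": 0.032165, "V": 0.064409,
}
AA_BACKGROUND = np.array([_AA_BG[a] for a in AA_ALPHABET])
AA_BACKGROUND = AA_BACKGROUND / AA_BACKGROUND.sum()

# Observed Protein Block frequencies in a representative non-redundant
# structure set (core helix m and core strand d dominate).
_PB_BG = {
    "a": 0.0388, "b": 0.0446, "c": 0.0810, "d": 0.1885, "e": 0.0248,
    "f": 0.0669, "g": 0.0115, "h": 0.0240, "i": 0.0186, "j": 0.0083,
    "k": 0.0572, "l": 0.0549, "m": 0.3188, "n": 0.0199, "o": 0.0278,
    "p": 0.0199,
}
PB_BACKGROUND = np.array([_PB_BG[c] for c in "abcdefghijklmnop"])
PB_BACKGROUND = PB_BACKGROUND / PB_BACKGROUND.sum()

ORP_VERSION = 1
_N_COLS = 2 + 20 + 1 + 16 + 10  # pos, residue, AA, gap, PB, SA


def _blosum62_conditional() -> np.ndarray:
    """P(a | b) reconstructed from BLOSUM62 half-bit scores and background.

    The joint target distribution is recovered as
    q(a,b) ∝ f(a) f(b) 2^(S(a,b)/2) and renormalised; rows of the
    conditional matrix sum to one.
    """
    mat = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    joint = np.zeros((n, n))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            joint[i, j] = AA_BACKGROUND[i] * AA_BACKGROUND[j] * 2.0 ** (mat[a][b] / 2.0)
    joint /= joint.sum()
    marginal = joint.sum(axis=0)
    return joint / marginal[None, :]  # column b: P(a|b)


_B62_COND = _blosum62_conditional()


@dataclass
class AAProfile:
    probs: np.ndarray  # (L, 20), rows sum to 1
    gap: np.ndarray  # (L,), in [0, 1]
    sequence: str

    def __post_init__(self):
        if self.probs.shape != (len(self.sequence), 20) or self.gap.shape != (len(self.sequence),):
            raise ValueError("AA profile shape mismatch with master sequence")

    def __len__(self):
        return len(self.sequence)


@dataclass
class PBProfile:
    probs: np.ndarray  # (L, 16)

    def __len__(self):
        return self.probs.shape[0]


@dataclass
class SAProfile:
    probs: np.ndarray  # (L, 10)

    def __len__(self):
        return self.probs.shape[0]


@dataclass
class HybridProfile:
    """Concatenated AA(20)+gap / PB(16) / SA(10) probability profile."""

    identifier: str
    sequence: str
    aa: np.ndarray  # (L, 20)
    gap: np.ndarray  # (L,)
    pb: np.ndarray  # (L, 16)
    sa: np.ndarray  # (L, 10)
    description: str = ""
    pb_string: str | None = None  # per-position PB letters, if known
    sa_string: str | None = None  # per-position SA classes, encoded
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.sequence)

    def validate(self) -> None:
        L = len(self.sequence)
        if L == 0:
            raise ValueError("empty profile")
        for name, arr, width in (("aa", self.aa, 20), ("pb", self.pb, 16), ("sa", self.sa, 10)):
            if arr.shape != (L, width):
                raise ValueError(f"{name} profile shape {arr.shape} != ({L}, {width})")
            if (arr < -1e-12).any():
                raise ValueError(f"negative probability in {name} profile")
            if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} profile rows must sum to 1")
        if self.gap.shape != (L,) or (self.gap < -1e-12).any() or (self.gap > 1 + 1e-12).any():
            raise ValueError("gap probabilities must lie in [0, 1]")


def read_alignment_fasta(path) -> tuple[list[str], list[str]]:
    """Read an aligned FASTA file; returns (ids, rows). Rows must be equal length."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise ValueError(f"no sequences in {path}")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    return ids, rows


def henikoff_weights(rows: list[str]) -> np.ndarray:
    """Position-based Henikoff sequence weights, normalised to sum 1.

    Per column with r distinct residue types, a sequence showing a type seen
    s times gets 1/(r*s); gap positions contribute nothing; all-gap columns
    are skipped.
    """
    if not rows:
        raise ValueError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    n = len(rows)
    raw = np.zeros(n)
    for col in zip(*[r.upper() for r in rows]):
        symbols = [c for c in col if c not in GAP_CHARS]
        if not symbols:
            continue
        counts: dict[str, int] = {}
        for c in symbols:
            counts[c] = counts.get(c, 0) + 1
        r = len(counts)
        for k, c in enumerate(col):
            if c not in GAP_CHARS:
                raw[k] += 1.0 / (r * counts[c])
    if raw.sum() == 0:
        raw[:] = 1.0
    return raw / raw.sum()


def build_aa_profile(
    rows: list[str],
    master_index: int = 0,
    pseudocount_beta: float = 10.0,
    weights: np.ndarray | None = None,
) -> AAProfile:
    """Amino-acid profile (20 probabilities + gap frequency) in master coordinates.

    Columns where the master row is gapped are dropped, so profile length
    equals the ungapped master length.  Residue frequencies are Henikoff
    weighted; 'X' (and any unknown letter) contributes the background
    distribution; the gap probability is the weighted fraction of gap
    symbols, stored beside the renormalised amino-acid simplex.
    """
    if not rows:
        raise ValueError("empty alignment")
    if not 0 <= master_index < len(rows):
        raise ValueError("master index out of range")
    rows = [r.upper() for r in rows]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    if weights is None:
        weights = henikoff_weights(rows)
    w = np.asarray(weights, dtype=float)
    n_eff = 1.0 / float((w**2).sum())

    master = rows[master_index]
    keep = [j for j, c in enumerate(master) if c not in GAP_CHARS]
    L = len(keep)
    probs = np.zeros((L, 20))
    gap = np.zeros(L)
    for out_i, j in enumerate(keep):
        counts = np.zeros(20)
        gap_w = 0.0
        total_w = 0.0
        for k, row in enumerate(rows):
            c = row[j]
            total_w += w[k]
            if c in GAP_CHARS:
                gap_w += w[k]
            elif c in _AA_INDEX:
                counts[_AA_INDEX[c]] += w[k]
            else:  # X / unknown: background evidence
                counts += w[k] * AA_BACKGROUND
        gap[out_i] = gap_w / total_w if total_w else 0.0
        if counts.sum() == 0:
            f_obs = AA_BACKGROUND.copy()
        else:
            f_obs = counts / counts.sum()
        if pseudocount_beta > 0:
            f_pc = _B62_COND @ f_obs
            p = (n_eff * f_obs + pseudocount_beta * f_pc) / (n_eff + pseudocount_beta)
        else:
            p = f_obs
        probs[out_i] = p / p.sum()
    sequence = "".join(master[j] for j in keep)
    return AAProfile(probs=probs, gap=gap, sequence=sequence)


def _categorical_profile(
    member_strings: list[str],
    rows: list[str] | None,
    master_index: int,
    alphabet: str,
    undefined: set[str],
    epsilon: float,
) -> np.ndarray:
    """Shared frequency-profile builder for categorical (PB / SA) tracks.

    ``member_strings`` are per-structure annotation strings in residue
    coordinates; ``rows`` the family alignment mapping them to columns
    (``None`` for ungapped members of equal length).  Columns gapped in the
    master are dropped; add-eps/|alphabet| smoothing; columns with no
    defined evidence are uniform.
    """
    n_sym = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    if rows is None:
        rows = member_strings
        aligned = member_strings
    else:
        if len(rows) != len(member_strings):
            raise ValueError("alignment rows and member strings differ in count")
        aligned = []
        for row, s in zip(rows, member_strings):
            if len(s) != sum(c not in GAP_CHARS for c in row):
                raise ValueError("member string length does not match its alignment row")
            it = iter(s)
            aligned.append("".join("-" if c in GAP_CHARS else next(it) for c in row))
    if len({len(a) for a in aligned}) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    master = rows[master_index]
    keep = [j for j, c in enumerate(master) if c not in GAP_CHARS]
    out = np.zeros((len(keep), n_sym))
    for out_i, j in enumerate(keep):
        counts = np.zeros(n_sym)
        for a in aligned:
            c = a[j]
            if c == "-" or c in undefined:
                continue
            if c not in idx:
                raise ValueError(f"symbol {c!r} outside alphabet")
            counts[idx[c]] += 1.0
        if counts.sum() == 0:
            out[out_i] = 1.0 / n_sym
        else:
            p = counts / counts.sum()
            out[out_i] = (1.0 - epsilon) * p + epsilon / n_sym
    return out


def build_pb_profile_from_structures(
    pb_strings: list[str],
    rows: list[str] | None = None,
    master_index: int = 0,
    epsilon: float = 0.05,
) -> PBProfile:
    """PB frequency profile over family members, with add-1/16 smoothing weight eps."""
    probs = _categorical_profile(pb_strings, rows, master_index, "abcdefghijklmnop", {"Z"}, epsilon)
    return PBProfile(probs=probs)


def sa_classes_to_string(classes: list[int]) -> str:
    """Encode SA classes 1..10 as characters '1'..'9', '0' for class 10."""
    return "".join("-" if c is None else str(c % 10) for c in classes)


def sa_string_to_classes(s: str) -> list[int | None]:
    return [None if c == "-" else (10 if c == "0" else int(c)) for c in s]


def build_sa_profile_from_structures(
    sa_class_lists: list[list[int]],
    rows: list[str] | None = None,
    master_index: int = 0,
    epsilon: float = 0.05,
) -> SAProfile:
    """SA-class frequency profile over family members (10 classes, uniform fallback)."""
    strings = [sa_classes_to_string(cl) for cl in sa_class_lists]
    probs = _categorical_profile(strings, rows, master_index, "1234567890", {"-"}, epsilon)
    return SAProfile(probs=probs)


def concat_hybrid(
    aa: AAProfile,
    pb: PBProfile,
    sa: SAProfile,
    identifier: str = "query",
    description: str = "",
    pb_string: str | None = None,
    sa_string: str | None = None,
) -> HybridProfile:
    """Bundle AA, PB and SA profiles of identical length into a hybrid profile."""
    if len(aa) == 0 or len(pb) == 0 or len(sa) == 0:
        raise ValueError("empty profile")
    for name, comp in (("PB", pb), ("SA", sa)):
        if len(comp) != len(aa):
            raise ValueError(f"{name} profile length {len(comp)} != AA profile length {len(aa)}")
    hp = HybridProfile(
        identifier=identifier,
        sequence=aa.sequence,
        aa=aa.probs,
        gap=aa.gap,
        pb=pb.probs,
        sa=sa.probs,
        description=description,
        pb_string=pb_string,
        sa_string=sa_string,
    )
    hp.validate()
    return hp


def _fmt(x: float) -> str:
    return repr(float(x))


def write_profile(profile: HybridProfile, path) -> None:
    """Write the tab-delimited `.orp` text format (lossless float round trip)."""
    profile.validate()
    with open(path, "w") as fh:
        fh.write(format_profile(profile))


def format_profile(profile: HybridProfile) -> str:
    lines = [f"#ORP {ORP_VERSION}"]
    lines.append(f"#ID {profile.identifier}")
    if profile.description:
        lines.append(f"#DE {profile.description}")
    lines.append(f"#SQ {profile.sequence}")
    if profile.pb_string:
        lines.append(f"#PB {profile.pb_string}")
    if profile.sa_string:
        lines.append(f"#SA {profile.sa_string}")
    header = (
        ["pos", "res"]
        + list(AA_ALPHABET)
        + ["gap"]
        + [f"pb_{c}" for c in "abcdefghijklmnop"]
        + [f"sa_{k}" for k in range(1, 11)]
    )
    lines.append("#COLUMNS " + "\t".join(header))
    for i in range(len(profile)):
        row = [str(i + 1), profile.sequence[i]]
        row += [_fmt(x) for x in profile.aa[i]]
        row.append(_fmt(profile.gap[i]))
        row += [_fmt(x) for x in profile.pb[i]]
        row += [_fmt(x) for x in profile.sa[i]]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def read_profile(path) -> HybridProfile:
    with open(path) as fh:
        return parse_profile(fh.read(), source=str(path))


def parse_profile(text: str, source: str = "<string>") -> HybridProfile:
    """Parse the `.orp` text format; errors carry the offending line number."""
    identifier, description, sequence = "", "", ""
    pb_string = sa_string = None
    data_rows: list[list[str]] = []
    version_seen = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#ORP"):
            version = line.split()[1] if len(line.split()) > 1 else "?"
            if version != str(ORP_VERSION):
                raise ValueError(f"{source}: unsupported version {version!r}")
            version_seen = True
        elif line.startswith("#ID"):
            identifier = line[3:].strip()
        elif line.startswith("#DE"):
            description = line[3:].strip()
        elif line.startswith("#SQ"):
            sequence = line[3:].strip()
        elif line.startswith("#PB"):
            pb_string = line[3:].strip()
        elif line.startswith("#SA"):
            sa_string = line[3:].strip()
        elif line.startswith("#"):
            continue
        else:
            parts = line.split("\t")
            if len(parts) != _N_COLS:
                raise ValueError(
                    f"{source}:{lineno}: expected {_N_COLS} columns, got {len(parts)}"
                )
            data_rows.append(parts)
    if not version_seen:
        raise ValueError(f"{source}: missing #ORP version header")
    if not data_rows:
        raise ValueError(f"{source}: empty profile")
    L = len(data_rows)
    aa = np.zeros((L, 20))
    gap = np.zeros(L)
    pb = np.zeros((L, 16))
    sa = np.zeros((L, 10))
    seq_chars = []
    for i, parts in enumerate(data_rows):
        seq_chars.append(parts[1])
        vals = [float(x) for x in parts[2:]]
        aa[i] = vals[0:20]
        gap[i] = vals[20]
        pb[i] = vals[21:37]
        sa[i] = vals[37:47]
    seq = "".join(seq_chars)
    if sequence and sequence != seq:
        raise ValueError(f"{source}: #SQ header disagrees with data rows")
    hp = HybridProfile(
        identifier=identifier or "profile",
        sequence=seq,
        aa=aa,
        gap=gap,
        pb=pb,
        sa=sa,
        description=description,
        pb_string=pb_string,
        sa_string=sa_string,
    )
    hp.validate()
    return hp
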