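"""Template databanks: build from structures, search, render and export hits.

A databank is a directory holding one concatenated `.orp` stream of template
hybrid profiles plus a tab-separated index (identifier, byte offset, record
length, profile length, description), so records can be inspected with a
pager and streamed without loading everything.

Templates are built per family: Protein Blocks and solvent-accessibility
classes are computed from each member structure, the amino-acid profile from
the family alignment (a single-member family degenerates to a one-hot
profile plus pseudocounts), and all profiles are laid out on the columns of
the family master.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import accessibility, pb_alphabet
from .aligner import AlignmentResult, ScoringParams, align, column_score_matrix
from .pb_alphabet import pb_string_to_ss
from .profiles import (
    GAP_CHARS,
    HybridProfile,
    build_aa_profile,
    build_pb_profile_from_structures,
    build_sa_profile_from_structures,
    concat_hybrid,
    format_profile,
    parse_profile,
    sa_classes_to_string,
)
from .structure import StructureChain, read_pdb_chain

__all__ = [
    "FamilySpec",
    "TemplateRecord",
    "TemplateDatabank",
    "Hit",
    "build_databank",
    "search",
    "render_alignment",
    "write_hit_table",
    "HIT_COLUMNS",
    "QUERY_MIN_LEN",
    "QUERY_MAX_LEN",
]

logger = logging.getLogger(__name__)

QUERY_MIN_LEN = 15
QUERY_MAX_LEN = 1000

DB_PROFILE_FILE = "templates.orp"
DB_INDEX_FILE = "index.tsv"
DB_INDEX_VERSION = "HYBRIDFOLD-DB 1"

HIT_COLUMNS = [
    "rank",
    "template_id",
    "description",
    "score",
    "template_length",
    "query_start",
    "query_end",
    "template_start",
    "template_end",
    "coverage",
    "identity",
]


@dataclass
class FamilySpec:
    """One template family: member structures plus an optional alignment.

    ``members`` are (chain, label) pairs; multi-member families must supply
    ``alignment`` rows (aligned FASTA strings, same order as members) that
    are consistent with each member's structure sequence.
    """

    identifier: str
    members: list[tuple[StructureChain, str]]
    alignment: list[str] | None = None
    description: str = ""
    master_index: int = 0


@dataclass
class TemplateRecord:
    identifier: str
    description: str
    profile: HybridProfile
    sequence: str
    pb_string: str
    sa_string: str

    @property
    def length(self) -> int:
        return len(self.profile)


@dataclass
class TemplateDatabank:
    records: list[TemplateRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, identifier: str) -> TemplateRecord:
        for r in self.records:
            if r.identifier == identifier:
                return r
        raise KeyError(identifier)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index_lines = [f"#{DB_INDEX_VERSION}", "#id\toffset\tbytes\tlength\tdescription"]
        offset = 0
        with open(directory / DB_PROFILE_FILE, "w") as fh:
            for rec in self.records:
                blob = format_profile(rec.profile)
                fh.write(blob)
                index_lines.append(
                    f"{rec.identifier}\t{offset}\t{len(blob.encode())}\t"
                    f"{rec.length}\t{rec.description}"
                )
                offset += len(blob.encode())
        (directory / DB_INDEX_FILE).write_text("\n".join(index_lines) + "\n")

    @classmethod
    def read(cls, directory) -> "TemplateDatabank":
        directory = Path(directory)
        index_path = directory / DB_INDEX_FILE
        lines = index_path.read_text().splitlines()
        if not lines or lines[0] != f"#{DB_INDEX_VERSION}":
            raise ValueError(f"{index_path}: unsupported databank index version")
        records = []
        with open(directory / DB_PROFILE_FILE, "rb") as fh:
            for line in lines[1:]:
                if line.startswith("#") or not line.strip():
                    continue
                ident, offset, nbytes, _length, description = line.split("\t", 4)
                fh.seek(int(offset))
                profile = parse_profile(fh.read(int(nbytes)).decode(), source=ident)
                records.append(
                    TemplateRecord(
                        identifier=ident,
                        description=description,
                        profile=profile,
                        sequence=profile.sequence,
                        pb_string=profile.pb_string or "",
                        sa_string=profile.sa_string or "",
                    )
                )
        return cls(records=records)


@dataclass
class Hit:
    rank: int
    template_id: str
    description: str
    score: float
    template_length: int
    query_start: int
    query_end: int
    template_start: int
    template_end: int
    coverage: float
    identity: float
    alignment: AlignmentResult | None = None

    def row(self) -> list:
        return [
            self.rank,
            self.template_id,
            self.description,
            round(self.score, 4),
            self.template_length,
            self.query_start,
            self.query_end,
            self.template_start,
            self.template_end,
            round(self.coverage, 2),
            round(self.identity, 2),
        ]


def _family_strings(spec: FamilySpec):
    """Map each member to residue-coordinate sequence / PB / SA-class strings."""
    seqs, pbs, sas = [], [], []
    for chain, label in spec.members:
        seqs.append(chain.sequence)
        d = pb_alphabet.backbone_dihedrals(chain)
        pbs.append(pb_alphabet.assign_pb(d))
        sas.append(accessibility.sa_classes(chain))
        logger.debug("family %s member %s: %d residues", spec.identifier, label, len(chain))
    return seqs, pbs, sas


def build_template(spec: FamilySpec, pseudocount_beta: float = 10.0) -> TemplateRecord:
    """Build one template record from a family of structures."""
    seqs, pbs, sas = _family_strings(spec)
    rows = spec.alignment
    if rows is None:
        if len(spec.members) > 1 and len({len(s) for s in seqs}) != 1:
            raise ValueError(
                f"family {spec.identifier}: multi-member family needs an alignment"
            )
        rows = seqs
    rows = [r.upper() for r in rows]
    for (chain, label), row, seq in zip(spec.members, rows, seqs):
        ungapped = "".join(c for c in row if c not in GAP_CHARS)
        if ungapped != seq:
            raise ValueError(
                f"family {spec.identifier}: alignment row for member {label!r} "
                "does not match its structure sequence"
            )
    mi = spec.master_index
    aa = build_aa_profile(rows, master_index=mi, pseudocount_beta=pseudocount_beta)
    pb = build_pb_profile_from_structures(pbs, rows=rows, master_index=mi)
    sa = build_sa_profile_from_structures(sas, rows=rows, master_index=mi)
    master_pb = _master_annotation(pbs[mi], rows[mi])
    master_sa = _master_annotation(sa_classes_to_string(sas[mi]), rows[mi])
    profile = concat_hybrid(
        aa,
        pb,
        sa,
        identifier=spec.identifier,
        description=spec.description,
        pb_string=master_pb,
        sa_string=master_sa,
    )
    return TemplateRecord(
        identifier=spec.identifier,
        description=spec.description,
        profile=profile,
        sequence=profile.sequence,
        pb_string=master_pb,
        sa_string=master_sa,
    )


def _master_annotation(annotation: str, master_row: str) -> str:
    """The master's own annotation string (already in residue coordinates)."""
    assert len(annotation) == sum(c not in GAP_CHARS for c in master_row)
    return annotation


def build_databank(
    family_specs: list[FamilySpec],
    out_path=None,
    pseudocount_beta: float = 10.0,
) -> TemplateDatabank:
    """Build a databank of template records, optionally writing it to disk.

    Families whose structures cannot be processed are skipped with a
    warning; an empty result is an error.
    """
    records = []
    for spec in family_specs:
        try:
            records.append(build_template(spec, pseudocount_beta=pseudocount_beta))
        except (OSError, KeyError) as exc:  # unreadable structure input
            warnings.warn(f"skipping family {spec.identifier}: {exc}")
    if not records:
        raise ValueError("no usable families: databank would be empty")
    db = TemplateDatabank(records=records)
    if out_path is not None:
        db.write(out_path)
    return db


def load_family_specs(yaml_path) -> list[FamilySpec]:
    """Read a family-spec YAML: list of {id, description, members: [{pdb, chain}], alignment}."""
    import yaml as _yaml

    base = Path(yaml_path).parent
    with open(yaml_path) as fh:
        data = _yaml.safe_load(fh)
    specs = []
    for fam in data["families"]:
        members = []
        for mem in fam["members"]:
            chain = read_pdb_chain(base / mem["pdb"], mem.get("chain"))
            members.append((chain, mem["pdb"]))
        alignment = None
        if fam.get("alignment"):
            from .profiles import read_alignment_fasta

            _, alignment = read_alignment_fasta(base / fam["alignment"])
        specs.append(
            FamilySpec(
                identifier=fam["id"],
                members=members,
                alignment=alignment,
                description=fam.get("description", ""),
            )
        )
    return specs


def search(
    query: HybridProfile,
    db: TemplateDatabank,
    params: ScoringParams | None = None,
    max_hits: int = 100,
) -> list[Hit]:
    """Align the query against every template; return the top hits.

    Hits are ranked by descending total score, ties broken by template
    identifier, so results do not depend on databank record order.
    """
    if params is None:
        params = ScoringParams()
    if len(db) == 0:
        raise ValueError("empty databank")
    if max_hits < 1:
        raise ValueError("max_hits must be >= 1")
    L = len(query)
    if not QUERY_MIN_LEN <= L <= QUERY_MAX_LEN:
        warnings.warn(
            f"query length {L} outside the supported range "
            f"[{QUERY_MIN_LEN}, {QUERY_MAX_LEN}]; results may be unreliable"
        )
    scored = []
    for rec in db:
        aln = align(query, rec.profile, params)
        logger.debug("searched %s: total %.3f", rec.identifier, aln.score_total)
        scored.append((aln.score_total, rec, aln))
    scored.sort(key=lambda x: (-x[0], x[1].identifier))
    hits = []
    for rank, (score, rec, aln) in enumerate(scored[:max_hits], start=1):
        hits.append(
            Hit(
                rank=rank,
                template_id=rec.identifier,
                description=rec.description,
                score=score,
                template_length=rec.length,
                query_start=aln.query_start,
                query_end=aln.query_end,
                template_start=aln.template_start,
                template_end=aln.template_end,
                coverage=aln.coverage,
                identity=aln.identity,
                alignment=aln,
            )
        )
    return hits


def render_alignment(
    hit: Hit,
    query: HybridProfile,
    record: TemplateRecord,
    params: ScoringParams | None = None,
    width: int = 60,
) -> str:
    """Plain-text alignment block with PB and secondary-structure tracks.

    Tracks per block: query SS, query PB, query sequence (1-based numbers),
    match line ('|' identity, '+' positive column score), template sequence,
    template PB, template SS.  The query PB track is the supplied prediction
    when present, else the argmax of the query's PB profile.
    """
    if params is None:
        params = ScoringParams()
    aln = hit.alignment
    if aln is None:
        raise ValueError("hit carries no alignment")
    S = column_score_matrix(query, record.profile, params)
    qpb_full = query.pb_string or "".join(
        "abcdefghijklmnop"[k] for k in query.pb.argmax(axis=1)
    )
    tpb_full = record.pb_string or "".join(
        "abcdefghijklmnop"[k] for k in record.profile.pb.argmax(axis=1)
    )

    qss_row, qpb_row, qseq_row, match_row, tseq_row, tpb_row, tss_row = ([] for _ in range(7))
    for qi, tj in aln.columns:
        qc = query.sequence[qi] if qi is not None else "-"
        tc = record.sequence[tj] if tj is not None else "-"
        qpb = qpb_full[qi] if qi is not None else "-"
        tpb = tpb_full[tj] if tj is not None else "-"
        qseq_row.append(qc)
        tseq_row.append(tc)
        qpb_row.append(qpb)
        tpb_row.append(tpb)
        qss_row.append(pb_string_to_ss(qpb)[0] if qpb != "-" else "-")
        tss_row.append(pb_string_to_ss(tpb)[0] if tpb != "-" else "-")
        if qi is None or tj is None:
            match_row.append(" ")
        elif qc == tc:
            match_row.append("|")
        elif S[qi, tj] > 0:
            match_row.append("+")
        else:
            match_row.append(" ")

    lines = [
        f"# {query.identifier} vs {record.identifier}  mode={aln.mode} "
        f"score={hit.score:.3f} identity={hit.identity:.1f}% coverage={hit.coverage:.1f}%"
    ]
    L = len(aln.columns)
    qpos = aln.query_start
    tpos = aln.template_start
    for start in range(0, L, width):
        end = min(start + width, L)
        q_in_block = sum(1 for qi, _ in aln.columns[start:end] if qi is not None)
        t_in_block = sum(1 for _, tj in aln.columns[start:end] if tj is not None)
        lines.append(f"q_ss   {''.join(qss_row[start:end])}")
        lines.append(f"q_pb   {''.join(qpb_row[start:end])}")
        lines.append(f"query  {''.join(qseq_row[start:end])}  {qpos}-{qpos + max(q_in_block - 1, 0)}")
        lines.append(f"       {''.join(match_row[start:end])}")
        lines.append(f"templ  {''.join(tseq_row[start:end])}  {tpos}-{tpos + max(t_in_block - 1, 0)}")
        lines.append(f"t_pb   {''.join(tpb_row[start:end])}")
        lines.append(f"t_ss   {''.join(tss_row[start:end])}")
        lines.append("")
        qpos += q_in_block
        tpos += t_in_block
    return "\n".join(lines)


def write_hit_table(hits: list[Hit], path, fmt: str = "tsv") -> None:
    """Write the ranked hit table as TSV or JSON with a stable column order."""
    path = Path(path)
    if fmt == "tsv":
        lines = ["\t".join(HIT_COLUMNS)]
        for h in hits:
            lines.append("\t".join(str(x) for x in h.row()))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = [dict(zip(HIT_COLUMNS, h.row())) for h in hits]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise ValueError(f"unknown hit-table format {fmt!r}")


def read_hit_table(path) -> list[dict]:
    """Parse a TSV hit table back into dictionaries (numbers converted)."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        vals = line.split("\t")
        row = dict(zip(header, vals))
        for k in ("rank", "template_length", "query_start", "query_end", "template_start", "template_end"):
            row[k] = int(row[k])
        for k in ("score", "coverage", "identity"):
            row[k] = float(row[k])
        out.append(row)
    return out
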