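"""Sequence preprocessing for candidate imine-reductase (IRED) panels.

Candidate sequences are matched against a library of characterized-IRED
template sequences; only candidates whose closest template is a
characterized IRED are treated as putative IREDs and carried forward to
structure modeling. The module also implements the database-collection
filters (identity/coverage/E-value), exact deduplication plus greedy
identity clustering, and construction of the doubled (homodimer)
alignment used to model the dimeric IRED fold, whose active site sits
at the monomer interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "SequenceRecord",
    "TemplateHit",
    "HomologyHitRecord",
    "HomologyFilterConfig",
    "PairwiseAlignment",
    "CHARACTERIZED_IRED_TEMPLATES",
    "read_fasta",
    "write_fasta",
    "pairwise_identity",
    "align_pair",
    "assign_template",
    "filter_putative_ireds",
    "apply_homology_filters",
    "read_homology_hits",
    "dedupe_and_cluster",
    "build_dimer_alignment",
    "write_pir",
]

#: PDB codes of the characterized IRED structures accepted as templates.
CHARACTERIZED_IRED_TEMPLATES = frozenset(
    {
        "3ZGY", "4D3D", "4D3S", "4OQY", "4OQZ", "5A9T", "5OCM",
        "5OJL", "6EOD", "6JIT", "6JIZ", "6GRL", "5G6R",
    }
)

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

Denominator = Literal["alignment_columns", "shorter_sequence"]


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (uppercase one-letter code)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residue letters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class TemplateHit:
    """Best-matching template for a query sequence."""

    query_id: str
    template_id: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be a fraction in [0, 1]")


@dataclass(frozen=True)
class HomologyHitRecord:
    """One row of a homology-search result table."""

    query_id: str
    subject_id: str
    identity: float
    coverage: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must be in [0, 1]")
        if self.e_value < 0:
            raise ValueError("e_value must be nonnegative")


@dataclass(frozen=True)
class HomologyFilterConfig:
    """Thresholds for collecting homologs of seed sequences.

    The comparisons are strict ("over 30%", "over 80%", "under 10").
    """

    min_identity: float = 0.30
    min_coverage: float = 0.80
    max_e_value: float = 10.0
    cluster_threshold: float = 0.7

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "cluster_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of a query against a template."""

    query_row: str
    template_row: str
    identity: float

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.template_row):
            raise ValueError("alignment rows must have equal length")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read sequences from a FASTA file, preserving order.

    Residues are uppercased and whitespace-stripped. Duplicate ids or
    empty sequences raise a ``ValueError`` naming the offender.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if not rid:
            raise ValueError(f"{path}: FASTA record with empty header")
        if rid in seen:
            raise ValueError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        residues = "".join(str(rec.seq).split()).upper()
        if not residues:
            raise ValueError(f"{path}: sequence {rid!r} is empty")
        records.append(SequenceRecord(id=rid, residues=residues))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    *,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: Denominator = "alignment_columns",
) -> PairwiseAlignment:
    """Globally align two sequences (BLOSUM62, affine gaps).

    Identity is the number of identical aligned columns divided by the
    chosen denominator: all alignment columns (including gap columns) or
    the length of the shorter input sequence.
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x != "-"
    )
    if denominator == "alignment_columns":
        denom = len(row_a)
    elif denominator == "shorter_sequence":
        denom = min(len(a.residues), len(b.residues))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return PairwiseAlignment(
        query_row=row_a, template_row=row_b, identity=matches / denom
    )


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    denominator: Denominator = "alignment_columns",
    **kwargs,
) -> float:
    """Fractional sequence identity from a global alignment."""
    return align_pair(a, b, denominator=denominator, **kwargs).identity


def assign_template(
    query: SequenceRecord, templates: Sequence[SequenceRecord]
) -> TemplateHit:
    """Assign the template with the highest sequence identity.

    Ties are broken by lexicographic template id so the assignment is
    deterministic.
    """
    if not templates:
        raise ValueError("template library is empty")
    best: TemplateHit | None = None
    for tmpl in templates:
        ident = pairwise_identity(query, tmpl)
        if (
            best is None
            or ident > best.identity
            or (ident == best.identity and tmpl.id < best.template_id)
        ):
            best = TemplateHit(
                query_id=query.id, template_id=tmpl.id, identity=ident
            )
    assert best is not None
    return best


def filter_putative_ireds(
    queries: Sequence[SequenceRecord],
    templates: Sequence[SequenceRecord],
    ired_ids: frozenset[str] | set[str] = CHARACTERIZED_IRED_TEMPLATES,
) -> list[SequenceRecord]:
    """Keep queries whose best template is a characterized IRED.

    Order is preserved; a query whose closest template falls outside
    ``ired_ids`` is considered a non-IRED homolog and dropped.
    """
    template_ids = {t.id for t in templates}
    unknown = set(ired_ids) - template_ids
    if unknown:
        raise ValueError(
            f"ired_ids not present in template library: {sorted(unknown)}"
        )
    kept = []
    for q in queries:
        hit = assign_template(q, templates)
        if hit.template_id in ired_ids:
            kept.append(q)
    return kept


def apply_homology_filters(
    hits: Iterable[HomologyHitRecord],
    cfg: HomologyFilterConfig = HomologyFilterConfig(),
) -> list[HomologyHitRecord]:
    """Keep hits with identity and coverage strictly over, and E-value
    strictly under, the configured thresholds."""
    return [
        h
        for h in hits
        if h.identity > cfg.min_identity
        and h.coverage > cfg.min_coverage
        and h.e_value < cfg.max_e_value
    ]


def read_homology_hits(path: str | Path) -> list[HomologyHitRecord]:
    """Read a homology-hit table (CSV with header
    query_id,subject_id,identity,coverage,e_value)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"query_id", "subject_id", "identity", "coverage", "e_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        HomologyHitRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            identity=float(r.identity),
            coverage=float(r.coverage),
            e_value=float(r.e_value),
        )
        for r in df.itertuples()
    ]


def dedupe_and_cluster(
    seqs: Sequence[SequenceRecord], threshold: float = 0.7
) -> list[SequenceRecord]:
    """Remove exact duplicates, then cluster greedily (longest first).

    A sequence joins the first existing cluster whose representative has
    identity >= threshold (identity over the shorter sequence, the
    convention of cd-hit-style tools); otherwise it founds a new
    cluster. Representatives are returned in founding order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    seen_residues: set[str] = set()
    unique: list[SequenceRecord] = []
    for s in seqs:
        if s.residues not in seen_residues:
            seen_residues.add(s.residues)
            unique.append(s)
    # longest-first; stable for equal lengths
    ordered = sorted(
        range(len(unique)), key=lambda i: (-len(unique[i]), i)
    )
    representatives: list[SequenceRecord] = []
    for i in ordered:
        s = unique[i]
        for rep in representatives:
            if (
                pairwise_identity(s, rep, denominator="shorter_sequence")
                >= threshold
            ):
                break
        else:
            representatives.append(s)
    return representatives


def build_dimer_alignment(
    aln: PairwiseAlignment, chain_break: str = "/"
) -> PairwiseAlignment:
    """Double a single-chain alignment into a homodimer alignment.

    Each row becomes ``row + chain_break + row``, giving both chains of
    the dimeric IRED the same aligned sequence.
    """
    if not aln.query_row or not aln.template_row:
        raise ValueError("cannot double an empty alignment")
    return PairwiseAlignment(
        query_row=aln.query_row + chain_break + aln.query_row,
        template_row=aln.template_row + chain_break + aln.template_row,
        identity=aln.identity,
    )


def write_pir(
    aln: PairwiseAlignment,
    query_id: str,
    template_id: str,
    path: str | Path,
) -> None:
    """Write a (possibly doubled) alignment in PIR-style text."""
    with open(path, "w") as fh:
        for code, name, row in (
            ("P1", query_id, aln.query_row),
            ("P1", template_id, aln.template_row),
        ):
            fh.write(f">{code};{name}\n")
            fh.write(f"sequence:{name}::::::::\n")
            for i in range(0, len(row), 75):
                fh.write(row[i : i + 75] + "\n")
            fh.write("*\n")
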