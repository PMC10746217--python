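"""Readers and writers for annotation bundles, plus the genome QC filter.

Formats handled: GFF3 gene coordinates, protein FASTA, 12-column tabular
homology hits (BLAST ``outfmt 6`` dialect), per-domain tabular HMMER
hits (``domtblout`` dialect), a genome-metadata TSV, and the four-state
presence/absence matrix TSV.

All readers validate rather than coerce: out-of-range percentages,
inverted coordinates, or negative scores are rejected with the offending
line or row number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "PRESENT",
    "ABSENT",
    "PSEUDOGENE",
    "PARTIAL",
    "GenomeMeta",
    "GeneCall",
    "HomologyHit",
    "DomainHit",
    "AnnotationParseError",
    "read_gff",
    "read_fasta",
    "read_tabular_hits",
    "read_domain_hits",
    "read_metadata",
    "write_metadata",
    "qc_filter",
    "write_presence_matrix",
    "read_presence_matrix",
]

# Gene-call / matrix-cell states.  PARTIAL means a coding sequence
# truncated by a contig edge (likely intact in the underlying genome),
# distinct from a PSEUDOGENE (disrupted coding sequence).
PRESENT = "present"
ABSENT = "absent"
PSEUDOGENE = "pseudogene"
PARTIAL = "partial"

_CELL_CHAR = {PRESENT: "1", ABSENT: "0", PSEUDOGENE: "P", PARTIAL: "H"}
_CHAR_CELL = {v: k for k, v in _CELL_CHAR.items()}

ASSEMBLY_LEVELS = ("complete", "draft", "MAG")
ECOLOGIES = ("sea", "terrestrial_water", "soil", "host_associated", "other")


class AnnotationParseError(ValueError):
    """Malformed input; message carries the file position when known."""


@dataclass(frozen=True)
class GenomeMeta:
    """Per-genome metadata row (taxonomy, ecology, assembly QC, GC%)."""

    genome_id: str
    species: str = ""
    tax_class: str = ""
    ecology: str = "other"
    assembly_level: str = "complete"
    completeness: float = 100.0
    contamination: float = 0.0
    genome_gc: float = 50.0
    genome_size: int = 1
    zoospore_former: bool = False

    def __post_init__(self):
        for name in ("completeness", "contamination", "genome_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise AnnotationParseError(
                    f"{self.genome_id}: {name}={v} outside [0, 100]"
                )
        if self.genome_size <= 0:
            raise AnnotationParseError(f"{self.genome_id}: genome_size <= 0")
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise AnnotationParseError(
                f"{self.genome_id}: unknown assembly_level "
                f"{self.assembly_level!r} (expected one of {ASSEMBLY_LEVELS})"
            )


@dataclass(frozen=True)
class GeneCall:
    """A located, labeled gene with 1-based inclusive coordinates."""

    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    label: str = "unassigned"
    status: str = PRESENT

    def __post_init__(self):
        if self.start > self.end:
            raise AnnotationParseError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationParseError(
                f"{self.locus_tag}: strand must be '+' or '-'"
            )
        if self.status not in (PRESENT, PSEUDOGENE, PARTIAL):
            raise AnnotationParseError(
                f"{self.locus_tag}: unknown status {self.status!r}"
            )

    def with_label(self, label: str) -> "GeneCall":
        return replace(self, label=label)


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular homology search result."""

    query_symbol: str
    subject_locus: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_coverage: float | None = None

    def __post_init__(self):
        if self.evalue < 0:
            raise AnnotationParseError(f"negative E-value {self.evalue}")
        if self.bitscore < 0:
            raise AnnotationParseError(f"negative bitscore {self.bitscore}")
        if self.query_coverage is not None and not 0 <= self.query_coverage <= 1:
            raise AnnotationParseError(
                f"query_coverage {self.query_coverage} outside [0, 1]"
            )


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit (e.g. GGDEF, CheW, MCP_signal) on a protein."""

    protein_locus: str
    domain_name: str
    env_start: int
    env_end: int
    score: float

    def __post_init__(self):
        if self.env_start > self.env_end:
            raise AnnotationParseError(
                f"{self.protein_locus}/{self.domain_name}: "
                f"env_start {self.env_start} > env_end {self.env_end}"
            )

    @property
    def length(self) -> int:
        return self.env_end - self.env_start + 1


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes"}


def read_gff(
    path: str,
    genome_id: str | None = None,
    edge_margin: int = 20,
) -> list[GeneCall]:
    """Parse a GFF3 file into unlabeled :class:`GeneCall` skeletons.

    Recognized feature types are ``CDS`` and ``pseudogene``; other types
    are skipped (a count is logged).  A feature is marked

    * ``pseudogene`` if its type is ``pseudogene`` or it carries a
      truthy ``pseudo`` attribute;
    * ``partial`` if it carries a truthy ``partial`` attribute *and*
      lies within ``edge_margin`` bp of a contig edge (contig lengths
      are taken from ``##sequence-region`` directives; without one the
      flag is trusted as written).

    A ``partial`` flag away from any contig edge is demoted to
    ``present``, since an interior truncation cannot be blamed on the
    assembly.
    """
    if genome_id is None:
        genome_id = path.rsplit("/", 1)[-1].split(".")[0]
    calls: list[GeneCall] = []
    contig_len: dict[str, int] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">") or line == "##FASTA":
                break  # sequence section; annotations never follow it
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_len[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationParseError(
                    f"{path}:{lineno}: malformed GFF3 line ({exc})"
                ) from exc
            if feat.featuretype not in ("CDS", "pseudogene"):
                skipped += 1
                continue
            attrs = {k.lower(): v for k, v in feat.attributes.items()}
            locus = (attrs.get("locus_tag") or attrs.get("id") or [f"line{lineno}"])[0]
            status = PRESENT
            if feat.featuretype == "pseudogene" or _attr_true(attrs, "pseudo"):
                status = PSEUDOGENE
            elif _attr_true(attrs, "partial"):
                clen = contig_len.get(feat.seqid)
                at_edge = (
                    clen is None
                    or feat.start <= edge_margin
                    or feat.end >= clen - edge_margin + 1
                )
                status = PARTIAL if at_edge else PRESENT
            calls.append(
                GeneCall(
                    genome_id=genome_id,
                    contig_id=feat.seqid,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand,
                    locus_tag=locus,
                    status=status,
                )
            )
    if skipped:
        logger.info("%s: skipped %d non-CDS features", path, skipped)
    return calls


def _attr_true(attrs: dict, key: str) -> bool:
    vals = attrs.get(key)
    return bool(vals) and str(vals[0]).lower() in _TRUE


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# Tabular homology hits (12-column outfmt-6 dialect)
# ---------------------------------------------------------------------------

_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_tabular_hits(
    path: str, query_lengths: dict[str, int] | None = None
) -> list[HomologyHit]:
    """Load a 12-column tab-separated homology hit table.

    ``query_lengths`` (symbol -> residues), when given, is used to
    compute query coverage from the aligned query span; otherwise
    coverage is left unset.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise AnnotationParseError(
            f"{path}: expected 12 tab-separated columns, found {df.shape[1]}"
        )
    df.columns = _HIT_COLUMNS
    hits = []
    for idx, row in df.iterrows():
        try:
            cov = None
            if query_lengths and row.qseqid in query_lengths:
                span = abs(int(row.qend) - int(row.qstart)) + 1
                cov = min(1.0, span / query_lengths[row.qseqid])
            hits.append(
                HomologyHit(
                    query_symbol=row.qseqid,
                    subject_locus=row.sseqid,
                    percent_identity=float(row.pident),
                    alignment_length=int(row.length),
                    evalue=float(row.evalue),
                    bitscore=float(row.bitscore),
                    query_coverage=cov,
                )
            )
        except (ValueError, AnnotationParseError) as exc:
            raise AnnotationParseError(f"{path}: row {idx + 1}: {exc}") from exc
    return hits


# ---------------------------------------------------------------------------
# Per-domain hits (domtblout dialect)
# ---------------------------------------------------------------------------


def read_domain_hits(path: str) -> list[DomainHit]:
    """Load a whitespace-separated per-domain hit table.

    Columns follow the HMMER ``--domtblout`` layout: target name in
    column 1, query (domain) name in column 4, this-domain score in
    column 14, envelope coordinates in columns 20-21.  ``#`` lines are
    comments.
    """
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 21:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected >= 21 columns, found {len(parts)}"
                )
            try:
                hits.append(
                    DomainHit(
                        protein_locus=parts[0],
                        domain_name=parts[3],
                        score=float(parts[13]),
                        env_start=int(parts[19]),
                        env_end=int(parts[20]),
                    )
                )
            except (ValueError, AnnotationParseError) as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: {exc}"
                ) from exc
    return hits


# ---------------------------------------------------------------------------
# Genome metadata + QC filter
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "genome_id", "species", "tax_class", "ecology", "assembly_level",
    "completeness", "contamination", "genome_gc", "genome_size",
    "zoospore_former",
]


def read_metadata(path: str) -> list[GenomeMeta]:
    """Read the genome-metadata TSV (documented column set)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _META_COLUMNS if c not in df.columns]
    if missing_cols:
        raise AnnotationParseError(f"{path}: missing columns {missing_cols}")
    incomplete = df[df[_META_COLUMNS].isna().any(axis=1)]
    if len(incomplete):
        ids = incomplete["genome_id"].fillna("<no id>").tolist()
        raise AnnotationParseError(
            f"{path}: rows with missing fields for genomes {ids}"
        )
    return [
        GenomeMeta(
            genome_id=row.genome_id,
            species=row.species,
            tax_class=row.tax_class,
            ecology=row.ecology,
            assembly_level=row.assembly_level,
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            genome_gc=float(row.genome_gc),
            genome_size=int(row.genome_size),
            zoospore_former=str(row.zoospore_former).lower() in _TRUE,
        )
        for row in df.itertuples()
    ]


def write_metadata(genomes: list[GenomeMeta], path: str) -> None:
    rows = [
        [
            m.genome_id, m.species, m.tax_class, m.ecology, m.assembly_level,
            m.completeness, m.contamination, m.genome_gc, m.genome_size,
            str(m.zoospore_former).lower(),
        ]
        for m in genomes
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def qc_filter(
    genomes: list[GenomeMeta], whitelist: set[str] | frozenset[str] = frozenset()
) -> tuple[list[GenomeMeta], list[GenomeMeta]]:
    """Partition genomes into (retained, removed) by assembly quality.

    A genome is removed iff completeness < 80% OR contamination > 5%,
    unless its id is whitelisted.  OR-semantics is used for the removal
    clause so that a whitelist exemption is meaningful for genomes whose
    only defect is moderate contamination (the intended use case:
    keeping a small number of flagellated species with contamination
    between 5% and 8%).  Filtering is idempotent.
    """
    retained, removed = [], []
    for m in genomes:
        bad = m.completeness < 80.0 or m.contamination > 5.0
        if bad and m.genome_id not in whitelist:
            removed.append(m)
        else:
            retained.append(m)
    return retained, removed


# ---------------------------------------------------------------------------
# Presence-matrix TSV
# ---------------------------------------------------------------------------


def write_presence_matrix(matrix, path: str) -> None:
    """Write a presence matrix as TSV with cells in {1, 0, P, H}."""
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(matrix.genes) + "\n")
        for gid in matrix.genomes:
            cells = [_CELL_CHAR[matrix.cell(gid, g)] for g in matrix.genes]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def read_presence_matrix(path: str):
    """Read a presence-matrix TSV back into a :class:`PresenceMatrix`."""
    from flagscan.flagellar import PresenceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = list(df.columns)
    cells = {}
    for gid, row in df.iterrows():
        for g in genes:
            ch = row[g]
            if ch not in _CHAR_CELL:
                raise AnnotationParseError(
                    f"{path}: invalid cell {ch!r} for {gid}/{g}"
                )
            cells[(gid, g)] = _CHAR_CELL[ch]
    return PresenceMatrix(genomes=list(df.index), genes=genes, cells=cells)
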