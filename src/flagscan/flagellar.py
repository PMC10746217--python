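"""Flagellar gene labeling and flagellated-species calling.

Stages, in pipeline order:

1. :func:`assign_labels` — turn homology hits into gene labels on
   coordinates (best hit below the E-value cutoff wins per locus);
2. :func:`disambiguate_rod_hook` — resolve the FlgE/FlgF/FlgG paralog
   group, which shares high similarity at the D0/Dc domains, using the
   conserved *flgD-flgE* and *flgF-flgG* gene order as the cue;
3. :func:`build_matrix` — collapse labeled calls into a genomes x genes
   four-state presence/absence matrix;
4. :func:`call_flagellated` — apply the assembly-level-specific core
   gene rules (24-core rule with a pseudogene allowance for complete
   and draft genomes; relaxed >= 10-of-24 rule for MAGs).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from flagscan.annotation_io import (
    ABSENT,
    PARTIAL,
    PRESENT,
    PSEUDOGENE,
    GeneCall,
    GenomeMeta,
    HomologyHit,
)
from flagscan.registry import AMBIGUOUS_EFG, EFG_SYMBOLS, Registry

__all__ = [
    "PresenceMatrix",
    "FlagellarCall",
    "ClusterSpan",
    "ClusterResult",
    "assign_labels",
    "disambiguate_rod_hook",
    "build_matrix",
    "call_flagellated",
    "count_flagellar_genes",
    "detect_major_cluster",
]


@dataclass
class PresenceMatrix:
    """Genomes x registry-genes matrix with four-state cells."""

    genomes: list[str]
    genes: list[str]
    cells: dict[tuple[str, str], str]

    def __post_init__(self):
        for gid in self.genomes:
            for g in self.genes:
                if (gid, g) not in self.cells:
                    raise ValueError(f"unset cell ({gid}, {g})")

    def cell(self, genome_id: str, gene: str) -> str:
        return self.cells[(genome_id, gene)]

    def row(self, genome_id: str) -> dict[str, str]:
        return {g: self.cells[(genome_id, g)] for g in self.genes}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PresenceMatrix)
            and self.genomes == other.genomes
            and self.genes == other.genes
            and self.cells == other.cells
        )


@dataclass(frozen=True)
class FlagellarCall:
    """Outcome of the flagellated-species rule for one genome."""

    genome_id: str
    flagellated: bool
    tier: str  # complete_rule | mag_rule
    core_present: int  # core genes counted present or partial
    core_pseudogenes: int
    rationale: str
    representative_candidate: bool = False  # MAG with >= 20 of 24 core


@dataclass(frozen=True)
class ClusterSpan:
    contig_id: str
    start: int
    end: int
    loci: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return len(self.loci)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class ClusterResult:
    major: ClusterSpan | None
    clusters: list[ClusterSpan]
    outlier_loci: list[str]
    tie: bool = False


# ---------------------------------------------------------------------------
# 1. Label assignment
# ---------------------------------------------------------------------------


def assign_labels(
    hits: list[HomologyHit],
    calls: list[GeneCall],
    evalue_max: float = 1e-5,
    registry: Registry | None = None,
) -> list[GeneCall]:
    """Assign at most one gene label per locus from homology hits.

    Hits with E-value >= ``evalue_max`` are ignored (the cutoff is the
    conventional 1e-5, applied strictly).  Among the passing hits of a
    locus the winner is the lowest E-value, ties broken by highest
    bitscore, then lexicographically smallest query symbol — a fully
    deterministic rule.  Query symbols are canonicalized through the
    registry's alias table when a registry is given (FlhO -> FlgF etc.).
    FlgE/FlgF/FlgG labels produced here are provisional: homology alone
    cannot separate the three, see :func:`disambiguate_rod_hook`.

    Raises ``ValueError`` listing orphan loci if a hit references a
    locus tag absent from ``calls``.
    """
    known = {c.locus_tag for c in calls}
    orphans = sorted({h.subject_locus for h in hits} - known)
    if orphans:
        raise ValueError(f"hits reference unknown loci: {orphans}")

    by_locus: dict[str, list[HomologyHit]] = defaultdict(list)
    for h in hits:
        if h.evalue < evalue_max:
            by_locus[h.subject_locus].append(h)

    labeled = []
    for call in calls:
        cand = by_locus.get(call.locus_tag)
        if not cand:
            labeled.append(call)
            continue
        best = min(cand, key=lambda h: (h.evalue, -h.bitscore, h.query_symbol))
        symbol = best.query_symbol
        if registry is not None:
            symbol = registry.resolve_symbol(symbol) or symbol
        labeled.append(call.with_label(symbol))
    return labeled


# ---------------------------------------------------------------------------
# 2. Rod/hook paralog disambiguation
# ---------------------------------------------------------------------------


def _runs_reverse(calls_at: list[GeneCall]) -> bool:
    """True if the majority strand is '-', i.e. transcription runs
    right-to-left in genomic coordinates."""
    minus = sum(1 for c in calls_at if c.strand == "-")
    return minus * 2 > len(calls_at)


def disambiguate_rod_hook(
    calls: list[GeneCall], max_gap: int = 3
) -> list[GeneCall]:
    """Finalize FlgE/FlgF/FlgG labels using conserved gene order.

    On each contig (genes sorted by coordinate):

    * for every FlgD call, the nearest provisional E/F/G candidate with
      at most ``max_gap`` intervening genes becomes FlgE (ties between
      up- and downstream candidates prefer the transcriptionally
      downstream one, matching the conserved *flgD-flgE* order);
    * remaining candidates that form an adjacent pair (<= ``max_gap``
      intervening genes) become FlgF (transcriptionally upstream) and
      FlgG (downstream);
    * candidates resolvable by neither cue are labeled
      ``FlgEFG_ambiguous``.

    The multiset of loci is unchanged; only labels are rewritten.
    """
    by_contig: dict[str, list[int]] = defaultdict(list)
    order = sorted(range(len(calls)), key=lambda i: (calls[i].contig_id, calls[i].start))
    final: dict[int, str] = {}

    for i in order:
        by_contig[calls[i].contig_id].append(i)

    for contig, idxs in by_contig.items():
        pos = {call_idx: p for p, call_idx in enumerate(idxs)}
        candidates = [i for i in idxs if calls[i].label in EFG_SYMBOLS]
        if not candidates:
            continue
        flgd = [i for i in idxs if calls[i].label == "FlgD"]
        unresolved = set(candidates)

        # flgD-flgE cue: one FlgE per FlgD, nearest candidate wins.
        # Ties between an up- and a downstream candidate go downstream
        # in transcriptional order, read off the FlgD strand.
        for d in flgd:
            d_reverse = calls[d].strand == "-"
            best = None
            for c in sorted(unresolved, key=lambda i: pos[i]):
                gap = abs(pos[c] - pos[d]) - 1
                if gap > max_gap:
                    continue
                downstream = (pos[c] > pos[d]) != d_reverse
                key = (gap, 0 if downstream else 1)
                if best is None or key < best[0]:
                    best = (key, c)
            if best is not None:
                final[best[1]] = "FlgE"
                unresolved.discard(best[1])

        # flgF-flgG cue: an isolated adjacent candidate pair, FlgF
        # transcriptionally upstream (per the pair's own strand).
        rest = sorted(unresolved, key=lambda i: pos[i])
        runs: list[list[int]] = []
        for c in rest:
            if runs and pos[c] - pos[runs[-1][-1]] - 1 <= max_gap:
                runs[-1].append(c)
            else:
                runs.append([c])
        for run in runs:
            if len(run) == 2:
                reverse = _runs_reverse([calls[i] for i in run])
                up, down = (run[1], run[0]) if reverse else (run[0], run[1])
                final[up] = "FlgF"
                final[down] = "FlgG"
            else:
                for c in run:
                    final[c] = AMBIGUOUS_EFG

    return [
        calls[i].with_label(final[i]) if i in final else calls[i]
        for i in range(len(calls))
    ]


# ---------------------------------------------------------------------------
# 3. Presence matrix
# ---------------------------------------------------------------------------

_STATUS_RANK = {PRESENT: 3, PSEUDOGENE: 2, PARTIAL: 1}


def build_matrix(
    calls_by_genome: dict[str, list[GeneCall]], registry: Registry
) -> PresenceMatrix:
    """Collapse labeled gene calls into the four-state presence matrix.

    Cell precedence when a genome has several calls for one gene:
    present > pseudogene > partial; no call at all means absent.
    Columns follow registry (catalog) order.
    """
    genes = registry.gene_order
    genomes = list(calls_by_genome)
    cells: dict[tuple[str, str], str] = {}
    for gid in genomes:
        best: dict[str, int] = {}
        for call in calls_by_genome[gid]:
            if call.label in registry.genes:
                rank = _STATUS_RANK[call.status]
                if rank > best.get(call.label, 0):
                    best[call.label] = rank
        inv = {v: k for k, v in _STATUS_RANK.items()}
        for g in genes:
            cells[(gid, g)] = inv[best[g]] if g in best else ABSENT
    return PresenceMatrix(genomes=genomes, genes=genes, cells=cells)


# ---------------------------------------------------------------------------
# 4. Flagellated call
# ---------------------------------------------------------------------------


def call_flagellated(
    row: dict[str, str],
    meta: GenomeMeta,
    registry: Registry,
    pseudogene_allowance: int = 2,
    mag_min_core: int = 10,
    representative_min_core: int = 20,
    absent_core_allowance: int = 0,
    optional_core: frozenset[str] | set[str] = frozenset(),
) -> FlagellarCall:
    """Apply the assembly-level-specific core-gene rule to one matrix row.

    Complete and draft genomes (``complete_rule``): flagellated iff all
    24 core genes are non-absent — up to ``absent_core_allowance``
    missing core genes tolerated, 0 by default — and at most
    ``pseudogene_allowance`` of them are pseudogenes.  Partial calls
    (contig-edge truncations) count as present, since the coding
    sequence is likely complete in the genome.

    ``optional_core`` names core genes whose *absence* is tolerated in
    the complete rule.  The distal-rod genes FlgF and FlgG belong to
    the ancient core yet were lost wholesale in the later
    actinobacterial classes, whose species are nonetheless flagellated;
    callers analyzing those lineages pass ``{"FlgF", "FlgG"}`` so that
    the loss does not veto the call.  The registry deliberately keeps
    both genes core — the exemption is the caller's decision.

    MAG genomes (``mag_rule``): flagellated iff at least
    ``mag_min_core`` of the 24 core genes are present or partial.  MAGs
    with at least ``representative_min_core`` core genes are flagged as
    representative candidates (used to pick the most intact MAGs per
    class); the flag never affects the flagellated call itself.
    """
    core = sorted(registry.core_gene_set())
    n_present = sum(row[g] in (PRESENT, PARTIAL) for g in core)
    n_pseudo = sum(row[g] == PSEUDOGENE for g in core)
    n_absent = sum(row[g] == ABSENT for g in core)
    n_absent_strict = sum(
        row[g] == ABSENT for g in core if g not in optional_core
    )

    if meta.assembly_level in ("complete", "draft"):
        flagellated = (
            n_absent_strict <= absent_core_allowance
            and n_pseudo <= pseudogene_allowance
        )
        rationale = (
            f"{n_present}/24 core present, {n_pseudo} pseudogene, "
            f"{n_absent} absent (allowance: {pseudogene_allowance} "
            f"pseudogenes, {absent_core_allowance} absent)"
        )
        return FlagellarCall(
            genome_id=meta.genome_id,
            flagellated=flagellated,
            tier="complete_rule",
            core_present=n_present,
            core_pseudogenes=n_pseudo,
            rationale=rationale,
        )
    if meta.assembly_level == "MAG":
        flagellated = n_present >= mag_min_core
        return FlagellarCall(
            genome_id=meta.genome_id,
            flagellated=flagellated,
            tier="mag_rule",
            core_present=n_present,
            core_pseudogenes=n_pseudo,
            rationale=f"{n_present}/24 core present (MAG threshold {mag_min_core})",
            representative_candidate=n_present >= representative_min_core,
        )
    raise ValueError(f"unknown assembly_level {meta.assembly_level!r}")


def count_flagellar_genes(row: dict[str, str]) -> int:
    """Number of non-absent flagellar genes in a matrix row."""
    return sum(status != ABSENT for status in row.values())


# ---------------------------------------------------------------------------
# 5. Cluster detection
# ---------------------------------------------------------------------------


def detect_major_cluster(
    calls: list[GeneCall],
    max_gap_bp: int = 10_000,
    registry: Registry | None = None,
) -> ClusterResult:
    """Merge flagellar-labeled calls into genomic clusters.

    Calls on one contig separated by at most ``max_gap_bp`` (distance
    between the end of one gene and the start of the next) join one
    cluster.  The cluster with the most flagellar genes is "major";
    ties go to the larger genomic span and are reported on the result.
    Genes outside the major cluster are outliers.  In actinobacterial
    genomes nearly all flagellar genes sit in one large cluster with at
    most one or two genes apart, so outliers are worth inspecting.
    """

    def is_flagellar(c: GeneCall) -> bool:
        if c.label == AMBIGUOUS_EFG:
            return True
        if registry is not None:
            return c.label in registry.genes
        return c.label not in ("unassigned",)

    flag_calls = [c for c in calls if is_flagellar(c)]
    if not flag_calls:
        return ClusterResult(major=None, clusters=[], outlier_loci=[])

    clusters: list[ClusterSpan] = []
    by_contig: dict[str, list[GeneCall]] = defaultdict(list)
    for c in sorted(flag_calls, key=lambda c: (c.contig_id, c.start)):
        by_contig[c.contig_id].append(c)
    for contig, cc in by_contig.items():
        run = [cc[0]]
        for c in cc[1:]:
            if c.start - run[-1].end - 1 <= max_gap_bp:
                run.append(c)
            else:
                clusters.append(_to_span(contig, run))
                run = [c]
        clusters.append(_to_span(contig, run))

    best_key = max((cl.n_genes, cl.span) for cl in clusters)
    winners = [cl for cl in clusters if (cl.n_genes, cl.span) == best_key]
    major = winners[0]
    tie = len(winners) > 1 or sum(cl.n_genes == major.n_genes for cl in clusters) > 1
    outliers = [
        locus for cl in clusters if cl is not major for locus in cl.loci
    ]
    return ClusterResult(major=major, clusters=clusters, outlier_loci=outliers, tie=tie)


def _to_span(contig: str, run: list[GeneCall]) -> ClusterSpan:
    return ClusterSpan(
        contig_id=contig,
        start=min(c.start for c in run),
        end=max(c.end for c in run),
        loci=tuple(c.locus_tag for c in run),
    )
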