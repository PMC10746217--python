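"""Evolutionary screens: GC-content HGT check and GGDEF-domain census.

A flagellar gene cluster acquired by recent horizontal transfer tends
to carry the donor's nucleotide composition, so a GC% difference
between the cluster and the rest of the genome above a threshold
(default 5 percentage points, strict) flags a candidate transfer.

The GGDEF domain is the catalytic domain of diguanylate cyclases; the
number of GGDEF-domain proteins per genome proxies the size of the
c-di-GMP signaling network and is compared between ecological and
phenotypic groups with a rank-based two-sample test (robust to the
heavy right tail of the counts).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from flagscan.annotation_io import DomainHit, GenomeMeta

__all__ = [
    "GCComparison",
    "GgdefCensusRow",
    "gc_content",
    "hgt_screen",
    "ggdef_census",
    "group_compare",
]


@dataclass(frozen=True)
class GCComparison:
    genome_id: str
    cluster_gc: float
    genome_gc: float
    abs_difference: float
    flagged: bool
    note: str = ""


@dataclass(frozen=True)
class GgdefCensusRow:
    genome_id: str
    n_ggdef: int
    ecology: str
    flagellated: bool
    zoospore_former: bool = False


def gc_content(sequence: str) -> float:
    """GC percentage of a nucleotide sequence.

    ``N`` (unknown) bases are excluded from both numerator and
    denominator; any other character raises.  An empty or all-N
    sequence has no defined GC content and raises ``ValueError``.
    """
    counts = defaultdict(int)
    for base in sequence.upper():
        counts[base] += 1
    bad = set(counts) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    effective = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if effective == 0:
        raise ValueError("empty or unknown-only sequence has no GC content")
    return 100.0 * (counts["G"] + counts["C"]) / effective


def hgt_screen(
    genome_id: str,
    cluster_sequence: str | None,
    genome_gc: float,
    threshold: float = 5.0,
    cluster_gc: float | None = None,
) -> GCComparison:
    """Compare flagellar-cluster GC% against whole-genome GC%.

    Flagged iff the absolute difference strictly exceeds ``threshold``
    percentage points.  Pass either the cluster nucleotide span
    (``cluster_sequence``) or a precomputed ``cluster_gc``.  A genome
    without a detected cluster yields an unflagged result carrying a
    "no-cluster" note.
    """
    if cluster_gc is None:
        if not cluster_sequence:
            return GCComparison(
                genome_id=genome_id,
                cluster_gc=float("nan"),
                genome_gc=genome_gc,
                abs_difference=0.0,
                flagged=False,
                note="no-cluster",
            )
        cluster_gc = gc_content(cluster_sequence)
    diff = abs(cluster_gc - genome_gc)
    return GCComparison(
        genome_id=genome_id,
        cluster_gc=cluster_gc,
        genome_gc=genome_gc,
        abs_difference=diff,
        flagged=diff > threshold,
    )


def ggdef_census(
    domain_hits_by_genome: dict[str, list[DomainHit]],
    metas: list[GenomeMeta],
    flagellated: dict[str, bool] | None = None,
    include_mags: bool = False,
    domain_name: str = "GGDEF",
) -> list[GgdefCensusRow]:
    """Count distinct GGDEF-domain-containing proteins per genome.

    A protein with several GGDEF hits counts once.  MAG genomes are
    excluded by default (incomplete assemblies undercount).
    """
    flagellated = flagellated or {}
    rows = []
    for meta in metas:
        if meta.assembly_level == "MAG" and not include_mags:
            continue
        loci = {
            d.protein_locus
            for d in domain_hits_by_genome.get(meta.genome_id, [])
            if d.domain_name == domain_name
        }
        rows.append(
            GgdefCensusRow(
                genome_id=meta.genome_id,
                n_ggdef=len(loci),
                ecology=meta.ecology,
                flagellated=flagellated.get(meta.genome_id, False),
                zoospore_former=meta.zoospore_former,
            )
        )
    return rows


def group_compare(
    rows: list[GgdefCensusRow], grouping: str
) -> tuple[pd.DataFrame, dict | None]:
    """Summarize GGDEF counts per group and rank-test binary splits.

    ``grouping`` is one of ``ecology``, ``flagellated``, ``zoospore``.
    Returns a per-group summary (n, mean, median) and — when exactly
    two groups exist — a two-sided Mann-Whitney U test result
    ``{"statistic", "pvalue", "groups"}``.  The rank test is invariant
    under any strictly increasing transform of the counts.
    """
    key = {
        "ecology": lambda r: r.ecology,
        "flagellated": lambda r: "flagellated" if r.flagellated else "non_flagellated",
        "zoospore": lambda r: "zoospore" if r.zoospore_former else "other",
    }.get(grouping)
    if key is None:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups: dict[str, list[int]] = defaultdict(list)
    for r in rows:
        groups[key(r)].append(r.n_ggdef)
    for name, vals in groups.items():
        if not vals:
            raise ValueError(f"empty group {name!r}")
    if not groups:
        raise ValueError("no census rows to compare")
    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n": len(vals),
                "mean": float(pd.Series(vals).mean()),
                "median": float(pd.Series(vals).median()),
            }
            for name, vals in sorted(groups.items())
        ]
    )
    test = None
    if len(groups) == 2:
        (name_a, a), (name_b, b) = sorted(groups.items())
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = {"statistic": float(stat), "pvalue": float(p), "groups": (name_a, name_b)}
    return summary, test
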