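"""Chemosensory system detection and classification.

A chemosensory (chemotaxis) system is a gene neighborhood of signal
transduction components: the kinase CheA, adaptor CheW, response
regulator CheY, methylation enzymes CheB/CheR, auxiliaries
CheC/CheD/CheX, and chemoreceptors (MCPs).  Systems fall into
phylogenomic classes; the two that dominate Actinobacteria are

* **F1** — carries the two diagnostic auxiliaries CheC and CheD, no
  conserved operon order, cognate 44H receptors;
* **F5** — conserved operon order "A:W W ... B R" with a CheA kinase
  bearing an additional CheW domain, cognate 38H receptors.

F7, F9, and ACF are matched by component signatures shipped as editable
placeholders in the registry.  Chemoreceptors are binned by the length
of their cytoplasmic signaling domain in 7-residue heptads (e.g. a
308-residue domain = 44 heptads = class 44H).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace

import pandas as pd

from flagscan.annotation_io import DomainHit, GeneCall
from flagscan.registry import (
    CHEMO_COMPONENTS,
    COMPONENT_LETTERS,
    F_CLASS_PRECEDENCE,
    Registry,
)

__all__ = [
    "ChemoSystem",
    "ChemoreceptorRecord",
    "detect_systems",
    "has_chemotaxis_set",
    "classify_f_class",
    "classify_receptor_h",
    "cognate_report",
]

#: Domain names accepted as the MCP signaling domain.
MCP_SIGNAL_DOMAINS = frozenset({"MCPsignal", "MCP_signal", "MA"})


@dataclass(frozen=True)
class ChemoSystem:
    """A detected chemosensory gene neighborhood."""

    genome_id: str
    contig_id: str
    member_loci: tuple[str, ...]
    components: tuple[str, ...]  # in transcriptional order, CheA:W resolved
    order_string: str
    f_class: str = "unclassified"
    evidence: str = ""

    def component_set(self) -> set[str]:
        """Component names with the kinase variant folded into CheA."""
        return {"CheA" if c == "CheA:W" else c for c in self.components}

    @property
    def has_kinase_variant(self) -> bool:
        return "CheA:W" in self.components


@dataclass(frozen=True)
class ChemoreceptorRecord:
    """One chemoreceptor with its measured signaling-domain length."""

    genome_id: str
    protein_locus: str
    signaling_domain_length: int  # residues; 0 when no domain hit found
    h_class: str = "unassigned"


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


def detect_systems(
    calls: list[GeneCall],
    domain_hits: list[DomainHit],
    max_gap_genes: int = 5,
) -> tuple[list[ChemoSystem], list[ChemoreceptorRecord]]:
    """Group chemosensory-labeled genes into systems.

    Chemosensory genes on one contig separated by at most
    ``max_gap_genes`` intervening non-chemosensory genes form one
    neighborhood.  A neighborhood is a *system* when it has at least
    two members, at least one of which is not a chemoreceptor; lone or
    receptor-only groups contribute chemoreceptor records but no
    system.  A CheA locus with an additional CheW domain hit is
    reported as the F5-style variant kinase ``CheA:W``.

    Returns ``(systems, receptors)``; receptors cover every MCP locus
    in the genome, inside or outside systems, with the signaling-domain
    length measured from the envelope of its MCP-signal domain hit
    (0 when no hit exists).
    """
    chew_domains_on: set[str] = set()
    signal_len: dict[str, int] = {}
    for d in domain_hits:
        if d.domain_name == "CheW":
            chew_domains_on.add(d.protein_locus)
        elif d.domain_name in MCP_SIGNAL_DOMAINS:
            # keep the longest envelope if a receptor has several hits
            signal_len[d.protein_locus] = max(
                signal_len.get(d.protein_locus, 0), d.length
            )

    by_contig: dict[str, list[GeneCall]] = defaultdict(list)
    for c in sorted(calls, key=lambda c: (c.contig_id, c.start)):
        by_contig[c.contig_id].append(c)

    systems: list[ChemoSystem] = []
    receptors: list[ChemoreceptorRecord] = []

    for contig, contig_calls in by_contig.items():
        chemo_idx = [
            i for i, c in enumerate(contig_calls) if c.label in CHEMO_COMPONENTS
        ]
        groups: list[list[int]] = []
        for i in chemo_idx:
            if groups and i - groups[-1][-1] - 1 <= max_gap_genes:
                groups[-1].append(i)
            else:
                groups.append([i])
        for grp in groups:
            members = [contig_calls[i] for i in grp]
            comps = [
                "CheA:W"
                if m.label == "CheA" and m.locus_tag in chew_domains_on
                else m.label
                for m in members
            ]
            minus = sum(1 for m in members if m.strand == "-")
            if minus * 2 > len(members):  # transcribed right-to-left
                members = members[::-1]
                comps = comps[::-1]
            non_mcp = sum(1 for c in comps if c != "MCP")
            if len(members) >= 2 and non_mcp >= 1:
                systems.append(
                    ChemoSystem(
                        genome_id=members[0].genome_id,
                        contig_id=contig,
                        member_loci=tuple(m.locus_tag for m in members),
                        components=tuple(comps),
                        order_string=" ".join(COMPONENT_LETTERS[c] for c in comps),
                    )
                )

    for c in calls:
        if c.label == "MCP":
            receptors.append(
                ChemoreceptorRecord(
                    genome_id=c.genome_id,
                    protein_locus=c.locus_tag,
                    signaling_domain_length=signal_len.get(c.locus_tag, 0),
                )
            )
    return systems, receptors


def has_chemotaxis_set(calls: list[GeneCall]) -> bool:
    """True iff the genome encodes the four core chemotaxis components.

    The minimal chemotaxis gene set is a chemoreceptor (MCP), CheA,
    CheW, and CheY, each anywhere in the genome — operon context is
    irrelevant for this call.
    """
    labels = {c.label for c in calls}
    return {"MCP", "CheA", "CheW", "CheY"} <= labels


# ---------------------------------------------------------------------------
# F-class classification
# ---------------------------------------------------------------------------


def _f5_order_ok(components: tuple[str, ...]) -> bool:
    """Match the conserved F5 operon order "A:W W ... B R".

    Interleaved chemoreceptors (M) and CheY genes are ignored — both
    are drawn inside the F5 operon model.
    """
    core = [c for c in components if c not in ("MCP", "CheY")]
    return (
        len(core) >= 4
        and core[0] == "CheA:W"
        and core[1] == "CheW"
        and core[-2] == "CheB"
        and core[-1] == "CheR"
    )


def classify_f_class(system: ChemoSystem, registry: Registry) -> ChemoSystem:
    """Assign the chemosensory class of one system, with evidence.

    Rules, in precedence order (conflicts are recorded in the evidence
    trail, never silently dropped):

    * F1 — both diagnostic auxiliaries (CheC and CheD) present;
      components only, as F1 has no conserved gene order;
    * F5 — variant kinase CheA:W present and operon order matches
      "A:W W ... B R" (ignoring interleaved M/Y);
    * F9 / F7 / ACF — component signature subset match against the
      registry placeholders, most specific first.

    Systems matching no rule are left "unclassified".
    """
    comps = system.component_set()
    matches: list[tuple[str, str]] = []
    for name in F_CLASS_PRECEDENCE:
        fc = registry.f_classes.get(name)
        if fc is None:
            continue
        if name == "F1":
            if fc.diagnostic_components <= comps:
                matches.append((name, "diagnostic CheC+CheD present"))
        elif name == "F5":
            if system.has_kinase_variant and _f5_order_ok(system.components):
                matches.append((name, f"kinase CheA:W + order '{system.order_string}'"))
        else:
            if fc.required_components <= comps:
                matches.append((name, f"components ⊇ {sorted(fc.required_components)}"))
                break  # F9 > F7 > ACF are nested signatures; keep the first
    if not matches:
        return replace(system, f_class="unclassified", evidence="no signature matched")
    winner, reason = matches[0]
    evidence = f"{winner}: {reason}"
    if len(matches) > 1:
        also = ", ".join(m for m, _ in matches[1:])
        evidence += f" (also matched: {also}; precedence {'>'.join(m for m, _ in matches)})"
    return replace(system, f_class=winner, evidence=evidence)


# ---------------------------------------------------------------------------
# Heptad-class assignment
# ---------------------------------------------------------------------------


def classify_receptor_h(
    record: ChemoreceptorRecord, registry: Registry
) -> ChemoreceptorRecord:
    """Bin a chemoreceptor by signaling-domain length in heptads.

    The class whose heptad count is nearest to ``length / 7`` wins,
    provided the distance is within the class tolerance (default 2
    heptads); otherwise the receptor stays "unassigned".  Ties go to
    the smaller heptad count (deterministic).
    """
    if record.signaling_domain_length <= 0:
        raise ValueError(
            f"{record.protein_locus}: non-positive signaling-domain length"
        )
    heptads = record.signaling_domain_length / 7.0
    best = min(
        registry.h_classes.values(),
        key=lambda h: (abs(h.heptad_count - heptads), h.heptad_count),
    )
    label = (
        best.label
        if abs(best.heptad_count - heptads) <= best.tolerance
        else "unassigned"
    )
    return replace(record, h_class=label)


# ---------------------------------------------------------------------------
# Cognate matching report
# ---------------------------------------------------------------------------


def cognate_report(
    systems: list[ChemoSystem],
    receptors: list[ChemoreceptorRecord],
    registry: Registry,
) -> pd.DataFrame:
    """Per-genome table of F classes against receptor H-class counts.

    One row per (genome, detected F class) — or a single row with
    ``f_class = "-"`` for genomes with receptors but no classified
    system.  ``match`` flags whether the genome's modal H class equals
    the cognate H class of that F class (e.g. F1-44H, F5-38H).
    """
    rec_by_genome: dict[str, list[ChemoreceptorRecord]] = defaultdict(list)
    for r in receptors:
        rec_by_genome[r.genome_id].append(r)
    sys_by_genome: dict[str, list[ChemoSystem]] = defaultdict(list)
    for s in systems:
        sys_by_genome[s.genome_id].append(s)

    h_labels = list(registry.h_classes)
    rows = []
    for gid in sorted(set(rec_by_genome) | set(sys_by_genome)):
        counts = Counter(
            r.h_class for r in rec_by_genome.get(gid, []) if r.h_class != "unassigned"
        )
        modal = (
            min(c for c in counts if counts[c] == max(counts.values()))
            if counts
            else ""
        )
        f_classes = sorted(
            {s.f_class for s in sys_by_genome.get(gid, [])} - {"unclassified"}
        )
        base = {
            "genome_id": gid,
            "n_receptors": len(rec_by_genome.get(gid, [])),
            "modal_h": modal,
            **{h: counts.get(h, 0) for h in h_labels},
        }
        if not f_classes:
            rows.append({**base, "f_class": "-", "cognate_h": "", "match": False})
        for fc in f_classes:
            cognate = registry.f_classes[fc].cognate_h
            rows.append(
                {**base, "f_class": fc, "cognate_h": cognate,
                 "match": bool(modal) and modal == cognate}
            )
    return pd.DataFrame(
        rows,
        columns=["genome_id", "f_class", "cognate_h", "modal_h", "match",
                 "n_receptors", *h_labels],
    )
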