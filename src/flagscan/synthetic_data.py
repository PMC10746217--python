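"""Seeded synthetic genome-annotation generator with planted ground truth.

The generator emits the exact formats the ingest readers consume — GFF3
coordinates, nucleotide and protein FASTA, 12-column homology hit
tables, domtblout-style domain tables, and the metadata TSV — for
genomes whose every analyzable property is planted and recorded:

* a flagellar gene cluster in a conserved order with the *flgD-flgE*
  and *flgF-flgG* adjacencies (cross-reactive FlgE/F/G homology hits
  force the gene-order disambiguation step to do real work);
* chemosensory operons from per-class templates (F1, F5, F7, F9, ACF)
  and chemoreceptors with heptad-exact signaling-domain lengths;
* per-gene nucleotide composition, with an optional GC offset on the
  flagellar cluster to plant horizontal-transfer signals;
* GGDEF-domain protein counts drawn per ecological group from a
  negative binomial (the observed counts are heavily right-tailed,
  which a Poisson cannot mimic);
* MAG truncation: uniform gene dropout and contig splitting with
  partial (contig-edge) gene calls.

Fixtures are structural, not phylogenetically realistic: no
substitution model, no codon bias.  All randomness flows from the
spec/cohort seed, so identical seeds give byte-identical bundles.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field

import numpy as np

from flagscan.annotation_io import GenomeMeta, write_metadata
from flagscan.registry import Registry, load_registry
from flagscan.tree_analysis import PhyloTree

__all__ = [
    "GenomeSpec",
    "GenomeBundle",
    "CohortBundle",
    "GroundTruth",
    "ClassProfile",
    "DEFAULT_PROFILES",
    "generate_genome",
    "generate_cohort",
    "generate_tree_pair",
]

# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

#: Conserved flagellar cluster gene order used for all planted clusters.
#: flgD-flgE are adjacent; flgF-flgG form an adjacent pair well separated
#: from flgD (so each disambiguation cue is exercised in isolation).
CLUSTER_ORDER: tuple[str, ...] = (
    "FlhA", "FlhB", "FlhE", "FliP", "FliQ", "FliR", "FliI",
    "FliJ", "FliH", "FliO",
    "FliF", "FliG", "FliM", "FliN", "FliY", "FliL", "MotA", "MotB", "SwrD",
    "FliE", "FlgB", "FlgC", "FlgD", "FlgE", "FliK", "FlgK", "FlgL", "FlgN",
    "FliC", "FliD", "FliS", "FliT", "YvyC",
    "FlgF", "FlgG", "FlgJ",
    "FlhF", "FlhG", "FliA", "FlgM",
)

#: Genes additionally lost in the later (FlgFG-less) classes.
NON_FLGFG_ABSENT = frozenset(
    {"FlgF", "FlgG", "FlgJ", "YvyC", "FlhF", "FlgM"}
)

#: Chemosensory operon templates per F class (transcriptional order).
#: "CheA:W" denotes the F5 variant kinase carrying an extra CheW domain.
OPERON_TEMPLATES: dict[str, tuple[str, ...]] = {
    "F1": ("CheA", "CheW", "CheC", "CheD", "MCP", "CheB", "CheR", "CheY"),
    "F5": ("CheA:W", "CheW", "MCP", "CheY", "CheB", "CheR"),
    "F7": ("CheA", "CheW", "MCP", "CheB", "CheR", "CheY"),
    "F9": ("CheA", "CheW", "CheX", "MCP", "CheB", "CheR", "CheY"),
    "ACF": ("CheA", "CheW", "MCP", "CheB", "CheR"),
}

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_SPACER = 100  # default intergenic spacer, bp


# ---------------------------------------------------------------------------
# Specs and outputs
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Everything plantable about one synthetic genome."""

    genome_id: str
    tax_class: str = "Actinomycetia"
    ecology: str = "soil"
    assembly_level: str = "complete"
    flagellated: bool = False
    include_flgFG: bool = False
    f_class: str | None = None
    extra_f_classes: tuple[str, ...] = ()
    n_receptors: dict[str, int] = field(default_factory=dict)
    n_ggdef: int = 0
    pseudogene_rate: float = 0.0
    mag_retention: float = 1.0
    cluster_gc_offset: float = 0.0
    genome_gc: float = 65.0
    zoospore_former: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not self.flagellated and self.include_flgFG:
            raise ValueError(
                f"{self.genome_id}: include_flgFG without flagellated is contradictory"
            )
        for name in ("pseudogene_rate", "mag_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.genome_id}: {name}={v} outside [0, 1]")
        if self.f_class is not None and self.f_class not in OPERON_TEMPLATES:
            raise ValueError(f"{self.genome_id}: unknown f_class {self.f_class!r}")
        if not 0 <= self.genome_gc <= 100:
            raise ValueError(f"{self.genome_id}: genome_gc outside [0, 100]")
        if self.n_ggdef < 0:
            raise ValueError(f"{self.genome_id}: n_ggdef < 0")


@dataclass
class GenomeBundle:
    """One genome's annotation bundle as text blobs."""

    meta: GenomeMeta
    gff_text: str
    nucleotide_fasta: str
    protein_fasta: str
    hits_text: str
    domains_text: str

    def write(self, genomes_dir: str) -> None:
        gid = self.meta.genome_id
        os.makedirs(genomes_dir, exist_ok=True)
        for suffix, text in [
            (".gff", self.gff_text),
            (".fna", self.nucleotide_fasta),
            (".faa", self.protein_fasta),
            ("_hits.tsv", self.hits_text),
            ("_domains.tbl", self.domains_text),
        ]:
            with open(os.path.join(genomes_dir, gid + suffix), "w") as fh:
                fh.write(text)


@dataclass
class GroundTruth:
    """Planted values for every quantity the pipeline estimates."""

    genomes: dict[str, dict] = field(default_factory=dict)
    transfers: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {"genomes": self.genomes, "transfers": self.transfers},
            indent=1, sort_keys=True,
        )


@dataclass
class CohortBundle:
    genomes: list[GenomeBundle]
    truth: GroundTruth
    specs: list[GenomeSpec]

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        gdir = os.path.join(out_dir, "genomes")
        for g in self.genomes:
            g.write(gdir)
        write_metadata(
            [g.meta for g in self.genomes], os.path.join(out_dir, "metadata.tsv")
        )
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            fh.write(self.truth.to_json())


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def _rand_nt(rng: np.random.Generator, n: int, gc_pct: float) -> np.ndarray:
    g = min(max(gc_pct, 0.0), 100.0) / 100.0
    p = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    return rng.choice(_NT, size=n, p=p)


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_AA, size=n).tobytes().decode()


def _wrap_fasta(name: str, seq: str, width: int = 70) -> str:
    body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
    return f">{name}\n{body}\n"


# ---------------------------------------------------------------------------
# Gene plan
# ---------------------------------------------------------------------------


@dataclass
class _Gene:
    locus: str
    kind: str  # flag | chemo | mcp | ggdef | filler
    symbol: str | None  # homology query symbol / label
    length: int  # nucleotides, multiple of 3
    strand: str = "+"
    status: str = "present"  # present | pseudogene | partial
    gc: float | None = None  # None -> genome background
    signal_len: int = 0  # MCP signaling-domain residues
    chew_domain: bool = False  # CheA:W variant kinase
    extra_ggdef_hit: bool = False


def _gene_len(rng: np.random.Generator, kind: str) -> int:
    if kind == "mcp":
        return 3 * int(rng.integers(450, 650))
    return 3 * int(rng.integers(220, 480))


def generate_genome(
    spec: GenomeSpec, registry: Registry | None = None
) -> tuple[GenomeBundle, dict]:
    """Emit one genome's annotation bundle plus its ground-truth record.

    All randomness flows from ``spec.seed``: the same spec generates a
    byte-identical bundle on every run.
    """
    spec.validate()
    registry = registry or load_registry()
    rng = np.random.default_rng(spec.seed)
    gid = spec.genome_id
    counter = [0]

    def tag() -> str:
        counter[0] += 1
        return f"{gid}_{counter[0]:05d}"

    def fillers(k: int) -> list[_Gene]:
        return [
            _Gene(tag(), "filler", None, _gene_len(rng, "filler"),
                  strand=rng.choice(("+", "-")))
            for _ in range(k)
        ]

    genes: list[_Gene] = []
    truth: dict = {
        "flagellated": spec.flagellated,
        "include_flgFG": spec.include_flgFG,
        "tax_class": spec.tax_class,
        "assembly_level": spec.assembly_level,
        "ecology": spec.ecology,
        "efg_loci": {},
        "f_classes": [],
        "chemotaxis_set": False,
        "receptor_h_counts": {},
        "n_ggdef": spec.n_ggdef,
        "hgt_flag": abs(spec.cluster_gc_offset) > 5.0,
        "pseudogene_loci": [],
        "flagellar_genes_planted": 0,
        "zoospore_former": spec.zoospore_former,
    }

    genes += fillers(int(rng.integers(2, 5)))

    # ---- flagellar cluster -------------------------------------------
    if spec.flagellated:
        order = [
            s for s in CLUSTER_ORDER
            if spec.include_flgFG or s not in NON_FLGFG_ABSENT
        ]
        cluster_strand = str(rng.choice(("+", "-")))
        placed = order if cluster_strand == "+" else order[::-1]
        cluster_gc = spec.genome_gc + spec.cluster_gc_offset
        core = registry.core_gene_set()
        for sym in placed:
            g = _Gene(tag(), "flag", sym, _gene_len(rng, "flag"),
                      strand=cluster_strand, gc=cluster_gc)
            if sym not in core and rng.random() < spec.pseudogene_rate:
                g.status = "pseudogene"
                truth["pseudogene_loci"].append(g.locus)
            genes.append(g)
            if sym in ("FlgE", "FlgF", "FlgG"):
                truth["efg_loci"][sym] = g.locus
        truth["flagellar_genes_planted"] = len(order)

    genes += fillers(int(rng.integers(4, 8)))

    # ---- chemosensory operons ----------------------------------------
    f_classes = ([spec.f_class] if spec.f_class else []) + list(spec.extra_f_classes)
    receptor_counts: dict[str, int] = dict(spec.n_receptors)
    for fc in f_classes:
        template = OPERON_TEMPLATES[fc]
        strand = str(rng.choice(("+", "-")))
        placed = template if strand == "+" else template[::-1]
        cognate = registry.f_classes[fc].cognate_h
        for comp in placed:
            kind = "mcp" if comp == "MCP" else "chemo"
            g = _Gene(tag(), kind, "MCP" if kind == "mcp" else comp.split(":")[0],
                      _gene_len(rng, kind), strand=strand)
            if comp == "CheA:W":
                g.chew_domain = True
            if kind == "mcp":
                g.signal_len = 7 * registry.h_classes[cognate].heptad_count
                receptor_counts[cognate] = receptor_counts.get(cognate, 0) + 1
            genes.append(g)
        truth["f_classes"].append(fc)
        genes += fillers(int(rng.integers(6, 10)))

    # ---- scattered chemoreceptors ------------------------------------
    for h_label in sorted(spec.n_receptors):
        heptads = registry.h_classes[h_label].heptad_count
        for _ in range(spec.n_receptors[h_label]):
            g = _Gene(tag(), "mcp", "MCP", _gene_len(rng, "mcp"),
                      strand=rng.choice(("+", "-")), signal_len=7 * heptads)
            genes.append(g)
            genes += fillers(int(rng.integers(1, 3)))

    truth["receptor_h_counts"] = {
        k: v for k, v in sorted(receptor_counts.items()) if v > 0
    }
    planted_components = {
        c.split(":")[0] for fc in f_classes for c in OPERON_TEMPLATES[fc]
    }
    if spec.n_receptors:
        planted_components.add("MCP")
    truth["chemotaxis_set"] = {"MCP", "CheA", "CheW", "CheY"} <= planted_components

    # ---- GGDEF-domain proteins ---------------------------------------
    for i in range(spec.n_ggdef):
        g = _Gene(tag(), "ggdef", None, _gene_len(rng, "ggdef"),
                  strand=rng.choice(("+", "-")),
                  extra_ggdef_hit=(i % 5 == 4))
        genes.append(g)
        if rng.random() < 0.5:
            genes += fillers(1)

    genes += fillers(int(rng.integers(2, 5)))

    # ---- MAG truncation ----------------------------------------------
    # mag_retention < 1 models assembly fragmentation: uniform gene
    # dropout plus contig splitting with partial calls at contig edges.
    # Full retention means an intact (single-contig) assembly, the
    # regime in which every planted value must be recoverable.
    if spec.assembly_level == "MAG" and spec.mag_retention < 1.0:
        keep = rng.random(len(genes)) < spec.mag_retention
        genes = [g for g, k in zip(genes, keep) if k]
        truth["efg_loci"] = {
            s: l for s, l in truth["efg_loci"].items()
            if any(g.locus == l for g in genes)
        }
        contigs = _split_contigs(genes, rng)
    else:
        contigs = [genes]

    # ---- layout + emission -------------------------------------------
    bundle = _emit(spec, contigs, rng)
    truth["flagellar_genes_planted"] = len(
        {g.symbol for c in contigs for g in c if g.kind == "flag"}
    )
    return bundle, truth


def _split_contigs(
    genes: list[_Gene], rng: np.random.Generator
) -> list[list[_Gene]]:
    """Split a MAG's gene list into contigs; edge genes may be partial."""
    contigs: list[list[_Gene]] = [[]]
    for g in genes:
        if len(contigs[-1]) >= 3 and rng.random() < 0.12:
            contigs.append([])
        contigs[-1].append(g)
    contigs = [c for c in contigs if c]
    for c in contigs:
        if rng.random() < 0.5 and c[0].status == "present":
            c[0].status = "partial"
        if len(c) > 1 and rng.random() < 0.5 and c[-1].status == "present":
            c[-1].status = "partial"
    return contigs


def _emit(
    spec: GenomeSpec, contigs: list[list[_Gene]], rng: np.random.Generator
) -> GenomeBundle:
    gid = spec.genome_id
    gff = ["##gff-version 3"]
    feature_lines: list[str] = []
    fna_parts: list[str] = []
    faa_parts: list[str] = []
    hit_rows: list[str] = []
    dom_rows: list[str] = [
        "# synthetic per-domain hits (domtblout dialect)",
    ]
    total_nt = 0

    for ci, contig_genes in enumerate(contigs, start=1):
        contig = f"{gid}_contig{ci}"
        pos = 1
        seq_chunks: list[np.ndarray] = []
        for i, g in enumerate(contig_genes):
            edge_start = i == 0 and g.status == "partial"
            if not edge_start:
                # a spacer leading into a cluster gene carries the cluster
                # composition: a transferred cluster includes its
                # intergenic DNA, so the GC anomaly spans the whole locus
                spacer_gc = g.gc if g.gc is not None else spec.genome_gc
                seq_chunks.append(_rand_nt(rng, _SPACER, spacer_gc))
                pos += _SPACER
            start = pos
            end = pos + g.length - 1
            seq_chunks.append(
                _rand_nt(rng, g.length, g.gc if g.gc is not None else spec.genome_gc)
            )
            pos = end + 1
            attrs = f"ID={g.locus};locus_tag={g.locus}"
            if g.status == "pseudogene":
                attrs += ";pseudo=true"
            elif g.status == "partial":
                attrs += ";partial=true"
            feature_lines.append(
                f"{contig}\tflagscan_sim\tCDS\t{start}\t{end}\t.\t{g.strand}\t0\t{attrs}"
            )
            aa_len = g.length // 3
            faa_parts.append(_wrap_fasta(g.locus, _rand_aa(rng, aa_len)))
            hit_rows.extend(_hit_rows_for(g, aa_len, rng))
            dom_rows.extend(_domain_rows_for(g, aa_len, rng))
        trailer = _SPACER if contig_genes[-1].status != "partial" else 0
        if trailer:
            seq_chunks.append(_rand_nt(rng, trailer, spec.genome_gc))
            pos += trailer
        contig_len = pos - 1
        total_nt += contig_len
        gff.append(f"##sequence-region {contig} 1 {contig_len}")
        fna_parts.append(
            _wrap_fasta(contig, np.concatenate(seq_chunks).tobytes().decode())
        )

    gff.extend(feature_lines)
    completeness = {
        "complete": 100.0,
        "draft": round(float(rng.uniform(88, 99)), 2),
        "MAG": round(float(85 + 14 * spec.mag_retention * rng.uniform(0.9, 1.0)), 2),
    }[spec.assembly_level]
    meta = GenomeMeta(
        genome_id=gid,
        species=f"Synthetica {gid.lower()}",
        tax_class=spec.tax_class,
        ecology=spec.ecology,
        assembly_level=spec.assembly_level,
        completeness=completeness,
        contamination=round(float(rng.uniform(0, 2)), 2),
        genome_gc=spec.genome_gc,
        genome_size=total_nt,
        zoospore_former=spec.zoospore_former,
    )
    return GenomeBundle(
        meta=meta,
        gff_text="\n".join(gff) + "\n",
        nucleotide_fasta="".join(fna_parts),
        protein_fasta="".join(faa_parts),
        hits_text="\n".join(hit_rows) + ("\n" if hit_rows else ""),
        domains_text="\n".join(dom_rows) + "\n",
    )


def _hit_row(query: str, locus: str, aa_len: int, evalue: float,
             bitscore: float, rng: np.random.Generator) -> str:
    pident = round(float(rng.uniform(35, 85)), 1)
    return "\t".join(
        map(str, [query, locus, pident, aa_len, int(aa_len * 0.2), 2,
                  1, aa_len, 1, aa_len, f"{evalue:.2e}", round(bitscore, 1)])
    )


def _hit_rows_for(g: _Gene, aa_len: int, rng: np.random.Generator) -> list[str]:
    rows: list[str] = []
    if g.kind == "flag":
        if g.symbol in ("FlgE", "FlgF", "FlgG"):
            # cross-reactive paralogs: strong hits to all three symbols in
            # a random E-value ranking, so homology alone cannot decide
            exps = rng.permutation([60, 55, 50])
            for sym, ex in zip(("FlgE", "FlgF", "FlgG"), exps):
                rows.append(_hit_row(sym, g.locus, aa_len, 10.0 ** -ex,
                                     200 + 5 * ex, rng))
        else:
            query = g.symbol
            if g.symbol == "YvyC" and rng.random() < 0.5:
                query = "FlaG"  # alias form, resolved by the registry
            ev = 10.0 ** -float(rng.uniform(20, 80))
            rows.append(_hit_row(query, g.locus, aa_len, ev,
                                 float(rng.uniform(150, 500)), rng))
    elif g.kind in ("chemo", "mcp"):
        ev = 10.0 ** -float(rng.uniform(25, 70))
        rows.append(_hit_row(g.symbol, g.locus, aa_len, ev,
                             float(rng.uniform(150, 450)), rng))
    elif g.kind == "filler" and rng.random() < 0.03:
        # sub-threshold decoy: E-value above the 1e-5 cutoff, must be ignored
        ev = 10.0 ** -float(rng.uniform(2, 4.8))
        rows.append(_hit_row("FliC", g.locus, aa_len, ev,
                             float(rng.uniform(30, 45)), rng))
    return rows


def _dom_row(locus: str, domain: str, aa_len: int, env_from: int, env_to: int,
             score: float) -> str:
    cols = [
        locus, "-", aa_len, domain, "-", env_to - env_from + 1,
        "1e-20", f"{score:.1f}", "0.1", 1, 1, "1e-22", "1e-20",
        f"{score:.1f}", "0.1", 1, env_to - env_from + 1,
        env_from, env_to, env_from, env_to, "0.95", "-",
    ]
    return " ".join(map(str, cols))


def _domain_rows_for(g: _Gene, aa_len: int, rng: np.random.Generator) -> list[str]:
    rows: list[str] = []
    if g.chew_domain:
        rows.append(_dom_row(g.locus, "CheW", aa_len, aa_len - 160, aa_len - 21,
                             float(rng.uniform(40, 90))))
    if g.kind == "mcp" and g.signal_len > 0:
        start = max(1, aa_len - g.signal_len - 30)
        rows.append(_dom_row(g.locus, "MCPsignal", aa_len, start,
                             start + g.signal_len - 1,
                             float(rng.uniform(80, 200))))
    if g.kind == "ggdef":
        start = int(rng.integers(20, max(21, aa_len - 180)))
        rows.append(_dom_row(g.locus, "GGDEF", aa_len, start, start + 159,
                             float(rng.uniform(60, 150))))
        if g.extra_ggdef_hit and start + 359 <= aa_len:
            rows.append(_dom_row(g.locus, "GGDEF", aa_len, start + 200,
                                 start + 359, float(rng.uniform(40, 90))))
    return rows


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class ClassProfile:
    """Study-condition parameters for one taxonomic class."""

    n: int
    flagellated_frac: float
    include_flgFG: bool
    assembly_level: str  # complete | draft_mix | MAG
    f_class_probs: dict[str, float]  # over F classes for flagellated genomes
    ecology_probs: dict[str, float]
    chemo_absent_frac: float = 0.0
    zoospore_frac: float = 0.0
    pseudogene_rate: float = 0.05
    mag_retention: float = 0.85


#: Default cohort: 538 genomes across the nine actinobacterial classes,
#: flagellated fractions high (41-91%) in the basal classes, 6% in
#: Actinomycetia and zero in Coriobacteriia/Rubrobacteria; F1 systems in
#: the FlgFG-bearing basal classes, F5 in the later classes.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "Ca_Aquicultoria": ClassProfile(
        12, 0.75, True, "MAG", {"F1": 0.7, "F7": 0.3},
        {"sea": 0.6, "terrestrial_water": 0.4}),
    "Ca_Geothermincolia": ClassProfile(
        12, 0.60, True, "MAG", {"F1": 0.6, "F7": 0.4},
        {"terrestrial_water": 0.8, "other": 0.2}),
    "Ca_Humimicrobiia": ClassProfile(
        11, 0.45, True, "MAG", {"F1": 1.0},
        {"soil": 0.5, "terrestrial_water": 0.5}),
    "Thermoleophilia": ClassProfile(
        20, 0.50, True, "complete", {"F1": 1.0},
        {"terrestrial_water": 0.5, "soil": 0.5}),
    "Acidimicrobiia": ClassProfile(
        15, 0.45, False, "draft_mix", {"F5": 1.0}, {"sea": 1.0}),
    "Nitriliruptoria": ClassProfile(
        10, 0.60, False, "draft_mix", {"F5": 1.0},
        {"sea": 0.8, "terrestrial_water": 0.2}),
    "Rubrobacteria": ClassProfile(
        8, 0.0, False, "complete", {}, {"terrestrial_water": 1.0}),
    "Coriobacteriia": ClassProfile(
        30, 0.0, False, "complete", {}, {"host_associated": 1.0}),
    "Actinomycetia": ClassProfile(
        420, 0.06, False, "complete", {"F5": 0.85, "F9": 0.15},
        {"soil": 0.46, "host_associated": 0.43, "sea": 0.06,
         "terrestrial_water": 0.05},
        chemo_absent_frac=0.55, zoospore_frac=0.15),
}

#: Classes carrying FlgFG (the basal lineage); used by reporting.
BASAL_CLASSES = (
    "Ca_Aquicultoria", "Ca_Geothermincolia", "Ca_Humimicrobiia",
    "Thermoleophilia",
)

#: Negative-binomial GGDEF-count means per ecological group; the
#: host-associated mean sits well below the free-living groups.
GGDEF_ECOLOGY_MEAN = {
    "sea": 14.0,
    "terrestrial_water": 14.0,
    "soil": 16.0,
    "host_associated": 4.0,
    "other": 10.0,
}
GGDEF_FLAGELLATED_MULT = 1.8
GGDEF_ZOOSPORE_MEAN = 55.0
GGDEF_NB_K = 2.0  # dispersion; small k = heavy right tail
# zoospore formers sit at the top of the census but are not open-ended:
# a tighter dispersion keeps their counts in a realistic band (~40-80)
GGDEF_ZOOSPORE_K = 12.0


def _nb(rng: np.random.Generator, mean: float, k: float = GGDEF_NB_K) -> int:
    return int(rng.negative_binomial(k, k / (k + mean)))


def _choice(rng: np.random.Generator, probs: dict[str, float]) -> str:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return str(rng.choice(keys, p=p / p.sum()))


def generate_cohort(
    profiles: dict[str, ClassProfile] | None = None,
    n_per_class: dict[str, int] | None = None,
    seed: int = 0,
    noise_free: bool = False,
    registry: Registry | None = None,
) -> CohortBundle:
    """Generate a cohort of synthetic genomes with planted truth.

    ``n_per_class`` overrides profile sizes (useful for scaled-down
    cohorts).  ``noise_free`` forces pseudogene_rate=0 and full MAG
    retention, the regime under which the pipeline must recover every
    planted value exactly.  Exactly one flagellated genome gets a +8%
    cluster GC offset (the planted horizontal-transfer signal); all
    others get a sub-threshold jitter.
    """
    profiles = profiles or DEFAULT_PROFILES
    registry = registry or load_registry()
    rng = np.random.default_rng(seed)
    specs: list[GenomeSpec] = []

    for tax_class in sorted(profiles):
        prof = profiles[tax_class]
        n = (n_per_class or {}).get(tax_class, prof.n)
        for i in range(n):
            gid = f"{tax_class[:6]}_{i + 1:04d}"
            flagellated = bool(rng.random() < prof.flagellated_frac)
            if prof.assembly_level == "draft_mix":
                level = "complete" if rng.random() < 0.8 else "draft"
            else:
                level = prof.assembly_level
            ecology = _choice(rng, prof.ecology_probs)
            zoospore = flagellated and rng.random() < prof.zoospore_frac
            f_class = None
            receptors: dict[str, int] = {}
            if flagellated and prof.f_class_probs:
                if rng.random() >= prof.chemo_absent_frac:
                    f_class = _choice(rng, prof.f_class_probs)
                    if zoospore and "F9" in prof.f_class_probs:
                        f_class = "F9"
                    cognate = registry.f_classes[f_class].cognate_h
                    receptors[cognate] = 5 + int(rng.poisson(4))
                    if rng.random() < 0.4:
                        minor = "38H" if cognate != "38H" else "44H"
                        receptors[minor] = 1 + min(2, int(rng.poisson(0.7)))
            mean, disp = GGDEF_ECOLOGY_MEAN[ecology], GGDEF_NB_K
            if zoospore:
                mean, disp = GGDEF_ZOOSPORE_MEAN, GGDEF_ZOOSPORE_K
            elif flagellated:
                mean *= GGDEF_FLAGELLATED_MULT
            specs.append(
                GenomeSpec(
                    genome_id=gid,
                    tax_class=tax_class,
                    ecology=ecology,
                    assembly_level=level,
                    flagellated=flagellated,
                    include_flgFG=flagellated and prof.include_flgFG,
                    f_class=f_class,
                    n_receptors=receptors,
                    n_ggdef=_nb(rng, mean, disp),
                    pseudogene_rate=0.0 if noise_free else prof.pseudogene_rate,
                    mag_retention=1.0 if noise_free else prof.mag_retention,
                    cluster_gc_offset=float(np.clip(rng.normal(0, 0.6), -2, 2)),
                    genome_gc=round(float(rng.uniform(58, 72)), 1),
                    zoospore_former=zoospore,
                    seed=int(rng.integers(2**31)),
                )
            )

    flagged_idx = [i for i, s in enumerate(specs) if s.flagellated]
    if flagged_idx:
        hgt_i = int(rng.choice(flagged_idx))
        specs[hgt_i].cluster_gc_offset = 8.0

    truth = GroundTruth()
    bundles = []
    for s in specs:
        bundle, t = generate_genome(s, registry)
        bundles.append(bundle)
        truth.genomes[s.genome_id] = t
    return CohortBundle(genomes=bundles, truth=truth, specs=specs)


# ---------------------------------------------------------------------------
# Tree pairs with planted transfers
# ---------------------------------------------------------------------------

_TREE_CLASSES = (
    "Acidimicrobiia", "Nitriliruptoria", "Thermoleophilia",
    "Actinomycetia", "Ca_Aquicultoria", "Ca_Geothermincolia",
)


def _rand_topology(labels: list[str], rng: np.random.Generator):
    """Random binary topology over labels as nested 2-lists."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append([a, b])
    return nodes[0]


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return _leaves(node[0]) + _leaves(node[1])


def _remove_leaf(node, leaf):
    """Return the topology with ``leaf`` pruned (unifurcations collapsed)."""
    if isinstance(node, str):
        return None if node == leaf else node
    a = _remove_leaf(node[0], leaf)
    b = _remove_leaf(node[1], leaf)
    if a is None:
        return b
    if b is None:
        return a
    return [a, b]


def _internal_nodes(node) -> list[list]:
    if isinstance(node, str):
        return []
    return [node] + _internal_nodes(node[0]) + _internal_nodes(node[1])


def _to_newick(node, rng: np.random.Generator) -> str:
    def fmt(n):
        bl = round(float(rng.uniform(0.02, 0.3)), 4)
        if isinstance(n, str):
            return f"{n}:{bl}"
        return f"({fmt(n[0])},{fmt(n[1])}):{bl}"

    if isinstance(node, str):
        return node + ";"
    return f"({fmt(node[0])},{fmt(node[1])});"


def generate_tree_pair(
    n_leaves: int,
    class_assignment: dict[str, str] | None = None,
    k_transfers: int = 0,
    seed: int = 0,
) -> tuple[PhyloTree, PhyloTree, list[dict]]:
    """Build a species tree / gene tree pair with k planted transfers.

    Classes are monophyletic in the species tree.  The gene tree starts
    as a copy; each transfer prunes one leaf and regrafts it as sister
    to a pure clade (>= 2 leaves) of a different class.  Transfers are
    non-overlapping: every source and target class is used at most
    once, and source classes keep at least two leaves after pruning, so
    detection context stays clean for every unmoved leaf.
    """
    if k_transfers > n_leaves // 4:
        raise ValueError("k_transfers must be at most n_leaves / 4")
    rng = np.random.default_rng(seed)
    if class_assignment is None:
        n_classes = max(2, min(len(_TREE_CLASSES), n_leaves // 3))
        class_assignment = {
            f"g{i + 1:03d}": _TREE_CLASSES[i % n_classes] for i in range(n_leaves)
        }
    by_class: dict[str, list[str]] = {}
    for leaf, cls in class_assignment.items():
        by_class.setdefault(cls, []).append(leaf)

    subtrees = [
        _rand_topology(sorted(by_class[c]), rng) for c in sorted(by_class)
    ]
    species = subtrees[0]
    for st in subtrees[1:]:
        species = [species, st]
    gene = copy.deepcopy(species)

    eligible_sources = [c for c in sorted(by_class) if len(by_class[c]) >= 3]
    used: set[str] = set()
    transfers: list[dict] = []
    for _ in range(k_transfers):
        sources = [c for c in eligible_sources if c not in used]
        if not sources:
            raise ValueError("infeasible regraft: not enough untouched classes")
        src = sources[int(rng.integers(len(sources)))]
        used.add(src)
        leaf = sorted(by_class[src])[int(rng.integers(len(by_class[src])))]
        gene = _remove_leaf(gene, leaf)
        targets = []
        for node in _internal_nodes(gene):
            node_leaves = _leaves(node)
            node_classes = {class_assignment[x] for x in node_leaves}
            if (
                len(node_leaves) >= 2
                and len(node_classes) == 1
                and next(iter(node_classes)) not in used | {src}
            ):
                targets.append(node)
        if not targets:
            raise ValueError("infeasible regraft: no pure foreign clade available")
        target = targets[int(rng.integers(len(targets)))]
        tgt_class = class_assignment[_leaves(target)[0]]
        used.add(tgt_class)
        target[:] = [[copy.deepcopy(target[0]), copy.deepcopy(target[1])], leaf]
        transfers.append({"leaf": leaf, "from": src, "to": tgt_class})

    import dendropy

    def parse(nested) -> PhyloTree:
        tree = dendropy.Tree.get(
            data=_to_newick(nested, rng), schema="newick",
            preserve_underscores=True,
        )
        return PhyloTree(tree=tree, classes=dict(class_assignment))

    return parse(species), parse(gene), transfers
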