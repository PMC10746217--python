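# Methods

## The analysis model

`flagscan` operationalizes a rule-based comparative-genomics analysis
of flagellar and chemosensory evolution in *Actinobacteria*. It does
not run homology searches or infer trees; it consumes their tabular
and Newick outputs and applies explicit, deterministic rules on top of
them. Every rule, threshold, and tie-break is stated below with its
default.

### Genome QC

A genome is removed when completeness < 80% **or** contamination > 5%,
unless whitelisted. OR-semantics was chosen because the whitelist
exists precisely for genomes whose only defect is moderate
contamination (flagellated species with 5–8% contamination that a
conjunctive rule would never remove in the first place). The filter is
idempotent.

### Flagellar gene labeling

Homology hits (12-column tabular, one row per query–locus pair) label
a locus when the E-value is **strictly** below `evalue_max = 1e-5`.
Among passing hits the winner is the lowest E-value, ties broken by
higher bitscore, then lexicographically smaller query symbol — fully
deterministic. Query aliases (FlhO/FlhP for FlgF/FlgG, FlaG for YvyC,
FlhX for FlhB) are canonicalized through the registry.

The paralogs FlgE (hook), FlgF and FlgG (distal rod) are too similar
at their D0/Dc domains for homology to separate, so their labels are
finalized from gene order: the candidate nearest a FlgD call (at most
`max_gap = 3` intervening genes; ties prefer the transcriptionally
downstream side, matching the conserved *flgD–flgE* arrangement)
becomes FlgE; a remaining adjacent candidate pair becomes FlgF
(transcriptionally upstream) and FlgG (downstream); anything else is
`FlgEFG_ambiguous` — ambiguity is a value, not an error. Strandedness
is read per decision (the FlgD call's strand; the candidate pair's
majority strand), so clusters encoded on either strand resolve
identically.

### Presence matrix and the flagellated call

Cells take four states — present, absent, pseudogene, partial — with
precedence present > pseudogene > partial when a genome has multiple
calls for one gene. "Partial" means a coding sequence truncated within
20 bp (configurable) of a contig edge; it counts as *present* for all
core-gene arithmetic, since the gene is likely intact in the organism.
Pseudogene status is taken from the input annotation (`pseudo=true` or
a `pseudogene` feature type); no length heuristic is applied by
default.

Complete/draft rule: flagellated iff every one of the 24 core genes is
non-absent and at most `pseudogene_allowance = 2` of them are
pseudogenes. Absent core genes veto the call by default
(`absent_core_allowance = 0`). MAG rule: flagellated iff ≥ 10 of 24
core genes are present-or-partial; MAGs with ≥ 20 are additionally
flagged as representative candidates, which never affects the
flagellated call itself.

**The FlgF/FlgG exemption.** FlgF and FlgG belong to the 24-gene
ancient core, yet the later actinobacterial lineage lost both while
remaining flagellated (their rod is built differently). A literal
24-core rule would therefore declare every later-class species
non-flagellated. The registry deliberately keeps both genes core; the
exemption is a *caller* decision: `call_flagellated` accepts an
`optional_core` set whose absence is tolerated, and the pipeline
passes `{FlgF, FlgG}` by default (`--strict-core` disables it). This
is the only reading under which the published species calls are
reproducible.

### Catalog accounting

The flagellar query catalog has 50 entries in six categories (fT3SS,
MS-ring, motor, rod, hook/filament, regulator), 24 of them core. The
conventional enumeration names more symbols than 50; the built-in
catalog merges YvyC/FlaG into one entry and folds FlhX (a standalone
homolog of the FlhB C-terminal domain) into FlhB as an alias. Users
preferring split entries can load an edited registry file; the
sectioned-TSV format round-trips exactly.

### Chemosensory classification

Chemosensory genes (CheA/W/B/R/C/D/X/Y and MCPs) within
`operon_gap_genes = 5` intervening non-chemosensory genes group into a
neighborhood; a neighborhood with ≥ 2 members, at least one of them
not an MCP, is a system. A CheA locus carrying an additional CheW
domain hit is the F5 variant kinase `A:W`. Classification precedence
is F1 > F5 > F9 > F7 > ACF, with every co-match recorded in the
evidence string:

* **F1** — CheC and CheD both present (components only; F1 has no
  conserved gene order);
* **F5** — variant kinase present and the operon order, read
  transcriptionally and ignoring interleaved MCP/CheY genes, starts
  `A:W W` and ends `B R`;
* **F9 / F7 / ACF** — component-set placeholders (core four + CheX +
  CheY; core four + CheY; core four). The published discrimination
  scheme for these classes is profile-based and richer; the shipped
  signatures are editable registry entries, not code.

A genome "has a chemotaxis gene set" iff MCP, CheA, CheW, and CheY are
each encoded anywhere in it. In cohort summaries this statistic is
reported over non-MAG genomes only: absence in an incomplete assembly
is not evidence of absence in the organism.

Receptor heptad classes: the signaling-domain length (from the
envelope of the MCP-signal domain hit) divided by 7 is matched to the
nearest class in {24, 28, 34, 36, 38, 40, 44, 48, 52, 58, 64} heptads
within a tolerance of 2; ties go to the smaller class; outside all
tolerances the receptor is unassigned. This nearest-neighbor rule is a
deliberately simple, replaceable stand-in for profile-based H-class
assignment.

### GC screen and GGDEF census

Cluster detection merges flagellar-labeled genes within
`cluster_gap_bp = 10 kb`; the cluster with the most genes is major
(ties broken by span and reported). The screen compares the GC% of the
major cluster's full nucleotide span (intergenic DNA included; a
CDS-only variant would require only passing the concatenated CDS
sequence) against the metadata genome GC%, flagging a **strict** > 5
percentage-point difference. `gc_content` excludes `N` from numerator
and denominator and rejects empty/unknown-only input.

The GGDEF census counts distinct protein loci with ≥ 1 GGDEF domain
hit (multiple hits on one protein count once), excluding MAGs by
default. Group comparisons report n/mean/median per group and, for
binary groupings, a two-sided Mann-Whitney U test — chosen because the
counts are heavily right-skewed and the rank test is invariant under
monotone transforms; the choice of test is this package's, not
inherited from a reference analysis.

### Tree concordance

Robinson-Foulds distance is the symmetric difference of non-trivial
bipartition sets; trees are compared unrooted (bipartitions are
encoded as unordered side-pairs, which makes the encoding
rooting-independent). Transfer detection reports a leaf iff the
plurality class of its smallest enclosing gene-tree clade of ≥ 2
leaves differs from its own class **and** its species-tree context is
uniformly its own class — the second condition suppresses discordance
that is shared by both trees. Plurality ties excluding the own class
are reported as ambiguous rather than resolved; bootstrap supports are
carried but not used.

## The synthetic-data generator

The generator emulates the *structure* of annotated actinobacterial
genomes, not their sequence evolution: no substitution model, no codon
bias. What it plants, the pipeline must recover:

* a flagellar cluster in a fixed conserved gene order (40 genes with
  FlgFG and accessories, 34 without the FlgFG-lineage genes), with
  *flgD–flgE* adjacent and *flgF–flgG* an adjacent pair well separated
  from *flgD*; every FlgE/F/G locus gets strong cross-reactive hits to
  all three symbols in a random E-value ranking, so gene order — not
  homology — must decide;
* chemosensory operons from per-class templates, receptors with
  heptad-exact signaling-domain envelopes, GGDEF proteins (every fifth
  with a second domain hit, exercising per-protein deduplication),
  sub-threshold decoy hits on occasional filler genes;
* per-gene nucleotide composition sampled i.i.d. at the target GC.
  A planted transfer adds a GC offset to the cluster *span* including
  its intergenic spacers. Direct compositional sampling is used rather
  than synonymous substitution on a template because composition is
  the only property any downstream consumer reads;
* MAG truncation when `mag_retention < 1`: uniform gene dropout at
  `1 − retention`, contig splitting, and partial (contig-edge) calls.
  Full retention produces an intact single-contig assembly — the
  noise-free regime in which recovery must be exact.

Default cohort profiles encode the study conditions: 538 genomes
across nine classes (420 Actinomycetia, 35 MAGs in the three
candidate classes, the rest complete/draft); flagellated fractions of
0.45–0.75 in the basal classes, 0.06 in Actinomycetia, zero in
Coriobacteriia and Rubrobacteria (expected ≈ 69 flagellated ≈ 13%);
F1 systems with FlgFG in basal classes, F5 (occasionally F9) without
FlgFG in later ones; 55% of flagellated Actinomycetia lack chemotaxis
genes entirely (expected ≈ 14 such genomes); GGDEF counts drawn from
negative binomials (dispersion k = 2 — a Poisson cannot produce the
observed 0-to-80 spread) with ecology means {host-associated 4, other
10, sea/terrestrial-water 14, soil 16}, a ×1.8 factor for flagellated
genomes, and mean 55 with tighter dispersion (k = 12) for
zoospore-forming genomes so they top the census without running away;
exactly one flagellated genome per cohort carries a +8-point cluster
GC offset, all others a sub-threshold jitter (σ = 0.6, clipped at
±2). Tree pairs plant k ≤ 3 non-overlapping regrafts: a moved leaf is
reattached as sister to a pure ≥ 2-leaf clade of an unused foreign
class, which provably leaves every unmoved leaf's detection context
intact.

All randomness descends from a single integer seed; identical seeds
give byte-identical bundles.

**What passing tests do and do not show.** Exact recovery on
noise-free cohorts demonstrates that the rules are implemented
self-consistently and invert the generator, not that they are robust
to real annotation noise (mispredicted gene boundaries, chimeric
contigs, divergent homologs below the E-value floor, fragmented
operons). The noisy default cohort exercises graceful degradation
(ambiguous paralogs, partial calls) but is still far cleaner than real
RefSeq + MAG data.

## Problem sizes and numerics

The test suite runs the full pipeline on a quarter-scale (~135-genome)
noise-free cohort and enumerates the flagellated-rule truth table over
all core-state combinations with ≤ 3 non-present cells (57,205 cases)
and the RF axioms over all 15 five-leaf topologies; the acceptance
script uses the full 538-genome cohort. Both finish in seconds on one
CPU. Floating-point comparisons appear only in GC arithmetic (exact
rational counts divided once) and the rank test; all calling rules are
integer/threshold logic with documented strictness (E-value `<`, GC
difference `>`).

## Known limitations

* F7/F9/ACF signatures are component-set placeholders; genuine
  discrimination needs profile-level evidence.
* Heptad-class assignment ignores sub-class structure (e.g. 36H vs
  38H receptors differing by indel position, not just length).
* Transfer detection is a topological screen; it does not model
  incomplete lineage sorting or estimate support for the transfer.
* The QC filter consumes completeness/contamination values; it does
  not compute them.
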