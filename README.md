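# flagscan

Comparative-genomics toolkit for studying the evolution of flagellar
motility and chemosensory signaling in the phylum *Actinobacteria*.

## The scientific problem

Very few actinobacterial species are flagellated, and the pattern of
flagellar gene retention and loss across the phylum's nine classes
carries the signal of how motility degenerated: basal, mostly aquatic
classes keep a full flagellar gene cluster including the distal-rod
genes *flgF*/*flgG*, while the later lineage (Acidimicrobiia,
Nitriliruptoria, Actinomycetia) lost FlgFG — and, in parallel, swapped
its chemosensory system from the F1 class (diagnosed by the auxiliary
proteins CheC and CheD, cognate 44H chemoreceptors) to the F5 class
(conserved operon order `A:W W … B R`, a CheA kinase with an extra CheW
domain, cognate 38H receptors).

`flagscan` turns that analysis into a tested, reusable pipeline over
per-genome annotation bundles (GFF3 coordinates, homology hits in
12-column tabular form, HMMER-style domain tables, genome metadata,
Newick trees). It implements:

* **Registry** — the 50-gene flagellar query catalog with its 24-gene
  ancient core (after Liu & Ochman), chemosensory F-class signatures,
  and chemoreceptor heptad-length classes, serializable as plain text.
* **Flagellar calling** — best-hit gene labeling at E < 1e-5;
  FlgE/FlgF/FlgG paralog disambiguation from the conserved
  *flgD–flgE* and *flgF–flgG* gene order; a four-state
  presence/absence matrix (present / absent / pseudogene / partial);
  and the flagellated-species rule: a complete or draft genome is
  flagellated iff all 24 core genes are non-absent with at most two
  core pseudogenes; a MAG iff ≥ 10 of 24 core genes are present.
* **Chemosensory classification** — operon detection, F1/F5/F7/F9/ACF
  assignment with an evidence trail, heptad-class binning of receptor
  signaling-domain lengths (length/7 nearest class, ±2 heptads), and a
  cognate-matching report (F1↔44H, F5↔38H, …).
* **Evolutionary screens** — GC% of the major flagellar cluster vs the
  genome (a strict >5-point difference flags candidate horizontal
  transfer) and a census of GGDEF-domain (diguanylate cyclase)
  proteins compared across ecology/flagellation groups with a
  Mann-Whitney rank test.
* **Tree concordance** — Robinson-Foulds distance between species and
  flagellar trees, and detection of leaves whose gene-tree
  neighborhood belongs to a foreign taxonomic class (candidate
  inter-class transfers).
* **Synthetic data** — a seeded generator that emits complete
  annotation bundles with planted ground truth for every quantity the
  pipeline estimates, so the whole analysis is testable without
  downloading genomes.

## Worked example

Simulate a small cohort with planted ground truth, then run the whole
pipeline on it:

```bash
$ flagscan simulate --out-dir demo --seed 42 --n-scale 0.05
wrote 30 genomes and a tree pair (1 planted transfer(s)) to demo

$ flagscan run-all --input-dir demo --out-dir demo_out
{
 "flagellar_gene_count_range": [34, 34],
 "flagellated_count": 5,
 "flagellated_percent": 17,
 "flagellated_without_chemotaxis": 0,
 "ggdef_range": [0, 43],
 ...
 "hgt_flagged": 1,
 "total_genomes": 30,
 ...
}
```

Reading the summary: 5 of the 30 genomes carry a complete core gene
set and are called flagellated (17%); flagellated complete genomes
carry 34 flagellar genes each (this small draw contains only
FlgFG-less flagellated genomes; FlgFG-bearing basal genomes carry 40);
exactly one genome's flagellar cluster deviates from its genome GC by
more than 5 points (the planted horizontal-transfer signal); GGDEF
counts span 0–43. `demo_out/` holds the per-genome tables behind every
number: `presence_matrix.tsv` (cells `1`/`0`/`P`/`H` for
present/absent/pseudogene/partial), `flagellar_calls.tsv`,
`chemo_systems.tsv`, `receptors.tsv`, `cognate_report.tsv`,
`gc_screen.tsv`, `ggdef_census.tsv`, `tree_transfers.tsv`, and
`summary.json`.

The same stages are available individually (`call-flagella`,
`classify-chemo`, `hgt-screen`, `ggdef-census`, `tree-concordance`,
`ingest`) and as library functions; real annotation bundles are
analyzed by laying them out in the same directory structure.

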