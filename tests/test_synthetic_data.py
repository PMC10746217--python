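import numpy as np
import pytest

from flagscan import annotation_io as aio
from flagscan import chemosensory as chemo
from flagscan import flagellar as flg
from flagscan import synthetic_data as synth


def write_and_read(bundle, tmp_path, gid):
    bundle.write(str(tmp_path))
    calls = aio.read_gff(str(tmp_path / f"{gid}.gff"), gid)
    hits = aio.read_tabular_hits(str(tmp_path / f"{gid}_hits.tsv"))
    doms = aio.read_domain_hits(str(tmp_path / f"{gid}_domains.tbl"))
    seqs = aio.read_fasta(str(tmp_path / f"{gid}.fna"))
    return calls, hits, doms, seqs


def test_same_seed_identical_bundles():
    spec = synth.GenomeSpec(genome_id="G", flagellated=True,
                            include_flgFG=True, f_class="F1",
                            n_ggdef=5, seed=99)
    b1, t1 = synth.generate_genome(spec)
    b2, t2 = synth.generate_genome(spec)
    assert b1.gff_text == b2.gff_text
    assert b1.nucleotide_fasta == b2.nucleotide_fasta
    assert b1.hits_text == b2.hits_text
    assert b1.domains_text == b2.domains_text
    assert t1 == t2


def test_contradictory_spec_rejected():
    spec = synth.GenomeSpec(genome_id="G", flagellated=False,
                            include_flgFG=True)
    with pytest.raises(ValueError, match="contradictory"):
        synth.generate_genome(spec)


def test_fixtures_parse_with_pipeline_readers(tmp_path, registry):
    spec = synth.GenomeSpec(genome_id="G", flagellated=True,
                            include_flgFG=True, f_class="F5",
                            n_receptors={"38H": 3}, n_ggdef=4, seed=5)
    bundle, truth = synth.generate_genome(spec)
    calls, hits, doms, seqs = write_and_read(bundle, tmp_path, "G")
    assert len(calls) > 40 and hits and doms
    assert sum(len(s) for s in seqs.values()) == bundle.meta.genome_size

    labeled = flg.disambiguate_rod_hook(
        flg.assign_labels(hits, calls, registry=registry)
    )
    matrix = flg.build_matrix({"G": labeled}, registry)
    row = matrix.row("G")
    assert all(row[g] == "present" for g in registry.core_gene_set())
    # planted paralog identities recovered from gene order
    by_locus = {c.locus_tag: c.label for c in labeled}
    for sym, locus in truth["efg_loci"].items():
        assert by_locus[locus] == sym

    systems, receptors = chemo.detect_systems(labeled, doms)
    systems = [chemo.classify_f_class(s, registry) for s in systems]
    assert [s.f_class for s in systems] == ["F5"]
    assert len(receptors) == 4  # 3 scattered + 1 in the operon


def test_f5_operon_order_matches_model(registry):
    spec = synth.GenomeSpec(genome_id="G", flagellated=True, f_class="F5",
                            seed=7)
    bundle, _ = synth.generate_genome(spec)
    assert "CheA" in bundle.hits_text
    # the planted template is the conserved A:W W ... B R arrangement
    assert synth.OPERON_TEMPLATES["F5"][0] == "CheA:W"
    assert synth.OPERON_TEMPLATES["F5"][-2:] == ("CheB", "CheR")


def test_cluster_gc_offset_shifts_composition(tmp_path, registry):
    spec = synth.GenomeSpec(genome_id="G", flagellated=True,
                            include_flgFG=True, cluster_gc_offset=8.0,
                            genome_gc=60.0, seed=3)
    bundle, truth = synth.generate_genome(spec)
    assert truth["hgt_flag"]
    calls, hits, _, seqs = write_and_read(bundle, tmp_path, "G")
    labeled = flg.disambiguate_rod_hook(
        flg.assign_labels(hits, calls, registry=registry)
    )
    cluster = flg.detect_major_cluster(labeled, registry=registry)
    seq = seqs[cluster.major.contig_id][cluster.major.start - 1:cluster.major.end]
    from flagscan.evolution_screens import gc_content

    assert gc_content(seq) == pytest.approx(68.0, abs=1.0)


def test_mag_truncation_drops_and_splits(tmp_path):
    spec = synth.GenomeSpec(genome_id="M", tax_class="Ca_Aquicultoria",
                            assembly_level="MAG", flagellated=True,
                            include_flgFG=True, mag_retention=0.6, seed=21)
    bundle, truth = synth.generate_genome(spec)
    calls, _, _, seqs = write_and_read(bundle, tmp_path, "M")
    assert len(seqs) > 1  # fragmented assembly
    assert len(truth["efg_loci"]) <= 3
    statuses = {c.status for c in calls}
    assert "partial" in statuses  # contig-edge truncations planted


def test_cohort_profile_contrast():
    profiles = {
        k: synth.DEFAULT_PROFILES[k]
        for k in ("Thermoleophilia", "Actinomycetia")
    }
    cohort = synth.generate_cohort(
        profiles=profiles,
        n_per_class={"Thermoleophilia": 60, "Actinomycetia": 100},
        seed=3, noise_free=True,
    )
    frac = {}
    for cls in profiles:
        flags = [
            t["flagellated"] for t in cohort.truth.genomes.values()
            if t["tax_class"] == cls
        ]
        frac[cls] = np.mean(flags)
    assert frac["Thermoleophilia"] > frac["Actinomycetia"]


def test_cohort_ggdef_ecology_ordering():
    cohort = synth.generate_cohort(
        n_per_class={c: max(1, p.n // 4) for c, p in
                     synth.DEFAULT_PROFILES.items()},
        seed=12, noise_free=True,
    )
    host, free = [], []
    for t in cohort.truth.genomes.values():
        (host if t["ecology"] == "host_associated" else free).append(t["n_ggdef"])
    assert np.mean(host) < np.mean(free)


def test_cohort_determinism():
    n = {c: 2 for c in synth.DEFAULT_PROFILES}
    c1 = synth.generate_cohort(n_per_class=n, seed=8)
    c2 = synth.generate_cohort(n_per_class=n, seed=8)
    assert c1.truth.to_json() == c2.truth.to_json()
    assert c1.genomes[0].gff_text == c2.genomes[0].gff_text


def test_tree_pair_determinism_and_truth():
    sp1, gn1, tr1 = synth.generate_tree_pair(24, k_transfers=2, seed=13)
    sp2, gn2, tr2 = synth.generate_tree_pair(24, k_transfers=2, seed=13)
    assert tr1 == tr2 and len(tr1) == 2
    assert {t["leaf"] for t in tr1} <= sp1.leaf_labels
    from flagscan.tree_analysis import robinson_foulds

    assert robinson_foulds(sp1, sp2)[0] == 0
    assert robinson_foulds(gn1, gn2)[0] == 0


def test_tree_pair_infeasible_k():
    with pytest.raises(ValueError):
        synth.generate_tree_pair(8, k_transfers=3, seed=1)
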