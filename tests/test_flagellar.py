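from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from flagscan import flagellar as flg
from flagscan.annotation_io import GenomeMeta, HomologyHit
from flagscan.registry import AMBIGUOUS_EFG

from conftest import make_calls


def hit(q, locus, evalue, bitscore=100.0):
    return HomologyHit(query_symbol=q, subject_locus=locus,
                       percent_identity=50.0, alignment_length=300,
                       evalue=evalue, bitscore=bitscore)


class TestAssignLabels:
    def test_best_evalue_wins(self, registry):
        calls = make_calls("G", ["unassigned"])
        locus = calls[0].locus_tag
        hits = [hit("FliM", locus, 1e-8), hit("FliN", locus, 1e-12)]
        out = flg.assign_labels(hits, calls, registry=registry)
        assert out[0].label == "FliN"

    def test_tie_broken_by_bitscore_then_symbol(self, registry):
        calls = make_calls("G", ["unassigned"])
        locus = calls[0].locus_tag
        hits = [hit("FliM", locus, 1e-8, 90), hit("FliN", locus, 1e-8, 120)]
        assert flg.assign_labels(hits, calls, registry=registry)[0].label == "FliN"
        hits = [hit("FliN", locus, 1e-8, 90), hit("FliM", locus, 1e-8, 90)]
        assert flg.assign_labels(hits, calls, registry=registry)[0].label == "FliM"

    def test_threshold_is_strict(self, registry):
        calls = make_calls("G", ["unassigned"])
        locus = calls[0].locus_tag
        out = flg.assign_labels([hit("FliF", locus, 1e-4)], calls,
                                registry=registry)
        assert out[0].label == "unassigned"
        out = flg.assign_labels([hit("FliF", locus, 1e-5)], calls,
                                registry=registry)
        assert out[0].label == "unassigned"  # cutoff is < 1e-5, not <=
        out = flg.assign_labels([hit("FliF", locus, 9e-6)], calls,
                                registry=registry)
        assert out[0].label == "FliF"

    def test_alias_resolution(self, registry):
        calls = make_calls("G", ["unassigned"])
        out = flg.assign_labels([hit("FlaG", calls[0].locus_tag, 1e-30)],
                                calls, registry=registry)
        assert out[0].label == "YvyC"

    def test_orphan_hit_rejected(self, registry):
        calls = make_calls("G", ["unassigned"])
        with pytest.raises(ValueError, match="ghost"):
            flg.assign_labels([hit("FliF", "ghost", 1e-30)], calls,
                              registry=registry)


class TestDisambiguateRodHook:
    def test_flgd_neighbor_becomes_flge(self):
        calls = make_calls("G", ["FlgC", "FlgD", "FlgE", "FliK"])
        out = flg.disambiguate_rod_hook(calls)
        assert out[2].label == "FlgE"

    def test_pair_without_flgd_becomes_f_then_g(self):
        # provisional labels are arbitrary within the paralog group
        calls = make_calls("G", ["FliD", "FlgG", "FlgE", "FliS"])
        out = flg.disambiguate_rod_hook(calls)
        assert [c.label for c in out] == ["FliD", "FlgF", "FlgG", "FliS"]

    def test_pair_on_minus_strand_reversed(self):
        calls = make_calls("G", ["FliD", "FlgE", "FlgF", "FliS"], strand="-")
        out = flg.disambiguate_rod_hook(calls)
        # transcription runs right-to-left: FlgF is the right-hand gene
        assert [c.label for c in out] == ["FliD", "FlgG", "FlgF", "FliS"]

    def test_isolated_candidate_ambiguous(self):
        calls = make_calls("G", ["FlgE"])
        assert flg.disambiguate_rod_hook(calls)[0].label == AMBIGUOUS_EFG

    def test_full_cluster_resolves_all_three(self):
        labels = ["FlgB", "FlgC", "FlgD", "FlgG", "FliK", "FlgK", "FlgL",
                  "FlgN", "FliC", "FliD", "FlgE", "FlgF"]
        # provisional EFG labels scrambled: position decides identity
        out = flg.disambiguate_rod_hook(make_calls("G", labels))
        assert out[3].label == "FlgE"     # next to FlgD
        assert out[10].label == "FlgF"    # adjacent pair, upstream
        assert out[11].label == "FlgG"

    def test_loci_conserved(self):
        calls = make_calls("G", ["FlgD", "FlgE", "FlgF", "FlgG", "FliC"])
        out = flg.disambiguate_rod_hook(calls)
        assert Counter(c.locus_tag for c in out) == Counter(
            c.locus_tag for c in calls
        )
        assert sum(c.label in ("FlgF", "FlgG") for c in out) <= 2


class TestMatrixAndCalls:
    def test_build_matrix_precedence(self, registry):
        calls = make_calls("G", ["FliC", "FliC"], statuses={0: "pseudogene"})
        m = flg.build_matrix({"G": calls}, registry)
        assert m.cell("G", "FliC") == "present"
        assert m.cell("G", "MotA") == "absent"
        assert m.genes == registry.gene_order

    def test_pseudogene_only_cell(self, registry):
        calls = make_calls("G", ["FliC"], statuses={0: "pseudogene"})
        m = flg.build_matrix({"G": calls}, registry)
        assert m.cell("G", "FliC") == "pseudogene"

    def _row(self, registry, absent=(), pseudo=(), partial=()):
        row = {}
        for g in registry.gene_order:
            if g in absent:
                row[g] = "absent"
            elif g in pseudo:
                row[g] = "pseudogene"
            elif g in partial:
                row[g] = "partial"
            else:
                row[g] = "present"
        return row

    def test_complete_rule(self, registry, complete_meta):
        full = self._row(registry)
        assert flg.call_flagellated(full, complete_meta, registry).flagellated
        two_pseudo = self._row(registry, pseudo=("FliC", "MotA"))
        assert flg.call_flagellated(two_pseudo, complete_meta, registry).flagellated
        three_pseudo = self._row(registry, pseudo=("FliC", "MotA", "FliM"))
        assert not flg.call_flagellated(
            three_pseudo, complete_meta, registry
        ).flagellated
        one_absent = self._row(registry, absent=("FliF",))
        assert not flg.call_flagellated(one_absent, complete_meta, registry).flagellated

    def test_partial_counts_as_present(self, registry, complete_meta):
        row = self._row(registry, partial=("FliC", "FlgE", "FlgK"))
        call = flg.call_flagellated(row, complete_meta, registry)
        assert call.flagellated and call.core_present == 24

    def test_optional_core_exemption(self, registry, complete_meta):
        row = self._row(registry, absent=("FlgF", "FlgG"))
        strict = flg.call_flagellated(row, complete_meta, registry)
        assert not strict.flagellated
        exempt = flg.call_flagellated(
            row, complete_meta, registry, optional_core={"FlgF", "FlgG"}
        )
        assert exempt.flagellated

    def test_mag_rule(self, registry, mag_meta):
        core = sorted(registry.core_gene_set())
        row = self._row(registry, absent=core[10:])  # 10 core present
        call = flg.call_flagellated(row, mag_meta, registry)
        assert call.flagellated and call.tier == "mag_rule"
        assert not call.representative_candidate
        row9 = self._row(registry, absent=core[9:])
        assert not flg.call_flagellated(row9, mag_meta, registry).flagellated
        row20 = self._row(registry, absent=core[20:])
        assert flg.call_flagellated(row20, mag_meta, registry).representative_candidate

    def test_unknown_assembly_level(self, registry):
        meta = GenomeMeta(genome_id="X", genome_size=10)
        object.__setattr__(meta, "assembly_level", "hologram")
        with pytest.raises(ValueError, match="hologram"):
            flg.call_flagellated(self._row(registry), meta, registry)

    def test_count_flagellar_genes(self, registry):
        genes = registry.gene_order
        row = {g: "absent" for g in genes}
        assert flg.count_flagellar_genes(row) == 0
        for g in genes[:30]:
            row[g] = "present"
        for g in genes[30:32]:
            row[g] = "pseudogene"
        assert flg.count_flagellar_genes(row) == 32
        assert flg.count_flagellar_genes({g: "present" for g in genes}) == 50

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_monotonicity(self, registry, data):
        """Upgrading any core cell toward 'present' never revokes a call."""
        core = sorted(registry.core_gene_set())
        states = data.draw(
            st.lists(
                st.sampled_from(["present", "absent", "pseudogene", "partial"]),
                min_size=24, max_size=24,
            )
        )
        row = {g: "present" for g in registry.gene_order}
        row.update(dict(zip(core, states)))
        upgrade_gene = data.draw(st.sampled_from(core))
        level = data.draw(st.sampled_from(["complete", "MAG"]))
        meta = GenomeMeta(genome_id="G", assembly_level=level,
                          completeness=90, genome_size=10)
        before = flg.call_flagellated(row, meta, registry).flagellated
        row[upgrade_gene] = "present"
        after = flg.call_flagellated(row, meta, registry).flagellated
        assert after >= before


class TestClusterDetection:
    def test_one_contiguous_cluster(self, registry):
        labels = list(registry.gene_order[:30])
        res = flg.detect_major_cluster(make_calls("G", labels), registry=registry)
        assert res.major.n_genes == 30 and res.outlier_loci == []

    def test_outliers_far_away(self, registry):
        labels = list(registry.gene_order[:28])
        calls = make_calls("G", labels)
        far = make_calls("G", ["FliC", "FliD"], start=calls[-1].end + 500_000)
        res = flg.detect_major_cluster(calls + far, registry=registry)
        assert res.major.n_genes == 28
        assert len(res.outlier_loci) == 2 and not res.tie

    def test_equal_clusters_tie_reported(self, registry):
        a = make_calls("G", registry.gene_order[:15], contig="c1")
        b = make_calls("G", registry.gene_order[15:30], contig="c2")
        res = flg.detect_major_cluster(a + b, registry=registry)
        assert res.tie and res.major.n_genes == 15

    def test_no_flagellar_calls(self, registry):
        res = flg.detect_major_cluster(
            make_calls("G", ["unassigned"] * 3), registry=registry
        )
        assert res.major is None and res.clusters == []
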