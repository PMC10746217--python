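import pytest

from flagscan import chemosensory as chemo
from flagscan.annotation_io import DomainHit

from conftest import make_calls


def dom(locus, name, start, end):
    return DomainHit(protein_locus=locus, domain_name=name,
                     env_start=start, env_end=end, score=80.0)


def chew_on(locus):
    return dom(locus, "CheW", 300, 440)


def mcp_signal(locus, length, offset=200):
    return dom(locus, "MCPsignal", offset, offset + length - 1)


class TestDetectSystems:
    def test_f5_operon_order_string(self):
        calls = make_calls("G", ["CheA", "CheW", "MCP", "CheY", "CheB", "CheR"])
        doms = [chew_on(calls[0].locus_tag), mcp_signal(calls[2].locus_tag, 266)]
        systems, receptors = chemo.detect_systems(calls, doms)
        assert len(systems) == 1
        assert systems[0].order_string == "A:W W M Y B R"
        assert systems[0].has_kinase_variant
        assert len(receptors) == 1
        assert receptors[0].signaling_domain_length == 266

    def test_minus_strand_operon_reads_transcriptionally(self):
        calls = make_calls("G", ["CheR", "CheB", "CheY", "MCP", "CheW", "CheA"],
                           strand="-")
        doms = [chew_on(calls[-1].locus_tag)]
        systems, _ = chemo.detect_systems(calls, doms)
        assert systems[0].order_string == "A:W W M Y B R"

    def test_scattered_receptors_are_not_systems(self):
        calls = make_calls("G", ["MCP", "unassigned", "unassigned", "unassigned",
                                 "unassigned", "unassigned", "unassigned", "MCP",
                                 "unassigned", "unassigned", "unassigned",
                                 "unassigned", "unassigned", "unassigned", "MCP"])
        systems, receptors = chemo.detect_systems(calls, [])
        assert systems == [] and len(receptors) == 3

    def test_gap_rule_splits_systems(self):
        labels = (["CheA", "CheW", "CheB", "CheR"]
                  + ["unassigned"] * 50
                  + ["CheA", "CheW", "CheY"])
        systems, _ = chemo.detect_systems(make_calls("G", labels), [])
        assert len(systems) == 2


class TestChemotaxisSet:
    def test_core_four_present(self):
        calls = make_calls("G", ["MCP", "CheA", "CheW", "CheY"])
        assert chemo.has_chemotaxis_set(calls)

    def test_missing_receptor(self):
        calls = make_calls("G", ["CheA", "CheW", "CheY"])
        assert not chemo.has_chemotaxis_set(calls)

    def test_no_chemo_genes_at_all(self):
        assert not chemo.has_chemotaxis_set(make_calls("G", ["FliC", "MotA"]))


class TestClassifyFClass:
    def _system(self, components, order=None):
        return chemo.ChemoSystem(
            genome_id="G", contig_id="c1",
            member_loci=tuple(f"l{i}" for i in range(len(components))),
            components=tuple(components),
            order_string=order or " ".join(
                chemo.COMPONENT_LETTERS[c] for c in components
            ),
        )

    def test_f1_by_diagnostic_components(self, registry):
        s = self._system(["CheA", "CheW", "CheC", "CheD", "CheB", "CheR"])
        out = chemo.classify_f_class(s, registry)
        assert out.f_class == "F1" and "CheC" in out.evidence

    def test_f5_by_kinase_and_order(self, registry):
        s = self._system(["CheA:W", "CheW", "MCP", "CheY", "CheB", "CheR"])
        assert chemo.classify_f_class(s, registry).f_class == "F5"

    def test_wrong_order_is_not_f5(self, registry):
        s = self._system(["CheR", "CheA:W", "CheW", "CheB"])
        out = chemo.classify_f_class(s, registry)
        assert out.f_class != "F5"

    def test_unclassified_plain_system(self, registry):
        s = self._system(["CheR", "CheA", "CheW", "CheB"], order="R A W B")
        out = chemo.classify_f_class(s, registry)
        # matches the ACF placeholder component set but no motile class
        assert out.f_class not in ("F1", "F5", "F7", "F9")

    def test_f1_precedence_over_f5(self, registry):
        s = self._system(
            ["CheA:W", "CheW", "CheC", "CheD", "CheB", "CheR"]
        )
        out = chemo.classify_f_class(s, registry)
        assert out.f_class == "F1" and "F5" in out.evidence  # conflict recorded

    def test_f7_f9_placeholders(self, registry):
        f7 = self._system(["CheA", "CheW", "MCP", "CheB", "CheR", "CheY"])
        assert chemo.classify_f_class(f7, registry).f_class == "F7"
        f9 = self._system(["CheA", "CheW", "CheX", "MCP", "CheB", "CheR", "CheY"])
        assert chemo.classify_f_class(f9, registry).f_class == "F9"


class TestReceptorHClass:
    def rec(self, length):
        return chemo.ChemoreceptorRecord(
            genome_id="G", protein_locus="p", signaling_domain_length=length
        )

    @pytest.mark.parametrize("length,expected", [
        (308, "44H"),   # 44 x 7
        (266, "38H"),   # 38 x 7
        (252, "36H"),
        (280, "40H"),
        (150, "unassigned"),
    ])
    def test_examples(self, registry, length, expected):
        out = chemo.classify_receptor_h(self.rec(length), registry)
        # independent nearest-class check over the registry table
        heptads = length / 7
        best = min(registry.h_classes.values(),
                   key=lambda h: (abs(h.heptad_count - heptads), h.heptad_count))
        oracle = (best.label if abs(best.heptad_count - heptads) <= best.tolerance
                  else "unassigned")
        assert out.h_class == expected == oracle

    @pytest.mark.parametrize("delta", [-6, -3, 3, 6])
    def test_stable_under_small_perturbation(self, registry, delta):
        base = chemo.classify_receptor_h(self.rec(308), registry).h_class
        shifted = chemo.classify_receptor_h(self.rec(308 + delta), registry).h_class
        assert shifted == base == "44H"

    def test_non_positive_length_rejected(self, registry):
        with pytest.raises(ValueError):
            chemo.classify_receptor_h(self.rec(0), registry)


class TestCognateReport:
    def test_modal_match(self, registry):
        systems = [
            chemo.ChemoSystem("G", "c1", ("a",), ("CheA",), "A", f_class="F1")
        ]
        receptors = [
            chemo.ChemoreceptorRecord("G", f"p{i}", 308, h_class="44H")
            for i in range(10)
        ] + [chemo.ChemoreceptorRecord("G", "q", 266, h_class="38H")]
        df = chemo.cognate_report(systems, receptors, registry)
        row = df[df.f_class == "F1"].iloc[0]
        assert row.modal_h == "44H" and bool(row.match)
        assert row["44H"] == 10 and row["38H"] == 1

    def test_genome_without_systems(self, registry):
        receptors = [chemo.ChemoreceptorRecord("G", "p", 266, h_class="38H")]
        df = chemo.cognate_report([], receptors, registry)
        assert len(df) == 1 and df.iloc[0].f_class == "-"
        assert df.iloc[0].n_receptors == 1
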