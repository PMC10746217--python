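import pytest

from flagscan.annotation_io import GeneCall, GenomeMeta
from flagscan.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


def make_calls(genome_id, labels, contig="c1", strand="+", start=1, gene_len=900,
               spacer=100, statuses=None):
    """Lay out labeled genes left-to-right on one contig."""
    calls = []
    pos = start
    for i, label in enumerate(labels):
        calls.append(
            GeneCall(
                genome_id=genome_id,
                contig_id=contig,
                start=pos,
                end=pos + gene_len - 1,
                strand=strand,
                locus_tag=f"{genome_id}_{i + 1:03d}",
                label=label,
                status=(statuses or {}).get(i, "present"),
            )
        )
        pos += gene_len + spacer
    return calls


@pytest.fixture
def complete_meta():
    return GenomeMeta(genome_id="G1", assembly_level="complete",
                      genome_size=1000)


@pytest.fixture
def mag_meta():
    return GenomeMeta(genome_id="M1", assembly_level="MAG", completeness=85,
                      genome_size=1000)
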