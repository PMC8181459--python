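import pytest

from ystrkit.alleles import AlleleValue
from ystrkit.haplotypes import Haplotype, HaplotypeTable, LocusCall
from ystrkit.panel import PanelConfig


@pytest.fixture
def small_panel() -> PanelConfig:
    """Four-locus panel with one multi-copy locus, for compact fixtures."""
    return PanelConfig(
        loci=("DYS19", "DYS390", "DYS391", "DYS385a/b"),
        multicopy_loci=frozenset({"DYS385a/b"}),
    )


def make_haplotype(panel, sample_id, population, allele_map):
    """allele_map: locus -> int | float | list | None (None = missing)."""

    def to_allele(v):
        return AlleleValue.parse(str(v))

    calls = {}
    for locus in panel.loci:
        v = allele_map[locus]
        if v is None:
            calls[locus] = LocusCall(locus, missing=True)
        elif isinstance(v, (list, tuple)):
            calls[locus] = LocusCall(locus, tuple(to_allele(x) for x in v))
        else:
            calls[locus] = LocusCall(locus, (to_allele(v),))
    return Haplotype(sample_id, population, calls)


@pytest.fixture
def make_table(small_panel):
    """Factory: rows of (sample_id, population, allele_map) -> table."""

    def build(rows):
        return HaplotypeTable(
            small_panel, [make_haplotype(small_panel, *row) for row in rows]
        )

    return build
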