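import pytest

from reanalyzer.models import (
    Affection,
    Consequence,
    Origin,
    SampleInfo,
    Sex,
    VariantRecord,
)


@pytest.fixture
def trio():
    """A standard trio: affected proband, unaffected parents."""
    return [
        SampleInfo("kid", "F1", father_id="dad", mother_id="mom", sex=Sex.female,
                   affection=Affection.affected, is_proband=True),
        SampleInfo("dad", "F1", sex=Sex.male, affection=Affection.unaffected),
        SampleInfo("mom", "F1", sex=Sex.female, affection=Affection.unaffected),
    ]


def make_variant(
    pos=1000,
    gene="SG001",
    consequence=Consequence.missense,
    genotypes=None,
    chrom="chr1",
    ref="A",
    alt="G",
    origin=Origin.autosomal,
):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        transcript=f"NM_{gene}.1", hgvs_c=f"c.{pos}{ref}>{alt}",
        consequence=consequence, genotypes=genotypes or {"kid": 1, "dad": 0, "mom": 0},
        origin=origin,
    )


@pytest.fixture
def variant_factory():
    return make_variant
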