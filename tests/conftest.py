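import pytest

from synclone.variant_io import SomaticVariant


def make_variant(
    vid="v1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="",
    consequence="missense",
    adenoma=(60, 0),
    carcinoma=(60, 0),
    normal=(60, 0),
):
    return SomaticVariant(
        id=vid,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        depths={"adenoma": adenoma, "carcinoma": carcinoma, "normal": normal},
    )


@pytest.fixture
def variant_factory():
    return make_variant
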