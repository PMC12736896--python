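import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from prickleid import (
    FragmentRecord,
    Organ,
    PrickleType,
    ReferenceCollection,
)


def record(taxon, t1=0, t2=0, to=0, length=5.0, organ=Organ.STEM, source=""):
    return FragmentRecord(
        taxon=taxon,
        organ=organ,
        length_cm=length,
        counts={PrickleType.T1: t1, PrickleType.T2: t2, PrickleType.TO: to},
        source_id=source,
    )


@pytest.fixture
def tiny_collection():
    """Two taxa, three fragments, both organs — the smallest interesting set."""
    return ReferenceCollection(
        records=[
            record("R. moschata Herrm.", t1=4, length=4.0, source="m1"),
            record("R. moschata Herrm.", t1=3, t2=1, length=6.0, source="m2"),
            record(
                "R. foetida Herrm.", t2=5, to=1, length=5.0,
                organ=Organ.LEAF_RACHIS, source="f1",
            ),
        ]
    )
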