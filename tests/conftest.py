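import random

import pytest

from clonetriage.variants import (
    GenomicInterval,
    SampleVariantSet,
    VariantCall,
    VariantKey,
    classify_variant_type,
)


def make_call(
    chrom="1", start=100, ref="A", alt="G", depth=120, alt_reads=50, **kw
) -> VariantCall:
    return VariantCall(
        interval=GenomicInterval(chrom, start, start + len(ref)),
        vtype=classify_variant_type(ref, alt),
        ref_allele=ref,
        alt_allele=alt,
        position_read_depth=depth,
        alt_read_count=alt_reads,
        normalized=True,
        **kw,
    )


def random_call(rng: random.Random, chrom="1") -> VariantCall:
    """A random normalized SNV/indel/sub at a random position."""
    pos = rng.randrange(10, 10_000)
    kind = rng.choice(["snv", "ins", "del", "sub"])
    bases = "ACGT"
    if kind == "snv":
        ref = rng.choice(bases)
        alt = rng.choice([b for b in bases if b != ref])
    elif kind == "ins":
        ref, alt = "", "".join(rng.choice(bases) for _ in range(rng.randint(1, 3)))
    elif kind == "del":
        ref, alt = "".join(rng.choice(bases) for _ in range(rng.randint(1, 3))), ""
    else:
        ref = "".join(rng.choice(bases) for _ in range(2))
        while True:
            alt = "".join(rng.choice(bases) for _ in range(2))
            if alt[0] != ref[0] and alt[1] != ref[1]:
                break
    depth = rng.randint(1, 300)
    return make_call(
        chrom, pos, ref, alt, depth=depth, alt_reads=rng.randint(0, depth)
    )


def random_sample(rng: random.Random, role: str, n: int) -> SampleVariantSet:
    s = SampleVariantSet(f"rand_{role}", role)
    while len(s) < n:
        c = random_call(rng)
        if c.key not in s:
            s.add(c)
    return s


@pytest.fixture
def rng():
    return random.Random(20260927)
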