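import numpy as np
import pytest

from numtshadow import (
    MitoReference,
    NumtRecord,
    World,
    generate_mito_reference,
    plant_heteroplasmy,
    sample_heteroplasmy,
    generate_numts,
)
from numtshadow._util import random_dna, revcomp


@pytest.fixture(scope="session")
def mito16k() -> MitoReference:
    return generate_mito_reference(16_569, seed=101)


@pytest.fixture(scope="session")
def mito2k() -> MitoReference:
    return generate_mito_reference(2_000, seed=7)


def make_numt(
    world: World,
    mito_start: int,
    length: int,
    mutations: dict[int, str] | None = None,
    numt_id: str = "numtX",
    strand: str = "+",
    flank: int = 500,
    copy_number: int = 2,
) -> NumtRecord:
    """Hand-built NUMT with exact mutations (mito coordinate -> new base),
    appended to the world's contigs."""
    mutations = mutations or {}
    L = world.mito.length
    seq = list(world.mito.segment(mito_start, mito_start + length))
    for pos, base in mutations.items():
        off = (pos - mito_start) % L
        assert off < length
        assert seq[off] != base, "mutation must change the base"
        seq[off] = base
    numt_seq = "".join(seq)
    embedded = revcomp(numt_seq) if strand == "-" else numt_seq
    rng = np.random.default_rng(hash(numt_id) % (2**31))
    contig_name = f"nuc_{numt_id}"
    contig = random_dna(rng, flank) + embedded + random_dna(rng, flank)
    record = NumtRecord(
        numt_id=numt_id,
        mito_start=mito_start,
        mito_end=mito_start + length,
        nuclear_contig=contig_name,
        nuclear_offset=flank,
        similarity=1 - len(mutations) / length if mutations else 0.999,
        strand=strand,
        copy_number=copy_number,
        mismatch_positions=frozenset(p % L for p in mutations),
    )
    world.nuclear_contigs[contig_name] = contig
    world.numts.append(record)
    return record


def make_world(
    mito: MitoReference,
    het_spec: list[tuple[int, str, float]] | None = None,
    n_numts: int = 0,
    seed: int = 0,
    **numt_kwargs,
) -> World:
    truth = plant_heteroplasmy(mito, het_spec) if het_spec else []
    if n_numts:
        numts, contigs = generate_numts(mito, n_numts, seed=seed, **numt_kwargs)
    else:
        numts, contigs = [], {}
    return World(mito=mito, truth=truth, numts=numts, nuclear_contigs=contigs, rng_seed=seed)


@pytest.fixture()
def alt_of():
    """First base differing from the reference base at a position."""

    def _alt(mito: MitoReference, position: int) -> str:
        ref = mito.sequence[position]
        return next(b for b in "ACGT" if b != ref)

    return _alt
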