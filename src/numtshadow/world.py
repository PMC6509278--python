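"""Synthetic ground-truth worlds: mtDNA reference, heteroplasmy truth and NUMTs.

A *world* bundles everything the downstream simulation needs: a circular
mitochondrial reference, a list of true heteroplasmic sites, and a set of
NUMTs — diverged copies of mitochondrial intervals embedded in their own
nuclear contigs with random flanking sequence. Worlds are fully determined
by their parameters and a seed, and round-trip losslessly through plain-text
files (FASTA / BED / TSV / JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import BASES, encode, decode, random_dna, revcomp, wrapped_slice

MIN_MITO_LENGTH = 1_000
RCRS_LENGTH = 16_569  # human mtDNA reference length

__all__ = [
    "MitoReference",
    "HeteroplasmySite",
    "NumtRecord",
    "World",
    "generate_mito_reference",
    "plant_heteroplasmy",
    "sample_heteroplasmy",
    "generate_numts",
    "write_world",
    "read_world",
]


@dataclass(frozen=True)
class MitoReference:
    """A circular mitochondrial reference sequence."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_MITO_LENGTH:
            raise ValueError(
                f"mito reference must be >= {MIN_MITO_LENGTH} bp, got {len(self.sequence)}"
            )
        if set(self.sequence) - set(BASES):
            raise ValueError("mito reference may contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def segment(self, start: int, end: int) -> str:
        """Sequence of the circular interval [start, end); end may exceed length."""
        return wrapped_slice(self.sequence, start, end)


@dataclass(frozen=True)
class HeteroplasmySite:
    """One true heteroplasmic (or, at frequency 1, homoplasmic) substitution.

    ``position`` is 0-based; human-facing reports convert to 1-based.
    """

    position: int
    ref_allele: str
    alt_allele: str
    true_frequency: float


@dataclass(frozen=True)
class NumtRecord:
    """A nuclear-embedded, diverged copy of a mitochondrial interval.

    ``mito_start``/``mito_end`` form a 0-based half-open interval on the
    circle; ``mito_end`` may exceed the mito length to denote wrapping past
    the origin. ``similarity`` is the realized fraction of identical bases
    versus the source segment. ``mismatch_positions`` (mito coordinates,
    modulo L) is derived from the sequences and is not serialized.
    """

    numt_id: str
    mito_start: int
    mito_end: int
    nuclear_contig: str
    nuclear_offset: int
    similarity: float
    strand: str = "+"
    copy_number: int = 2
    mismatch_positions: frozenset[int] = field(default_factory=frozenset)

    @property
    def length(self) -> int:
        return self.mito_end - self.mito_start

    def wraps(self, mito_length: int) -> bool:
        return self.mito_end > mito_length

    def projection_intervals(self, mito_length: int) -> list[tuple[int, int]]:
        """Mito projection as one interval, or two if it wraps the origin."""
        if not self.wraps(mito_length):
            return [(self.mito_start, self.mito_end)]
        return [(self.mito_start, mito_length), (0, self.mito_end - mito_length)]


@dataclass
class World:
    """Complete synthetic ground truth for one simulated individual."""

    mito: MitoReference
    truth: list[HeteroplasmySite]
    numts: list[NumtRecord]
    nuclear_contigs: dict[str, str]
    rng_seed: int

    def validate(self) -> None:
        L = self.mito.length
        seen = set()
        for site in self.truth:
            if not 0 <= site.position < L:
                raise ValueError(f"truth position {site.position} outside [0, {L})")
            if site.position in seen:
                raise ValueError(f"duplicate truth position {site.position}")
            seen.add(site.position)
            if site.ref_allele != self.mito.sequence[site.position]:
                raise ValueError(f"truth ref allele mismatch at {site.position}")
            if site.alt_allele == site.ref_allele:
                raise ValueError(f"alt equals ref at {site.position}")
            if not 0 < site.true_frequency <= 1:
                raise ValueError("true_frequency must be in (0, 1]")
        for numt in self.numts:
            if numt.nuclear_contig not in self.nuclear_contigs:
                raise ValueError(f"{numt.numt_id}: contig {numt.nuclear_contig} missing")
            if not 0 < numt.similarity < 1:
                raise ValueError(f"{numt.numt_id}: similarity must be in (0, 1)")
            if numt.copy_number < 1:
                raise ValueError(f"{numt.numt_id}: copy_number must be >= 1")

    def numt_mito_sequence(self, numt: NumtRecord) -> str:
        """The NUMT's diverged sequence, oriented to the forward mito strand."""
        contig = self.nuclear_contigs[numt.nuclear_contig]
        embedded = contig[numt.nuclear_offset : numt.nuclear_offset + numt.length]
        return revcomp(embedded) if numt.strand == "-" else embedded


def generate_mito_reference(length: int, seed: int, name: str = "mito") -> MitoReference:
    """Random circular reference of ``length`` bases (deterministic per seed)."""
    if length < MIN_MITO_LENGTH:
        raise ValueError(f"length must be >= {MIN_MITO_LENGTH}, got {length}")
    rng = np.random.default_rng(seed)
    return MitoReference(name=name, sequence=random_dna(rng, length))


def plant_heteroplasmy(
    mito: MitoReference, spec: list[tuple[int, str, float]]
) -> list[HeteroplasmySite]:
    """Validate and materialize a heteroplasmy truth list.

    ``spec`` items are (0-based position, alt allele, true frequency);
    frequency 1.0 encodes a homoplasmic variant.
    """
    sites: list[HeteroplasmySite] = []
    seen: set[int] = set()
    for position, alt, freq in spec:
        if not 0 <= position < mito.length:
            raise ValueError(f"position {position} outside the reference")
        if position in seen:
            raise ValueError(f"duplicate heteroplasmy position {position}")
        seen.add(position)
        ref = mito.sequence[position]
        if alt == ref:
            raise ValueError(f"alt allele equals reference base at {position}")
        if alt not in BASES:
            raise ValueError(f"invalid alt allele {alt!r}")
        if not 0 < freq <= 1:
            raise ValueError(f"frequency {freq} outside (0, 1]")
        sites.append(HeteroplasmySite(position, ref, alt, freq))
    return sorted(sites, key=lambda s: s.position)


def sample_heteroplasmy(
    mito: MitoReference,
    n_sites: int,
    seed: int,
    freq_range: tuple[float, float] = (0.01, 0.5),
    min_spacing: int = 200,
) -> list[HeteroplasmySite]:
    """Draw ``n_sites`` random heteroplasmic sites with uniform frequencies.

    Positions are spaced at least ``min_spacing`` apart so that sites fall on
    distinct amplicons/reads in typical configurations.
    """
    rng = np.random.default_rng(seed)
    positions: list[int] = []
    attempts = 0
    while len(positions) < n_sites:
        p = int(rng.integers(0, mito.length))
        if all(abs(p - q) >= min_spacing for q in positions):
            positions.append(p)
        attempts += 1
        if attempts > 100 * n_sites + 1000:
            raise ValueError("cannot place sites with the requested spacing")
    spec = []
    for p in sorted(positions):
        ref = mito.sequence[p]
        alt = rng.choice([b for b in BASES if b != ref])
        freq = float(rng.uniform(*freq_range))
        spec.append((p, str(alt), freq))
    return plant_heteroplasmy(mito, spec)


def _sample_similarity(
    rng: np.random.Generator, mean: float, sd: float, lo: float = 0.70, hi: float = 0.995
) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    while True:  # rejection sampling from the truncated normal
        s = rng.normal(mean, sd)
        if lo <= s <= hi:
            return float(s)


def _mismatch_positions(mito: MitoReference, numt_seq: str, mito_start: int) -> frozenset[int]:
    src = encode(mito.segment(mito_start, mito_start + len(numt_seq)))
    offs = np.nonzero(src != encode(numt_seq))[0]
    L = mito.length
    return frozenset(int((mito_start + o) % L) for o in offs)


def generate_numts(
    mito: MitoReference,
    count: int,
    size_range: tuple[int, int] = (100, 6_000),
    similarity_mean: float = 0.86,
    similarity_sd: float = 0.041,
    flank_length: int = 2_000,
    seed: int = 0,
    copy_number: int = 2,
    position_range: tuple[int, int] | None = None,
) -> tuple[list[NumtRecord], dict[str, str]]:
    """Generate ``count`` NUMTs, each embedded in its own random nuclear contig.

    Each NUMT copies a random circular interval of the mito reference whose
    length is uniform over ``size_range``, substitutes each base
    independently with probability ``1 - s`` where ``s`` is drawn from
    Normal(similarity_mean, similarity_sd) truncated to [0.70, 0.995], and is
    inserted (on a random strand) between ``flank_length`` random bases on
    each side. ``position_range`` optionally confines the copied intervals to
    a sub-arc of the circle, which produces positionally clustered NUMTs.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    lo, hi = size_range
    if lo > hi:
        raise ValueError(f"size_range inverted: {size_range}")
    if lo < 50 or hi > mito.length:
        raise ValueError(f"size_range must lie within [50, {mito.length}]")
    if not 0 < similarity_mean < 1:
        raise ValueError("similarity_mean must be in (0, 1)")

    rng = np.random.default_rng(seed)
    records: list[NumtRecord] = []
    contigs: dict[str, str] = {}
    L = mito.length
    for i in range(count):
        length = int(rng.integers(lo, hi + 1))
        if position_range is None:
            start = int(rng.integers(0, L))
        else:
            a, b = position_range
            start = int(rng.integers(a, max(a + 1, b - length))) % L
        s = _sample_similarity(rng, similarity_mean, similarity_sd)
        src = encode(mito.segment(start, start + length))
        mask = rng.random(length) < (1 - s)
        mutated = src.copy()
        n_mut = int(mask.sum())
        if n_mut:
            mutated[mask] = (mutated[mask] + rng.integers(1, 4, size=n_mut, dtype=np.uint8)) % 4
        numt_seq = decode(mutated)
        realized = 1 - n_mut / length
        strand = "+" if rng.random() < 0.5 else "-"
        embedded = revcomp(numt_seq) if strand == "-" else numt_seq
        numt_id = f"numt{i:04d}"
        contig_name = f"nuc_{numt_id}"
        contig = random_dna(rng, flank_length) + embedded + random_dna(rng, flank_length)
        contigs[contig_name] = contig
        records.append(
            NumtRecord(
                numt_id=numt_id,
                mito_start=start,
                mito_end=start + length,
                nuclear_contig=contig_name,
                nuclear_offset=flank_length,
                similarity=realized,
                strand=strand,
                copy_number=copy_number,
                mismatch_positions=frozenset(
                    int((start + o) % L) for o in np.nonzero(mask)[0]
                ),
            )
        )
    return records, contigs


# ---------------------------------------------------------------------------
# serialization


def write_world(world: World, out_dir: str | Path) -> dict[str, Path]:
    """Write a world as FASTA + BED + TSV + JSON; returns the file map.

    The BED file carries the NUMT projections on the mito circle (0-based
    half-open; wrapping NUMTs are split into two intervals; score is
    round(1000 * similarity)). The registry TSV carries the full per-NUMT
    fields, and the truth TSV uses 1-based positions (VCF convention).
    """
    world.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mito_fasta": out / "mito.fasta",
        "nuclear_fasta": out / "nuclear.fasta",
        "numt_bed": out / "numts.bed",
        "numt_tsv": out / "numts.tsv",
        "truth_tsv": out / "truth.tsv",
        "meta_json": out / "world.json",
    }
    SeqIO.write(
        [SeqRecord(Seq(world.mito.sequence), id=world.mito.name, description="circular")],
        paths["mito_fasta"],
        "fasta",
    )
    SeqIO.write(
        [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in sorted(world.nuclear_contigs.items())
        ],
        paths["nuclear_fasta"],
        "fasta",
    )
    L = world.mito.length
    with open(paths["numt_bed"], "w") as bed:
        for numt in world.numts:
            score = round(1000 * numt.similarity)
            for a, b in numt.projection_intervals(L):
                bed.write(
                    f"{world.mito.name}\t{a}\t{b}\t{numt.numt_id}\t{score}\t{numt.strand}\n"
                )
    pd.DataFrame(
        [
            {
                "numt_id": n.numt_id,
                "mito_start": n.mito_start,
                "mito_end": n.mito_end,
                "nuclear_contig": n.nuclear_contig,
                "nuclear_offset": n.nuclear_offset,
                "similarity": repr(n.similarity),
                "strand": n.strand,
                "copy_number": n.copy_number,
            }
            for n in world.numts
        ],
        columns=[
            "numt_id",
            "mito_start",
            "mito_end",
            "nuclear_contig",
            "nuclear_offset",
            "similarity",
            "strand",
            "copy_number",
        ],
    ).to_csv(paths["numt_tsv"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "POS": s.position + 1,
                "REF": s.ref_allele,
                "ALT": s.alt_allele,
                "FREQ": repr(s.true_frequency),
            }
            for s in world.truth
        ],
        columns=["POS", "REF", "ALT", "FREQ"],
    ).to_csv(paths["truth_tsv"], sep="\t", index=False)
    with open(paths["meta_json"], "w") as fh:
        json.dump(
            {
                "mito_name": world.mito.name,
                "mito_length": world.mito.length,
                "n_truth_sites": len(world.truth),
                "n_numts": len(world.numts),
                "rng_seed": world.rng_seed,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


def read_world(in_dir: str | Path) -> World:
    """Read a world written by :func:`write_world` (lossless round-trip)."""
    src = Path(in_dir)
    with open(src / "world.json") as fh:
        meta = json.load(fh)
    mito_rec = next(SeqIO.parse(src / "mito.fasta", "fasta"))
    mito = MitoReference(name=mito_rec.id, sequence=str(mito_rec.seq))
    contigs = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(src / "nuclear.fasta", "fasta")
    }
    truth_df = pd.read_csv(src / "truth.tsv", sep="\t", dtype={"REF": str, "ALT": str})
    truth = [
        HeteroplasmySite(int(r.POS) - 1, r.REF, r.ALT, float(r.FREQ))
        for r in truth_df.itertuples()
    ]
    numt_df = pd.read_csv(src / "numts.tsv", sep="\t")
    numts = []
    for r in numt_df.itertuples():
        rec = NumtRecord(
            numt_id=r.numt_id,
            mito_start=int(r.mito_start),
            mito_end=int(r.mito_end),
            nuclear_contig=r.nuclear_contig,
            nuclear_offset=int(r.nuclear_offset),
            similarity=float(r.similarity),
            strand=r.strand,
            copy_number=int(r.copy_number),
        )
        numts.append(rec)
    world = World(
        mito=mito,
        truth=truth,
        numts=numts,
        nuclear_contigs=contigs,
        rng_seed=int(meta["rng_seed"]),
    )
    # mismatch positions are derived data; recompute them from the sequences
    world.numts = [
        replace(
            n,
            mismatch_positions=_mismatch_positions(
                mito, world.numt_mito_sequence(n), n.mito_start
            ),
        )
        for n in world.numts
    ]
    world.validate()
    return world
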