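"""Seed-and-extend read mapping against mito-only and combined references.

The mapper reproduces the mechanism under study rather than any particular
production aligner: exact k-mer seeds nominate candidate loci, each
candidate is scored by ungapped comparison (+1 match, -1 mismatch), and the
best locus is reported if its identity clears an acceptance threshold and is
uniquely best. Ties across distinct loci yield an ``ambiguous`` status and
the read is excluded from pileups (the analogue of MAPQ-0 filtering).

Mapping the same reads against a mito-only reference versus a combined
(mito + nuclear contigs) reference exposes the competition effect: a
NUMT-derived read is close enough to the mitochondrial sequence to be
accepted by the mito-only reference, but maps to its true nuclear origin —
with higher identity — as soon as that origin is present in the reference.

The mito contig is circular; internally it is extended by ``wrap`` bases so
reads spanning the origin align contiguously, and positions are reported
modulo the mito length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import encode, revcomp
from .sequencing import ReadSet
from .world import World

__all__ = [
    "ReferenceIndex",
    "ReadAlignment",
    "build_index",
    "build_indexes",
    "map_read",
    "map_all",
    "write_alignments",
    "read_alignments",
]

MIN_K, MAX_K = 11, 31
DEFAULT_MIN_IDENTITY = 0.88
MAX_CANDIDATES = 200


@dataclass
class ReferenceIndex:
    """Exact k-mer index over one or more contigs.

    The mito contig (if present) is stored with a circular wrap extension of
    ``wrap`` bases; seed positions inside the extension are normalized
    modulo the mito length at query time.
    """

    contigs: dict[str, str]
    k: int
    mito_name: str | None
    mito_length: int
    wrap: int
    arrays: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    table: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)


@dataclass
class ReadAlignment:
    """One read's placement under one reference mode."""

    read_id: str
    mode: str  # "rcrs_only" | "combined"
    status: str  # "mapped" | "unmapped" | "ambiguous"
    contig: str | None = None
    position: int | None = None  # 0-based; modulo L on the mito contig
    strand: str | None = None
    score: int | None = None
    mismatches: int | None = None
    aligned_sequence: str | None = None  # read oriented to the reference forward strand


def build_index(
    references: Mapping[str, str],
    k: int = 15,
    mito_name: str | None = "mito",
    wrap: int = 300,
) -> ReferenceIndex:
    """Index every forward-strand k-mer of every contig.

    ``wrap`` must be at least the longest read that will be mapped so that
    origin-spanning reads score against a contiguous extended sequence.
    """
    if not MIN_K <= k <= MAX_K:
        raise ValueError(f"k must be in [{MIN_K}, {MAX_K}], got {k}")
    contigs = dict(references)
    mito_len = 0
    if mito_name is not None and mito_name in contigs:
        mito_len = len(contigs[mito_name])
        wrap = min(wrap, mito_len)
    else:
        mito_name = None
    table: dict[str, list[tuple[str, int]]] = {}
    arrays: dict[str, np.ndarray] = {}
    for name, seq in contigs.items():
        if len(seq) < k:
            raise ValueError(f"contig {name} is shorter than k={k}")
        indexed = seq + seq[:wrap] if name == mito_name else seq
        arrays[name] = encode(indexed)
        for i in range(len(indexed) - k + 1):
            table.setdefault(indexed[i : i + k], []).append((name, i))
    return ReferenceIndex(
        contigs=contigs,
        k=k,
        mito_name=mito_name,
        mito_length=mito_len,
        wrap=wrap,
        arrays=arrays,
        table=table,
    )


def build_indexes(world: World, k: int = 15, wrap: int = 300) -> tuple[ReferenceIndex, ReferenceIndex]:
    """The pair of indexes for the two mapping modes of one world."""
    mito_only = build_index({world.mito.name: world.mito.sequence}, k=k, mito_name=world.mito.name, wrap=wrap)
    combined = build_index(
        {world.mito.name: world.mito.sequence, **world.nuclear_contigs},
        k=k,
        mito_name=world.mito.name,
        wrap=wrap,
    )
    return mito_only, combined


def map_read(
    read_id: str,
    sequence: str,
    index: ReferenceIndex,
    accept_min_identity: float = DEFAULT_MIN_IDENTITY,
    max_candidates: int = MAX_CANDIDATES,
) -> ReadAlignment:
    """Map one read: seed with every read k-mer, extend ungapped, pick best.

    Candidate loci are collected from all k-mer hits on both strands
    (deterministic order, capped at ``max_candidates``). The best-scoring
    locus is reported as mapped when its identity is at least
    ``accept_min_identity`` and its score is uniquely best; an exact score
    tie across distinct loci gives ``ambiguous``; everything else is
    ``unmapped``.
    """
    k = index.k
    n = len(sequence)
    if n < k:
        raise ValueError(f"read shorter than k={k}")
    table = index.table
    L = index.mito_length
    mito_name = index.mito_name
    candidates: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int, str]] = set()
    queries = ((u"+", sequence), (u"-", revcomp(sequence)))
    for strand, q in queries:
        if len(candidates) >= max_candidates:
            break
        for i in range(n - k + 1):
            hits = table.get(q[i : i + k])
            if not hits:
                continue
            for name, p in hits:
                start = p - i
                if name == mito_name:
                    start %= L
                elif start < 0 or start + n > len(index.contigs[name]):
                    continue
                key = (name, start, strand)
                if key not in seen:
                    seen.add(key)
                    candidates.append(key)
            if len(candidates) >= max_candidates:
                break
    if not candidates:
        return ReadAlignment(read_id=read_id, mode="", status="unmapped")

    enc_cache: dict[str, np.ndarray] = {}
    best = None
    best_mism = n + 1
    tie = False
    for name, start, strand in candidates:
        if strand not in enc_cache:
            enc_cache[strand] = encode(sequence if strand == "+" else revcomp(sequence))
        qa = enc_cache[strand]
        ref = index.arrays[name]
        seg = ref[start : start + n]
        if len(seg) < n:  # read runs off a linear contig end (shouldn't happen)
            continue
        mism = int(np.count_nonzero(seg != qa))
        if mism < best_mism:
            best_mism = mism
            best = (name, start, strand)
            tie = False
        elif mism == best_mism:
            tie = True
    if best is None:
        return ReadAlignment(read_id=read_id, mode="", status="unmapped")
    identity = (n - best_mism) / n
    if identity < accept_min_identity:
        return ReadAlignment(read_id=read_id, mode="", status="unmapped")
    if tie:
        return ReadAlignment(read_id=read_id, mode="", status="ambiguous")
    name, start, strand = best
    oriented = sequence if strand == "+" else revcomp(sequence)
    return ReadAlignment(
        read_id=read_id,
        mode="",
        status="mapped",
        contig=name,
        position=start,
        strand=strand,
        score=(n - best_mism) - best_mism,
        mismatches=best_mism,
        aligned_sequence=oriented,
    )


def map_all(
    reads: ReadSet,
    mito_index: ReferenceIndex,
    combined_index: ReferenceIndex,
    accept_min_identity: float = DEFAULT_MIN_IDENTITY,
) -> tuple[list[ReadAlignment], list[ReadAlignment], dict]:
    """Map every read under both reference modes; returns alignments + stats."""
    aln_rcrs: list[ReadAlignment] = []
    aln_comb: list[ReadAlignment] = []
    stats = {
        mode: {"mapped": 0, "unmapped": 0, "ambiguous": 0, "mito_mapped": 0}
        for mode in ("rcrs_only", "combined")
    }
    for read_id, seq, _ in reads.reads:
        for mode, index, out in (
            ("rcrs_only", mito_index, aln_rcrs),
            ("combined", combined_index, aln_comb),
        ):
            if len(seq) < index.k:  # clipped fragments can undercut the seed size
                aln = ReadAlignment(read_id=read_id, mode=mode, status="unmapped")
            else:
                aln = map_read(read_id, seq, index, accept_min_identity)
            aln.mode = mode
            out.append(aln)
            stats[mode][aln.status] += 1
            if aln.status == "mapped" and aln.contig == index.mito_name:
                stats[mode]["mito_mapped"] += 1
    return aln_rcrs, aln_comb, stats


# ---------------------------------------------------------------------------
# serialization (SAM-like TSV; 1-based positions, like SAM)


def write_alignments(alignments: Iterable[ReadAlignment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "mode": a.mode,
                "status": a.status,
                "contig": a.contig if a.contig else ".",
                "position": (a.position + 1) if a.position is not None else 0,
                "strand": a.strand if a.strand else ".",
                "mismatches": a.mismatches if a.mismatches is not None else -1,
                "score": a.score if a.score is not None else 0,
                "sequence": a.aligned_sequence if a.aligned_sequence else ".",
            }
            for a in alignments
        ],
        columns=[
            "read_id",
            "mode",
            "status",
            "contig",
            "position",
            "strand",
            "mismatches",
            "score",
            "sequence",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_alignments(path: str | Path) -> list[ReadAlignment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        mapped = r.status == "mapped"
        out.append(
            ReadAlignment(
                read_id=r.read_id,
                mode=r.mode,
                status=r.status,
                contig=None if r.contig == "." else r.contig,
                position=(int(r.position) - 1) if mapped else None,
                strand=None if r.strand == "." else r.strand,
                score=int(r.score) if mapped else None,
                mismatches=int(r.mismatches) if mapped else None,
                aligned_sequence=None if r.sequence == "." else r.sequence,
            )
        )
    return out
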