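"""Read simulation over an enriched template pool, plus primer trimming.

Single-end reads are drawn from pool molecules proportionally to template
weight, with uniform start positions, uniform strand, and independent
per-base substitution errors. Base qualities are a constant Q30 symbol: the
downstream callers work on counts, not qualities. Each read keeps a
provenance record (source molecule, offset, strand) so that oracle tests can
verify mapping and pileup behaviour against the known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import BASES, revcomp
from .enrichment import AmpliconPanel, MoleculePool

QUALITY_CHAR = "?"  # Phred+33 Q30

__all__ = ["Provenance", "ReadSet", "sequence_reads", "trim_primers", "write_fastq", "read_fastq"]


@dataclass(frozen=True)
class Provenance:
    """Where a read came from: molecule, 0-based molecule offset, strand."""

    molecule_id: str
    origin: str
    offset: int
    strand: str
    molecule_length: int
    truncated: bool = False


@dataclass
class ReadSet:
    """Simulated reads plus per-read provenance."""

    reads: list[tuple[str, str, str]]  # (read_id, sequence, quality)
    provenance: dict[str, Provenance]

    def __len__(self) -> int:
        return len(self.reads)


def sequence_reads(
    pool: MoleculePool,
    read_length: int = 150,
    total_reads: int = 10_000,
    error_rate: float = 0.002,
    seed: int = 0,
) -> ReadSet:
    """Draw ``total_reads`` single-end reads from a molecule pool.

    Molecules are sampled proportionally to weight; the read start is
    uniform over valid positions and the strand uniform. Each base is
    substituted independently with probability ``error_rate``. Reads from
    molecules shorter than ``read_length`` cover the whole molecule and are
    flagged as truncated. Deterministic for a fixed seed.
    """
    if read_length < 36:
        raise ValueError("read_length must be >= 36")
    if not 0 <= error_rate < 0.1:
        raise ValueError("error_rate must be in [0, 0.1)")
    if not pool.molecules:
        raise ValueError("cannot sequence an empty pool")
    rng = np.random.default_rng(seed)
    mols = pool.molecules
    w = np.array([m.weight for m in mols])
    choice = rng.choice(len(mols), size=total_reads, p=w / w.sum())
    strands = rng.random(total_reads) < 0.5
    u = rng.random(total_reads)

    reads: list[tuple[str, str, str]] = []
    provenance: dict[str, Provenance] = {}
    for i in range(total_reads):
        m = mols[choice[i]]
        mlen = len(m.sequence)
        if mlen <= read_length:
            offset, truncated = 0, mlen < read_length
            frag = m.sequence
        else:
            offset = int(u[i] * (mlen - read_length + 1))
            truncated = False
            frag = m.sequence[offset : offset + read_length]
        strand = "-" if strands[i] else "+"
        seq = revcomp(frag) if strand == "-" else frag
        if error_rate > 0:
            n_err = rng.binomial(len(seq), error_rate)
            if n_err:
                pos = rng.choice(len(seq), size=n_err, replace=False)
                arr = list(seq)
                shifts = rng.integers(1, 4, size=n_err)
                for p, sh in zip(pos, shifts):
                    arr[p] = BASES[(BASES.index(arr[p]) + sh) % 4]
                seq = "".join(arr)
        read_id = f"read{i:07d}"
        reads.append((read_id, seq, QUALITY_CHAR * len(seq)))
        provenance[read_id] = Provenance(
            molecule_id=m.molecule_id,
            origin=m.origin,
            offset=offset,
            strand=strand,
            molecule_length=mlen,
            truncated=truncated,
        )
    return ReadSet(reads=reads, provenance=provenance)


def trim_primers(reads: ReadSet, panel: AmpliconPanel) -> ReadSet:
    """Remove primer-footprint bases from reads at molecule termini.

    Every molecule in an amplicon pool begins and ends with a primer
    footprint of ``panel.primer_length`` bases. Any read whose provenance
    overlaps a terminal footprint loses those bases; fully interior reads
    are unchanged. Reads left empty are dropped.
    """
    p = panel.primer_length
    out_reads: list[tuple[str, str, str]] = []
    out_prov: dict[str, Provenance] = {}
    for read_id, seq, qual in reads.reads:
        prov = reads.provenance[read_id]
        lo = prov.offset
        hi = prov.offset + len(seq)
        new_lo = max(lo, p)
        new_hi = min(hi, prov.molecule_length - p)
        if new_hi <= new_lo:
            continue
        cut_left = new_lo - lo  # molecule-coordinate cuts
        cut_right = hi - new_hi
        if prov.strand == "+":
            seq2 = seq[cut_left : len(seq) - cut_right]
            qual2 = qual[cut_left : len(qual) - cut_right]
        else:  # read is reverse-complemented: molecule-left cut is at read end
            seq2 = seq[cut_right : len(seq) - cut_left]
            qual2 = qual[cut_right : len(qual) - cut_left]
        out_reads.append((read_id, seq2, qual2))
        out_prov[read_id] = replace(prov, offset=new_lo)
    return ReadSet(reads=out_reads, provenance=out_prov)


# ---------------------------------------------------------------------------
# serialization


def write_fastq(reads: ReadSet, fastq_path: str | Path, provenance_path: str | Path | None = None) -> None:
    with open(fastq_path, "w") as fh:
        for read_id, seq, qual in reads.reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
    if provenance_path is not None:
        pd.DataFrame(
            [
                {
                    "read_id": rid,
                    "molecule_id": p.molecule_id,
                    "origin": p.origin,
                    "offset": p.offset,
                    "strand": p.strand,
                    "molecule_length": p.molecule_length,
                    "truncated": int(p.truncated),
                }
                for rid, p in ((rid, reads.provenance[rid]) for rid, _, _ in reads.reads)
            ],
            columns=[
                "read_id",
                "molecule_id",
                "origin",
                "offset",
                "strand",
                "molecule_length",
                "truncated",
            ],
        ).to_csv(provenance_path, sep="\t", index=False)


def read_fastq(fastq_path: str | Path, provenance_path: str | Path | None = None) -> ReadSet:
    reads: list[tuple[str, str, str]] = []
    with open(fastq_path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            reads.append((header[1:].split()[0], seq, qual))
    provenance: dict[str, Provenance] = {}
    if provenance_path is not None:
        df = pd.read_csv(provenance_path, sep="\t")
        for r in df.itertuples():
            provenance[r.read_id] = Provenance(
                molecule_id=r.molecule_id,
                origin=r.origin,
                offset=int(r.offset),
                strand=r.strand,
                molecule_length=int(r.molecule_length),
                truncated=bool(r.truncated),
            )
    return ReadSet(reads=reads, provenance=provenance)
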