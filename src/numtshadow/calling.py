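"""Per-site allele counting and heteroplasmy calling on mito alignments.

The caller is deliberately transparent: a pileup tallies A/C/G/T counts per
mitochondrial position from mapped reads (circular positions wrap modulo
the reference length), and a site call reports the single best-supported
non-reference allele wherever depth and frequency clear the configured
floors. Frequencies are percentages of read depth; no base-quality or
strand-bias filtering is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import BASES, encode
from .mapper import ReadAlignment
from .world import MitoReference

__all__ = ["SiteCall", "pileup", "call_sites", "write_calls", "read_calls", "write_vcf"]

DEFAULT_MIN_DEPTH = 100
DEFAULT_MIN_FREQUENCY = 0.2  # percent; below the 0.5 pp comparison threshold


@dataclass(frozen=True)
class SiteCall:
    """A per-site variant call with its heteroplasmy level.

    ``position`` is 1-based (VCF convention); ``variant_frequency`` is the
    variant allele's percentage of read depth.
    """

    position: int
    depth: int
    counts: tuple[int, int, int, int]  # A, C, G, T
    ref_allele: str
    major_allele: str
    variant_allele: str
    variant_frequency: float

    def __post_init__(self) -> None:
        if sum(self.counts) != self.depth:
            raise ValueError("counts must sum to depth")
        if not 0 <= self.variant_frequency <= 100:
            raise ValueError("variant_frequency must be in [0, 100]")
        if self.variant_allele == self.ref_allele:
            raise ValueError("variant allele equals the reference allele")


def pileup(
    alignments: Iterable[ReadAlignment],
    mito_length: int,
    mito_name: str = "mito",
) -> np.ndarray:
    """Per-position base counts, shape (L, 4) ordered A,C,G,T.

    Only ``mapped`` alignments on the mito contig contribute; read bases are
    taken from the reference-forward-oriented sequence, and positions wrap
    modulo ``mito_length``. Non-ACGT bases are ignored.
    """
    counts = np.zeros((mito_length, 4), dtype=np.int64)
    for aln in alignments:
        if aln.status != "mapped" or aln.contig != mito_name:
            continue
        if aln.position is None or aln.aligned_sequence is None:
            continue
        if not 0 <= aln.position < mito_length:
            raise ValueError(f"alignment position {aln.position} outside contig bounds")
        codes = encode(aln.aligned_sequence)
        pos = (aln.position + np.arange(len(codes))) % mito_length
        valid = codes < 4
        np.add.at(counts, (pos[valid], codes[valid]), 1)
    return counts


def call_sites(
    counts: np.ndarray,
    reference: MitoReference | str,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
) -> list[SiteCall]:
    """Call the best-supported non-reference allele per sufficiently deep site.

    A variant is reported where depth >= ``min_depth`` and the top
    non-reference allele's frequency (100 * count / depth) is at least
    ``min_frequency`` percent. Triallelic sites collapse to the strongest
    variant allele.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0 < min_frequency < 50:
        raise ValueError("min_frequency must be in (0, 50) percent")
    ref_seq = reference.sequence if isinstance(reference, MitoReference) else reference
    if counts.shape[0] != len(ref_seq):
        raise ValueError("counts and reference lengths differ")
    depths = counts.sum(axis=1)
    ref_codes = encode(ref_seq)
    calls: list[SiteCall] = []
    candidate_pos = np.nonzero(depths >= min_depth)[0]
    for pos in candidate_pos:
        row = counts[pos]
        ref_idx = int(ref_codes[pos])
        alt_counts = row.copy()
        alt_counts[ref_idx] = -1
        alt_idx = int(alt_counts.argmax())
        alt_n = int(row[alt_idx])
        depth = int(depths[pos])
        freq = 100.0 * alt_n / depth
        if alt_n == 0 or freq < min_frequency:
            continue
        calls.append(
            SiteCall(
                position=int(pos) + 1,
                depth=depth,
                counts=tuple(int(c) for c in row),
                ref_allele=BASES[ref_idx],
                major_allele=BASES[int(row.argmax())],
                variant_allele=BASES[alt_idx],
                variant_frequency=freq,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# serialization


def write_calls(
    calls: Sequence[SiteCall],
    tsv_path: str | Path,
    vcf_path: str | Path | None = None,
    reference_name: str = "mito",
    reference_length: int | None = None,
) -> None:
    """Write calls as a TSV (POS, REF, ALT, DEPTH, FREQ) and optionally a VCF."""
    pd.DataFrame(
        [
            {
                "POS": c.position,
                "REF": c.ref_allele,
                "ALT": c.variant_allele,
                "DEPTH": c.depth,
                "FREQ": repr(c.variant_frequency),
                "A": c.counts[0],
                "C": c.counts[1],
                "G": c.counts[2],
                "T": c.counts[3],
            }
            for c in calls
        ],
        columns=["POS", "REF", "ALT", "DEPTH", "FREQ", "A", "C", "G", "T"],
    ).to_csv(tsv_path, sep="\t", index=False)
    if vcf_path is not None:
        write_vcf(calls, vcf_path, reference_name, reference_length)


def write_vcf(
    calls: Sequence[SiteCall],
    path: str | Path,
    reference_name: str = "mito",
    reference_length: int | None = None,
) -> None:
    """Minimal single-sample-free VCF with AF and DP in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if reference_length is not None:
            fh.write(f"##contig=<ID={reference_name},length={reference_length}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            af = c.variant_frequency / 100.0
            fh.write(
                f"{reference_name}\t{c.position}\t.\t{c.ref_allele}\t{c.variant_allele}"
                f"\t.\tPASS\tAF={af:.6f};DP={c.depth}\n"
            )


def read_calls(tsv_path: str | Path, reference: MitoReference | str | None = None) -> list[SiteCall]:
    """Read back a calls TSV written by :func:`write_calls`."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"REF": str, "ALT": str})
    calls = []
    for r in df.itertuples():
        counts = (int(r.A), int(r.C), int(r.G), int(r.T))
        row = np.array(counts)
        calls.append(
            SiteCall(
                position=int(r.POS),
                depth=int(r.DEPTH),
                counts=counts,
                ref_allele=r.REF,
                major_allele=BASES[int(row.argmax())],
                variant_allele=r.ALT,
                variant_frequency=float(r.FREQ),
            )
        )
    return calls
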