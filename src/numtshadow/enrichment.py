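"""Enrichment simulation: amplicon PCR panels and MDA fragmentation.

The module turns a synthetic world into a :class:`MoleculePool` — the set of
template molecules that the sequencer will sample — under one of the four
enrichment strategies studied here: 2-amplicon long-range PCR, 9-amplicon
PCR, 180-amplicon PCR, or untargeted multiple displacement amplification
(MDA).

The central mechanism is co-amplification: a PCR amplicon can pick up a NUMT
template only if both primer footprints fall inside the NUMT's mitochondrial
projection with at most a small number of primer-site mismatches. Amplicons
longer than the longest NUMT therefore never co-amplify nuclear copies,
while short-amplicon panels and MDA readily do. Template abundance follows
the mito:nuclear copy-number stoichiometry (hundreds of mtDNA copies per
cell versus two nuclear copies), which pins expected NUMT-derived allele
fractions near ``2k / (C + 2k)`` for ``k`` diploid NUMT copies and ``C``
mtDNA copies per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import arc_contains, wrapped_slice
from .world import MitoReference, NumtRecord, World

__all__ = [
    "AmpliconPanel",
    "Molecule",
    "MoleculePool",
    "Stoichiometry",
    "STOICHIOMETRY_PRESETS",
    "design_amplicon_panel",
    "numt_coamplified",
    "amplify",
    "mda_fragments",
    "write_pool",
    "read_pool",
    "write_panel",
    "read_panel",
]


@dataclass(frozen=True)
class AmpliconPanel:
    """A circular tiling of the mito reference by overlapping amplicons.

    Amplicon intervals are 0-based half-open on the circle; ``end`` may
    exceed the mito length to denote wrapping past the origin.
    """

    amplicons: tuple[tuple[int, int], ...]
    primer_length: int
    min_overlap: int
    mito_length: int

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)

    def footprints(self, index: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """The two primer footprints (terminal intervals) of one amplicon."""
        a, b = self.amplicons[index]
        p = self.primer_length
        return (a, a + p), (b - p, b)


@dataclass
class Molecule:
    """One template molecule in an enriched pool.

    ``origin`` is ``"mito"`` for true mitochondrial templates, a NUMT id for
    NUMT-derived templates, or ``"<numt_id>|flank"`` for fragments starting
    in nuclear flanking sequence. ``mito_interval`` is the projected
    half-open interval on the mito circle where applicable.
    """

    molecule_id: str
    origin: str
    sequence: str
    mito_interval: tuple[int, int] | None
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("molecule weight must be positive")
        if self.origin == "mito" and self.mito_interval is None:
            raise ValueError("mito molecules must carry a mito_interval")


@dataclass
class MoleculePool:
    """A labelled collection of template molecules from one enrichment run."""

    molecules: list[Molecule]
    strategy: str
    seed: int
    params: dict = field(default_factory=dict)

    def total_weight(self) -> float:
        return float(sum(m.weight for m in self.molecules))


@dataclass(frozen=True)
class Stoichiometry:
    """Copy-number stoichiometry and PCR noise for one starting material.

    ``mito_copies_per_cell`` (C) against two nuclear copies per diploid cell
    bounds the NUMT template fraction; ``pcr_jackpot_sd`` is the sigma of a
    lognormal per-template amplification factor modelling stochastic
    amplification in low-template reactions (0 disables it).
    """

    mito_copies_per_cell: int = 500
    nuclear_copies: int = 2
    cells: int = 1_000
    pcr_jackpot_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mito_copies_per_cell < 1 or self.cells < 1:
            raise ValueError("copy numbers and cell counts must be >= 1")


#: Starting-material presets. Copy numbers per cell are configuration
#: defaults chosen to reproduce the qualitative ordering between pooled-cell
#: and homogenate experiments; jackpot noise mimics low-template reactions.
STOICHIOMETRY_PRESETS: dict[str, Stoichiometry] = {
    "pooled_cells": Stoichiometry(mito_copies_per_cell=100, cells=200, pcr_jackpot_sd=0.5),
    "homogenate": Stoichiometry(mito_copies_per_cell=500, cells=10_000, pcr_jackpot_sd=0.1),
    "csf": Stoichiometry(mito_copies_per_cell=100, cells=500, pcr_jackpot_sd=0.0),
}


def design_amplicon_panel(
    mito: MitoReference,
    n_amplicons: int,
    primer_length: int = 25,
    min_overlap: int = 50,
) -> AmpliconPanel:
    """Evenly spaced circular tiling by ``n_amplicons`` overlapping amplicons.

    Amplicon *i* starts at ``round(i * L / n)`` and ends ``min_overlap``
    bases into the next amplicon, giving near-equal lengths of about
    ``L / n + min_overlap``. Deterministic.
    """
    L = mito.length
    if n_amplicons < 1:
        raise ValueError("n_amplicons must be >= 1")
    approx_len = L // n_amplicons + min_overlap
    if n_amplicons > L or approx_len < 2 * primer_length + 1 or approx_len > L:
        raise ValueError(
            f"infeasible tiling: {n_amplicons} amplicons of ~{approx_len} bp on a {L} bp circle"
        )
    starts = [i * L // n_amplicons for i in range(n_amplicons)]
    amplicons = []
    for i, a in enumerate(starts):
        nxt = starts[i + 1] if i + 1 < n_amplicons else L + starts[0]
        amplicons.append((a, nxt + min_overlap))
    return AmpliconPanel(
        amplicons=tuple(amplicons),
        primer_length=primer_length,
        min_overlap=min_overlap,
        mito_length=L,
    )


def numt_coamplified(
    numt: NumtRecord,
    amplicon: tuple[int, int],
    panel: AmpliconPanel,
    max_primer_mismatches: int = 2,
) -> bool:
    """Whether one amplicon would amplify this NUMT.

    True iff the amplicon's mito interval lies entirely within the NUMT's
    projection (so both primer footprints sit on NUMT sequence) and the
    NUMT's realized mismatches within each footprint number at most
    ``max_primer_mismatches``. An amplicon longer than the NUMT can never
    satisfy this, which is why long-range PCR escapes NUMT co-amplification.
    """
    L = panel.mito_length
    a, b = amplicon
    if not arc_contains(numt.mito_start, numt.mito_end, a, b, L):
        return False
    p = panel.primer_length
    ms = numt.mismatch_positions
    for fa, fb in ((a, a + p), (b - p, b)):
        n_mm = sum(1 for pos in range(fa, fb) if (pos % L) in ms)
        if n_mm > max_primer_mismatches:
            return False
    return True


def _jackpot(rng: np.random.Generator, sd: float) -> float:
    return float(rng.lognormal(mean=0.0, sigma=sd)) if sd > 0 else 1.0


def _haplotype_classes(frequencies: list[float]) -> list[tuple[frozenset[int], float]]:
    """Deterministic haplotype classes matching the per-site marginals exactly.

    Sites are laid out on the unit circle: site ``i`` is alt on the arc
    ``[c_i, c_i + f_i)`` (mod 1) where ``c_i`` is the cumulative frequency of
    the preceding sites. The arcs' endpoints partition the circle into at
    most ``2k`` segments; each segment is one haplotype class whose weight is
    the segment length and whose alt set is the arcs covering it. Every
    site's marginal alt fraction is exactly ``f_i`` for any frequency sum,
    including homoplasmic (frequency 1) sites.
    """
    k = len(frequencies)
    if k == 0:
        return [(frozenset(), 1.0)]
    arcs: list[list[tuple[float, float]]] = []
    c = 0.0
    cuts = {0.0}
    for f in frequencies:
        a = c % 1.0
        b = a + f
        if b <= 1.0 + 1e-12:
            parts = [(a, min(b, 1.0))]
        else:
            parts = [(a, 1.0), (0.0, b - 1.0)]
        arcs.append(parts)
        for u, v in parts:
            cuts.add(u)
            cuts.add(v if v < 1.0 else 0.0)
        c += f
    points = sorted(cuts)
    classes: list[tuple[frozenset[int], float]] = []
    for idx, u in enumerate(points):
        v = points[idx + 1] if idx + 1 < len(points) else 1.0
        if v - u <= 1e-15:
            continue
        mid = (u + v) / 2
        alt = frozenset(
            i for i, parts in enumerate(arcs) if any(a <= mid < b for a, b in parts)
        )
        classes.append((alt, v - u))
    return classes


def amplify(
    world: World,
    panel: AmpliconPanel,
    stoich: Stoichiometry,
    max_primer_mismatches: int = 2,
    seed: int = 0,
) -> MoleculePool:
    """Simulate amplicon PCR on a world, producing a labelled template pool.

    Per amplicon, one mito molecule is emitted per haplotype class (the
    reference haplotype plus one per covered heteroplasmy site) with weight
    proportional to ``C * cells * frequency``, and one molecule per
    co-amplified NUMT with weight proportional to ``copy_number * cells``.
    Each weight is multiplied by a lognormal jackpot factor when
    ``pcr_jackpot_sd > 0``. PCR efficiency is otherwise equal across
    templates.
    """
    rng = np.random.default_rng(seed)
    L = world.mito.length
    C = stoich.mito_copies_per_cell
    molecules: list[Molecule] = []
    for j, (a, b) in enumerate(panel.amplicons):
        covered = [
            s for s in world.truth if arc_contains(a, b, s.position, s.position + 1, L)
        ]
        base_seq = world.mito.segment(a, b)
        for h, (alt_set, frac) in enumerate(_haplotype_classes([s.true_frequency for s in covered])):
            seq = base_seq
            for i in alt_set:
                s = covered[i]
                off = (s.position - a) % L
                seq = seq[:off] + s.alt_allele + seq[off + 1 :]
            suffix = "ref" if not alt_set else f"hap{h}"
            molecules.append(
                Molecule(
                    molecule_id=f"amp{j:03d}_{suffix}",
                    origin="mito",
                    sequence=seq,
                    mito_interval=(a, b),
                    weight=C * stoich.cells * frac * _jackpot(rng, stoich.pcr_jackpot_sd),
                )
            )
        for numt in world.numts:
            if not numt_coamplified(numt, (a, b), panel, max_primer_mismatches):
                continue
            numt_seq = world.numt_mito_sequence(numt)
            off = (a - numt.mito_start) % L
            molecules.append(
                Molecule(
                    molecule_id=f"amp{j:03d}_{numt.numt_id}",
                    origin=numt.numt_id,
                    sequence=numt_seq[off : off + (b - a)],
                    mito_interval=(a, b),
                    weight=numt.copy_number
                    * stoich.cells
                    * _jackpot(rng, stoich.pcr_jackpot_sd),
                )
            )
    return MoleculePool(
        molecules=molecules,
        strategy=f"pcr{panel.n_amplicons}",
        seed=seed,
        params={
            "n_amplicons": panel.n_amplicons,
            "primer_length": panel.primer_length,
            "min_overlap": panel.min_overlap,
            "max_primer_mismatches": max_primer_mismatches,
            "mito_copies_per_cell": C,
        },
    )


def mda_fragments(
    world: World,
    stoich: Stoichiometry,
    fragment_length_mean: int = 2_000,
    fragment_length_sd: int = 300,
    n_fragments: int = 100_000,
    seed: int = 0,
) -> MoleculePool:
    """Simulate untargeted MDA as copy-number-weighted random fragmentation.

    Each fragment's source (the mito circle, one NUMT insert, or that NUMT's
    nuclear flanks) is drawn with probability proportional to its
    copy-number-weighted length; the start is uniform on the source, and the
    length is Normal(mean, sd) truncated at 100 bp. Mito fragments may wrap
    the origin and carry alt alleles per site with probability equal to the
    site's true frequency. Nuclear fragments are clipped at contig ends. No
    branching or chimera structure is modelled.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    rng = np.random.default_rng(seed)
    L = world.mito.length
    C = stoich.mito_copies_per_cell

    # source catalogue: (kind, numt, region_start, region_len, weight)
    sources: list[tuple[str, NumtRecord | None, int, int]] = [("mito", None, 0, L)]
    weights = [float(C * stoich.cells * L)]
    for numt in world.numts:
        contig_len = len(world.nuclear_contigs[numt.nuclear_contig])
        ins_a = numt.nuclear_offset
        ins_b = numt.nuclear_offset + numt.length
        sources.append(("numt", numt, ins_a, numt.length))
        weights.append(float(numt.copy_number * stoich.cells * numt.length))
        if ins_a > 0:
            sources.append(("flank", numt, 0, ins_a))
            weights.append(float(numt.copy_number * stoich.cells * ins_a))
        if contig_len > ins_b:
            sources.append(("flank", numt, ins_b, contig_len - ins_b))
            weights.append(float(numt.copy_number * stoich.cells * (contig_len - ins_b)))

    w = np.asarray(weights)
    src_idx = rng.choice(len(sources), size=n_fragments, p=w / w.sum())
    lengths = np.maximum(
        100, rng.normal(fragment_length_mean, fragment_length_sd, size=n_fragments)
    ).astype(int)
    u = rng.random(n_fragments)

    truth = world.truth
    molecules: list[Molecule] = []
    for i in range(n_fragments):
        kind, numt, reg_start, reg_len = sources[src_idx[i]]
        length = int(lengths[i])
        if kind == "mito":
            start = int(u[i] * L)
            end = start + min(length, L)
            seq = world.mito.segment(start, end)
            if truth:
                carried = []
                for s in truth:
                    if arc_contains(start, end, s.position, s.position + 1, L):
                        if rng.random() < s.true_frequency:
                            off = (s.position - start) % L
                            seq = seq[:off] + s.alt_allele + seq[off + 1 :]
                            carried.append(s.position)
            molecules.append(
                Molecule(
                    molecule_id=f"mda{i:06d}",
                    origin="mito",
                    sequence=seq,
                    mito_interval=(start, end),
                    weight=1.0,
                )
            )
        else:
            contig = world.nuclear_contigs[numt.nuclear_contig]
            start = reg_start + int(u[i] * reg_len)
            end = min(start + length, len(contig))
            origin = numt.numt_id if kind == "numt" else f"{numt.numt_id}|flank"
            mito_iv = None
            if kind == "numt":
                rel = start - numt.nuclear_offset
                if numt.strand == "+":
                    mstart = numt.mito_start + rel
                else:
                    mstart = numt.mito_start + (numt.length - (end - numt.nuclear_offset))
                mito_iv = (mstart % L, mstart % L + min(end - start, numt.length))
            molecules.append(
                Molecule(
                    molecule_id=f"mda{i:06d}",
                    origin=origin,
                    sequence=contig[start:end],
                    mito_interval=mito_iv,
                    weight=1.0,
                )
            )
    return MoleculePool(
        molecules=molecules,
        strategy="mda",
        seed=seed,
        params={
            "fragment_length_mean": fragment_length_mean,
            "fragment_length_sd": fragment_length_sd,
            "n_fragments": n_fragments,
            "mito_copies_per_cell": C,
        },
    )


# ---------------------------------------------------------------------------
# serialization


def write_panel(panel: AmpliconPanel, path: str | Path) -> None:
    rows = [
        {"amplicon": i, "start": a, "end": b}
        for i, (a, b) in enumerate(panel.amplicons)
    ]
    df = pd.DataFrame(rows, columns=["amplicon", "start", "end"])
    with open(path, "w") as fh:
        fh.write(
            f"#primer_length={panel.primer_length}\t"
            f"min_overlap={panel.min_overlap}\tmito_length={panel.mito_length}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_panel(path: str | Path) -> AmpliconPanel:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip()
        meta = dict(kv.split("=") for kv in header.split("\t"))
        df = pd.read_csv(fh, sep="\t")
    return AmpliconPanel(
        amplicons=tuple((int(r.start), int(r.end)) for r in df.itertuples()),
        primer_length=int(meta["primer_length"]),
        min_overlap=int(meta["min_overlap"]),
        mito_length=int(meta["mito_length"]),
    )


def write_pool(pool: MoleculePool, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write a pool as FASTA plus a sidecar TSV with origin/weight metadata."""
    with open(fasta_path, "w") as fa:
        for m in pool.molecules:
            fa.write(f">{m.molecule_id}\n{m.sequence}\n")
    pd.DataFrame(
        [
            {
                "molecule_id": m.molecule_id,
                "origin": m.origin,
                "mito_start": m.mito_interval[0] if m.mito_interval else -1,
                "mito_end": m.mito_interval[1] if m.mito_interval else -1,
                "weight": repr(m.weight),
            }
            for m in pool.molecules
        ],
        columns=["molecule_id", "origin", "mito_start", "mito_end", "weight"],
    ).to_csv(tsv_path, sep="\t", index=False)


def read_pool(
    fasta_path: str | Path, tsv_path: str | Path, strategy: str = "unknown", seed: int = -1
) -> MoleculePool:
    seqs: dict[str, str] = {}
    with open(fasta_path) as fa:
        name = None
        chunks: list[str] = []
        for line in fa:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
        if name is not None:
            seqs[name] = "".join(chunks)
    df = pd.read_csv(tsv_path, sep="\t")
    molecules = [
        Molecule(
            molecule_id=r.molecule_id,
            origin=r.origin,
            sequence=seqs[r.molecule_id],
            mito_interval=None if r.mito_start < 0 else (int(r.mito_start), int(r.mito_end)),
            weight=float(r.weight),
        )
        for r in df.itertuples()
    ]
    return MoleculePool(molecules=molecules, strategy=strategy, seed=seed)
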