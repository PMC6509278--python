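"""End-to-end orchestration: world → enrichment → reads → dual mapping →
calling → comparison.

``run_pipeline`` executes one enrichment strategy on one world and returns
everything the analyses need: call tables under both reference modes, the
per-variant discrepancy records and the class summary. All stage seeds are
derived deterministically from the single pipeline seed and recorded in the
result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calling import (
    DEFAULT_MIN_DEPTH,
    DEFAULT_MIN_FREQUENCY,
    SiteCall,
    call_sites,
    pileup,
)
from .comparison import (
    DEFAULT_THRESHOLD_PP,
    ComparisonSummary,
    DiscrepancyRecord,
    compare_runs,
)
from .enrichment import (
    STOICHIOMETRY_PRESETS,
    AmpliconPanel,
    MoleculePool,
    Stoichiometry,
    amplify,
    design_amplicon_panel,
    mda_fragments,
)
from .mapper import DEFAULT_MIN_IDENTITY, ReferenceIndex, build_indexes, map_all
from .sequencing import ReadSet, sequence_reads, trim_primers
from .world import World

__all__ = ["AMPLICON_STRATEGIES", "PipelineResult", "run_pipeline", "stage_seeds"]

#: Amplicon-count presets for the three PCR strategies. Primer lengths and
#: overlaps are configuration, not measured values.
AMPLICON_STRATEGIES: dict[str, dict] = {
    "lrpcr2": {"n_amplicons": 2, "primer_length": 25, "min_overlap": 100},
    "pcr9": {"n_amplicons": 9, "primer_length": 25, "min_overlap": 50},
    "pcr180": {"n_amplicons": 180, "primer_length": 20, "min_overlap": 30},
}


def stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Deterministic per-stage seeds derived from one pipeline seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


@dataclass
class PipelineResult:
    """Everything one strategy run produces."""

    strategy: str
    panel: AmpliconPanel | None
    calls_rcrs_only: list[SiteCall]
    calls_combined: list[SiteCall]
    records: list[DiscrepancyRecord]
    summary: ComparisonSummary
    mapping_stats: dict
    seeds: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def run_pipeline(
    world: World,
    strategy: str,
    stoich: Stoichiometry | str = "pooled_cells",
    seed: int = 0,
    n_reads: int = 60_000,
    read_length: int = 150,
    error_rate: float = 0.002,
    trim: bool = False,
    k: int = 15,
    accept_min_identity: float = DEFAULT_MIN_IDENTITY,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
    threshold_pp: float = DEFAULT_THRESHOLD_PP,
    max_primer_mismatches: int = 2,
    n_fragments: int = 100_000,
    fragment_length_mean: int = 2_000,
    fragment_length_sd: int = 300,
    indexes: tuple[ReferenceIndex, ReferenceIndex] | None = None,
) -> PipelineResult:
    """Run one enrichment strategy end to end on a world.

    ``strategy`` is one of ``lrpcr2``, ``pcr9``, ``pcr180`` or ``mda``;
    ``stoich`` is a :class:`Stoichiometry` or a preset name. Pre-built
    reference indexes can be passed to amortize indexing across strategies
    on the same world.
    """
    if isinstance(stoich, str):
        stoich = STOICHIOMETRY_PRESETS[stoich]
    s_enrich, s_reads, _, _ = stage_seeds(seed)

    panel: AmpliconPanel | None = None
    if strategy == "mda":
        pool: MoleculePool = mda_fragments(
            world,
            stoich,
            fragment_length_mean=fragment_length_mean,
            fragment_length_sd=fragment_length_sd,
            n_fragments=n_fragments,
            seed=s_enrich,
        )
    elif strategy in AMPLICON_STRATEGIES:
        cfg = AMPLICON_STRATEGIES[strategy]
        panel = design_amplicon_panel(
            world.mito,
            n_amplicons=cfg["n_amplicons"],
            primer_length=cfg["primer_length"],
            min_overlap=cfg["min_overlap"],
        )
        pool = amplify(world, panel, stoich, max_primer_mismatches, seed=s_enrich)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    reads: ReadSet = sequence_reads(
        pool,
        read_length=read_length,
        total_reads=n_reads,
        error_rate=error_rate,
        seed=s_reads,
    )
    if trim:
        if panel is None:
            raise ValueError("primer trimming requires an amplicon strategy")
        reads = trim_primers(reads, panel)

    if indexes is None:
        indexes = build_indexes(world, k=k, wrap=read_length + 150)
    mito_index, combined_index = indexes
    aln_rcrs, aln_comb, stats = map_all(
        reads, mito_index, combined_index, accept_min_identity
    )
    L = world.mito.length
    calls_r = call_sites(
        pileup(aln_rcrs, L, world.mito.name), world.mito, min_depth, min_frequency
    )
    calls_c = call_sites(
        pileup(aln_comb, L, world.mito.name), world.mito, min_depth, min_frequency
    )
    records, summary = compare_runs(calls_r, calls_c, threshold_pp)
    return PipelineResult(
        strategy=strategy,
        panel=panel,
        calls_rcrs_only=calls_r,
        calls_combined=calls_c,
        records=records,
        summary=summary,
        mapping_stats=stats,
        seeds={"pipeline": seed, "enrichment": s_enrich, "sequencing": s_reads},
        params={
            "n_reads": n_reads,
            "read_length": read_length,
            "error_rate": error_rate,
            "trim": trim,
            "k": k,
            "accept_min_identity": accept_min_identity,
            "min_depth": min_depth,
            "min_frequency": min_frequency,
            "threshold_pp": threshold_pp,
            "mito_copies_per_cell": stoich.mito_copies_per_cell,
            "pcr_jackpot_sd": stoich.pcr_jackpot_sd,
        },
    )
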