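"""Dual-reference comparison: discrepancy classes, clustering and tests.

Given the two call tables produced from the same reads — one aligned to the
mitochondrial reference in isolation, one to the combined mito + nuclear
reference — this module joins them per (position, variant allele), assigns
each variant a concordance class against an absolute frequency-difference
threshold (default 0.5 percentage points), and derives the downstream
analyses: scatter tables for frequency–frequency plots, positional
histograms against a NUMT coverage track, a Fisher exact test for
condition-level discrepancy proportions, and a circular-rotation
permutation test for positional clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calling import SiteCall
from .world import NumtRecord

__all__ = [
    "DiscrepancyRecord",
    "ComparisonSummary",
    "compare_runs",
    "scatter_data",
    "numt_coverage_track",
    "numt_base_track",
    "positional_histogram",
    "proportion_test",
    "permutation_position_test",
    "numt_similarity_stats",
    "report",
]

DEFAULT_THRESHOLD_PP = 0.5  # percentage points of heteroplasmy


@dataclass(frozen=True)
class DiscrepancyRecord:
    """Per-variant comparison between the two reference modes.

    Frequencies are percentages; ``None`` marks a variant absent from that
    mode. ``delta`` is the absolute frequency difference when both modes
    called the variant.
    """

    position: int  # 1-based
    variant_allele: str
    freq_rcrs_only: float | None
    freq_combined: float | None
    delta: float | None
    klass: str  # concordant | discrepant | exclusive_rcrs | exclusive_combined


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-run tallies of the discrepancy classes."""

    n_variants_union: int
    n_concordant: int
    n_discrepant: int
    n_exclusive_rcrs: int
    n_exclusive_combined: int
    pct_concordant: float
    threshold_pp: float

    def __post_init__(self) -> None:
        total = (
            self.n_concordant
            + self.n_discrepant
            + self.n_exclusive_rcrs
            + self.n_exclusive_combined
        )
        if total != self.n_variants_union:
            raise ValueError("class counts must sum to the union count")


def compare_runs(
    calls_rcrs_only: Sequence[SiteCall],
    calls_combined: Sequence[SiteCall],
    threshold_pp: float = DEFAULT_THRESHOLD_PP,
    reference_length_rcrs: int | None = None,
    reference_length_combined: int | None = None,
) -> tuple[list[DiscrepancyRecord], ComparisonSummary]:
    """Join two call sets on (position, variant allele) and classify each.

    A variant present in both modes is concordant when the absolute
    frequency difference is below ``threshold_pp`` percentage points and
    discrepant otherwise; variants present in exactly one mode are
    reference-exclusive.
    """
    if threshold_pp <= 0:
        raise ValueError("threshold_pp must be positive")
    if (
        reference_length_rcrs is not None
        and reference_length_combined is not None
        and reference_length_rcrs != reference_length_combined
    ):
        raise ValueError("reference lengths differ between the two call sets")
    a = {(c.position, c.variant_allele): c.variant_frequency for c in calls_rcrs_only}
    b = {(c.position, c.variant_allele): c.variant_frequency for c in calls_combined}
    records: list[DiscrepancyRecord] = []
    for key in sorted(set(a) | set(b)):
        fa, fb = a.get(key), b.get(key)
        if fa is not None and fb is not None:
            delta = abs(fa - fb)
            klass = "concordant" if delta < threshold_pp else "discrepant"
        elif fa is not None:
            delta, klass = None, "exclusive_rcrs"
        else:
            delta, klass = None, "exclusive_combined"
        records.append(
            DiscrepancyRecord(
                position=key[0],
                variant_allele=key[1],
                freq_rcrs_only=fa,
                freq_combined=fb,
                delta=delta,
                klass=klass,
            )
        )
    n = {k: sum(1 for r in records if r.klass == k) for k in
         ("concordant", "discrepant", "exclusive_rcrs", "exclusive_combined")}
    union = len(records)
    summary = ComparisonSummary(
        n_variants_union=union,
        n_concordant=n["concordant"],
        n_discrepant=n["discrepant"],
        n_exclusive_rcrs=n["exclusive_rcrs"],
        n_exclusive_combined=n["exclusive_combined"],
        pct_concordant=(100.0 * n["concordant"] / union) if union else 100.0,
        threshold_pp=threshold_pp,
    )
    return records, summary


def scatter_data(records: Iterable[DiscrepancyRecord], low_freq_cutoff: float = 4.0) -> pd.DataFrame:
    """Frequency–frequency scatter table (combined on x, mito-only on y).

    Reference-exclusive variants are plotted at 0 on the axis where they
    were not called. ``in_low_subset`` marks the expanded low-frequency
    panel (both frequencies below ``low_freq_cutoff`` percent).
    """
    rows = []
    for r in records:
        x = r.freq_combined if r.freq_combined is not None else 0.0
        y = r.freq_rcrs_only if r.freq_rcrs_only is not None else 0.0
        rows.append(
            {
                "position": r.position,
                "variant_allele": r.variant_allele,
                "freq_combined": x,
                "freq_rcrs_only": y,
                "klass": r.klass,
                "in_low_subset": bool(x < low_freq_cutoff and y < low_freq_cutoff),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["position", "variant_allele", "freq_combined", "freq_rcrs_only", "klass", "in_low_subset"],
    )


def numt_coverage_track(
    numts: Sequence[NumtRecord], mito_length: int, bin_size: int = 500
) -> np.ndarray:
    """Per-bin count of NUMT projections overlapping each mito bin.

    A NUMT increments every bin its projection touches; wrapping NUMTs
    count in the bins on both sides of the origin. With ``bin_size=1`` the
    track sums to the total number of NUMT-projected bases.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = (mito_length + bin_size - 1) // bin_size
    track = np.zeros(n_bins, dtype=np.int64)
    for numt in numts:
        touched: set[int] = set()
        for a, b in numt.projection_intervals(mito_length):
            if b <= a:
                continue
            touched.update(range(a // bin_size, (b - 1) // bin_size + 1))
        for t in touched:
            track[t] += 1
    return track


def numt_base_track(numts: Sequence[NumtRecord], mito_length: int) -> np.ndarray:
    """Per-base NUMT copy coverage (bin size 1), as weights for the
    positional permutation test."""
    return numt_coverage_track(numts, mito_length, bin_size=1)


def positional_histogram(
    records: Iterable[DiscrepancyRecord], mito_length: int, bin_size: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Two per-bin histograms aligned to the NUMT coverage track's bins:
    (a) variants whose mito-only frequency exceeds the combined frequency,
    (b) variants exclusive to the mito-only mode."""
    n_bins = (mito_length + bin_size - 1) // bin_size
    inflated = np.zeros(n_bins, dtype=np.int64)
    exclusive = np.zeros(n_bins, dtype=np.int64)
    for r in records:
        b = (r.position - 1) // bin_size
        if r.klass == "exclusive_rcrs":
            exclusive[b] += 1
        elif (
            r.freq_rcrs_only is not None
            and r.freq_combined is not None
            and r.freq_rcrs_only > r.freq_combined
        ):
            inflated[b] += 1
    return inflated, exclusive


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p-value comparing two discrepancy proportions."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    return float(sps.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided")[1])


def permutation_position_test(
    site_positions: Sequence[int],
    track: np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Circular-rotation permutation test for positional clustering.

    The statistic is the mean per-base track weight at the (0-based) site
    positions; the null rotates the whole position set by a uniform random
    offset around the circle. Returns the add-one-smoothed upper-tail
    p-value: ``(1 + #{rotations with statistic >= observed}) / (n + 1)``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    positions = np.asarray(site_positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("need at least one site position")
    track = np.asarray(track, dtype=float)
    L = track.shape[0]
    observed = float(track[positions % L].mean())
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, L, size=n_permutations)
    rotated = (positions[None, :] + offsets[:, None]) % L
    null_stats = track[rotated].mean(axis=1)
    n_ge = int(np.count_nonzero(null_stats >= observed - 1e-12))
    return (1 + n_ge) / (n_permutations + 1)


def numt_similarity_stats(numts: Sequence[NumtRecord]) -> tuple[float, float]:
    """Sample mean and SD of realized NUMT/mtDNA similarities.

    A single NUMT has SD 0 by convention.
    """
    if not numts:
        raise ValueError("need at least one NUMT")
    sims = np.array([n.similarity for n in numts], dtype=float)
    sd = float(sims.std(ddof=1)) if sims.size > 1 else 0.0
    return float(sims.mean()), sd


def report(
    summary: ComparisonSummary,
    records: Sequence[DiscrepancyRecord],
    histograms: tuple[np.ndarray, np.ndarray] | None,
    coverage_track: np.ndarray | None,
    tests: dict | None,
    out_dir: str | Path,
    metadata: dict | None = None,
    bin_size: int = 500,
) -> dict[str, Path]:
    """Write the machine-readable comparison report.

    Produces ``summary.json`` (class tallies, thresholds, test p-values,
    run metadata), ``scatter.csv`` (frequency–frequency table) and
    ``histograms.csv`` (per-bin NUMT coverage and variant histograms).
    Byte-identical for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary_json": out / "summary.json",
        "scatter_csv": out / "scatter.csv",
        "histograms_csv": out / "histograms.csv",
    }
    payload = {
        "summary": asdict(summary),
        "tests": tests or {},
        "metadata": metadata or {},
    }
    with open(paths["summary_json"], "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    scatter_data(records).to_csv(paths["scatter_csv"], index=False)
    if histograms is not None:
        inflated, exclusive = histograms
        df = pd.DataFrame(
            {
                "bin_start": np.arange(len(inflated)) * bin_size,
                "inflated": inflated,
                "exclusive_rcrs": exclusive,
            }
        )
        if coverage_track is not None:
            df["numt_coverage"] = coverage_track
        df.to_csv(paths["histograms_csv"], index=False)
    return paths
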