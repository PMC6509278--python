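# Methods

## The problem

Human cells carry hundreds to thousands of copies of the 16,569 bp circular
mitochondrial genome against two copies of each nuclear chromosome. A
sequence variant present in a fraction of the mtDNA molecules
(heteroplasmy) is quantified as the minor-allele fraction at a site, and
clinical thresholds (typically 60–80% mutant load) make the *accuracy* of
that fraction matter. The nuclear genome, however, contains on the order of
750 NUMTs — old insertions of mitochondrial sequence, ~100–6,000 bp long,
diverged to roughly 86% mean identity (SD ~4%) from today's mtDNA. When
sequencing reads are aligned to a mitochondrial reference *in isolation*,
NUMT-derived reads that were co-enriched with the mtDNA have nowhere else
to go: they are close enough to pass identity filters, pile up on the
mitochondrial coordinate system, and masquerade as low-level heteroplasmy.
Aligning the same reads to a *combined* mito + nuclear reference lets them
map to their true origin and removes the artifact. `numtshadow` reproduces
this mechanism end to end in a fully synthetic, ground-truthed world.

## The simulated world

`world.generate_*` builds one synthetic individual:

- **Mito reference** — a random circular ACGT sequence (default 16,569 bp,
  matching the rCRS length). A real reference FASTA can be loaded instead
  through `read_world`; nothing downstream assumes random sequence.
- **Heteroplasmy truth** — a list of (position, alt, frequency) sites;
  frequency 1.0 encodes homoplasmy. Positions are 0-based internally and
  1-based in every human-facing table (VCF convention).
- **NUMTs** — each copies a random circular interval (length uniform over
  100–6,000 bp; the literature gives only the range, so uniform is the
  simplest defensible choice), substitutes each base independently with
  probability 1−s where s ~ Normal(0.86, 0.041) truncated to [0.70, 0.995],
  and embeds the copy (random strand) in its own fresh random contig with
  2,000 bp flanks per side. One contig per NUMT preserves the mapping
  competition without a 3-Gb nuclear genome. Substitutions only — the
  mapper is ungapped, and indel structure is out of scope. Intervals may
  wrap the origin; BED output splits wrapped projections in two.
  `position_range` confines insertions to a sub-arc, used to emulate the
  positional clustering of NUMT interference.

Worlds round-trip losslessly through plain-text FASTA/BED/TSV/JSON, and
every stage derives its RNG seed deterministically from one pipeline seed.

## Enrichment

Four strategies, mirroring common laboratory practice:

- **Amplicon PCR** (`lrpcr2` = 2 amplicons of ~8.4 kb, `pcr9` ≈ 1.9 kb,
  `pcr180` ≈ 122 bp): amplicons tile the circle evenly with configurable
  overlap. A NUMT is **co-amplified** by an amplicon iff the amplicon's
  interval lies inside the NUMT's mito projection and the NUMT's realized
  mismatches within each primer footprint (the terminal `primer_length`
  bases) number ≤ 2. This is the minimal primer-binding model consistent
  with the geometry: an amplicon longer than the longest NUMT can never be
  co-amplified, which is what makes long-range PCR NUMT-safe. Product
  termini retain *template* bases (primer replacement of the footprint is
  not modelled); consequently primer trimming removes the NUMT-divergent
  footprint bases, which is the trimming benefit observed downstream.
- **Template weights**: mito haplotype classes get weight ∝ C·cells·f,
  co-amplified NUMTs ∝ copy_number·cells; C is the mtDNA copy number per
  cell (presets: 100 for pooled cells, 500 for tissue homogenate — chosen
  configuration, not measured values). Haplotype classes are built by an
  exact stick-breaking coupling, so per-site marginal alt fractions equal
  the true frequencies for *any* frequency sum. An optional lognormal
  "jackpot" factor (σ = `pcr_jackpot_sd`) models stochastic amplification
  in low-template reactions; it is 0 in all quantitative tests.
- **MDA** (`mda`): untargeted fragmentation. Each fragment's source (mito
  circle, a NUMT insert, or its flanks) is drawn ∝ copy-number-weighted
  length; starts are uniform, lengths Normal(2,000, 300) truncated at 100
  bp, mito fragments wrap and carry alt alleles per site with probability
  f. No displacement branching or chimeras — uniform copy-weighted sampling
  is sufficient to produce the stoichiometric contamination level. A site
  covered by k diploid NUMT copies acquires a NUMT-read fraction of
  2k/(C + 2k); at C=100, k=1 that is ≈1.96%, and the pipeline recovers it.

## Sequencing

Single-end reads (default 150 bp, substitution rate 0.002, constant Q30)
are drawn from molecules ∝ weight with uniform start and strand. Provenance
(molecule, offset, strand) is retained for every read so oracle tests can
audit the mapper and pileup. `trim_primers` removes the bases of a read
that overlap its molecule's terminal primer footprints.

## Dual-reference mapping

A deliberately transparent seed-and-extend mapper: exact k-mer seeds
(k = 15, every read position, both strands, candidates capped at 200 in
deterministic order), ungapped scoring (+1/−1), acceptance when the best
locus has identity ≥ 0.88 and is uniquely best. Exact ties across distinct
loci → `ambiguous`, excluded from pileups (the analogue of MAPQ-0
filtering). The mito contig is extended by a wrap margin so origin-spanning
reads align contiguously; positions are reported modulo L.

The identity floor of 0.88 sits *below* typical NUMT divergence plus error,
deliberately: mito-only references must accept high-similarity NUMT reads
for the phenomenon to exist, while the 86%-mean divergence keeps the most
diverged NUMTs out. Two properties are guaranteed by construction and
verified over randomized worlds: with zero NUMTs the two modes are
identical, and the set of mito-mapped reads under the combined reference is
a subset of the mito-only set (competition can only remove or re-home
reads). A brute-force all-positions scorer — written independently in the
test suite — agrees with the mapper on status, position, strand and score
for short reads, where ≤3 substitutions in a 60 bp read provably leave an
intact 15-mer seed.

## Calling and comparison

Pileup counts A/C/G/T per position (wrapping modulo L); a site call reports
the single best-supported non-reference allele where depth ≥ 100 and
frequency ≥ 0.2% (below the 0.5 pp comparison threshold, so the comparison,
not the caller, defines discrepancy classes). One practical corollary: the
0.2% floor only sits above single-read noise once depth exceeds ~500, so
quantitative comparisons in this package run at ≥500× mean depth. No
strand-bias or quality filtering — the data are simulated and the frequency
pathway is kept transparent.

`compare_runs` joins the two modes' calls on (position, variant allele) —
a different allele at the same position is deliberately counted as two
exclusives — and classifies: **concordant** (|Δf| < 0.5 pp, absolute
difference), **discrepant** (≥ 0.5 pp), or **exclusive** to one mode.
Downstream analyses: frequency–frequency scatter tables (exclusives plotted
at 0 on the absent axis; a <4% sub-panel flag), per-bin histograms of
frequency-inflated and mito-only-exclusive variants aligned to a NUMT
coverage track, Fisher's exact test for condition-level discrepancy
proportions (chosen over a z-test because exclusive counts are small), and
a circular-rotation permutation test for positional clustering (statistic:
mean per-base track weight at the variant positions; null: random rotation
of the position set; add-one smoothing). The rotation test is a declared
stand-in for an unnamed correlation analysis; on a constant track all
rotations tie and p = 1 by construction.

## What the synthetic world does and does not show

The generator reproduces the *mechanism*: copy-number stoichiometry,
amplicon-size geometry, primer-site divergence, and mapping competition.
Passing tests therefore demonstrate that the pipeline's discrepancy classes
respond to NUMT interference exactly as the mechanism predicts — they do
not calibrate against any real sequencing run. Not modelled: indels and
rearranged NUMT structure, PCR chimeras and true MDA branching, paired-end
reads, base-quality variation, platform error spectra, population NUMT
polymorphism, and real primer thermodynamics. Random reference sequence
also lacks the repeat structure of real mtDNA, so ambiguity rates here are
a lower bound.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.default_rng`; stage seeds are
  spawned from one pipeline seed and recorded in result metadata; identical
  seeds give byte-identical output files.
- Truncated-normal similarity is drawn by rejection (exact, deterministic);
  SD 0 short-circuits to the mean.
- Stick-breaking haplotype segments below 1e-15 are dropped; the permutation
  test compares with a 1e-12 tolerance so exact ties count as ≥.
- Fragments clipped at contig ends may undercut the seed size; such reads
  are reported unmapped rather than erroring.
- Empty inputs: empty truth lists produce header-only tables; an empty pool
  refuses to sequence; similarity statistics require ≥1 NUMT (SD of a single
  NUMT is 0 by convention).

## Default problem sizes

Tests and the acceptance script run, per condition, ~30–60k reads
(≈270–540× mean depth), 80–200k MDA fragments, and worlds of 1–750 NUMTs;
these sizes make every Monte-Carlo check resolvable within its stated
standard-error tolerance while keeping a full run in minutes on one CPU.
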