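# Methods

## Coordinate model

All internal coordinates are 0-based, half-open (BED convention); two spans
share a base iff `a.start < b.end and b.start < a.end`, so book-ended
records do not overlap. Supplementary-style XLSX tables are treated as
1-based, fully-closed browser coordinates and converted on read (the
`one_based` flag disables this). Chromosome naming is normalized by a
`chrom_style` flag (`"chr"`/`"plain"`) on every reader, because mismatched
naming between tracks is the most common silent failure in interval work.
When a peak record carries no explicit summit, the region midpoint
`floor((start+end)/2)` is used; this is a documented assumption, since
peak callers that emit summits were upstream of the published tables.

## Peak-set construction

- **Reproducibility**: a peak is kept when it shares ≥ 1 bp with a peak in
  the other replicate. Replicate-1 coordinates are retained by default;
  which replicate's span survives is a genuinely open choice, so
  `span="intersection"` is available as the alternative.
- **Stringency refinement**: where a region was called at both p < 1e-4 and
  p < 1e-5, the narrower high-stringency coordinates replace the loose
  ones; several strict peaks inside one loose region all survive and the
  loose record is dropped. Strict peaks overlapping no loose peak indicate
  inconsistent call sets and trigger a warning.
- **Time-point combination**: overlapping peaks take the late (3–3.5 h)
  coordinates; early-only peaks pass through; every output record carries
  the set of contributing time-point labels.
- **Factor combination (BMP list)**: precedence pMad-late > Brk-late >
  pMad-early > Brk-early. Only the first sentence of that ordering (late
  pMad wins) is externally fixed; the rest follows the same late-over-early,
  pMad-over-Brk logic and is a package design choice. Chained overlaps
  collapse transitively onto the highest-precedence accepted coordinates,
  contributing flags only.
- **Normalization factors**: factor_i = mean(sample medians)/median_i, so
  applying the factors equalizes all sample medians exactly.

## Association testing

Anchors are the peak summit and the gene TSS on both analysis directions
(TSS is only externally fixed for the peak-to-gene direction; using it for
gene-to-peak as well keeps the two directions symmetric, and the unordered
pair set of both directions is identical when the gene subset is "all").
The window boundary is inclusive (|TSS − summit| ≤ d). Genes on
chromosomes without peaks count as "not near" rather than being dropped,
since dropping them would inflate the near rates of both classes.

The 2×2 table {DE, non-DE} × {near, not near} is tested with Pearson's χ²
(df = 1, no continuity correction; `scipy.stats.chi2_contingency`). The
binomial test is one-sided (upper tail) because the scientific question is
directional — are DE genes *more* likely to be near a peak: P(X ≥
near_DE), X ~ Binomial(tot_DE, near_nonDE/tot_nonDE). When the non-DE near
count is zero while the DE count is not, the null rate is degenerate; the
result is reported as p = 0 with a `degenerate_null` flag rather than an
error. A table with a zero near-column or far-column carries no
association signal and is reported as χ² p = 1.

## Overlap analysis

Percentage overlap is query-record based: 100 × |records of the query with
≥ 1 bp in the target| / |query|. Merging the target first never changes
this count (a tested invariant), and multi-experiment factor tracks are
concatenated and merged before use so neither side double-counts.
External enhancer sets are stripped of BMP-overlapping records
(`exclusive_prep`) before their own overlap statistics are computed, so
the comparison describes genuinely non-BMP regions. Phantom-Peak
classification intersects dual-bound regions with the published phantom
catalogue, reassigns candidates present in the DamID track as real, and
reports the remainder as potential phantoms; the percentage is taken
relative to the dual-bound set (not the candidate set), matching how the
headline fraction is phrased.

## Motif enrichment

Windows are 250 bp (125 bp either side of the summit); windows that would
run off a chromosome end are skipped with a logged warning. Containment is
binary per window (≥ 1 match), which is what a "percent of peaks containing
the motif" means; both strands are scanned because Smad/Zld sites act
orientation-independently in enhancers. IUPAC codes in the consensus expand
to ACGT character classes, so an N in the *sequence* matches nothing.
Enrichment is pct_test/pct_control with a two-tailed Fisher's exact test
(`scipy.stats.fisher_exact`); the test suite cross-checks that route
against an exhaustive hypergeometric enumeration for every 2×2 table with
row margins ≤ 30. A motif absent from both sets reports ratio 1 (no
evidence either way); absent only from the control set, the ratio is
infinite and flagged.

## Synthetic-data generator

The generator emulates the statistical shape of the study: a
multi-chromosome i.i.d. genome at 42% GC (the fly genome's value), 2000
genes of which 15% are DE, 300 peaks with summits uniform over the genome,
a second replicate derived by Gaussian summit jitter (sd 20 bp) and 10%
Bernoulli dropout, interval tracks overlapping a Bernoulli fraction (60%
default) of reference records with decoys placed off-reference, and 250 bp
windows with a motif planted in 40% of test vs 10% of control windows.
Defaults are two 5 Mb chromosomes, keeping a full generate-analyze round
trip in seconds; these sizes are the package's default study conditions
for all statistical validation.

**DE placement.** Let *b* be the genomic fraction covered by the ±d₀
summit windows (computed exactly from the merged windows). A DE gene's TSS
is placed uniformly inside that union with probability
p_near = (effect − 1)·b/(1 − b), otherwise uniformly over the genome.
The resulting DE near-rate is then exactly effect·b while the non-DE rate
is b, so the planted DE/non-DE near-rate ratio equals the configured
`proximity_effect` — the quantity the recovery tests measure. The naive
rule "place near a summit with probability effect·b" would instead
converge to a ratio of effect + 1 at small b. Placement is declared
infeasible (an error) when the windows cover the whole genome. DE labels
are assigned before placement: labels cause geometry, mirroring the causal
direction the association test assumes.

**What the generator does not emulate:** read-level noise, fragment-size
effects, GC or mappability bias, clustered gene/TSS structure, correlated
peak widths, or real motif composition of enhancers. Passing tests
therefore demonstrate that the algebra, counting and tests behave as
specified under planted effects — not that any biological conclusion about
real data is reproduced.

## Numerical and degenerate-input choices

- Interval overlap queries run on `intervaltree` per chromosome; all
  brute-force oracles in the tests are independent all-pairs or per-base
  scans.
- `merge` joins book-ended records (distance 0), matching the common
  merge-tool default; it is idempotent and its covered-base count is
  verified against a per-base set oracle.
- Empty inputs: intersections of empty collections are empty; percentage
  overlap and phantom classification reject an empty query/dual-bound set
  (a percentage of nothing is undefined); enrichment rejects empty window
  lists.
- Determinism: every stochastic routine consumes a `numpy` `default_rng`
  seeded from `SimulationConfig.seed`; identical seeds give byte-identical
  FASTA/BED/JSON outputs.

## Validation scales

The statistical acceptance checks use: 200 random instances for
interval-algebra oracles; 200 null simulations for type-I error (exact
binomial 95% band around α = 0.05); 100 simulations at a 3× effect for
power (> 0.9 required); exhaustive Fisher enumeration for margins ≤ 30;
100 seeded runs for motif-ratio recovery (planted containment rates
0.4/0.1, 200 windows each, background match rate included in the expected
ratio); 500 reference records for track-overlap recovery inside the exact
binomial 95% interval. These sizes are the package's chosen validation
conditions and give each stochastic check a ~95% coverage band.

## Known limitations

- The reproduction mode recomputes counts from coordinate tables; it
  cannot re-derive peak calls or DE calls from raw reads (alignment, peak
  calling and expression modeling are upstream and out of scope).
- The binomial null treats the non-DE near rate as a fixed success
  probability rather than an estimated one; the χ² test is the primary
  calibrated statistic, and both are reported.
- `stringency_refine` trusts that strict calls are nested in loose calls;
  orphan strict peaks are warned about and ignored, never invented into
  the output.
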