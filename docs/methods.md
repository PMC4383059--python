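# Methods

## Problem setting

A case/control GWAS is m SNPs × n samples; genotypes are coded 0/1/2
(copies of the variant allele in a diploid), phenotypes Y ∈ {0 control,
1 case}. A k-way interaction screen scores every k-subset of SNPs by a
statistic on the 2 × |V| contingency table of phenotype class against
genotype combination, |V| = 3^k. The package implements the screening
stage only: a fast statistic applied exhaustively, whose survivors a
slower confirmatory analysis would re-examine. It does not correct for
multiple testing and does not model covariates.

## Bit-sliced representation

Each SNP is stored as three binary vectors (one per genotype value),
further split by phenotype class and packed into 64-bit words — six
packed vectors per SNP. Cell (c, v) of a tuple's table is the popcount
of the AND of the k class-c vectors selected by v's base-3 digits. Costs
scale with ⌈n_c/64⌉ words per vector; popcount is a word-level SWAR
computation inside the numba kernel and `numpy.bitwise_count` elsewhere,
never per-bit iteration.

Splitting by class (rather than masking a phenotype vector per cell) is
a deliberate choice: each cell is one AND+popcount pass and the class
split is paid once at binarisation.

Missing genotypes set no bit in any plane, so a sample missing at any
SNP of a tuple vanishes from that tuple's entire table — tuple-wise
complete-case analysis. Consequently n (the table total) varies by
tuple and equals the number of samples fully observed at its SNPs.

Column enumeration is fixed: the first SNP of the tuple (the largest
index, x_k) supplies the most significant base-3 digit. The chi-squared
statistic is invariant to this order; fixing it makes output
reproducible and lets the naive oracle compare cell-by-cell.

A pure-Python per-sample counting oracle (`naive_contingency_table`)
mirrors the same enumeration and is used throughout the tests to verify
the bitwise path.

## Chi-squared screen

χ² = Σᵢⱼ (nᵢⱼ − Eᵢⱼ)²/Eᵢⱼ with Eᵢⱼ = nᵢ₊·n₊ⱼ/n, df = |V| − 1, and the
p-value is the upper tail of the χ²_df distribution (scipy). Numerical
choices:

- **Empty columns.** Genotype combinations absent from the data
  (n₊ⱼ = 0) are skipped in the sum (their 0/0 terms contribute 0) while
  df remains |V| − 1. This follows the stated df rule literally;
  `df_mode="observed"` (non-default) counts only populated columns.
  Under strong LD or at k = 3 with n ~ 2000 many columns are nearly or
  exactly empty, and the full-df rule then makes the screen
  *conservative* (fewer small p-values than nominal) — verified by the
  null-calibration tests. A screen erring conservative was preferred
  over silently changing the printed rule.
- **No continuity correction, no minimum-expected-count guard**; the
  result flags tables with any Eᵢⱼ < 5 (`low_expected`) so callers can
  treat them cautiously.
- **Degenerate tables** (n = 0 or an empty phenotype row, e.g. a SNP
  entirely missing in one class) raise, and the scan reports the
  offending tuple.
- Thresholding is available in score space (keep score ≥ t, the
  default) or p-value space (keep p ≤ t); for the chi-squared fast path
  the p threshold is translated to the equivalent score cut through the
  inverse survival function, which is exact by monotonicity.

Any other table statistic can be registered (`register_statistic`) and
used by the scan; the registry path evaluates tuples in Python and is
intended for prototyping statistics, not throughput.

## Combinadic decomposition and the scan executor

rank(x_k,…,x₁) = Σᵢ C(xᵢ, i) bijects strictly decreasing tuples onto
[0, C(m,k)); unranking is greedy (largest xᵢ with C(xᵢ,i) ≤ remainder).
Work is split into contiguous intervals of size ⌊C(m,k)/N⌋, the first
C(m,k) mod N workers taking one extra. Each worker unranks its interval
start once and then walks tuples by the O(1)-amortised colexicographic
successor, so the inner loop does no binomial arithmetic. Workers are
threads over a shared read-only bit-sliced dataset; the chi-squared
kernel is numba-compiled `nogil`, so threads scale on real cores. Scores
are computed identically regardless of partitioning, making the merged
output bit-identical for any worker count (tested for N ∈ {1,2,3,8}).

Kept results are buffered per worker as arrays and concatenated in rank
order (the single merge point); a cap (default 10⁷ kept results)
protects keep-all scans at large m. Exact binomials use Python integer
arithmetic; the kernel's linear indices are int64, so scans are limited
to C(m,k) < 2⁶³ — far beyond anything a desk machine can enumerate.

## Synthetic cohorts

The generator emulates haplotype-mosaic resampling at desk scale; it is
not a reimplementation of a population-genetic simulator.

- **Panel.** h haplotypes over m sites. Per-site target frequencies are
  drawn uniformly from `maf_range` (default 0.05–0.5). Haplotypes come
  from a Gaussian-copula AR(1) latent process (coefficient
  `ld_strength`, default 0.9): marginals are exactly Bernoulli(f_j)
  while nearby sites correlate positively, giving the panel haplotype-
  block structure.
- **Mosaics.** Each individual is two independent haplotypes that copy
  a uniformly chosen panel template and re-choose it at each site with
  probability `recomb_rate` (default 0.01); genotype = allele sum. At
  `recomb_rate=0` samples are exact panel haplotype pairs; at 1 sites
  decouple. LD decay with site distance is tested (adjacent vs ≥ 50
  sites apart, both signed correlation and r²).
- **Phenotypes.** A penetrance table assigns P(case | genotype
  combination at a causal tuple); a flat table gives null data. An
  exact case/control split is obtained by simulating a larger pool
  (default 2n) and subsampling to `target_cases`. Effect embedding is
  an extension beyond plain null simulation — detection tests need
  signal. The shipped `xor_pair` model (case probability `high` on
  odd-parity combinations, `low` otherwise) is a standard
  pure-epistasis pattern with no marginal effect at allele frequency
  0.5.

What the generator does *not* reproduce: realistic recombination maps
and hotspots, allele-frequency spectra from real panels, population
structure and relatedness, genotyping error. Passing tests therefore
demonstrate correctness of the engine and qualitative realism of LD,
not calibration against any real cohort.

Default test-scale cohorts use hundreds to a few thousand SNPs and
2000 samples (the per-dataset sample size the screening literature
typically simulates); all sizes are arguments.

## Benchmarking and runtime projection

`measure_strong_scaling` runs the identical keep-all scan at each
worker count (first count must be 1 to define t₁), repeats each
measurement (default 3) and keeps the minimum; S = t₁/t_N, E = S/N.
The timed region covers binarisation, the kernel scan and the array
merge; materializing Python result objects and file I/O are outside it,
since they are presentation-layer and would serialise an otherwise
parallel measurement. Worker counts beyond the physical core count are
measured but warned about — a CPU-bound scan cannot speed up past the
hardware, so efficiency at N workers is only meaningful on ≥ N cores.

`scale_reported_runtime` projects a runtime reported on other hardware
and data size onto the reference configuration (1.1M SNPs, 2000
samples; 262,144 threads at 1.6 GHz for CPU, 448 at 1.22 GHz for GPU):
t·(1.1×10⁶/n_SNP)²·(2000/n_sample)·(n_cores/C_ref)·(f_clock/f_ref).
These are order-of-magnitude estimates — they ignore memory systems,
vector widths and algorithmic differences — and are kept at full
precision, rounding only for presentation.

`extrapolate_higher_order` multiplies a measured runtime by
C(m,k_to)/C(m,k_from) in exact rational arithmetic (for 2→3 this is
exactly (m−2)/3), assuming perfect linearity in the interaction count.

## Known limitations

- Single-machine workers only; no inter-node distribution or
  checkpointing.
- The chi-squared screen is anti-conservative on tables with very small
  expected counts and conservative under the full-df rule with many
  empty columns; it is a screen, not a final test.
- Keep-all p-values within one cohort are mutually dependent (pairs
  share SNPs, and LD correlates nearby pairs), so distributional checks
  of calibration must pool across independent cohorts rather than apply
  iid tests within one scan.
- No VCF/BGEN/binary-PLINK input, no imputation, no X-chromosome
  handling.
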