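# Methods

## The problem

RT-qPCR quantifies a target transcript relative to one or more reference
genes assumed to be uniformly expressed across samples. When no validated
reference panel exists for a species, candidates are screened from RNA-seq,
validated by RT-qPCR across tissues and treatments, ranked for stability by
several algorithms, and finally used to normalize target genes. This
package implements that pipeline end to end, together with synthetic-data
generators whose ground truth closes the testing loop.

## Screening statistics

For each gene across samples: MV (mean FPKM), SD, MFC = max/min and
CV = SD/MV. A candidate passes when MV > `mv_min` (default 50, FPKM),
MFC < `mfc_max` (default 1.5) and CV < `cv_max` (default 0.1); all
comparisons strict. A zero minimum FPKM leaves MFC undefined and the gene
fails. Candidates are ordered by ascending SD with lexicographic
tie-break; `top_n` truncation stands in for the manual annotation-based
curation that typically trims the list to a primer-design shortlist.
Every matrix column is one sample; if biological replicates should be
averaged first, that collapse is the caller's pre-step
(`collapse_technical_replicates` covers the technical-well case).

## Cq conventions

Missing Cq ("no amplification") stays missing and is deleted pairwise per
computation; any computation that falls below its minimum sample count
raises rather than degrading silently. Every standard deviation uses the
sample convention (n−1) via `sd_mode="sample"`; the population variant is
a config switch. Relative quantities are q = E^(Cq_min − Cq) with
amplification base E defaulting to 2.0 (perfect doubling) even when a
measured primer efficiency is available — matching the prevailing 2^−ΔΔCq
practice; per-gene bases are supported. The log2 quantities used by
geNorm/NormFinder are computed directly from Cq (not by logging the
exponentiated q) to avoid a needless rounding round trip.

## The four stability algorithms

* **delta-Ct**: stability of gene *i* = mean over partners *j* of
  SD_s(Cq_i − Cq_j), computed on each pair's common samples (≥ 3, else
  the pair is skipped with a warning). Units: cycles.
* **BestKeeper**: computed on complete-case samples (≥ 3). The stability
  value is the per-gene Cq SD (the original mean-absolute-deviation
  variant sits behind `use_mad`, default off; ranking always uses the
  dispersion value, not CV%). The BestKeeper index is the per-sample
  geometric mean of Cq over **all** input genes — the gene under study is
  not left out, matching the original description — and each gene's
  Pearson r against it is reported descriptively.
* **geNorm**: V_jk = SD_s(log2 q_j − log2 q_k); M_j = mean over remaining
  partners; the worst gene is removed and M recomputed until two remain,
  which are reported tied at rank 1.5 (the algorithm cannot order them).
  The reported value is M at the removal step (survivors: final M); the
  full-panel initial M is kept in the extras. Each pairwise log-ratio
  vector is anchored at its first common sample before the SD — a
  mathematical no-op that makes M bit-invariant to rescaling any gene's
  q (equivalently, to per-gene Cq offsets). Removal ties are broken by
  dropping the lexicographically last gene id, so results are
  deterministic and reproducible by the brute-force oracle in the test
  suite. Pairwise variation V(n/n+1) = SD_s(log2 NF_n − log2 NF_{n+1}),
  with NF_n the geometric mean of the n most stable genes, is reported;
  the conventional V < 0.15 sufficiency guideline is left to the reader.
* **NormFinder**: y = log2 q, complete cases within each group, ≥ 2
  samples per group, ≥ 3 genes. Within group i the residuals
  z = y − ȳ_g − ȳ_s + ȳ give raw mean squares u_g whose expectation is
  σ_g²(1 − 2/G) + σ̄²/G (removing per-sample means over G genes absorbs
  part of each gene's own noise); the implementation inverts that linear
  map for an unbiased σ̂_g², clipped at zero. With ≥ 2 groups the
  intergroup deviation d_gi = (ȳ_gi − ȳ_g·) − (ȳ_·i − ȳ_··) is shrunk by
  d̃ = d·γ²/(γ² + σ̂²/n_i), γ² = max(0, Var_g(d) − mean_g(σ̂²/n_i))
  estimated per group (γ² = 0 collapses d̃ to 0), and the stability is
  ρ_g = mean_i(|d̃_gi| + sqrt(σ̂²_gi/n_i)). With one group the stability
  is sqrt(σ̂_g²). The default grouping is the metadata `group` column
  (treatment); tissue or cultivar groupings are a flag away.

## Consensus

The comprehensive rank is the geometric mean of the per-method fractional
ranks (1 = most stable) — ranks, not stability magnitudes, so methods
with different units weigh equally. Fractional inputs (geNorm's 1.5/1.5
tie) enter as-is. The final order is ascending geomean with fractional
final ranks and gene-id tie-break; the result is invariant to the order
in which method results are supplied.

## Quantification

Standard curves are ordinary least squares of Cq on log10 concentration;
E = (10^(−1/slope) − 1) × 100%, R² the squared Pearson correlation. A
non-negative slope leaves E undefined with a warning (primer failure
signal). ΔΔCq is computed per sample against the **mean** control ΔCq
(not a single calibrator well); with two references the two
single-reference ΔΔCq values are averaged, which makes the double-
reference RQ exactly the geometric mean of the single-reference RQ
series — an identity the tests assert to 1e-12. Summaries report the SD
of biological replicates and label it as such. Concordance between
normalizations is a pairwise Pearson matrix on whatever scale the caller
supplies — raw Cq for cross-cultivar stability checks, log2 RQ for
comparing normalizations of the same targets; both are exposed because
either convention is defensible.

## Synthetic data

The Cq generator draws
Cq_gs = a_g + t_{g,grp(s)} + δ_s + e_gs, with baselines a_g ~ U(18, 30),
per-sample loading effect δ_s ~ N(0, σ_load²) shared by all genes of a
sample (pipetting / input-amount variation) and per-well noise
e_gs ~ N(0, σ_g²). Noise is Gaussian on the Cq scale — multiplicative on
abundance, the standard qPCR error structure; heavier tails are not
modelled. The loading and residual streams are drawn from separate
spawned PCG64 child generators, so runs differing only in σ_load share
their residuals (used by the loading-invariance tests). The expression
generator emulates a 4-tissue × 3-replicate FPKM profile: stable genes
with baseline > 60 and CV < 5%, tissue-variable genes with multipliers
forcing MFC ≥ 2, plus optional zero-FPKM and exactly-constant edge genes;
the recorded truth is always evaluated by brute force on the realized
matrix, never assumed from the construction. The default pooled-stress
scenario in the CLI uses 32 genes and 18 groups × 3 replicates = 54
samples, mirroring a multi-tissue multi-treatment design. Dilution series
run 10-fold from relative concentration 1 with
slope = −1/log10(1 + E_true). What passing these benchmarks does **not**
show: robustness to non-Gaussian dropout patterns, inhibition,
plate/batch structure beyond a scalar loading effect, or primer-specific
efficiency drift — real validation still needs wet-lab data.

## Numerical choices and benchmark scales

Fractional (mean-of-span) ranking throughout; validation errors name the
offending genes/samples; reports serialize floats at 6 significant
digits, the round-trip precision the IO tests assert. Exact-cancellation
tests (loading shifts) place Cq values and shifts on a 2^−10 grid where
IEEE addition is lossless, so pairwise-difference methods can be asserted
bit-identical rather than approximately equal.

Benchmark problem sizes were chosen to make each property statistically
decisive while staying desk-scale: 100 seeded replicates for the
efficiency (5-point series, noise SD 0.1 — per-replicate estimator SD is
~1.3 points by slope-error propagation, so recovery is asserted on the
mean) and noise-ordering benchmarks (5 genes with SDs 0.05–1.0 over 24
samples), 200 random instances for the geNorm oracle, 50 scenarios for
screening truth. On the noise-ordering benchmark, delta-Ct, BestKeeper
and geNorm identify the noisiest gene essentially always; resolving the
two quietest genes (SD 0.05 vs 0.1) is harder for methods whose
statistics mix in partner-gene noise — NormFinder lands the quietest gene
in the top 2 about 95% of the time, and the consensus, which inherits
geNorm's structural top-pair tie, puts it strictly first in roughly 80%
of replicates. BestKeeper's marginal SD resolves the same pair
essentially always, showing the information is present in the data; the
limitation is intrinsic to the published algorithms, and the acceptance
suite reports the measured rates rather than adjusting the benchmark.

## Known limitations

Annotation-based candidate curation and homolog search are outside the
package (supply curated gene lists directly). The RefFinder web tool's
undocumented internal variants are not replicated — the four algorithms
are implemented from their defining formulas. No differential-expression
testing is performed on quantification output; summaries are descriptive.
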