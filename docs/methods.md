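# Methods

## The analysis model

`stresscan` compares two cell populations — a control ("F/F") and a mutant
("FC/FC", MLL2-deficient) — profiled by γH2AX, H2AX, H3 and RNAPII ChIP-seq
and strand-resolved GRO-seq. All coordinates are 0-based half-open
internally; BED/bedGraph are consumed verbatim and GTF is shifted on read.
Coverage is piecewise-constant signal; regions absent from a bedGraph read
as zero, which is bedGraph semantics rather than missingness.

Per gene, mean density is computed over the gene body extended by a 500 bp
flank on each side (clamped to chromosome ends). γH2AX and H2AX densities
are divided per gene by the H3 density of the same condition before the
mutant:control ratio, which cancels nucleosome-occupancy differences;
RNAPII and GRO ratios are taken on densities directly. GRO is quantified on
each gene's sense strand only. A gene is *active* when its control-condition
GRO density is positive and its window holds at least 10 signal units
(density × window length); both knobs are explicit parameters because
"actively transcribed" has no canonical operational definition. Every
downstream selection uses active genes only.

Classification:

- **damage rank** — active genes sorted by γH2AX/H3 mutant:control ratio,
  descending, ties broken lexicographically on gene id; the top
  round-half-up(0.10 · n) genes form the top-damage set. Round-half-up is
  chosen because it reproduces both 414/4140 and 216/2158. Z-scores of the
  log₂ ratios are reported alongside; log₂ treats gains and losses
  symmetrically, and since the Z-score is a strictly monotone transform of
  the ratio, both statistics induce the same ranking.
- **stress call** — strictly r_RNAPII > 1 and r_GRO < 1. The boundary cases
  (1.0, 0.9) and (1.2, 1.0) are deliberately negative.
- **stress rank** — stress genes ordered by r_RNAPII / r_GRO. No canonical
  ranking statistic exists for "most transcription stress"; the
  ratio-of-ratios is used because it measures the RNAPII/nascent-RNA
  uncoupling directly and is monotone in both defining criteria. The decile
  fraction and the damage-ranking statistic are configurable.

Enrichment: hypergeometric upper tails P(X ≥ k) (the standard
over-representation convention; the ≥ vs > choice is documented to avoid
off-by-one p drift) for stress∩damage, histone-class and fragile-site
overlaps, with the active-gene set as the default universe (every analyzed
set is drawn from it; overridable). Rank enrichment uses the two-sample
Kolmogorov–Smirnov statistic of the subset's damage scores against the
complement's, with the finite-effective-size asymptotic p
(`kstwo` at round(mn/(m+n))); the exact two-sample distribution is
infeasible at n ≈ 4000 and unnecessary there. Gene-length comparisons
report both Mann–Whitney U (exact by enumeration when both n ≤ 20 without
ties, else normal approximation with tie correction) and Welch's t.

Mutation burden: baseline and endpoint VCF call sets are matched on
(chrom, pos, ref, alt) — genotype, zygosity and allele fraction are ignored
because the analysis counts mutation events. Records must be minimal
(non-trimmable); otherwise identity matching would miscount, so the check
fails loudly. The de novo count k inside the merged panel intervals
(L bp — merging prevents overlapping amplicons from inflating the
expectation) is tested against Binomial(L, 1 − (1 − μ)^g) with an
upper-tail p evaluated through the regularized incomplete beta function,
stable down to ~1e-300. The binomial is the primary test; the Poisson limit
serves as an independent oracle in tests (they agree within 1% whenever
L·p_site < 1 and L > 10⁴).

## The synthetic-data generator

The generator emulates the study's statistical structure, not its reads:

- **genome** — 2 chromosomes × 8 Mb, 500 non-overlapping genes placed with
  ≥ 2.5 kb gaps (so ±500 bp windows never touch a neighbour), coordinates
  snapped to the 50 bp bin grid.
- **gene lengths** — log-normal; damaged genes draw from a median-4.1 kb
  component (σ = 0.6), the rest from median 11.7 kb (σ = 0.7). At the
  default 10% damaged fraction the mixture median is ~10.6 kb, so the
  planted subset is short by construction and the generated annotation
  reproduces the 4.1 vs 10.6 kb contrast.
- **expression** — Gamma(2, 0.05) baseline density (counts/bp), tripled for
  damaged genes, making the planted subset highly expressed.
- **effects** — mutant condition scales γH2AX by 1.5 on damaged genes and
  RNAPII/GRO by 1.3/0.95 on stressed genes; the stressed set equals the
  damaged set by default (configurably decoupled, since real data show
  heavy but partial overlap).
- **noise** — per 50 bp bin, counts ~ Poisson(density × width), stored as
  count/width. This is the simplest generative model consistent with
  read-derived coverage; real sequencing data's dispersion, mappability and
  GC structure are *not* modelled, so passing tests demonstrate correctness
  of the computations, not robustness to those artefacts. Baseline
  densities of 0.05/bp give ≥ 250 expected counts per typical gene window,
  comfortably in the regime where the planted sets are recoverable. With
  noise disabled the stored values are the expected densities themselves
  and every downstream ratio equals its planted effect exactly (to float
  rounding) — the basis of the exactness tests.
- **fragile sites** — each gene is covered by an ERFS interval with base
  probability 0.10, odds-scaled ×4 for damaged genes; intervals extend the
  gene span by uniform 0–5 kb flanks.
- **histone-like genes** — 1.5% of genes, 40% of them drawn from the
  damaged subset, mirroring the strong histone-gene skew of the damage set.
- **panel and mutations** — the panel is the histone-like genes plus four
  damaged non-histone genes (~50–120 kb total). Each panel site mutates
  with probability 1 − (1 − μ)^g, μ = 6 × 10⁻⁸, g = 45; the mutant
  condition uses 50× that rate so its endpoint shows the several-mutation
  excess seen in MLL2-deficient cells, while the control arm stays at the
  background expectation (λ ≈ 0.3 for the default panel). Variants are 70%
  substitutions, 20% deletions, 10% insertions, written as minimal VCF
  records; a shared baseline call set is planted in both arms.

All draws descend from one master seed through named per-stage
`SeedSequence` streams, so outputs are bit-for-bit reproducible and adding
a stage cannot perturb earlier draws.

## Numerical choices

- **pseudocount** — ratio denominators receive ε = 1% of the assay's median
  per-gene density by default: scale-free, avoids blow-ups on silent genes,
  and is recorded in the table metadata. Exactness tests pass ε = 0.
  A 0/0 ratio with ε = 0 returns NaN with a warning instead of silently
  dropping the gene.
- **library scaling** — tracks can be rescaled to a common genome-wide
  total (signal per million). The pipeline default is *no* scaling because
  the generator emits depth-matched expected densities; rescaling to equal
  totals would fold the genuine condition-wide γH2AX increase into every
  per-gene ratio and break the generator's exactness contract. For real
  data with varying sequencing depth the flag should be on.
- **window integrals** — computed by summing locally over overlapping
  segments rather than differencing chromosome-wide cumulative sums, so a
  window's density depends only on the signal inside it, to the last ulp;
  this is what makes noiseless ratios exactly equal planted effects.
- **metagene profiles** — TSS ± 2 kb in fixed bins, or gene bodies rescaled
  to 100 bins with fixed-width 2 kb flanks; minus-strand genes are
  orientation-flipped before aggregation, genes truncated at chromosome
  edges contribute only covered bins, and genes shorter than the body bin
  count are skipped and logged.
- **tie-breaking** — all rankings break ties lexicographically on gene id,
  making classification invariant to input order.
- **degenerate inputs** — zero-length windows, sd = 0 Z-scores, empty gene
  sets, zero-total libraries, k > min(n, K) overlaps and non-minimal VCF
  records all raise typed errors rather than propagating NaNs.

## Problem sizes and what the tests show

The default study (500 genes, 16 Mb, 50 bp bins) runs end-to-end in a
couple of seconds and is the size used by the test suite and the acceptance
script. Null calibration simulates 1000 studies at the per-gene count level
(Poisson window counts → ratios → classification → enrichment), which is
exactly the sampling distribution the track pipeline induces while keeping
the loop fast; with 2000 genes per null study the discrete hypergeometric
p-grid is fine enough for the uniformity check to be meaningful. The
recovery criterion evaluates each ranking at the planted set size: the
binary stress flag alone has an irreducible ~25% false-positive rate under
the null (P(r_RNAPII > 1) · P(r_GRO < 1) = ¼), so flag-level specificity
mostly reflects that constant, not ranking quality.

## Known limitations

- Coverage noise is Poisson; overdispersion, mappability and GC bias are
  out of scope, as are read-level simulation, peak calling and alignment.
- Overlapping genes are quantified independently; no signal apportioning.
- Replicates are not modelled; per-gene ratios carry no variance estimate.
- The enrichment universe and the activity threshold materially affect the
  hypergeometric p-values and must be chosen (and are logged) explicitly.
- The burden test requires the panel size L as input; p-values are
  meaningless if L does not match the actually sequenced footprint.
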