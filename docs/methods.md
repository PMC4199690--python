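# Methods

## The differential-entropy bias score

A gene's codon usage bias is measured against the null hypothesis that,
given the protein it encodes, every synonymous codon was equally likely at
every position. For each gene we compute an entropy estimate of the
observed coding sequence and subtract the mean of the same estimate over
`n_random` random synonymous re-encodings:

    D = H_obs − mean_r H_null(r),     r = 1..n_random (default 20)

Negative `D` indicates codon choice more regular than random synonymous
coding. Because each null sequence encodes the identical protein at
identical length, amino-acid composition and gene length are controlled by
construction. The default `n_random = 20` keeps the score cheap at genome
scale; the null-mean standard error for a typical gene is a few
hundredths of a bit, which is small relative to the biologically
interesting range of `D` (tenths of bits and beyond). Property tests that
need more precision raise `n_random` to 10 000 and compare against exact
enumeration over all synonymous variants of small genes.

Two estimators are provided, both labeled in every output:

- `codon_shannon` (default): Shannon entropy of the gene's empirical
  codon distribution in bits/codon. Proportion-sensitive only, but exactly
  checkable by enumeration, and its small-sample bias cancels in the null
  subtraction because observed and null sequences share `n`. The
  length-independence test (|Pearson r(D, length)| < 0.1 on an unbiased
  genome spanning 100–3000 codons) is the explicit check of that
  cancellation.
- `lz76`: Lempel–Ziv-76 phrase count of the nucleotide string normalized
  by `n / log4(n)`, sensitive to order as well as proportion. Scores from
  different estimators are never comparable; the ortholog-pairing step
  refuses mixed-estimator inputs.

The null draws codons uniformly over each synonym set. A
`genome_frequency` option draws proportionally to genome-wide per-thousand
usage instead; this changes the meaning of `D` (bias relative to the
genome norm rather than to uniformity) and is off by default.

Determinism: each gene's random stream is seeded by a stable 64-bit hash
of `(master_seed, gene_id)` truncated below 2³¹, so results are
bit-identical across runs and independent of gene order or parallel
scheduling.

### Input hygiene

- Terminal stop codons are removed before scoring (recorded via
  `trimmed_stop`); bias among the 3 stop "synonyms" is not meaningful.
  Genome-wide usage tables, by contrast, retain stop codons whenever the
  input does, so the printed tables include the stop rows.
- Codons containing N are excluded from all counts and entropies. Genes
  with more than 10% N codons are flagged and excluded from ranking:
  masked assembly gaps (runs of N) would otherwise mimic low-entropy
  sequence.
- Genes with internal stop codons are ineligible for bias scoring and are
  the natural inputs for the pseudogene screen instead.
- Records whose length is not a multiple of 3 are handled by policy:
  `strict` (raise), `trim` (drop trailing 1–2 nt), or `skip`, always with
  a logged count.

## Effective number of codons (ENC)

Wright's ENC validates the entropy score with an unrelated estimator. Per
amino-acid family, the homozygosity `F̂ = (n·Σp̂² − 1)/(n − 1)` is computed
from synonym counts (families with `n < 2` are excluded as undefined);
class means over the 2-, 3-, 4-, and 6-fold degeneracy classes give

    ENC = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6

A missing 3-fold class (Ile rare) is imputed as the mean of `F̄2` and
`F̄4`; a missing class other than the 3-fold flags the gene as undefined
rather than imputing. The finite-sample estimator can leave [20, 61], and
a class mean of exactly zero (perfectly even usage at tiny counts) sends
the sum to infinity, so the result is clamped to the theoretical range.
The 6-fold families (Leu, Ser, Arg) are treated as single families, which
is the classical class structure behind the 20/61 bounds. Both statistics
decrease with planted bias, so their correlation on a graded-bias genome
is positive (the validation criterion requires r > 0.4).

## Ranked-list enrichment (mHG)

The ranked gene list (ascending `D`, ties broken by gene id and flagged)
is deduplicated keeping each symbol's best rank. The universe is the
deduplicated ranked genes that carry at least one annotation; unannotated
genes are dropped with a logged count. Terms are intersected with the
universe and filtered to sizes 3–2000 (configurable) to avoid degenerate
scans.

The mHG score of a term is `min_n P(X ≥ b(n))` over every prefix length
`n`, with `X ~ Hypergeometric(N, B, n)`. Because the threshold is
optimized, the score is not a p-value; the exact p-value is computed by a
dynamic program over the `(n, b)` lattice that accumulates the probability
a uniformly random label placement never enters the rejection region
`{(n, b): tail ≤ score}`, giving `p = 1 − P(survive)`. The DP is verified
against exhaustive enumeration of all `C(N, B)` placements for every
instance with `N ≤ 8`, and the Bonferroni bound `p ≤ N·score` is retained
as a cross-check. q-values are Benjamini–Hochberg across all terms tested
in one run.

## Between-genome comparison

Orthologs (two-column map; identity map when symbols are shared) are
paired on genes scored in both species; unpaired counts are reported per
side. For each pair, `Δ = D_A − D_B`; a scatter of `(D_A, D_B)` puts
equally biased genes on the identity diagonal, and the perpendicular
distance `|Δ|/√2` measures differential bias. Asymmetry between species is
summarized by counting pairs beyond a threshold `t` on `|Δ|` each way and
applying a two-sided sign test — chosen over rank-based alternatives
because the claim being tested is purely count-based and the sign test
needs no distributional assumption. The default `t = 2 × MAD(Δ)` adapts to
the run's noise scale.

## Pseudogene lesion screen

Inputs are pairwise alignments of an intact reference CDS against a
candidate region (the package deliberately does not run homology search
or gene-structure inference; alignments are supplied). The reference
reading frame is anchored at the alignment start. Every target indel with
length ≢ 0 (mod 3) is recorded as a frameshift at the reference codon
index where it begins; frame is tracked cumulatively, so compensating
indels restore frame downstream while each offending indel is still
recorded. Premature stops are stop codons in the target's running frame
(consecutive triplets of the ungapped target) mapped to a reference
position strictly before the reference terminal stop.

Filters mark calls without deleting them, so the report shows the full
evidence trail:

- `self_alignment`: the reference aligned to itself also shows lesions for
  that gene (an aligner artifact, not biology).
- `splice_adjacent`: lesion within `window` nt (default 10) of a supplied
  exon boundary, given in reference-CDS nucleotide coordinates.
- `low_coverage` / `heterozygous`: lesion site depth below `min_cov`
  (default 5), or alternate-allele fraction inside the heterozygosity band
  (default [0.2, 0.8]). These thresholds are explicit configuration with
  documented defaults, not established constants; they are echoed into
  output headers.

A gene with at least one call and no failed filters is reported as a
candidate pseudogene, with a local alignment excerpt around each lesion.

## Synthetic data: what it emulates and what it does not

Genes are generated from a preferred-codon mixture: for an amino acid
with `k` synonyms, the preferred codon is used with probability
`β + (1 − β)/k` and each other synonym with `(1 − β)/k`. This maps
directly onto the preferred/non-preferred framing of genome-wide usage
tables, makes `β = 0` coincide exactly with the scoring null (so the
score calibrates at zero), and makes every bias statistic monotone in
`β`. Defaults: lengths log-normal over codon counts (median 250, log-sd
0.6, clipped to [50, 3000] — a crude match to the spread of mammalian CDS
lengths), uniform amino-acid composition, background `β = 0.05` (mild
genome-wide bias), planted gene set of 20 genes at `β = 0.6` among 15
terms of size 20 in a 300-gene genome. The default preferred-codon map is
the lexicographically first synonym — arbitrary but fixed; tests needing
realism can derive a map from a usage table.

The generator does not emulate: realistic amino-acid composition or its
covariance with function, GC gradients along chromosomes, isochore
structure, expression-correlated bias, intron/exon structure, or
mutation–selection population dynamics. Passing tests therefore
demonstrate that the statistics behave correctly under their own model
assumptions (calibration, monotonicity, power against planted signal),
not that real genomes satisfy those assumptions — in real data, regional
GC content in particular must be checked per gene, which is what the
±10 kb flank GC profiler is for.

Ortholog-pair simulations hold the amino-acid sequence of each gene
identical across the two species and vary only the codon draws, so any
scored delta is attributable to the planted `β` shift. Lesion simulations
plant exactly one deletion, insertion, or stop substitution at a known
position and emit the gapped alignment directly (no realignment), so
recovery can be checked for exact type and codon index.

## Problem sizes used by the automated checks

The acceptance tests run at desk scale, chosen to make the statistical
assertions sharp while staying quick: 200 genes spanning 100–3000 codons
for null calibration; 50 genes × 500 codons per `β` level for
monotonicity; 500 random terms on a 100-gene universe for enrichment
calibration plus 50 seeded 300-gene pipeline runs for power; 100 planted
and 100 clean alignments for lesion recovery; 100 seeded 80-gene genome
pairs for ortholog symmetry and 50 seeded 100-gene pairs (30 shifted
genes, shift 0.6) for recovery. The two ENC bounds are exact analytic
checks on constructed sequences.

## Known limitations

- The entropy score does not correct for background GC content; GC is
  assessed retrospectively via the flank profiler rather than modeled.
- The `codon_shannon` estimator ignores codon order; the `lz76`
  alternative is order-sensitive but has no exact enumeration oracle.
- The mHG DP is O(N·B) per term with dense scipy tail evaluations; for
  very large universes (tens of thousands of genes) with thousands of
  terms it is the pipeline's slowest stage.
- ENC follows the classical family structure; variants that split 6-fold
  families or correct for GC are out of scope.
- The pseudogene screen trusts the supplied alignment; misalignment near
  lesion sites shifts reported codon indices.
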