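# Methods

This note documents the models, formulas, numerical choices, and known
limitations behind `poolmhc`. Notation: a *panel* is the set of retained
variants (candidate alleles) of one locus in one barcode, with read counts
`c_i`, frequencies `p_i = c_i / n`, `n` total reads, and a common aligned
length `L` (a multiple of 3; the reading frame starts at position 0).

## Read cleaning cascade

The cascade turns raw barcoded reads into validated allele tables in six
steps, applied in this order: length ≥ 180 bp → locus assignment at ≥ 70%
identity → dereplication at 100% identity → per-barcode singleton removal →
quality (≥ 80% of bases at Phred ≥ 20) → frameshift removal. Design choices
where the procedure is underdetermined:

- **Boundary semantics.** "Under 180 bp" and "under 80% quality" are read
  as strict inequalities: reads of exactly 180 bp, and reads with exactly
  80% high-quality bases, are retained.
- **"80% quality"** is defined as the fraction of bases with Phred ≥ 20
  (≈ 1% error probability, the usual amplicon QC convention); both the
  fraction and the Phred cutoff are configurable.
- **Locus assignment** uses global alignment with free end gaps
  (match +1, mismatch −1, gap −2, configurable). Identity is matches over
  all alignment columns, end-gap columns included — a whole-read similarity
  notion. Both orientations are tried and reads are normalized to reference
  orientation; a read is assigned to the best-scoring reference only if its
  identity reaches the threshold, otherwise it is discarded.
- **Singleton scope.** Variants are removed per barcode where their count
  is 1; a variant disappears entirely only when all of its per-barcode
  counts were 1 (a global-scope mode exists). This is the reading of
  "occurred only once in each barcode".
- **Frameshift rule.** A variant is removed when its net internal indel
  versus the reference, or its total length offset from the reference, is
  not a multiple of three. The second condition matters: under free-end-gap
  alignment a single-base gain or loss in a *terminal* homopolymer run
  appears as an end overhang rather than an internal gap, yet it is the
  same frameshift artefact. Insertions are treated like deletions
  (deliberate generalization of a deletions-only rule).
- **Order.** Quality filtering runs after dereplication (on the reads
  backing each surviving variant, dropping a variant only when none of its
  reads pass); a `quality_first` flag restores conventional read-level
  ordering. Filters are idempotent and the retained set is invariant under
  input read order.

Coordinates are 0-based half-open throughout.

## Diversity and selection statistics

Statistics are computed over **reads** by default — each variant weighted
by its read count — because pooled barcodes give no access to individuals
and the read set per barcode is the natural statistical unit. An
unweighted mode (`weighting="alleles"`, one copy per distinct variant) is
provided since a haplotype-level analysis is equally defensible; the
sample size `n` entering the estimators switches accordingly. Whether read
counts or gene-copy counts are the right `n` for pooled data is genuinely
unresolved; read-level is the default and the choice is surfaced in the
API rather than hidden.

- `Hd = n/(n−1)(1 − Σp_i²)`, the small-sample-corrected probability that
  two random reads differ.
- `π` is the mean number of pairwise nucleotide differences per site over
  reads, computed from the variant-level difference matrix with the same
  `n/(n−1)` correction. Positions where either sequence carries a gap or N
  are skipped in pairwise comparisons. `π ≤ S/L` always.
- **Tajima's D** uses the textbook constants `a₁, a₂, b₁, b₂, c₁, c₂, e₁,
  e₂` as functions of `n`, with `θ_π` the absolute (per-locus) mean
  pairwise difference and `S` the segregating-site count over variants
  (presence-based, not count-weighted). `S = 0` yields an undefined result
  (reported missing, never 0). Constants are cached per `n`.
- **Fu's Fs** is `ln(S′/(1−S′))` with
  `S′ = Pr(K ≥ k_obs | θ = θ_π)` under the Ewens sampling formula,
  `Pr(K = k) = |s(n,k)| θ^k / (θ)_n`. Unsigned Stirling numbers of the
  first kind are computed by the `|s(n+1,k)| = |s(n,k−1)| + n|s(n,k)|`
  recurrence entirely in log space, so the computation is stable for `n`
  up to ~10⁴ reads. The tail sum is normalized by the full sum to absorb
  rounding. `S′ = 1` (e.g. a single distinct allele) gives a −∞ sentinel;
  `θ_π = 0` gives an undefined result. No p-value is attached: Fs
  significance requires coalescent simulation, which is out of scope — the
  statistic's sign and magnitude are the deliverable.
- **Ka/Ks** follows Nei–Gojobori: per codon, synonymous site fractions
  count the synonymous share of the three possible changes (changes to
  stop codons excluded from numerator and denominator, so synonymous +
  nonsynonymous sites = 3 per codon exactly); per differing codon pair,
  all shortest mutational pathways are enumerated with equal weight,
  discarding pathways through stop codons unless every pathway is.
  Proportions are Jukes–Cantor corrected (`d = −¾ ln(1 − 4p/3)`); pairs
  beyond the correction's domain (`p ≥ ¾`) are excluded, and if every pair
  is excluded the result is NaN rather than 0. Pairs are averaged
  **unweighted over distinct variants** (the usual haplotype-data
  convention; a read-weighted mode exists), and `ω = Ka/Ks` is flagged
  undefined when `Ks = 0` rather than reported as infinity. No attempt is
  made to reproduce published ratio values that are inconsistent with
  their own printed numerator and denominator under rounding.
- **Drift check:** per-colony allele counts divided by the across-colony
  mean, correlated (Pearson, permutation p) against colony size estimates;
  a positive correlation is the drift expectation.

## Differentiation and isolation by distance

- **Φ_ST** (default mode) is `(π_T − π_W)/π_T`, with `π_W` the
  read-count-weighted mean of within-colony mean pairwise differences and
  `π_T` over the pooled reads. These use *uncorrected* mean pairwise
  differences (`Σ_ij w_i w_j d_ij`), which makes Φ_ST exactly 0 for two
  identically composed panels and exactly 1 for fixed differences with no
  within-colony diversity. Negative estimates are reported as computed.
  The alternative `freq` mode is Hudson's `1 − H_W/H_B` on allele
  identity. Permutation significance reshuffles reads between the two
  colonies with `p = (1 + #{F* ≥ F_obs}) / (n_perm + 1)`.
- **Geographic distance** is great-circle (haversine, R = 6371 km) from
  decimal-degree coordinates; degree–minute strings ("15°22′ S") are
  parsed with south/west negative. Whether along-coast distance would be
  more appropriate than great-circle is unknowable from coordinates alone;
  great-circle is chosen for reproducibility and an externally supplied
  distance matrix can be used instead.
- **Mantel test:** `r` is the Pearson correlation over the `k(k−1)/2`
  off-diagonal pairs, `Z` the raw cross-product (unit-bearing, so it is
  reported but not compared across distance scalings). The one-tailed p
  (positive association, the isolation-by-distance hypothesis) permutes
  rows and columns of one matrix simultaneously; for `k < 8`
  (≤ 5040 permutations) all `k!` permutations are enumerated and p is
  exact — which covers 3- and 4-colony species with exact p-values of
  granularity 1/6 and 1/24 — otherwise p uses sampled permutations with
  the observed labeling counted in the numerator. Ties in `r` are counted
  with a 10⁻¹² tolerance toward the numerator (conservative).

## Synthetic data generator

The generator emulates the study design: 7 barcodes × 25 pooled
individuals by default, a 261-bp multi-copy class I amplicon (2 copies per
individual by default) and a 270-bp single-copy class II amplicon,
colonies on a 1-D coastline, and 454-style noise. What it does, layer by
layer:

1. **Allele pool.** A Kingman coalescent genealogy over the pool
   (exponential waiting times at rate k(k−1)/2) carries Poisson-distributed
   mutations at rate θ/2 per unit branch length, so θ is the expected mean
   pairwise difference per locus between two pool members. Each mutation is
   proposed uniformly over positions and alternative bases, rejected and
   resampled if it creates a stop codon, and accepted with probability
   min(1, ω) if nonsynonymous and min(1, 1/ω) if synonymous. Because
   proposal frequencies are proportional to available changes, the realized
   event-level rate ratio equals the requested dN/dS target ω in
   expectation, exactly, for any ω ≥ 0 (ω = 0 is an explicit error if the
   reference offers no synonymous changes). Realized *pairwise-pathway*
   Ka/Ks additionally carries multiple-hit noise, so pool-level estimates
   should be aggregated (summed Ka over summed Ks) across seeds when
   checking the dial.
2. **Structure.** Colony allele frequencies follow a forward Wright–Fisher
   stepping-stone chain: every generation each deme exchanges a fraction m
   of its gene pool with its neighbours (m/2 each side, reflecting ends)
   and is multinomially resampled at its census gene-copy count
   (2 × copies × individuals). All demes start at the uniform pool
   frequency. Expected divergence between demes then grows with chain
   distance when m is small but nonzero; the isolation-by-distance regime
   requires the diffusion length √(mG) to lie between one deme spacing and
   the chain extent — fully drift-dominated chains (mG ≪ 1) have high but
   distance-free differentiation. With `generations=0` the demes sample
   directly and exchangeably from the pool: the panmictic/neutral
   condition used for Tajima's-D calibration (a forward-neutral process on
   a coalescent pool keeps the sample genealogy neutral; the pool should
   be much larger than a deme's sample so that with-replacement sampling
   approximates subsampling). Deme size equals the sampled census by
   design, so default drift is strong relative to real colonies of
   thousands of birds; configs aiming at study-like allele counts should
   use few generations or a larger pool.
3. **Genotypes and reads.** Each individual draws 2 × copies allele slots
   from its deme's frequency vector; true per-barcode frequencies are
   defined by these genotype tallies and sum to 1. Per individual,
   `depth_per_individual` reads are emitted with sources spread as evenly
   as possible over its slots, so under the default fixed depth the read
   tallies track the truth exactly (Poisson and log-normal depth-skew
   options exist but default off, keeping truth frequencies exact).
4. **Noise.** Chimeras form first (probability per read; partner drawn
   from the barcode's allele frequencies; uniform breakpoint), then each
   maximal homopolymer run of length ≥ 2 gains or loses one base with the
   configured probability, then substitution errors hit each base i.i.d.
   Quality strings encode the realized errors: faithful bases get Phred
   38, substituted or inserted bases Phred 10 — so the 80%-quality filter
   is exercisable. Error rates default to the published 454 profile:
   homopolymer indels dominate (0.01 per run), substitutions are rare
   (0.001 per base), chimeras 0.01 per read.

**What the generator does not emulate:** flowgram signal space, PCR
amplification bias per template, depth heterogeneity from pooling at
estimated concentrations (a log-normal skew knob exists but defaults to
uniform), pseudogene divergence as a separate sequence class, and
quality-score correlation structure along reads. Consequently, passing
tests demonstrate the pipeline's correctness under calibrated error
processes, not performance on any particular real run.

A practical consequence worth knowing: false variants that survive the
cascade are dominated by *identical-error collisions* — two reads of the
same (or 1-bp-sibling) allele acquiring the same substitution, or two
reads slipping in the same homopolymer run in compensating ways. Their
expected number grows quadratically with per-allele depth while true
alleles stay fixed, so precision is best at moderate coverage (~20–30
reads per allele) and degrades, counterintuitively, with oversequencing.
The frameshift filter removes nearly all homopolymer collisions; the
substitution-collision floor is set by the substitution rate.

## Numerical and degenerate-input conventions

- Deterministic ordering everywhere: variants sort by descending count
  then sequence; ties in dominant-allele frequency report all tied
  alleles; catalogs are independent of input order.
- Seeds: a single integer seed drives every stage through
  `numpy.random.default_rng` with fixed per-stage offsets; identical
  config + seed reproduces byte-identical FASTQ.
- Undefined statistics (D with S = 0, ω with Ks = 0, Fs with θ_π = 0,
  FST with zero total diversity, Mantel r on a constant matrix) are
  reported as missing/None or raised as errors — never silently 0.
- Empty FASTQ files warn and return empty read sets; barcodes present in
  reads but absent from the manifest are a hard error; FASTA input (no
  qualities) passes the quality filter only with an explicit opt-in flag
  and a warning.

## Scale of the shipped checks

The test suite validates the statistics against independent brute-force
oracles (pair enumeration, exact-rational Ewens probabilities, Biopython
translation, plain DP alignment) on panels up to 20 reads × 60 bp, and
runs the pipeline end to end on simulated studies of 2–7 colonies ×
8–25 individuals at 8–40 reads per individual — sizes chosen so the full
suite completes in minutes on one core while each check retains its
statistical meaning (e.g. 10-seed false-variant rates, 50-replicate
neutrality panels, 500-replicate permutation-calibration runs).

## Known limitations

- Individual genotypes, heterozygosity, and per-individual allele counts
  are unrecoverable from pooled barcodes; nothing here attempts them.
- Functional genes and pseudogenes of the multi-copy class I family
  cannot be separated by this sequencing design; "alleles" may derive
  from several loci.
- Homoplasy versus identity-by-descent for trans-species alleles is not
  adjudicated; sharing is exact sequence identity (full-length equality).
- Fs and D are reported without simulation-based significance.
- The Φ_ST estimator is the pairwise-difference AMOVA style without
  variance-component hierarchies; no spatial model beyond the Mantel test.
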