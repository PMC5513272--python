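# poolmhc

Pooled-amplicon MHC genotyping and population genetics for colony surveys.

`poolmhc` re-implements, as a tested and reusable pipeline, the analysis
used in penguin MHC surveys in which PCR products from ~25 individuals per
breeding colony are pooled into a single 454 barcode and sequenced: reads
are cleaned by a six-rule cascade into per-barcode allele tables, and those
tables feed per-colony diversity and selection statistics, pairwise
population differentiation, isolation-by-distance testing, and
cross-colony/cross-species allele bookkeeping. A truth-tracked synthetic
read generator emulates the full study design so that every stage can be
validated end to end without access to the original raw reads.

It is aimed at molecular ecologists working with pooled amplicon data from
multigene immune loci (here: MHC class I exon 3, 261 bp, multi-copy; MHC
class II DRB1-like exon 2, 270 bp, single-copy), where individual genotypes
cannot be resolved and all inference runs on read-weighted allele pools.

## What it computes

**Read cleaning / allele validation** (`poolmhc.qc`) — in order: drop reads
under 180 bp; assign each read to a locus by pairwise alignment against the
two reference amplicons (free-end-gap global alignment, identity =
matches / alignment columns, 70% minimum, both strands tried); collapse
reads to variants at 100% identity; remove per-barcode singletons; drop
reads with under 80% of bases at Phred ≥ 20; remove variants whose indels
against the reference are not multiples of three.

**Per-colony statistics** (`poolmhc.diversity`) — for each barcode × locus
panel of retained variants with read counts `c_i` (frequencies `p_i`,
`n = Σc_i` reads, alignment length `L`):

- segregating sites `S`; number of alleles `A`; alleles per individual `A/N`
- haplotype (allelic) diversity `Hd = n/(n−1) · (1 − Σ p_i²)`
- nucleotide diversity `π` = mean pairwise differences per site
- Tajima's `D = (θ_π − S/a₁) / √(e₁S + e₂S(S−1))` with the standard
  sample-size constants
- Fu's `Fs = ln(S′/(1−S′))` where `S′ = Pr(K ≥ k_obs | θ = θ_π)` under the
  Ewens sampling formula, computed with a log-space Stirling-number
  recurrence
- Nei–Gojobori `Ka`, `Ks` and `ω = Ka/Ks`: synonymous/nonsynonymous sites
  and equal-weight shortest-pathway differences per codon, Jukes–Cantor
  corrected, averaged over variant pairs
- the drift check: mean-centered allele counts vs colony size

**Differentiation and isolation by distance** (`poolmhc.differentiation`) —
pairwise `Φ_ST = (π_T − π_W)/π_T` from pairwise nucleotide differences
(Hudson's frequency-based FST as an alternative mode), permutation
significance, great-circle distances from colony coordinates, and the
Mantel test (Pearson `r` over off-diagonal pairs, one-tailed permutation
`p`, exhaustive enumeration of all `k!` label permutations for fewer than
8 localities).

**Allele catalog** (`poolmhc.catalog`) — private vs mixed-locality alleles,
trans-species alleles (identical sequence in both species), dominant-allele
frequencies, figure-ready count and frequency tables.

**Synthetic data** (`poolmhc.simulate`) — allele pools evolved on a Kingman
coalescent genealogy with codon-aware mutations biased to a target dN/dS
(stop codons rejected), stepping-stone colony structure with tunable
migration along a 1-D coastline, pooled-individual genotypes, and 454-style
reads (substitution errors, homopolymer indels, chimeras) with a full truth
table.

## Worked example

```python
from poolmhc import SimulationConfig, simulate_study, run_qc_pipeline, default_loci
from poolmhc.catalog import AlleleCatalog
from poolmhc.differentiation import distance_matrix_km, fst_matrix, mantel

config = SimulationConfig(n_populations=7, individuals_per_population=25,
                          depth_per_individual=20, theta=10.0,
                          migration_rate=0.1, seed=42)
reads, truth, manifest = simulate_study(config)
refs = {name: spec.reference_sequence for name, spec in default_loci().items()}
variants, report = run_qc_pipeline([r for rs in reads.values() for r in rs],
                                   refs, set(manifest.barcodes))
print(report.to_frame())
```

The filter report for this seed shows the cascade at work — 7,000 reads in,
3,646 raw variants collapsing to 96 validated alleles (the big drop at the
frameshift stage is the homopolymer-indel error class characteristic of
454 data):

```
          stage     unit  bc1  bc2  bc3  bc4  bc5  bc6  bc7  total
          input    reads 1000 1000 1000 1000 1000 1000 1000   7000
    length>=180    reads 1000 1000 1000 1000 1000 1000 1000   7000
     locus>=70%    reads 1000 1000 1000 1000 1000 1000 1000   7000
    dereplicate variants  503  534  496  564  519  505  525   3646
drop_singletons variants   55   43   46   41   46   44   53    328
        quality variants   55   43   46   41   46   44   53    328
     frameshift variants   10   14   12   18   17   12   13     96
       retained    reads  453  448  480  430  466  466  440   3183
```

Continuing to isolation by distance for the first species (colonies
bc1–bc4):

```python
cat = AlleleCatalog.from_variants(variants, manifest)
bcs = manifest.by_species()["species_A"]
sub = manifest.frame[manifest.frame.barcode.isin(bcs)]
km = distance_matrix_km(bcs, sub.latitude_dd.tolist(), sub.longitude_dd.tolist())
fst = fst_matrix([cat.panel(b, "MHC2ex2") for b in bcs], labels=bcs)
res = mantel(km, fst, seed=1)
print(f"Z={res.Z:.2f} r={res.r:.3f} p={res.p:.4f} ({res.n_permutations})")
```

```
Z=609.29 r=0.632 p=0.1667 (exhaustive)
```

With four colonies the Mantel test enumerates all 24 permutations, so `p`
is exact with a floor of 1/24 ≈ 0.042: a positive `r` of 0.63 here is
suggestive but not significant at this scale, which is the expected
behaviour for a short colony chain under moderate migration.

A command-line interface mirrors the library
(`poolmhc simulate | qc | stats | diff | catalog | all`); every output
directory receives the serialized run configuration for provenance.

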