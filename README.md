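# cranvar

A toolkit for comparing a crop genome against its wild relative and its own
breeding history, built around the kinds of bespoke analyses that accompany a
cranberry (*Vaccinium macrocarpon*) / small cranberry (*V. oxycoccos*)
genome-sequencing project:

- **Binned unique-heterozygous-SNP diversity scan.** For each resequenced
  line, heterozygous SNPs that are unique in both position and alternate
  nucleotide across a panel of lines are tallied into fixed 250 kb bins.
  Significance comes from a bootstrap null: a pooled SNP count *n* (the
  rounded mean of the genome-wide unique-SNP totals of a set of
  representative lines) is assigned multinomially to bins over many
  iterations; the 95th percentile of per-iteration bin **maxima** is the
  high-diversity threshold and the 5th percentile of the **minima** the
  low-diversity threshold. A bin is *high* when its count strictly exceeds
  the high threshold, *low* when strictly below the low one.
- **GO overrepresentation** of the genes under high (or low) bins, by
  upper-tail hypergeometric test — P(X ≥ k) with population N, successes K,
  draws n — with Benjamini–Hochberg values reported alongside the raw
  p < 0.01 convention.
- **K-mer-spectrum genome size.** From a coverage histogram, size is
  estimated as Σ<sub>c ≥ trough</sub> c·counts[c] / peak-coverage. A bimodal
  spectrum with the left (half-coverage) peak carrying more distinct k-mers
  than the right is flagged as the hybrid signature.
- **Telomere and centromere arrays.** A motif-tiling scanner finds
  AAACCCT-type telomeric arrays at sequence ends; a shift-identity period
  profile recovers the centromeric monomer length (e.g. 124 bp) and detects
  higher-order repeats (HORs) as better self-identity at an integer multiple
  of the monomer (e.g. 248 bp).
- **Ka/Ks selection classification** by Nei–Gojobori (NG86) counting with
  Jukes–Cantor correction: Ka/Ks > 1 positive, < 1 purifying, with the
  stricter > 2 convention available for between-cultivar comparisons.
- **Syntenic-block depth.** A boundary sweep over block tables yields
  constant-depth intervals, genome coverage and duplicated (depth ≥ 2)
  percentages, and the genes retained in duplicated regions.

A synthetic-data generator (`cranvar.simulate`) reproduces the statistical
structure these analyses assume — Poisson per-bin SNP backgrounds with
planted hotspot bins, shared-allele structure, a high-diversity outgroup, a
selfing series whose heterozygosity halves each generation, unimodal and
bimodal k-mer spectra, and planted telomere/centromere arrays — so the whole
pipeline is testable end to end without any external data.

## Worked example

```sh
cranvar simulate --seed 4 --n-chroms 2 --chrom-length 1000000 --out demo_data
cranvar scan --vcf demo_data/panel.vcf \
    --chrom-lengths demo_data/chrom_lengths.tsv \
    --panel ST,N35,MQ,BL --representative ST,N35,MQ,BL \
    --exclude-from-uniqueness VOXY,BL-S1,BL-S2,BL-S3,BL-S4,BL-S5,BL-S6,BL-S7 \
    --iterations 1000 --seed 1 --out demo_scan
```

prints (log excerpt):

```
INFO cranvar: scan: n_null=120 high_threshold=24 low_threshold=7 (nearest-rank
95th/5th percentiles, 1000 iterations, seed=1, bin_size=250000)
```

and `demo_scan/scan_summary.tsv` contains, per sample, its unique-SNP total
and the fraction of bins labelled high/low:

```
sample  n_unique_snps  n_bins  high_fraction  low_fraction
ST      122            8       0.0            0.0
...
VOXY    7896           8       1.0            0.0
BL-S2   50             8       0.0            0.5
BL-S5   8              8       0.0            1.0
```

Read: with a background of ~20 unique het SNPs per 250 kb bin, the four
panel cultivars sit inside the bootstrap band (thresholds 24/7) in every
bin (at this toy scale no hotspot bins are planted); the wild outgroup
VOXY, simulated at 50x the panel diversity, is high everywhere; the selfing
series loses half its heterozygosity per generation, so from BL-S3 onward
every bin falls below the low threshold. The full pipeline
(`cranvar demo --seed 7 --out demo_out`) also
writes GO-enrichment tables, genome-size JSON reports, telomere/centromere
reports, Ka/Ks tables, synteny-depth statistics, and a manifest of output
checksums.

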