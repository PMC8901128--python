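# Methods

This note documents the models and procedures cranvar implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Unique-heterozygous-SNP diversity scan

**Model.** For a panel of resequenced lines mapped to one reference, a
heterozygous SNP of a focal line is *unique* when no other panel line is
heterozygous at the same key (chromosome, position, alternate nucleotide).
The uniqueness key deliberately includes the nucleotide change: two lines
het at the same position with different alternates each keep their SNP.
Hom-alt calls in other lines do not veto uniqueness — the definition is
about heterozygous variation, and the het-only reading is the literal one.
Samples expected to distort uniqueness (a divergent outgroup would make
everything else look shared; near-homozygous inbreds would make everything
look unique) are excluded from vetoing but are still scanned as focal
samples against the full panel.

Unique SNPs are tallied into fixed-width bins (default 250,000 bp, the
scale at which per-bin counts are large enough for extrema statistics yet
the genome still resolves into hundreds-to-thousands of windows). The last
bin of each chromosome may be partial; it is retained and weighted by
length in the null rather than dropped, so the genome is never silently
truncated and terminal bins are not artificially prone to low labels.

**Bootstrap null.** The pooled null count `n_null` is the half-up-rounded
mean of the genome-wide unique-SNP totals of a configurable set of
representative lines ("average total" rather than averaging per-bin
vectors; the two differ only through rounding). Each of `n_iterations`
(default 1,000) iterations assigns `n_null` SNPs independently to bins with
probability proportional to bin length (a multinomial draw) and records the
maximum and minimum of the resulting count vector. The high threshold is
the 95th percentile of the maxima and the low threshold the 5th percentile
of the minima, both by the nearest-rank rule (the ceil(q·n)-th order
statistic), which keeps thresholds achievable integer counts and avoids an
interpolation convention. Classification is strict: a count equal to a
threshold is neutral. One global threshold pair is applied to every sample,
outgroup and inbreds included.

Because the threshold is a quantile of the *max* distribution, the
per-sample family-wise rate of any high label under the null is ~5% by
construction; the acceptance suite verifies calibration lands in
[0.02, 0.09] over 200 replicates (Poisson totals rather than fixed totals
add a little variance around the nominal 0.05).

## GO overrepresentation of classified regions

Genes overlapping any bin with the requested label by ≥ 1 bp (1-based
inclusive gene spans against 0-based half-open bins) form the selection;
the background is all genes carrying at least one GO annotation, since
unannotated genes cannot contribute to any term's tail. Each term annotated
in the background is tested with the upper-tail hypergeometric probability
P(X ≥ k) (scipy's `hypergeom.sf(k-1, N, K, n)`, exact for the discrete
distribution); Benjamini–Hochberg values are reported alongside. The
default significance filter is raw p < 0.01 (strict), with BH filtering
behind a flag. Terms are tested exactly as annotated — no GO-graph ancestor
propagation — because the annotation pipeline this mirrors is flat and
propagation would change counts invisibly.

## K-mer-spectrum genome size

After a centered moving-average smoothing (default window 3), the trough is
the first interior minimum at coverage ≥ 2, separating the low-coverage
error k-mers from the genomic bulge; a spectrum with no error mass falls
back to its support edge, and a monotone spectrum is an error ("no
error/signal separation"). Peaks are local maxima above the trough; peaks
closer than the merge window keep the taller, tail ripples under 5% of the
tallest peak are discarded as sampling noise, and each kept peak's coverage
is refined to the raw-histogram argmax within the smoothing window (an
asymmetric peak can shift by a bin under smoothing). Genome size is the
classic spectrum estimator

    size = Σ_{c ≥ trough} c · counts[c] / primary peak coverage

with no heterozygous-peak mixture modelling. For bimodal spectra the
higher-coverage peak anchors the formula — the half-coverage peak reflects
the heterozygous/divergent fraction — and hybridity is reported
qualitatively: two peaks with the left peak's distinct-k-mer mass exceeding
the right's (masses split at the midpoint between peak coverages) is the
interspecific-hybrid signature. The k-mer length k is carried as metadata
and is a free parameter of whatever counter produced the histogram.

## Telomere and centromere arrays

**Motif arrays.** Maximal intervals tiled by a short motif (default
AAACCCT) or its reverse complement, one orientation per array, are grown
greedily from exact seed matches: seeds within one unit are grouped, each
group is extended unit-by-unit while the appended unit matches ≥ 1 −
max_divergence of positions, and extended intervals separated by short
diverged stretches (≤ 10 units) are merged when the merged interval's
purity stays above the floor. Reported purity is the fraction of positions
matching the ideal phased tiling, so purity ≥ 1 − max_divergence holds by
construction. Defaults: end window 100 kb, minimum 10 copies, maximum
divergence 0.2 — chosen as a scientist's defaults for plant telomeres,
where arrays run to thousands of 7-bp copies. An end is telomere-bearing
when an array lies within half the end window of the terminus; the mean
telomere length averages over telomere-bearing ends (interstitial arrays
are detected but never counted as telomeric).

**Period profile.** For a window and shifts p in [min_p, max_p], the score
is the fraction of positions i with base(i) = base(i+p). Random DNA scores
~0.25, so no call is made unless some shift exceeds the 0.5 floor. The base
period is the smallest local-maximum shift whose integer multiple (within
2 bp) accounts for the best-scoring shift — this prefers the fundamental
monomer over its harmonics for pure arrays (where score[p] ≈ score[2p])
while still recovering the monomer of a higher-order repeat, whose
*super-unit* shift scores strictly higher than the monomer shift. The HOR
order is the smallest m > 1 with score[m·p] ≥ score[p] + δ (δ = 0.02),
else 1. A planted dimeric 124-bp array therefore reports base period 124
with HOR order 2 (identity at 248 exceeds identity at 124 by the variant
divergence).

## Ka/Ks (NG86 with Jukes–Cantor correction)

The estimator is deliberately the simplest standard one, and the method
name is recorded in output metadata. Per codon, each position's synonymous
fraction is the share of its three single-base substitutions preserving the
amino acid, with substitutions creating stop codons removed from the
denominator; sites sum to 3 per codon and are averaged across the two
sequences. Observed differences average over all orderings of the differing
positions whose intermediates are sense codons; if every pathway is blocked
by stops (impossible for pairs differing at ≤ 2 sites), each differing site
is classified independently with a warning. Proportions pN = Nd/N and
pS = Sd/S receive the Jukes–Cantor correction −(3/4)·ln(1 − (4/3)p);
saturation (p ≥ 3/4) yields an explicit *undefined* classification rather
than a NaN. Ks = 0 with Ka > 0 is flagged positive with an infinite ratio;
Ka = Ks = 0 is neutral. Classification thresholds: positive when
Ka/Ks > threshold (default 1; the stricter between-cultivar convention uses
2), negative when < 1; undefined results are excluded and counted.
Alignments are inputs (gap columns stripped pairwise); no aligner is
embedded.

## Syntenic-block depth

A boundary sweep (+1 at block start, −1 past block end) partitions each
reference chromosome into maximal constant-depth intervals that tile it
exactly, including depth-0 segments. Coverage is the percentage of bp at
depth ≥ 1 and duplication the percentage at depth ≥ 2 — both measured in
base pairs, matching a genome-block-coverage reading rather than a
block-count one. Genes overlap regions under any-overlap (≥ 1 bp, closed
1-based intervals); duplicate-retained genes are grouped per depth ≥ 2
interval. A minimum-block-span filter mirrors the common practice of
excluding sub-100-kb contigs from synteny analyses.

## Synthetic-data generator

The generator produces data with exactly the structure the analyses assume:

- i.i.d. uniform-base chromosomes (no repeats, GC structure, or Ns except
  what is planted);
- per-sample per-bin unique-het counts that are Poisson with mean
  `background_rate` (default 20 per full 250 kb bin, a mid-range diversity
  for a heterozygous woody crop at this bin size), scaled by bin length;
  hotspot bins (fraction 0.05 of bins per panel sample) multiply the rate
  by `hotspot_fold` (default 8);
- a `shared_fraction` (default 0.2) of each panel sample's SNPs copied het
  into one other random panel sample, so the uniqueness filter must remove
  them from both carriers;
- an outgroup at 50x the background rate (a strongly diverged wild
  relative) and a selfing series whose rate is halved each generation
  (default 7 generations; generation g retains 0.5^g of the starting
  heterozygosity, so the fifth generation is at ~3%, consistent with an
  inbreeding coefficient ≥ 0.97);
- one joint multi-sample VCF with explicit hom-ref genotypes, mirroring
  joint-calling output;
- closed-form k-mer spectra (Poisson components plus a geometric error
  spike at coverages 1–3), with optional Poisson count noise under a
  supplied generator; the bimodal variant places 1.5x the distinct-k-mer
  mass at half coverage, so the left peak is bigger by construction;
- planted tandem arrays: for HOR order m, a super-unit of m independently
  mutated unit variants is built once and tiled, giving perfect
  self-identity at m·|unit| and divergence-limited identity at |unit|;
- codon-aware CDS pairs where nonsynonymous substitutions are accepted with
  probability omega (default 0.5, mild purifying selection) and stops are
  never created.

Everything is a deterministic function of the config seed (child seeds are
derived per stage), and VCF/FASTA/GFF3 outputs are byte-identical across
runs.

**What passing tests do and do not show.** The generator has no linkage
structure, no mapping or calling artifacts, no depth- or quality-dependent
genotype error, uniform gene density, and flat GO annotation. Recovery and
calibration results therefore validate the *computations* — binning,
bootstrap, thresholds, interval arithmetic, counting — under their stated
statistical assumptions, not robustness to real-data artifacts such as
collapsed repeats, mapping bias toward the reference line, or overdispersed
per-bin counts (a Poisson dispersion is assumed; an overdispersion knob is
a natural config extension).

## Problem sizes

Tests and the acceptance script run at deliberately reduced scale chosen so
statistical assertions still have power: 2-chromosome genomes of 1–5 Mb
(8–40 bins), 400-bin single-chromosome grids for calibration (200
replicates), 20-seed recovery runs for hotspots and repeat arrays, 16
spectra spanning 1e6–1e8 bp, exact enumeration at 3 bins x 8 SNPs against
1e5 bootstrap iterations, and 100–200 simulated CDS pairs. These sizes are
the package's own test design; all operations scale linearly (or
n·iterations for the bootstrap) to genome scale.

## Known limitations

- The bootstrap null assumes independent placement of SNPs; real unique
  SNPs cluster with LD and mapping artifacts, so real-data thresholds are
  anti-conservative to an unquantified degree.
- The genome-size estimator does not model heterozygous peaks; for a truly
  heterozygous (not hybrid-bimodal) genome it under-counts by attributing
  half-coverage mass to the homozygous peak's denominator.
- The motif-array scanner requires exact seed matches; arrays diverged far
  beyond ~20% or with indel-dominated divergence fragment or escape it
  (indels also shift tiling phase, which the purity measure penalizes).
- NG86 ignores transition/transversion bias and codon-usage bias; ratios on
  strongly biased sequences differ from ML (codeml-style) estimates, and no
  numeric parity with any particular external Ka/Ks engine is promised.
- The period profile reports one base period per window; windows containing
  two interleaved array families report whichever dominates.
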