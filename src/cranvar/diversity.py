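"""Binned unique-heterozygous-SNP diversity scan with a bootstrap null.

The scan asks, for each resequenced line, where its private heterozygous
variation is concentrated. Heterozygous SNPs that are unique to one line in
both position and alternate nucleotide are tallied into fixed-width genomic
bins (250 kb by default). Significance comes from a bootstrap null: a pooled
SNP count — the rounded mean of the genome-wide unique-SNP totals of a set of
representative lines — is repeatedly thrown at the bins at random
(multinomially, weighted by bin length), and the 95th percentile of the
per-iteration bin maxima / 5th percentile of the minima become one global
high/low threshold pair. A bin is labelled ``high`` when its count strictly
exceeds the high threshold and ``low`` when strictly below the low threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import formats
from .formats import GT_HET, write_bed


@dataclass(frozen=True)
class UniqueSnpSet:
    """The focal sample's panel-unique heterozygous SNPs.

    Uniqueness key is (chrom, pos, alt): a het SNP survives only if no other
    panel member is het at the same position with the same alternate
    nucleotide. Hom-alt calls in other members do not veto uniqueness.
    """

    sample_id: str
    panel_ids: tuple[str, ...]
    snps: frozenset[tuple[str, int, str]]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling a set of chromosomes.

    Bins are 0-based half-open; the last bin per chromosome may be partial
    and carries a proportionally smaller weight in the bootstrap null.
    """

    chrom_lengths: dict[str, int]
    bin_size: int = 250_000
    bins: tuple[tuple[str, int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        bins = []
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom} has non-positive length")
            for start0 in range(0, length, self.bin_size):
                bins.append((chrom, start0, min(start0 + self.bin_size, length)))
        object.__setattr__(self, "bins", tuple(bins))

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def weights(self) -> np.ndarray:
        """Bin length / bin_size; partial terminal bins weigh less."""
        return np.array([(e - s) / self.bin_size for _, s, e in self.bins])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global bin index of a 1-based position."""
        length = self.chrom_lengths.get(chrom)
        if length is None:
            raise KeyError(f"chromosome {chrom!r} not in grid")
        if not 1 <= pos <= length:
            raise ValueError(f"position {chrom}:{pos} outside chromosome (length {length})")
        offset = 0
        for c, clen in self.chrom_lengths.items():
            if c == chrom:
                break
            offset += -(-clen // self.bin_size)
        return offset + (pos - 1) // self.bin_size


@dataclass(frozen=True)
class NullModel:
    """Bootstrap null: distributions of bin-count extrema and thresholds."""

    n_null: int
    n_iterations: int
    seed: int
    max_distribution: np.ndarray
    min_distribution: np.ndarray
    high_threshold: int
    low_threshold: int

    def __post_init__(self) -> None:
        if self.low_threshold > self.high_threshold:
            raise ValueError("low threshold exceeds high threshold")


LABEL_HIGH = "high"
LABEL_LOW = "low"
LABEL_NEUTRAL = "neutral"


@dataclass(frozen=True)
class BinClassification:
    sample_id: str
    bin_index: int
    count: int
    label: str


# ---------------------------------------------------------------------------
# unique het SNPs
# ---------------------------------------------------------------------------

def unique_het_snps(calls, focal: str, panel, excluded=()) -> UniqueSnpSet:
    """Extract the focal sample's panel-unique heterozygous SNPs.

    ``panel`` lists the samples whose het calls veto uniqueness; samples in
    ``excluded`` never veto (the outgroup and the inbred series, which would
    otherwise distort uniqueness). A focal sample outside the panel (e.g. the
    outgroup) is tested against the full panel.

    Raises KeyError if the focal sample has no calls in the stream.
    """
    panel = list(panel)
    excluded = set(excluded)
    if focal in excluded:
        raise ValueError(f"focal sample {focal!r} is in the excluded list")
    if not panel:
        raise ValueError("uniqueness panel is empty")
    veto_samples = {s for s in panel if s != focal} - excluded

    focal_het: set[tuple[str, int, str]] = set()
    veto_het: set[tuple[str, int, str]] = set()
    focal_seen = False
    for call in calls:
        if call.sample_id == focal:
            focal_seen = True
            if call.genotype == GT_HET:
                focal_het.add((call.chrom, call.pos, call.alt))
        elif call.sample_id in veto_samples and call.genotype == GT_HET:
            veto_het.add((call.chrom, call.pos, call.alt))
    if not focal_seen:
        raise KeyError(f"focal sample {focal!r} absent from call set")
    return UniqueSnpSet(
        sample_id=focal,
        panel_ids=tuple(panel),
        snps=frozenset(focal_het - veto_het),
    )


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_counts(snps: UniqueSnpSet, grid: BinGrid) -> np.ndarray:
    """Tally unique SNPs into the grid; counts sum to ``len(snps.snps)``."""
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    for chrom, pos, _alt in snps.snps:
        counts[grid.bin_index(chrom, pos)] += 1
    return counts


# ---------------------------------------------------------------------------
# bootstrap null
# ---------------------------------------------------------------------------

def pooled_null_count(per_sample_counts: dict[str, np.ndarray], representative) -> int:
    """Rounded (half-up) mean of the representative samples' SNP totals."""
    representative = list(representative)
    if not representative:
        raise ValueError("representative sample list is empty")
    missing = [s for s in representative if s not in per_sample_counts]
    if missing:
        raise KeyError(f"representative sample(s) {missing} have no counts")
    mean = sum(int(per_sample_counts[s].sum()) for s in representative) / len(representative)
    return math.floor(mean + 0.5)


def _nearest_rank(sorted_values: np.ndarray, q: float) -> int:
    """Nearest-rank percentile: the ceil(q*n)-th order statistic."""
    n = len(sorted_values)
    rank = max(1, math.ceil(q * n))
    return int(sorted_values[rank - 1])


def bootstrap_thresholds(n_null: int, grid: BinGrid, n_iterations: int = 1000,
                         seed: int = 0) -> NullModel:
    """Bootstrap the null distribution of bin-count extrema.

    Each iteration assigns ``n_null`` SNPs independently to bins with
    probability proportional to bin length (multinomial), then records the
    max and min of the resulting counts. Thresholds are nearest-rank
    percentiles: high = 95th of the maxima, low = 5th of the minima.
    """
    if grid.n_bins == 0:
        raise ValueError("grid has no bins")
    if n_null < 0 or n_iterations < 1:
        raise ValueError("n_null must be >= 0 and n_iterations >= 1")
    rng = np.random.default_rng(seed)
    w = grid.weights
    p = w / w.sum()
    if n_null == 0:
        maxima = np.zeros(n_iterations, dtype=np.int64)
        minima = np.zeros(n_iterations, dtype=np.int64)
    else:
        draws = rng.multinomial(n_null, p, size=n_iterations)
        maxima = np.sort(draws.max(axis=1))
        minima = np.sort(draws.min(axis=1))
        del draws
    maxima = np.sort(maxima)
    minima = np.sort(minima)
    return NullModel(
        n_null=n_null,
        n_iterations=n_iterations,
        seed=seed,
        max_distribution=maxima,
        min_distribution=minima,
        high_threshold=_nearest_rank(maxima, 0.95),
        low_threshold=_nearest_rank(minima, 0.05),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_bins(per_sample_counts: dict[str, np.ndarray], null: NullModel,
                  ) -> list[BinClassification]:
    """Apply one global threshold pair to every sample's bin counts.

    Strict inequalities: a count equal to a threshold is neutral.
    """
    out: list[BinClassification] = []
    for sample, counts in per_sample_counts.items():
        for i, c in enumerate(counts):
            c = int(c)
            if c > null.high_threshold:
                label = LABEL_HIGH
            elif c < null.low_threshold:
                label = LABEL_LOW
            else:
                label = LABEL_NEUTRAL
            out.append(BinClassification(sample, i, c, label))
    return out


# ---------------------------------------------------------------------------
# end-to-end scan
# ---------------------------------------------------------------------------

def scan(vcf_path, chrom_lengths: dict[str, int], panel, representative,
         excluded=(), bin_size: int = 250_000, n_iterations: int = 1000,
         seed: int = 0, out_dir=None, samples=None):
    """Run the full diversity scan on a multi-sample VCF.

    For every sample in the VCF (or the ``samples`` subset) the unique het
    SNPs are extracted against ``panel`` (ignoring ``excluded``), binned on a
    ``bin_size`` grid over ``chrom_lengths``, and classified against one
    bootstrap null whose pooled count is the mean total of ``representative``.

    Returns a dict with the grid, null model, per-sample counts,
    classifications, and a per-sample summary of high/low bin fractions.
    When ``out_dir`` is given, writes high/low BED5 files (score = bin count)
    and a TSV summary there.
    """
    grid = BinGrid(chrom_lengths=dict(chrom_lengths), bin_size=bin_size)
    calls = list(formats.read_vcf_snps(vcf_path, samples=samples))
    all_samples = []
    for c in calls:
        if c.sample_id not in all_samples:
            all_samples.append(c.sample_id)

    per_sample_counts: dict[str, np.ndarray] = {}
    per_sample_sets: dict[str, UniqueSnpSet] = {}
    excluded = set(excluded)
    for s in all_samples:
        # an excluded sample (outgroup, inbreds) is still scanned as focal
        uset = unique_het_snps(calls, focal=s, panel=panel, excluded=excluded - {s})
        per_sample_sets[s] = uset
        per_sample_counts[s] = bin_counts(uset, grid)

    n_null = pooled_null_count(per_sample_counts, representative)
    null = bootstrap_thresholds(n_null, grid, n_iterations=n_iterations, seed=seed)
    classifications = classify_bins(per_sample_counts, null)

    summary = []
    by_sample: dict[str, list[BinClassification]] = {}
    for bc in classifications:
        by_sample.setdefault(bc.sample_id, []).append(bc)
    for s in all_samples:
        labels = [bc.label for bc in by_sample[s]]
        n = len(labels)
        summary.append(
            {
                "sample": s,
                "n_unique_snps": len(per_sample_sets[s].snps),
                "n_bins": n,
                "high_fraction": labels.count(LABEL_HIGH) / n,
                "low_fraction": labels.count(LABEL_LOW) / n,
            }
        )

    result = {
        "grid": grid,
        "null": null,
        "counts": per_sample_counts,
        "classifications": classifications,
        "summary": summary,
    }

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for label, fname in ((LABEL_HIGH, "high_bins.bed"), (LABEL_LOW, "low_bins.bed")):
            rows = []
            for bc in classifications:
                if bc.label == label:
                    chrom, s0, e0 = grid.bins[bc.bin_index]
                    rows.append((chrom, s0, e0, bc.sample_id, bc.count))
            write_bed(rows, os.path.join(out_dir, fname))
        import csv

        with open(os.path.join(out_dir, "scan_summary.tsv"), "w", newline="") as fh:
            fh.write(
                f"# bin_size={bin_size} n_iterations={n_iterations} seed={seed} "
                f"n_null={n_null} high_threshold={null.high_threshold} "
                f"low_threshold={null.low_threshold}\n"
            )
            writer = csv.DictWriter(
                fh,
                fieldnames=["sample", "n_unique_snps", "n_bins", "high_fraction", "low_fraction"],
                delimiter="\t",
            )
            writer.writeheader()
            for row in summary:
                writer.writerow(row)
    return result
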