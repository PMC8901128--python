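"""Synthetic data with the statistical structure the analyses assume.

The generator emulates the shape of a crop/wild-relative resequencing study:
a small multi-chromosome reference; a panel of cultivar-like samples whose
heterozygous SNPs arrive at a uniform Poisson background rate per bin, with a
fraction of bins enriched by a fold factor (hotspots); a configurable share
of each sample's SNPs copied into another panel member so the downstream
uniqueness filter has real work to do; a high-diversity outgroup; and a
selfing series in which expected heterozygosity halves every generation.
Also: unimodal/bimodal k-mer coverage spectra, planted telomere motif arrays
and centromere monomer/higher-order-repeat arrays, and codon-aware diverged
CDS pairs for the selection analysis.

All outputs are deterministic functions of the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import formats
from .formats import GeneModel, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    ``background_rate`` is the expected number of unique het SNPs per full
    bin for a panel sample; hotspot bins multiply it by ``hotspot_fold``.
    The selfing series sample at generation g has rate ``background_rate *
    inbreeding_halving**g`` (default halving, so a fifth-generation inbred
    retains ~3% heterozygosity, matching an F >= 0.97 inbred clone).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 250_000
    samples: tuple[str, ...] = ("ST", "N35", "MQ", "BL")
    background_rate: float = 20.0
    hotspot_fraction: float = 0.05
    hotspot_fold: float = 8.0
    shared_fraction: float = 0.2
    outgroup_name: str = "VOXY"
    outgroup_rate_multiplier: float = 50.0
    selfing_generations: int = 7
    selfing_prefix: str = "BL-S"
    inbreeding_halving: float = 0.5
    go_vocab_size: int = 200
    genes_per_chrom: int = 200

    def __post_init__(self) -> None:
        for name, v in (("hotspot_fraction", self.hotspot_fraction),
                        ("shared_fraction", self.shared_fraction)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.background_rate < 0 or self.outgroup_rate_multiplier < 0:
            raise ValueError("rates must be >= 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names}

    @property
    def selfing_samples(self) -> list[str]:
        return [f"{self.selfing_prefix}{g}" for g in range(1, self.selfing_generations + 1)]

    @property
    def all_samples(self) -> list[str]:
        return list(self.samples) + [self.outgroup_name] + self.selfing_samples


@dataclass
class TruthSet:
    """Ground truth for recovery tests."""

    hotspot_bins: dict[str, set[int]] = field(default_factory=dict)
    planted_arrays: list[tuple] = field(default_factory=list)  # (chrom, start0, end0, unit_len, hor_order)
    true_genome_size: int = 0

    def to_json(self, path) -> None:
        obj = {
            "hotspot_bins": {s: sorted(b) for s, b in self.hotspot_bins.items()},
            "planted_arrays": [list(a) for a in self.planted_arrays],
            "true_genome_size": self.true_genome_size,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig):
    """I.i.d. uniform-base chromosomes, reproducible from the config seed."""
    rng = np.random.default_rng(config.seed)
    records = []
    for chrom in config.chrom_names:
        idx = rng.integers(0, 4, size=config.chrom_length)
        seq = _BASES[idx].tobytes().decode("ascii")
        records.append(SequenceRecord(chrom, seq))
    truth = TruthSet(true_genome_size=config.n_chroms * config.chrom_length)
    return records, truth


# ---------------------------------------------------------------------------
# variant panel
# ---------------------------------------------------------------------------

def _sample_rates(config: SimulationConfig) -> dict[str, float]:
    rates = {s: config.background_rate for s in config.samples}
    rates[config.outgroup_name] = config.background_rate * config.outgroup_rate_multiplier
    for g, s in enumerate(config.selfing_samples, start=1):
        rates[s] = config.background_rate * config.inbreeding_halving ** g
    return rates


def simulate_variant_panel(config: SimulationConfig, genome, vcf_path=None):
    """Plant per-sample het SNPs on the genome; optionally write a VCF.

    Panel samples get Poisson(background_rate) unique het SNPs per full bin
    (partial bins scaled by length) with hotspot bins multiplied by
    ``hotspot_fold``; a ``shared_fraction`` of each panel sample's SNPs is
    copied het into one other random panel sample, making those SNPs
    non-unique by construction. The outgroup and selfing series carry no
    hotspots. Returns (records, truth) where ``records`` is the list of
    (chrom, pos, ref, alt, genotypes) rows (also written to ``vcf_path``
    as one multi-sample VCF with explicit hom_ref for non-carriers).
    """
    from .diversity import BinGrid

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    grid = BinGrid(chrom_lengths=config.chrom_lengths, bin_size=config.bin_size)
    seq_by_chrom = {rec.id: rec.sequence for rec in genome}
    rates = _sample_rates(config)
    truth = TruthSet(true_genome_size=config.n_chroms * config.chrom_length)

    # planted[key] = set of samples carrying (chrom, pos, alt) het
    planted: dict[tuple[str, int, str], set[str]] = {}
    occupied: dict[str, set[tuple[str, int, str]]] = {s: set() for s in config.all_samples}
    per_sample_keys: dict[str, list[tuple[str, int, str]]] = {}

    for sample in config.all_samples:
        is_panel = sample in config.samples
        hotspots: set[int] = set()
        if is_panel and config.hotspot_fraction > 0:
            n_hot = int(round(config.hotspot_fraction * grid.n_bins))
            hotspots = set(rng.choice(grid.n_bins, size=n_hot, replace=False).tolist())
        truth.hotspot_bins[sample] = hotspots
        keys: list[tuple[str, int, str]] = []
        for b, (chrom, s0, e0) in enumerate(grid.bins):
            lam = rates[sample] * (e0 - s0) / config.bin_size
            if b in hotspots:
                lam *= config.hotspot_fold
            n = rng.poisson(lam)
            placed = 0
            while placed < n:
                pos = int(rng.integers(s0 + 1, e0 + 1))  # 1-based
                ref = seq_by_chrom[chrom][pos - 1]
                if ref == "N":
                    continue
                alts = [b_ for b_ in "ACGT" if b_ != ref]
                alt = alts[int(rng.integers(0, 3))]
                key = (chrom, pos, alt)
                if key in occupied[sample]:
                    continue  # collision: resample position
                occupied[sample].add(key)
                keys.append(key)
                planted.setdefault(key, set()).add(sample)
                placed += 1
        per_sample_keys[sample] = keys

    # duplicate a fraction of each panel sample's SNPs into another panel member
    panel = list(config.samples)
    if len(panel) >= 2 and config.shared_fraction > 0:
        for sample in panel:
            keys = per_sample_keys[sample]
            n_share = int(round(config.shared_fraction * len(keys)))
            if n_share == 0:
                continue
            share_idx = rng.choice(len(keys), size=n_share, replace=False)
            others = [s for s in panel if s != sample]
            for i in share_idx:
                key = keys[int(i)]
                recipient = others[int(rng.integers(0, len(others)))]
                occupied[recipient].add(key)
                planted[key].add(recipient)

    sample_ids = config.all_samples
    records = []
    for (chrom, pos, alt), carriers in planted.items():
        ref = seq_by_chrom[chrom][pos - 1]
        genotypes = {s: ("0/1" if s in carriers else "0/0") for s in sample_ids}
        records.append((chrom, pos, ref, alt, genotypes))
    if vcf_path is not None:
        formats.write_vcf(vcf_path, config.chrom_lengths, sample_ids, records)
    return records, truth


# ---------------------------------------------------------------------------
# genes and GO
# ---------------------------------------------------------------------------

ENRICHED_TERM = "GO:0000001"


def simulate_genes_and_go(config: SimulationConfig, genome, truth: TruthSet | None = None,
                          gff3_path=None, go_map_path=None, enrich: bool = False,
                          gene_length_range=(1000, 3000)):
    """Place non-overlapping genes and draw skewed GO annotations.

    Each gene draws 1-5 terms from a Zipf-weighted multinomial over the GO
    vocabulary. With ``enrich`` on (and a truth set with hotspot bins), the
    designated term ``GO:0000001`` is attached with probability 0.9 to genes
    overlapping any hotspot bin and 0.05 elsewhere — planted enrichment truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    lo, hi = gene_length_range
    if config.genes_per_chrom * hi > config.chrom_length:
        raise ValueError("gene placement infeasible: genes do not fit on chromosome")

    from .diversity import BinGrid

    grid = BinGrid(chrom_lengths=config.chrom_lengths, bin_size=config.bin_size)
    hotspot_union: set[int] = set()
    if truth is not None:
        for bins in truth.hotspot_bins.values():
            hotspot_union |= bins

    vocab = [f"GO:{i + 2:07d}" for i in range(config.go_vocab_size)]
    zipf = 1.0 / np.arange(1, config.go_vocab_size + 1)
    zipf /= zipf.sum()

    genes: list[GeneModel] = []
    go_map: dict[str, set[str]] = {}
    for chrom in config.chrom_names:
        n = config.genes_per_chrom
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        slack = config.chrom_length - int(lengths.sum())
        gaps = np.sort(rng.integers(0, slack + 1, size=n))
        starts0 = gaps + np.concatenate([[0], np.cumsum(lengths[:-1])])
        for i in range(n):
            start = int(starts0[i]) + 1  # 1-based inclusive
            end = start + int(lengths[i]) - 1
            gid = f"{chrom}_g{i + 1:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_terms = int(rng.integers(1, 6))
            terms = set(
                np.array(vocab)[rng.choice(config.go_vocab_size, size=n_terms,
                                           replace=False, p=zipf)].tolist()
            )
            if enrich:
                mid_bin = grid.bin_index(chrom, (start + end) // 2)
                in_hot = mid_bin in hotspot_union
                p_attach = 0.9 if in_hot else 0.05
                if rng.random() < p_attach:
                    terms.add(ENRICHED_TERM)
            genes.append(GeneModel(gid, chrom, start, end, strand))
            go_map[gid] = terms

    if gff3_path is not None:
        formats.write_gff3_genes(genes, gff3_path)
    if go_map_path is not None:
        formats.write_go_map(go_map, go_map_path)
    return genes, go_map


# ---------------------------------------------------------------------------
# k-mer spectra
# ---------------------------------------------------------------------------

def simulate_kmer_histogram(true_size_bp: int, mean_coverage: float,
                            error_kmer_fraction: float = 0.0, n_peaks: int = 1,
                            k: int = 31, rng=None):
    """Build a k-mer coverage spectrum for a genome of known size.

    The main component places ``true_size_bp`` distinct k-mers at
    Poisson(mean_coverage) multiplicities, so the classic estimator (total
    k-mer observations above the error trough divided by the peak coverage)
    recovers the size. Error k-mers are a geometric mass at coverage 1-3
    totaling ``error_kmer_fraction`` of all distinct k-mers. With
    ``n_peaks=2`` a second component at half coverage with 1.5x the mass is
    added (left peak bigger than the right — the hybrid signature).

    Deterministic closed-form expected counts by default; pass ``rng`` to
    draw Poisson-noised counts instead.
    """
    from scipy import stats

    from .kmer import KmerHistogram

    if mean_coverage < 5:
        raise ValueError("mean_coverage must be >= 5")
    if n_peaks not in (1, 2):
        raise ValueError("n_peaks must be 1 or 2")
    if n_peaks == 2 and mean_coverage / 2 <= 4:
        raise ValueError("peaks unresolvable: half-coverage peak inside the error region")

    max_cov = int(mean_coverage * 2.5) + 10
    cov = np.arange(max_cov + 1)
    expected = np.zeros(max_cov + 1)

    expected += true_size_bp * stats.poisson.pmf(cov, mean_coverage)
    if n_peaks == 2:
        expected += 1.5 * true_size_bp * stats.poisson.pmf(cov, mean_coverage / 2)
    if error_kmer_fraction > 0:
        total_real = expected.sum()
        n_error = error_kmer_fraction / (1 - error_kmer_fraction) * total_real
        geo = np.array([0.0, 4.0, 2.0, 1.0])  # halved mass at coverage 1..3
        geo /= geo.sum()
        expected[: 4] += n_error * geo

    expected[0] = 0.0
    if rng is None:
        counts = np.round(expected).astype(np.int64)
    else:
        counts = rng.poisson(expected).astype(np.int64)
    return KmerHistogram(k=k, counts=counts)


# ---------------------------------------------------------------------------
# repeat arrays
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        current = arr[i]
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def plant_repeat_array(sequence: str, unit: str, copies: int,
                       per_base_mutation_rate: float = 0.0, hor_order: int = 1,
                       offset: int | None = None, rng=None):
    """Overwrite part of ``sequence`` with a tandem array of ``unit``.

    ``hor_order=1``: the unit is repeated ``copies`` times with i.i.d.
    substitutions at ``per_base_mutation_rate``. ``hor_order=m`` (m>1): a
    super-unit of m independently mutated unit variants is built once and
    then tiled, so self-identity at shift m*|unit| exceeds identity at shift
    |unit| — the higher-order-repeat signature of plant centromeres.
    ``copies`` counts base-unit copies in both cases.

    Returns (new_sequence, (start0, end0, unit_length, hor_order)).
    """
    if set(unit) - set("ACGT"):
        raise ValueError("repeat unit must be over {A,C,G,T}")
    if rng is None:
        rng = np.random.default_rng(0)
    m = len(unit)
    if hor_order <= 1:
        array = "".join(_mutate(unit, per_base_mutation_rate, rng) for _ in range(copies))
    else:
        variants = [_mutate(unit, per_base_mutation_rate, rng) for _ in range(hor_order)]
        super_unit = "".join(variants)
        reps, rem = divmod(copies, hor_order)
        array = super_unit * reps + "".join(variants[: rem])
    if offset is None:
        offset = (len(sequence) - len(array)) // 2
    if offset < 0 or offset + len(array) > len(sequence):
        raise ValueError("array does not fit at requested offset")
    new_seq = sequence[:offset] + array + sequence[offset + len(array):]
    return new_seq, (offset, offset + len(array), m, hor_order)


# ---------------------------------------------------------------------------
# coding-sequence pairs for the selection analysis
# ---------------------------------------------------------------------------

def simulate_coding_pairs(n_pairs: int, n_codons: int = 100,
                          mutation_rate: float = 0.05, omega: float = 0.5,
                          seed: int = 0):
    """Codon-aware diverged CDS pairs for Ka/Ks exercises.

    Sequence A is random sense codons; sequence B applies single-base codon
    substitutions at ``mutation_rate`` per site, accepting nonsynonymous
    changes with probability ``omega`` (so omega<1 mimics purifying
    selection) and never creating stop codons. Returns a list of
    (gene_id, seq_a, seq_b) tuples.
    """
    from Bio.Data.CodonTable import standard_dna_table

    code = dict(standard_dna_table.forward_table)
    stops = set(standard_dna_table.stop_codons)
    sense = sorted(set(code))
    rng = np.random.default_rng(seed)
    pairs = []
    for g in range(n_pairs):
        codons_a = [sense[int(i)] for i in rng.integers(0, len(sense), size=n_codons)]
        codons_b = []
        for codon in codons_a:
            new = codon
            for p in range(3):
                if rng.random() >= mutation_rate:
                    continue
                base = new[p]
                alt = "ACGT"[int(rng.integers(0, 4))]
                if alt == base:
                    continue
                cand = new[:p] + alt + new[p + 1:]
                if cand in stops:
                    continue
                if code[cand] != code[new] and rng.random() >= omega:
                    continue
                new = cand
            codons_b.append(new)
        pairs.append((f"gene{g + 1:04d}", "".join(codons_a), "".join(codons_b)))
    return pairs
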