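"""Unique-het-SNP scan: uniqueness filter, binning, bootstrap null, labels."""

import itertools
import math

import numpy as np
import pytest

from cranvar.diversity import (
    BinGrid,
    LABEL_HIGH,
    LABEL_LOW,
    LABEL_NEUTRAL,
    NullModel,
    bin_counts,
    bootstrap_thresholds,
    classify_bins,
    pooled_null_count,
    scan,
    unique_het_snps,
)
from cranvar.formats import GT_HET, GT_HOM_ALT, VariantCall


def _call(sample, chrom, pos, alt, genotype=GT_HET, ref=None):
    refs = {"T": "A", "G": "A", "C": "A", "A": "G"}
    return VariantCall(sample, chrom, pos, ref or refs[alt], alt, genotype)


# ---------------------------------------------------------------------------
# uniqueness filter
# ---------------------------------------------------------------------------

class TestUniqueHetSnps:
    def test_shared_key_excluded(self):
        calls = [_call("A", "c1", 100, "T"), _call("B", "c1", 100, "T")]
        out = unique_het_snps(calls, "A", panel=["A", "B"])
        assert out.snps == frozenset()

    def test_different_alt_retained(self):
        # uniqueness key is position AND nucleotide change
        calls = [_call("A", "c1", 100, "T"), _call("B", "c1", 100, "G")]
        out = unique_het_snps(calls, "A", panel=["A", "B"])
        assert out.snps == {("c1", 100, "T")}

    def test_hom_alt_does_not_veto(self):
        calls = [_call("A", "c1", 100, "T"), _call("B", "c1", 100, "T", GT_HOM_ALT)]
        out = unique_het_snps(calls, "A", panel=["A", "B"])
        assert out.snps == {("c1", 100, "T")}

    def test_excluded_sample_never_vetoes(self):
        calls = [_call("A", "c1", 100, "T"), _call("X", "c1", 100, "T")]
        out = unique_het_snps(calls, "A", panel=["A", "X"], excluded=["X"])
        assert out.snps == {("c1", 100, "T")}

    def test_focal_outside_panel_tested_against_full_panel(self):
        calls = [
            _call("OUT", "c1", 100, "T"),
            _call("OUT", "c1", 200, "G"),
            _call("A", "c1", 100, "T"),
        ]
        out = unique_het_snps(calls, "OUT", panel=["A", "B"])
        assert out.snps == {("c1", 200, "G")}

    def test_absent_focal_raises(self):
        with pytest.raises(KeyError):
            unique_het_snps([_call("A", "c1", 1, "T")], "Z", panel=["A"])

    def test_matches_brute_force_enumeration(self, rng):
        """Random toy panels agree with a double-loop oracle exactly."""
        samples = ["s1", "s2", "s3"]
        for _ in range(50):
            calls = []
            for s in samples:
                n = rng.integers(5, 15)
                for _ in range(n):
                    pos = int(rng.integers(1, 30))
                    alt = "ACGT"[int(rng.integers(0, 4))]
                    ref = "A" if alt != "A" else "G"
                    gt = [GT_HET, GT_HOM_ALT, "hom_ref"][int(rng.integers(0, 3))]
                    calls.append(VariantCall(s, "c1", pos, ref, alt, gt))
            focal = samples[int(rng.integers(0, 3))]
            got = unique_het_snps(calls, focal, panel=samples).snps
            # oracle: double loop over focal het calls x other samples' het calls
            focal_het = {(c.chrom, c.pos, c.alt) for c in calls
                         if c.sample_id == focal and c.genotype == GT_HET}
            expected = set()
            for key in focal_het:
                vetoed = False
                for c in calls:
                    if (c.sample_id != focal and c.genotype == GT_HET
                            and (c.chrom, c.pos, c.alt) == key):
                        vetoed = True
                if not vetoed:
                    expected.add(key)
            assert got == expected


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

class TestBinCounts:
    def test_boundary_convention(self):
        grid = BinGrid({"c1": 600_000}, bin_size=250_000)
        uset = _uset({("c1", 1, "T"), ("c1", 250_000, "G"), ("c1", 250_001, "C")})
        counts = bin_counts(uset, grid)
        assert list(counts) == [2, 1, 0]

    def test_empty_set_zero_vector(self):
        grid = BinGrid({"c1": 500_000})
        assert bin_counts(_uset(set()), grid).sum() == 0

    def test_out_of_range_position_raises(self):
        grid = BinGrid({"c1": 100})
        with pytest.raises(ValueError, match="c1:500"):
            bin_counts(_uset({("c1", 500, "T")}), grid)

    def test_counts_match_brute_force_tally(self, rng):
        lengths = {"c1": 700_000, "c2": 500_000, "c3": 260_000}
        grid = BinGrid(lengths, bin_size=250_000)
        snps = set()
        while len(snps) < 100:
            chrom = ["c1", "c2", "c3"][int(rng.integers(0, 3))]
            snps.add((chrom, int(rng.integers(1, lengths[chrom] + 1)), "T"))
        counts = bin_counts(_uset(snps), grid)
        expected = np.zeros(grid.n_bins, dtype=int)
        for i, (chrom, s0, e0) in enumerate(grid.bins):
            for c, p, _a in snps:
                if c == chrom and s0 + 1 <= p <= e0:
                    expected[i] += 1
        assert list(counts) == list(expected)
        assert counts.sum() == len(snps)


def _uset(snps):
    from cranvar.diversity import UniqueSnpSet

    return UniqueSnpSet("s", ("s",), frozenset(snps))


# ---------------------------------------------------------------------------
# pooled null count
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "totals, expected",
    [({"a": 1000, "b": 2000, "c": 3000, "d": 4000}, 2500),
     ({"a": 7}, 7),
     ({"a": 1, "b": 2}, 2)],  # 1.5 rounds half-up
)
def test_pooled_null_count(totals, expected):
    counts = {s: np.array([t]) for s, t in totals.items()}
    assert pooled_null_count(counts, list(totals)) == expected


def test_pooled_null_count_empty_representative():
    with pytest.raises(ValueError):
        pooled_null_count({"a": np.array([1])}, [])


# ---------------------------------------------------------------------------
# bootstrap thresholds
# ---------------------------------------------------------------------------

class TestBootstrapThresholds:
    def test_degenerate_zero_null(self):
        grid = BinGrid({"c1": 1_000_000})
        null = bootstrap_thresholds(0, grid, n_iterations=100, seed=1)
        assert null.high_threshold == 0 and null.low_threshold == 0

    def test_single_bin_thresholds_equal_n_null(self):
        grid = BinGrid({"c1": 250_000})
        null = bootstrap_thresholds(17, grid, n_iterations=200, seed=1)
        assert null.high_threshold == 17 and null.low_threshold == 17

    def test_partial_bins_are_length_weighted(self):
        # one full bin plus a tiny terminal bin: nearly all mass in bin 0
        grid = BinGrid({"c1": 250_100}, bin_size=250_000)
        null = bootstrap_thresholds(1000, grid, n_iterations=500, seed=3)
        # min is the tiny bin: almost always 0 or 1
        assert null.low_threshold <= 2
        assert null.high_threshold > 900

    def test_matches_exact_enumeration_small_case(self):
        """3 equal bins, 8 SNPs: compare to the full 3^8 enumeration."""
        exact_max, exact_min = _exact_extrema_distribution(3, 8)
        grid = BinGrid({"c1": 750_000}, bin_size=250_000)
        null = bootstrap_thresholds(8, grid, n_iterations=20_000, seed=5)
        assert abs(null.high_threshold - _nearest_rank_of(exact_max, 0.95)) <= 1
        assert abs(null.low_threshold - _nearest_rank_of(exact_min, 0.05)) <= 1


def _exact_extrema_distribution(n_bins, n_snps):
    """Enumerate all equiprobable assignments of n_snps SNPs to n_bins."""
    maxima, minima = [], []
    for assign in itertools.product(range(n_bins), repeat=n_snps):
        counts = [assign.count(b) for b in range(n_bins)]
        maxima.append(max(counts))
        minima.append(min(counts))
    return sorted(maxima), sorted(minima)


def _nearest_rank_of(sorted_values, q):
    rank = max(1, math.ceil(q * len(sorted_values)))
    return sorted_values[rank - 1]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _null(high, low):
    return NullModel(0, 1, 0, np.array([high]), np.array([low]), high, low)


class TestClassifyBins:
    @pytest.mark.parametrize(
        "count, label",
        [(10, LABEL_NEUTRAL), (11, LABEL_HIGH), (2, LABEL_NEUTRAL), (1, LABEL_LOW)],
    )
    def test_strict_inequalities(self, count, label):
        (bc,) = classify_bins({"s": np.array([count])}, _null(10, 2))
        assert bc.label == label

    def test_zero_low_threshold_all_neutral(self):
        out = classify_bins({"s": np.zeros(5, dtype=int)}, _null(10, 0))
        assert all(bc.label == LABEL_NEUTRAL for bc in out)

    def test_increasing_a_count_never_demotes(self, rng):
        null = _null(10, 3)
        counts = rng.integers(0, 15, size=30)
        base = classify_bins({"s": counts}, null)
        order = {LABEL_LOW: 0, LABEL_NEUTRAL: 1, LABEL_HIGH: 2}
        for i in range(len(counts)):
            bumped = counts.copy()
            bumped[i] += 1
            new = classify_bins({"s": bumped}, null)
            assert order[new[i].label] >= order[base[i].label]


# ---------------------------------------------------------------------------
# end-to-end scan
# ---------------------------------------------------------------------------

class TestScan:
    def test_deterministic_outputs(self, small_config, small_panel_vcf, tmp_path):
        vcf_path, _ = small_panel_vcf
        outs = []
        for d in ("a", "b"):
            out = tmp_path / d
            scan(
                vcf_path, small_config.chrom_lengths,
                panel=list(small_config.samples),
                representative=list(small_config.samples),
                excluded=[small_config.outgroup_name] + small_config.selfing_samples,
                n_iterations=200, seed=3, out_dir=str(out),
            )
            outs.append((out / "high_bins.bed").read_bytes()
                        + (out / "low_bins.bed").read_bytes()
                        + (out / "scan_summary.tsv").read_bytes())
        assert outs[0] == outs[1]

    def test_counts_conserve_unique_snp_totals(self, small_config, small_panel_vcf, tmp_path):
        vcf_path, _ = small_panel_vcf
        result = scan(
            vcf_path, small_config.chrom_lengths,
            panel=list(small_config.samples),
            representative=list(small_config.samples),
            excluded=[small_config.outgroup_name] + small_config.selfing_samples,
            n_iterations=100, seed=3,
        )
        for row in result["summary"]:
            assert result["counts"][row["sample"]].sum() == row["n_unique_snps"]

    def test_high_diversity_outgroup_mostly_high(self, tmp_path):
        """A 50x-rate outgroup should have >90% of its bins labelled high."""
        from cranvar import SimulationConfig, simulate_genome, simulate_variant_panel

        config = SimulationConfig(
            seed=42, n_chroms=2, chrom_length=1_500_000, background_rate=20.0,
            hotspot_fraction=0.0, shared_fraction=0.0, outgroup_rate_multiplier=50.0,
            selfing_generations=2,
        )
        genome, _ = simulate_genome(config)
        vcf_path = tmp_path / "p.vcf"
        simulate_variant_panel(config, genome, vcf_path=str(vcf_path))
        result = scan(
            str(vcf_path), config.chrom_lengths, panel=list(config.samples),
            representative=list(config.samples),
            excluded=[config.outgroup_name] + config.selfing_samples,
            n_iterations=500, seed=1,
        )
        out_row = next(r for r in result["summary"] if r["sample"] == "VOXY")
        assert out_row["high_fraction"] > 0.9

    def test_selfing_series_trend(self, small_config, small_panel_vcf):
        """Later selfing generations: high fraction falls, low fraction rises."""
        vcf_path, _ = small_panel_vcf
        result = scan(
            vcf_path, small_config.chrom_lengths,
            panel=list(small_config.samples),
            representative=list(small_config.samples),
            excluded=[small_config.outgroup_name] + small_config.selfing_samples,
            n_iterations=300, seed=9,
        )
        rows = {r["sample"]: r for r in result["summary"]}
        lows = [rows[f"BL-S{g}"]["low_fraction"] for g in range(1, 8)]
        highs = [rows[f"BL-S{g}"]["high_fraction"] for g in range(1, 8)]
        # monotone trend up to sampling noise: compare early vs late thirds
        assert np.mean(lows[4:]) >= np.mean(lows[:3])
        assert np.mean(highs[4:]) <= np.mean(highs[:3])
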