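"""Interval calculus over syntenic block tables.

Depth profiles partition each reference chromosome into maximal intervals of
constant block-overlap depth via a boundary sweep; coverage and duplication
statistics and duplicate-retained gene sets derive from them. Intervals are
1-based inclusive internally; gene membership uses any-overlap (>= 1 bp).
"""

from __future__ import annotations

from collections import defaultdict

from intervaltree import IntervalTree


def depth_profile(blocks, ref_lengths: dict[str, int]):
    """Partition chromosomes into maximal constant-depth intervals.

    Returns {chrom: [(start, end, depth), ...]} with 1-based inclusive
    intervals tiling each chromosome exactly (depth 0 segments included).
    """
    by_chrom: dict[str, list] = defaultdict(list)
    for b in blocks:
        L = ref_lengths.get(b.ref_chrom)
        if L is None:
            raise KeyError(f"block chromosome {b.ref_chrom!r} not in ref_lengths")
        if b.ref_end > L:
            raise ValueError(
                f"block {b.ref_chrom}:{b.ref_start}-{b.ref_end} exceeds chromosome length {L}"
            )
        by_chrom[b.ref_chrom].append(b)

    profile: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, L in ref_lengths.items():
        events: dict[int, int] = defaultdict(int)
        for b in by_chrom.get(chrom, []):
            events[b.ref_start] += 1
            events[b.ref_end + 1] -= 1
        boundaries = sorted(set(events) | {1, L + 1})
        segments: list[tuple[int, int, int]] = []
        depth = 0
        for i in range(len(boundaries) - 1):
            pos = boundaries[i]
            depth += events.get(pos, 0)
            start, end = pos, boundaries[i + 1] - 1
            if start > L:
                break
            end = min(end, L)
            if segments and segments[-1][2] == depth:
                segments[-1] = (segments[-1][0], end, depth)
            else:
                segments.append((start, end, depth))
        profile[chrom] = segments
    return profile


def coverage_stats(blocks, ref_lengths: dict[str, int], size_threshold: int = 100_000):
    """Genome block coverage summary.

    covered_pct = bp at depth >= 1 / total bp; duplicated_pct = bp at depth
    >= 2 / total bp; n_large_blocks counts blocks whose reference span
    exceeds ``size_threshold``.
    """
    profile = depth_profile(blocks, ref_lengths)
    total = sum(ref_lengths.values())
    covered = sum(
        e - s + 1 for segs in profile.values() for s, e, d in segs if d >= 1
    )
    duplicated = sum(
        e - s + 1 for segs in profile.values() for s, e, d in segs if d >= 2
    )
    n_large = sum(1 for b in blocks if b.ref_span > size_threshold)
    return {
        "total_bp": total,
        "covered_bp": covered,
        "duplicated_bp": duplicated,
        "covered_pct": 100.0 * covered / total if total else 0.0,
        "duplicated_pct": 100.0 * duplicated / total if total else 0.0,
        "n_large_blocks": n_large,
        "size_threshold": size_threshold,
    }


def filter_blocks(blocks, min_ref_span: int = 0):
    """Drop blocks below a minimum reference span (analysis-scale filter)."""
    return [b for b in blocks if b.ref_span >= min_ref_span]


def duplicate_retained(blocks, genes, ref_lengths: dict[str, int]):
    """Genes overlapping each depth >= 2 interval, grouped per interval.

    Returns a list of ((chrom, start, end, depth), [gene ids]) in genomic
    order; a gene appears once per interval it overlaps.
    """
    profile = depth_profile(blocks, ref_lengths)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chrom].addi(g.start, g.end + 1, g.gene_id)  # half-open tree coords
    out = []
    for chrom in ref_lengths:
        for s, e, d in profile.get(chrom, []):
            if d < 2:
                continue
            hits = sorted({iv.data for iv in trees[chrom].overlap(s, e + 1)})
            out.append(((chrom, s, e, d), hits))
    return out


def genes_in_blocks_fraction(blocks, genes, ref_lengths: dict[str, int]) -> float:
    """Fraction of genes whose span overlaps any depth >= 1 region."""
    genes = list(genes)
    if not genes:
        raise ZeroDivisionError("no genes given")
    profile = depth_profile(blocks, ref_lengths)
    covered: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, segs in profile.items():
        for s, e, d in segs:
            if d >= 1:
                covered[chrom].addi(s, e + 1)
    n_in = sum(1 for g in genes if covered[g.chrom].overlap(g.start, g.end + 1))
    return n_in / len(genes)


def write_depth_bed(profile, path) -> None:
    """Depth profile as BED (0-based half-open, name=depth, score=depth)."""
    from .formats import write_bed

    rows = []
    for chrom, segs in profile.items():
        for s, e, d in segs:
            rows.append((chrom, s - 1, e, f"depth{d}", d))
    write_bed(rows, path)
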