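"""Telomere motif arrays and centromere-like tandem/higher-order repeats.

Two detectors: a motif-tiling scanner that finds maximal intervals matching
a short telomeric unit (either strand) above a purity floor, and a
shift-identity period profile that recovers the base monomer length of a
tandem array and its higher-order-repeat (HOR) order — a HOR shows better
self-identity at an integer multiple of the monomer length than at the
monomer itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatArray:
    """A detected tandem array (0-based half-open, forward coordinates)."""

    chrom: str
    start0: int
    end0: int
    unit: str
    copies: float
    purity: float
    kind: str  # telomere | tandem
    orientation: str = "+"

    @property
    def length(self) -> int:
        return self.end0 - self.start0


@dataclass(frozen=True)
class PeriodProfile:
    chrom: str
    start0: int
    end0: int
    scores: dict[int, float]
    base_period: int | None
    hor_order: int | None


# ---------------------------------------------------------------------------
# motif arrays
# ---------------------------------------------------------------------------

def _seed_positions(seq_arr: np.ndarray, motif: str) -> np.ndarray:
    """Start positions of exact motif matches (vectorized)."""
    m = len(motif)
    n = len(seq_arr)
    if n < m:
        return np.empty(0, dtype=np.int64)
    hit = np.ones(n - m + 1, dtype=bool)
    motif_b = np.frombuffer(motif.encode(), dtype="S1")
    for j in range(m):
        hit &= seq_arr[j : n - m + 1 + j] == motif_b[j]
    return np.nonzero(hit)[0]


def _match_mask(seq_arr: np.ndarray, motif: str, phase: int) -> np.ndarray:
    """mask[i] = sequence base i equals the ideal tiling base (given phase)."""
    m = len(motif)
    motif_b = np.frombuffer(motif.encode(), dtype="S1")
    idx = (np.arange(len(seq_arr)) - phase) % m
    return seq_arr == motif_b[idx]


def find_motif_arrays(sequence: str, motif: str, min_copies: int = 10,
                      max_divergence: float = 0.2, chrom: str = "",
                      kind: str = "tandem") -> list[RepeatArray]:
    """Find maximal tandem arrays of ``motif`` (or its reverse complement).

    Greedy: exact seed matches are merged when within one unit length, then
    each seeded interval is extended unit-by-unit in both directions while
    the appended unit matches at >= 1 - max_divergence identity and overall
    purity stays above the floor. One orientation per array; coordinates are
    always forward-strand.
    """
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    if not 2 <= len(motif) <= 100:
        raise ValueError("motif length must be in [2, 100]")
    seq_arr = np.frombuffer(sequence.encode(), dtype="S1")
    m = len(motif)
    arrays: list[RepeatArray] = []
    for orient, probe in (("+", motif), ("-", reverse_complement(motif))):
        if probe == motif and orient == "-":
            continue  # palindromic motif: one orientation suffices
        seeds = _seed_positions(seq_arr, probe)
        if len(seeds) == 0:
            continue
        # group seeds whose gaps are at most one unit
        groups: list[list[int]] = [[int(seeds[0])]]
        for s in seeds[1:]:
            s = int(s)
            if s - (groups[-1][-1] + m) <= m:
                groups[-1].append(s)
            else:
                groups.append([s])
        intervals: list[tuple[int, int]] = []
        for grp in groups:
            start, end = grp[0], grp[-1] + m
            phase = start % m
            mask = _match_mask(seq_arr, probe, phase)
            matched = int(mask[start:end].sum())
            # extend one unit at a time while the new unit passes the bar
            while start - m >= 0:
                unit_hits = int(mask[start - m : start].sum())
                if unit_hits / m < 1 - max_divergence:
                    break
                start -= m
                matched += unit_hits
            while end + m <= len(seq_arr):
                unit_hits = int(mask[end : end + m].sum())
                if unit_hits / m < 1 - max_divergence:
                    break
                end += m
                matched += unit_hits
            intervals.append((start, end))
        # merge extended intervals separated by short low-identity stretches
        # (runs of diverged units) as long as overall purity holds up
        intervals.sort()
        merged: list[list[int]] = []
        for s, e in intervals:
            if merged and s - merged[-1][1] <= 10 * m:
                phase = merged[-1][0] % m
                mask = _match_mask(seq_arr, probe, phase)
                cand_purity = float(mask[merged[-1][0]: max(e, merged[-1][1])].mean())
                if cand_purity >= 1 - max_divergence:
                    merged[-1][1] = max(merged[-1][1], e)
                    continue
            merged.append([s, e])
        for s, e in merged:
            phase = s % m
            mask = _match_mask(seq_arr, probe, phase)
            purity = float(mask[s:e].mean())
            copies = (e - s) / m
            if copies >= min_copies and purity >= 1 - max_divergence:
                arrays.append(
                    RepeatArray(chrom, s, e, motif, copies, purity, kind, orient)
                )
    arrays.sort(key=lambda a: (a.start0, a.end0))
    return arrays


# ---------------------------------------------------------------------------
# telomeres
# ---------------------------------------------------------------------------

TELOMERE_MOTIF = "AAACCCT"


def telomere_report(assembly, motif: str = TELOMERE_MOTIF,
                    end_window: int = 100_000, min_copies: int = 10,
                    max_divergence: float = 0.2):
    """Scan both ends of every sequence for telomeric arrays.

    An end is telomere-bearing when an array with >= min_copies lies within
    ``end_window/2`` of the terminus. Returns (per-end array list, mean
    telomere length over telomere-bearing ends; None when no end qualifies).
    """
    if end_window < 2 * len(motif):
        raise ValueError("end_window must cover at least two motif units")
    per_end = []
    lengths = []
    for rec in assembly:
        L = len(rec.sequence)
        w = min(end_window, L)
        for which, (s0, window_seq) in (
            ("start", (0, rec.sequence[:w])),
            ("end", (L - w, rec.sequence[L - w:])),
        ):
            arrays = [
                RepeatArray(rec.id, a.start0 + s0, a.end0 + s0, a.unit,
                            a.copies, a.purity, "telomere", a.orientation)
                for a in find_motif_arrays(window_seq, motif, min_copies,
                                           max_divergence, chrom=rec.id,
                                           kind="telomere")
            ]
            near = []
            for a in arrays:
                dist = a.start0 if which == "start" else L - a.end0
                if dist <= end_window / 2:
                    near.append(a)
            telomeric = max(near, key=lambda a: a.length) if near else None
            per_end.append({"chrom": rec.id, "terminus": which, "array": telomeric})
            if telomeric is not None:
                lengths.append(telomeric.length)
    mean_length = float(np.mean(lengths)) if lengths else None
    return per_end, mean_length


# ---------------------------------------------------------------------------
# period profile (centromere monomer / HOR)
# ---------------------------------------------------------------------------

SCORE_FLOOR = 0.5  # random DNA self-identity baseline is 0.25


def period_profile(sequence: str, min_p: int = 50, max_p: int = 500,
                   delta: float = 0.02, chrom: str = "", start0: int = 0,
                   ) -> PeriodProfile:
    """Self-identity profile over shifts p in [min_p, max_p].

    scores[p] = fraction of positions i with base(i) == base(i+p). The base
    period is the smallest local-maximum shift above the 0.5 score floor
    whose integer multiple accounts for the best-scoring shift (fundamental
    preferred over its harmonics). The HOR order is the smallest m > 1 with
    scores[m*p] >= scores[p] + delta, else 1. Both are None when no shift
    clears the floor.
    """
    L = len(sequence)
    if L < 4 * max_p:
        raise ValueError("window shorter than 4x the maximum period")
    arr = np.frombuffer(sequence.encode(), dtype="S1")
    shifts = np.arange(min_p, max_p + 1)
    scores = {
        int(p): float((arr[:-p] == arr[p:]).mean()) for p in shifts
    }
    svals = np.array([scores[int(p)] for p in shifts])
    best = float(svals.max())
    if best <= SCORE_FLOOR:
        return PeriodProfile(chrom, start0, start0 + L, scores, None, None)
    p_best = int(shifts[int(svals.argmax())])

    # local maxima of the profile above the floor
    candidates = []
    for i, p in enumerate(shifts):
        s = svals[i]
        if s <= SCORE_FLOOR:
            continue
        left = svals[i - 1] if i > 0 else -1.0
        right = svals[i + 1] if i + 1 < len(svals) else -1.0
        if s >= left and s >= right:
            candidates.append(int(p))
    base_period = p_best
    tol = 2  # bp slack when testing whether p_best is a multiple of p
    for p in sorted(candidates):
        r = p_best % p
        if min(r, p - r) <= tol or abs(scores[p] - best) <= delta:
            base_period = p
            break
    hor_order = 1
    m = 2
    while m * base_period <= max_p:
        if scores[m * base_period] >= scores[base_period] + delta:
            hor_order = m
            break
        m += 1
    return PeriodProfile(chrom, start0, start0 + L, scores, base_period, hor_order)
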