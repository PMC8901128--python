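"""Genome size and peak structure from a k-mer coverage spectrum.

The estimator is the classic one: smooth the histogram, find the trough that
separates low-coverage error k-mers from the genomic bulge, and divide the
total k-mer observations above the trough by the primary peak's coverage.
A bimodal spectrum with the lower-coverage (left) peak carrying more mass
than the right is the signature of an interspecific hybrid whose two
component genomes are distinct; it is reported as a flag, not resolved into
component sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SpectrumError(ValueError):
    """No usable error/signal separation in the spectrum."""


@dataclass(frozen=True)
class KmerHistogram:
    """counts[c] = number of distinct k-mers observed exactly c times."""

    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.counts < 0):
            raise ValueError("negative k-mer counts")

    @property
    def max_coverage(self) -> int:
        return len(self.counts) - 1

    def total_observations(self) -> int:
        cov = np.arange(len(self.counts))
        return int((cov * self.counts).sum())


@dataclass(frozen=True)
class GenomeSizeEstimate:
    trough: int
    peaks: tuple[tuple[int, float], ...]  # (coverage, height), sorted by coverage
    primary_peak: int
    size_bp: float
    n_peaks: int
    peak_masses: tuple[float, ...] = field(default=())
    left_peak_bigger: bool | None = None


def smooth(hist: KmerHistogram, window: int = 3) -> KmerHistogram:
    """Centered moving average; ``window`` must be odd (1 = identity)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return hist
    kernel = np.ones(window) / window
    smoothed = np.convolve(hist.counts.astype(float), kernel, mode="same")
    return KmerHistogram(k=hist.k, counts=smoothed)


def find_trough_and_peaks(hist: KmerHistogram, merge_window: int = 3):
    """Locate the error/signal trough and the genomic coverage peaks.

    Trough = smallest coverage c >= 2 with counts[c] <= counts[c-1] and
    counts[c] <= counts[c+1]; if the spectrum starts rising immediately
    (no error mass), the support edge is the trough. Peaks are local maxima
    at c > trough; peaks closer than ``merge_window`` are merged keeping the
    taller. Raises :class:`SpectrumError` for monotone spectra.
    """
    c = hist.counts.astype(float)
    n = len(c)
    if n < 4:
        raise SpectrumError("spectrum too short")
    trough = None
    for cov in range(2, n - 1):
        if c[cov] <= c[cov - 1] and c[cov] <= c[cov + 1]:
            trough = cov
            break
    if trough is None:
        # no interior minimum: rising spectrum means no error mass -> edge
        first = int(np.nonzero(c > 0)[0][0]) if np.any(c > 0) else None
        if first is None or np.all(np.diff(c[max(first, 1):]) <= 0):
            raise SpectrumError("monotone spectrum: no error/signal separation")
        trough = max(first, 1)
    peaks: list[tuple[int, float]] = []
    for cov in range(max(trough + 1, 1), n - 1):
        if c[cov] > c[cov - 1] and c[cov] >= c[cov + 1] and c[cov] > 0:
            peaks.append((cov, float(c[cov])))
    if not peaks:
        # a peak sitting at the right edge
        if n >= 2 and c[n - 1] > c[n - 2]:
            peaks = [(n - 1, float(c[n - 1]))]
        else:
            raise SpectrumError("no peak above the trough")
    merged: list[tuple[int, float]] = []
    for cov, h in peaks:
        if merged and cov - merged[-1][0] < merge_window:
            if h > merged[-1][1]:
                merged[-1] = (cov, h)
        else:
            merged.append((cov, h))
    return trough, merged


def estimate_genome_size(hist: KmerHistogram, smooth_window: int = 3,
                         merge_window: int = 3) -> GenomeSizeEstimate:
    """Estimate genome size as (k-mer mass above the trough) / peak coverage.

    For bimodal spectra the higher-coverage peak anchors the size formula
    (the half-coverage peak reflects the heterozygous/divergent fraction);
    the relative peak masses and the left-peak-bigger flag support the
    hybridity call.
    """
    sm = smooth(hist, smooth_window)
    trough, peaks = find_trough_and_peaks(sm, merge_window)
    # keep at most two dominant peaks; tail ripples below 5% of the tallest
    # peak are sampling noise, not genome components
    tallest = max(h for _, h in peaks)
    peaks = [p for p in peaks if p[1] >= 0.05 * tallest]
    dominant = sorted(peaks, key=lambda p: p[1], reverse=True)[:2]
    dominant.sort(key=lambda p: p[0])

    # refine each peak's coverage on the raw histogram (smoothing can shift
    # an asymmetric peak by a bin)
    raw = hist.counts.astype(float)
    refined = []
    for cov0, _h in dominant:
        lo = max(trough + 1, cov0 - smooth_window)
        hi = min(len(raw), cov0 + smooth_window + 1)
        cov_r = lo + int(np.argmax(raw[lo:hi]))
        refined.append((cov_r, float(raw[cov_r])))
    dominant = refined
    n_peaks = len(dominant)
    primary = dominant[-1][0]  # highest coverage among dominant peaks

    cov = np.arange(len(hist.counts))
    mass = cov * raw
    size_bp = float(mass[trough:].sum() / primary)

    # peak masses are distinct-k-mer totals: the "left peak bigger" hybrid
    # signature compares histogram bulk, not coverage-weighted observations
    peak_masses: tuple[float, ...] = ()
    left_bigger = None
    if n_peaks == 2:
        split = (dominant[0][0] + dominant[1][0]) // 2
        left = float(raw[trough: split + 1].sum())
        right = float(raw[split + 1:].sum())
        peak_masses = (left, right)
        left_bigger = left > right
    elif n_peaks == 1:
        peak_masses = (float(raw[trough:].sum()),)

    return GenomeSizeEstimate(
        trough=trough,
        peaks=tuple(dominant),
        primary_peak=primary,
        size_bp=size_bp,
        n_peaks=n_peaks,
        peak_masses=peak_masses,
        left_peak_bigger=left_bigger,
    )
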