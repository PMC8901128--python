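"""GO overrepresentation of genes in classified diversity regions.

Genes overlapping high (or low) diversity bins by at least one base pair are
tested term-by-term against the annotated background with an upper-tail
hypergeometric test; Benjamini-Hochberg adjusted values are reported
alongside. The default significance convention is raw p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import BinClassification, BinGrid
from .formats import GeneModel


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # genes with term in selection
    n: int  # selection size
    K: int  # genes with term in background
    N: int  # background size
    p_value: float
    adjusted_p: float


def genes_in_labelled_bins(classifications, grid: BinGrid, genes, label: str,
                           ) -> set[str]:
    """Genes whose span overlaps any bin with the requested label by >= 1 bp.

    Bins from multiple samples are pooled: a gene is selected if ANY sample's
    bin at that locus carries the label. Gene spans are 1-based inclusive;
    bins 0-based half-open.
    """
    labelled: list[tuple[str, int, int]] = []
    seen_bins: set[int] = set()
    for bc in classifications:
        if bc.label == label and bc.bin_index not in seen_bins:
            seen_bins.add(bc.bin_index)
            labelled.append(grid.bins[bc.bin_index])
    selected: set[str] = set()
    for g in genes:
        for chrom, s0, e0 in labelled:
            if g.chrom == chrom and g.start <= e0 and g.end >= s0 + 1:
                selected.add(g.gene_id)
                break
    return selected


def go_overrepresentation(selected: set[str], background: set[str],
                          go_map: dict[str, set[str]]) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per GO term, BH-adjusted, sorted by p.

    Population N = background genes, successes K = background genes carrying
    the term, draws n = selected genes, observed k; p = P(X >= k). Terms
    absent from the background (K = 0) are skipped. Genes without annotation
    contribute no terms but do count toward N and n if present in the sets.
    """
    extra = selected - background
    if extra:
        raise ValueError(f"selected genes not in background: {sorted(extra)[:5]}")
    N = len(background)
    n = len(selected)
    term_background: dict[str, int] = {}
    term_selected: dict[str, int] = {}
    for gene in background:
        for term in go_map.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in selected:
                term_selected[term] = term_selected.get(term, 0) + 1
    terms = sorted(term_background)
    pvals = []
    for term in terms:
        K = term_background[term]
        k = term_selected.get(term, 0)
        # P(X >= k) upper tail; sf(k-1) is exact for the discrete hypergeometric
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        pvals.append(min(max(p, 0.0), 1.0))
    if not terms:
        return []
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=t,
            k=term_selected.get(t, 0),
            n=n,
            K=term_background[t],
            N=N,
            p_value=p,
            adjusted_p=float(max(a, p)),
        )
        for t, p, a in zip(terms, pvals, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def report_significant(results, alpha: float = 0.01, use_adjusted: bool = False,
                       ) -> list[EnrichmentResult]:
    """Filter results at strict p < alpha (raw by default, BH by flag)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    key = (lambda r: r.adjusted_p) if use_adjusted else (lambda r: r.p_value)
    return [r for r in results if key(r) < alpha]


def write_enrichment_tsv(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("#term\tk\tK\tn\tN\tp_value\tadjusted_p\n")
        for r in results:
            fh.write(f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value:.6g}\t{r.adjusted_p:.6g}\n")
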