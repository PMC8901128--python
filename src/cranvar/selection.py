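"""Pairwise Ka/Ks on codon-aligned CDS pairs (Nei–Gojobori counting).

Synonymous and nonsynonymous sites are counted per codon from the standard
genetic code (substitutions creating stop codons are excluded from the
denominator); observed differences are averaged over all minimal mutational
pathways between each codon pair that avoid stop codons. Proportions are
Jukes–Cantor corrected. Ratios above/below the chosen threshold classify
genes as under positive/negative selection; saturated or zero-synonymous
cases are explicit states, never NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

log = logging.getLogger("cranvar")

CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = frozenset(CODE)

CLASS_POSITIVE = "positive"
CLASS_NEGATIVE = "negative"
CLASS_NEUTRAL = "neutral"
CLASS_UNDEFINED = "undefined"


@dataclass(frozen=True)
class CodonAlignmentPair:
    """A gap-stripped codon alignment of two CDS sequences."""

    gene_id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.gene_id}: aligned sequences differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.gene_id}: length not divisible by 3")


@dataclass(frozen=True)
class KaKsResult:
    gene_id: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    pn: float
    ps: float
    ka: float | None
    ks: float | None
    ratio: float | None  # math.inf when Ks=0 < Ka
    classification: str


def strip_gap_columns(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Drop alignment columns with a gap in either sequence, codon-wise safe.

    Gaps are stripped per column first; the caller is responsible for the
    result remaining in frame (codon-aligned inputs with codon gaps are).
    """
    kept_a = []
    kept_b = []
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a == "-" or b == "-":
            continue
        kept_a.append(a)
        kept_b.append(b)
    return "".join(kept_a), "".join(kept_b)


# ---------------------------------------------------------------------------
# per-codon site counts
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one sense codon.

    At each position the synonymous fraction is the share of the possible
    single-base changes that preserve the amino acid, with changes creating
    stop codons removed from the denominator; sites sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    if codon not in SENSE_CODONS:
        raise ValueError(f"not a codon: {codon!r}")
    aa = CODE[codon]
    s_total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if CODE[mutant] == aa:
                syn += 1
        if valid:
            s_total += syn / valid
    return 3.0 - s_total, s_total


# ---------------------------------------------------------------------------
# per-codon-pair differences
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) differences.

    All orderings of the differing positions are enumerated; pathways whose
    intermediate codons are stops are excluded from the average. If every
    pathway is blocked, each differing site is classified by substituting it
    alone into ``codon_a`` (with a warning) — a defined fallback for a case
    that cannot arise between sense codons differing at fewer than 3 sites.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c not in SENSE_CODONS:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    path_counts: list[tuple[int, int]] = []
    for order in permutations(diff_positions):
        current = codon_a
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODE[nxt] == CODE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        if not blocked:
            path_counts.append((nd, sd))
    if not path_counts:
        log.warning(
            "all mutational pathways between %s and %s pass through stops; "
            "classifying sites independently", codon_a, codon_b,
        )
        nd = sd = 0
        for pos in diff_positions:
            mutant = codon_a[:pos] + codon_b[pos] + codon_a[pos + 1:]
            if mutant in STOP_CODONS or CODE[mutant] != CODE[codon_a]:
                nd += 1
            else:
                sd += 1
        return float(nd), float(sd)
    nd = sum(p[0] for p in path_counts) / len(path_counts)
    sd = sum(p[1] for p in path_counts) / len(path_counts)
    return nd, sd


# ---------------------------------------------------------------------------
# Ka/Ks per pair
# ---------------------------------------------------------------------------

def _jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def kaks(pair: CodonAlignmentPair) -> KaKsResult:
    """NG86 Ka/Ks with Jukes–Cantor correction for one aligned pair.

    Site counts are averaged across the two sequences. Saturation (pN or pS
    >= 3/4) yields an undefined classification; Ks = 0 with Ka > 0 is
    flagged positive with an infinite ratio; Ka = Ks = 0 is neutral.
    """
    a, b = strip_gap_columns(pair.seq_a, pair.seq_b)
    if len(a) % 3 != 0:
        raise ValueError(f"{pair.gene_id}: gap-stripped alignment out of frame")
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        na_, sa_ = codon_site_counts(ca)
        nb_, sb_ = codon_site_counts(cb)
        n_a += na_
        s_a += sa_
        n_b += nb_
        s_b += sb_
        d_n, d_s = codon_pair_differences(ca, cb)
        nd += d_n
        sd += d_s
    n_sites = (n_a + n_b) / 2.0
    s_sites = (s_a + s_b) / 2.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka = _jukes_cantor(pn)
    ks = _jukes_cantor(ps)

    if ka is None or ks is None:
        ratio: float | None = None
        classification = CLASS_UNDEFINED
    elif ka == 0.0 and ks == 0.0:
        ratio = None
        classification = CLASS_NEUTRAL
    elif ks == 0.0:
        ratio = math.inf
        classification = CLASS_POSITIVE
    else:
        ratio = ka / ks
        if ratio > 1.0:
            classification = CLASS_POSITIVE
        elif ratio < 1.0:
            classification = CLASS_NEGATIVE
        else:
            classification = CLASS_NEUTRAL

    return KaKsResult(
        gene_id=pair.gene_id,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        ka=ka,
        ks=ks,
        ratio=ratio,
        classification=classification,
    )


def classify_selection(results, positive_threshold: float = 1.0):
    """Partition Ka/Ks results at the chosen positive threshold.

    Positive: ratio > threshold (default 1; the between-cultivar convention
    uses 2). Negative: ratio < 1. Undefined/saturated results are excluded
    and counted separately; neutral and in-between ratios fall in neither
    list. Returns a dict with ``positive``, ``negative``, ``neither`` gene
    lists and ``n_undefined``.
    """
    if positive_threshold < 1.0:
        raise ValueError("positive_threshold must be >= 1")
    positive, negative, neither = [], [], []
    n_undefined = 0
    for r in results:
        if r.classification == CLASS_UNDEFINED:
            n_undefined += 1
        elif r.ratio is not None and r.ratio > positive_threshold:
            positive.append(r.gene_id)
        elif r.ratio is not None and r.ratio < 1.0:
            negative.append(r.gene_id)
        else:
            neither.append(r.gene_id)
    return {
        "positive": positive,
        "negative": negative,
        "neither": neither,
        "n_undefined": n_undefined,
    }


def write_kaks_tsv(results, path, method: str = "NG86+JC69") -> None:
    with open(path, "w") as fh:
        fh.write(f"# method={method}\n")
        fh.write("#gene_id\tN_sites\tS_sites\tNd\tSd\tpN\tpS\tKa\tKs\tratio\tclassification\n")
        for r in results:
            fmt = lambda x: "NA" if x is None else ("inf" if x == math.inf else f"{x:.6g}")
            fh.write(
                f"{r.gene_id}\t{r.n_sites:.4f}\t{r.s_sites:.4f}\t{r.nd:.4f}\t{r.sd:.4f}\t"
                f"{r.pn:.6g}\t{r.ps:.6g}\t{fmt(r.ka)}\t{fmt(r.ks)}\t{fmt(r.ratio)}\t"
                f"{r.classification}\n"
            )
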