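"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions are normalized here and nowhere else: VCF and GFF3
coordinates are 1-based inclusive in memory; BED output is 0-based half-open.
All readers are deterministic (identical bytes yield identical objects).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO

log = logging.getLogger("cranvar")

_DNA = frozenset("ACGT")
_GO_RE = re.compile(r"^GO:\d{7}$")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")


#: genotype classifications relative to one alternate allele
GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
GT_MISSING = "missing"


@dataclass(frozen=True)
class VariantCall:
    """One sample's genotype at a biallelic SNP (pos is 1-based)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"non-positive position {self.pos}")


@dataclass(frozen=True)
class GeneModel:
    """A gene span (1-based inclusive) with its GO annotation."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class SyntenyBlock:
    """A colinear block between a reference and a query genome.

    Coordinates are 1-based inclusive and normalized so start <= end on both
    sides; reversed input spans are swapped with the orientation flag kept.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    orientation: str

    def __post_init__(self) -> None:
        if self.ref_start > self.ref_end or self.query_start > self.query_end:
            raise ValueError("block coordinates not normalized (start > end)")
        if self.orientation not in ("+", "-"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start + 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercase :class:`SequenceRecord` objects.

    Raises :class:`FormatError` on duplicate ids or empty sequences.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _classify_gt(allele_indices, alt_index: int) -> str:
    """Classify a GT tuple relative to one alternate-allele index."""
    if allele_indices is None or len(allele_indices) == 0:
        return GT_MISSING
    if any(a is None for a in allele_indices):
        return GT_MISSING
    alleles = set(allele_indices)
    if alleles == {alt_index}:
        return GT_HOM_ALT
    if alt_index in alleles:
        # mixed with ref or with another alt: one copy of this alt
        return GT_HET
    return GT_HOM_REF


def read_vcf_snps(path, samples=None):
    """Stream biallelic-SNP :class:`VariantCall` objects from a VCF.

    Multi-allelic records are split per alternate allele, so each
    (chrom, pos, alt) pair is an independent observation. Non-SNP alternate
    alleles (indels, MNPs, symbolic) are skipped and counted; the count is
    logged at the end of iteration. Genotypes with any missing allele are
    classified ``missing``. The FILTER column is ignored.
    """
    vcf = pysam.VariantFile(str(path))
    available = list(vcf.header.samples)
    if samples is None:
        samples = available
    else:
        missing = [s for s in samples if s not in available]
        if missing:
            raise KeyError(
                f"sample(s) {missing} not in VCF; available: {available}"
            )
    n_skipped = 0
    for rec in vcf:
        ref = rec.ref.upper() if rec.ref else ""
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            alt = alt.upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _DNA or alt not in _DNA:
                n_skipped += 1
                continue
            if alt == ref:
                n_skipped += 1
                continue
            for s in samples:
                gt = rec.samples[s].get("GT")
                yield VariantCall(
                    sample_id=s,
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    genotype=_classify_gt(gt, ai),
                )
    vcf.close()
    if n_skipped:
        log.info("read_vcf_snps: skipped %d non-SNP alternate alleles", n_skipped)


def vcf_snp_skip_count(path) -> int:
    """Count non-SNP alternate alleles that read_vcf_snps would skip."""
    vcf = pysam.VariantFile(str(path))
    n = 0
    for rec in vcf:
        ref = rec.ref.upper() if rec.ref else ""
        for alt in rec.alts or ():
            a = alt.upper()
            if len(ref) != 1 or len(a) != 1 or ref not in _DNA or a not in _DNA or a == ref:
                n += 1
    vcf.close()
    return n


def write_vcf(path, chrom_lengths, sample_ids, records) -> None:
    """Write a minimal multi-sample VCF 4.2 file.

    ``records`` is an iterable of (chrom, pos, ref, alt, genotypes) where
    genotypes is a map sample_id -> GT string (e.g. "0/1"). Records are
    written sorted by (chrom order as given, pos, alt) for determinism.
    """
    order = {c: i for i, c in enumerate(chrom_lengths)}
    recs = sorted(records, key=lambda r: (order[r[0]], r[1], r[3]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for chrom, pos, ref, alt, genotypes in recs:
            gts = "\t".join(genotypes.get(s, "0/0") for s in sample_ids)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3 (gene rows only)
# ---------------------------------------------------------------------------

_ID_RE = re.compile(r"(?:^|;)ID=([^;]+)")


def read_gff3_genes(path) -> list[GeneModel]:
    """Read gene features from a GFF3 file, sorted by (chrom, start).

    Only rows of type ``gene`` are retained; the hierarchy below genes is
    ignored. GO terms are not stored here (see :func:`read_go_map`).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            m = _ID_RE.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: gene row without ID attribute")
            genes.append(
                GeneModel(
                    gene_id=m.group(1),
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3_genes(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tcranvar\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# gene -> GO map (two-column TSV)
# ---------------------------------------------------------------------------

def read_go_map(path) -> dict[str, set[str]]:
    """Read a two-column TSV of (gene_id, GO id) into gene -> term-set.

    Rows whose GO id does not match ``GO:`` + 7 digits are skipped with a
    warning. Genes absent from the file simply map to no terms downstream.
    """
    go_map: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not _GO_RE.match(parts[1].strip()):
                log.warning("read_go_map: %s:%d: skipping malformed row %r", path, lineno, line)
                continue
            go_map.setdefault(parts[0], set()).add(parts[1].strip())
    return go_map


def write_go_map(go_map, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# k-mer histogram (two-column "coverage count" text, jellyfish-histo style)
# ---------------------------------------------------------------------------

def read_kmer_histogram(path, k: int = 31):
    """Read a two-column "coverage count" histogram into a KmerHistogram.

    Coverage must be strictly increasing; gaps are filled with zero counts.
    """
    from .kmer import KmerHistogram  # local import to avoid a cycle

    covs: list[int] = []
    cnts: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            cov, cnt = int(parts[0]), int(parts[1])
            if cov < 1:
                raise FormatError(f"{path}:{lineno}: coverage must be >= 1")
            if cnt < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if covs and cov <= covs[-1]:
                raise FormatError(f"{path}:{lineno}: coverage column not strictly increasing")
            covs.append(cov)
            cnts.append(cnt)
    import numpy as np

    if not covs:
        return KmerHistogram(k=k, counts=np.zeros(1, dtype=np.int64))
    dense = np.zeros(covs[-1] + 1, dtype=np.int64)
    for cov, cnt in zip(covs, cnts):
        dense[cov] = cnt
    return KmerHistogram(k=k, counts=dense)


def write_kmer_histogram(hist, path) -> None:
    with open(path, "w") as fh:
        for cov in range(1, len(hist.counts)):
            fh.write(f"{cov} {int(hist.counts[cov])}\n")


# ---------------------------------------------------------------------------
# BED5
# ---------------------------------------------------------------------------

def write_bed(intervals, path) -> None:
    """Write BED5 rows (chrom, start0, end0, name, score), sorted.

    Coordinates are 0-based half-open; start0 must be < end0.
    """
    rows = []
    for chrom, start0, end0, name, score in intervals:
        if start0 >= end0:
            raise ValueError(f"BED interval with start >= end: {chrom}:{start0}-{end0}")
        rows.append((chrom, int(start0), int(end0), str(name), score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for chrom, start0, end0, name, score in rows:
            fh.write(f"{chrom}\t{start0}\t{end0}\t{name}\t{score}\n")


def read_bed(path) -> list[tuple]:
    """Read BED5 rows back as (chrom, start0, end0, name, score) tuples."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            c = line.split("\t")
            rows.append((c[0], int(c[1]), int(c[2]), c[3], c[4]))
    return rows


# ---------------------------------------------------------------------------
# Synteny block TSV (7 columns, '#' header)
# ---------------------------------------------------------------------------

def read_synteny_blocks(path) -> list[SyntenyBlock]:
    """Read a SyMAP-style block export: 7-column TSV with a '#' header.

    Columns: ref_chrom, ref_start, ref_end, query_chrom, query_start,
    query_end, orientation. Spans given end-before-start are swapped with the
    orientation flag preserved.
    """
    blocks: list[SyntenyBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(cols)}")
            rc, rs, re_, qc, qs, qe, orient = cols
            if orient not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown orientation {orient!r}")
            rs, re_, qs, qe = int(rs), int(re_), int(qs), int(qe)
            if rs > re_:
                rs, re_ = re_, rs
            if qs > qe:
                qs, qe = qe, qs
            blocks.append(SyntenyBlock(rc, rs, re_, qc, qs, qe, orient))
    return blocks


def write_synteny_blocks(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("#ref_chrom\tref_start\tref_end\tquery_chrom\tquery_start\tquery_end\torientation\n")
        for b in blocks:
            fh.write(
                f"{b.ref_chrom}\t{b.ref_start}\t{b.ref_end}\t{b.query_chrom}\t"
                f"{b.query_start}\t{b.query_end}\t{b.orientation}\n"
            )
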