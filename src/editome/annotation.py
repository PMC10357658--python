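"""Strand-aware genomic-context annotation.

Sites overlapping exons or introns of annotated genes, lncRNAs or vlincRNAs
must lie on the same genomic strand as the transcript to be assigned a sense
context.  Because features overlap, every site gets exactly one label via a
fixed precedence: CDS > UTR5 > UTR3 > lncRNA_exon > intron > vlincRNA >
antisense_exon > antisense_intron > intergenic.  In particular an intronic
site inside a same-strand vlincRNA is labelled intron, and a same-strand
vlincRNA beats any antisense overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

from .model import (
    AnnotationBundle,
    ConsensusSite,
    CONTEXT_LABELS,
    DbSites,
    SiteKey,
    Transcript,
)

StrandedInterval = Tuple[str, int, int, str]  # chrom, start, end, strand (0-based half-open)


class StrandedIntervals:
    """Point-queryable set of stranded intervals."""

    def __init__(self, intervals: Iterable[StrandedInterval]):
        self._trees: Dict[str, IntervalTree] = {}
        for chrom, start, end, strand in intervals:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, strand)

    def query(
        self, chrom: str, pos0: int, strand: Optional[str] = None
    ) -> List[Tuple[int, int, str]]:
        """Intervals containing 0-based ``pos0``; restricted to ``strand`` if given."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [(iv.begin, iv.end, iv.data) for iv in tree[pos0]]
        if strand is not None:
            hits = [h for h in hits if h[2] == strand]
        return sorted(hits)


def overlap_stranded(
    query: SiteKey,
    intervals: StrandedIntervals,
    require_same_strand: bool = True,
) -> List[Tuple[int, int, str]]:
    """All intervals containing the site (optionally strand-matched)."""
    strand = query.strand if require_same_strand else None
    return intervals.query(query.chrom, query.pos - 1, strand)


def match_annotated_db(
    sites: Iterable[ConsensusSite], db_sites: DbSites
) -> Tuple[List[ConsensusSite], List[ConsensusSite]]:
    """Split sites into (annotated, unannotated) against the editing databases.

    Strand must match when the database record carries one; strandless
    records match either strand.  Sets the ``annotated`` flag in place.
    """
    annotated, unannotated = [], []
    for site in sites:
        site.annotated = db_sites.contains(site.key)
        (annotated if site.annotated else unannotated).append(site)
    return annotated, unannotated


@dataclass
class ContextIndex:
    """Per-category interval indexes derived from an annotation bundle.

    Sense categories are queried with the site's strand; the antisense
    categories with the opposite strand over the gene exon/intron sets.
    """

    cds: StrandedIntervals
    utr5: StrandedIntervals
    utr3: StrandedIntervals
    lnc_exon: StrandedIntervals
    intron: StrandedIntervals
    vlinc: StrandedIntervals
    gene_exon: StrandedIntervals  # all gene exons regardless of category
    gene_intron: StrandedIntervals

    @classmethod
    def from_bundle(cls, bundle: AnnotationBundle) -> "ContextIndex":
        return cls.from_parts(bundle.transcripts, bundle.vlincs)

    @classmethod
    def from_parts(
        cls,
        transcripts: Sequence[Transcript],
        vlincs: Sequence[StrandedInterval],
    ) -> "ContextIndex":
        cds, utr5, utr3, lnc_exon, intron, gene_exon, gene_intron = (
            [] for _ in range(7)
        )
        for tx in transcripts:
            for s, e in tx.exons:
                gene_exon.append((tx.chrom, s, e, tx.strand))
            for s, e in tx.introns():
                intron.append((tx.chrom, s, e, tx.strand))
                gene_intron.append((tx.chrom, s, e, tx.strand))
            if tx.cds:
                for s, e in tx.cds:
                    cds.append((tx.chrom, s, e, tx.strand))
                u5, u3 = tx.utr_intervals()
                for s, e in u5:
                    utr5.append((tx.chrom, s, e, tx.strand))
                for s, e in u3:
                    utr3.append((tx.chrom, s, e, tx.strand))
            else:
                # non-coding transcript (or coding model without CDS rows):
                # all exonic bases are non-coding exon
                for s, e in tx.exons:
                    lnc_exon.append((tx.chrom, s, e, tx.strand))
        return cls(
            cds=StrandedIntervals(cds),
            utr5=StrandedIntervals(utr5),
            utr3=StrandedIntervals(utr3),
            lnc_exon=StrandedIntervals(lnc_exon),
            intron=StrandedIntervals(intron),
            vlinc=StrandedIntervals(vlincs),
            gene_exon=StrandedIntervals(gene_exon),
            gene_intron=StrandedIntervals(gene_intron),
        )


_OPPOSITE = {"+": "-", "-": "+"}


def classify_context(key: SiteKey, index: ContextIndex) -> str:
    """Assign the single genomic-context label of a site (total function)."""
    chrom, pos0, strand = key.chrom, key.pos - 1, key.strand
    if index.cds.query(chrom, pos0, strand):
        return "CDS"
    if index.utr5.query(chrom, pos0, strand):
        return "UTR5"
    if index.utr3.query(chrom, pos0, strand):
        return "UTR3"
    if index.lnc_exon.query(chrom, pos0, strand):
        return "lncRNA_exon"
    if index.intron.query(chrom, pos0, strand):
        return "intron"
    if index.vlinc.query(chrom, pos0, strand):
        return "vlincRNA"
    anti = _OPPOSITE[strand]
    if index.gene_exon.query(chrom, pos0, anti):
        return "antisense_exon"
    if index.gene_intron.query(chrom, pos0, anti):
        return "antisense_intron"
    return "intergenic"


def assign_contexts(
    sites: Iterable[ConsensusSite], index: ContextIndex
) -> Dict[str, int]:
    """Label every site in place; returns the per-context count distribution."""
    counts = {label: 0 for label in CONTEXT_LABELS}
    for site in sites:
        site.context = classify_context(site.key, index)
        counts[site.context] += 1
    return counts


# ---------------------------------------------------------------------------
# Whole-genome context painting (used for the enrichment background)

_LABEL_CODE = {label: i for i, label in enumerate(CONTEXT_LABELS)}
# painting order: lowest precedence first, so higher-precedence labels
# overwrite lower ones
_PAINT_ORDER = list(reversed(CONTEXT_LABELS[:-1]))  # intergenic is the default


def context_label_arrays(
    transcripts: Sequence[Transcript],
    vlincs: Sequence[StrandedInterval],
    contig_lengths: Dict[str, int],
) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    """Per-contig context-code arrays for hypothetical sites on (+, -).

    ``arrays[chrom][0][i]`` is the context code a site at 0-based ``i`` on
    '+' would receive, ``arrays[chrom][1][i]`` the same for '-'.  Agreement
    with :func:`classify_context` is a tested invariant.
    """
    intergenic = _LABEL_CODE["intergenic"]
    arrays = {
        c: (
            np.full(n, intergenic, dtype=np.int8),
            np.full(n, intergenic, dtype=np.int8),
        )
        for c, n in contig_lengths.items()
    }

    by_label: Dict[str, List[StrandedInterval]] = {label: [] for label in CONTEXT_LABELS}
    for tx in transcripts:
        target = "lncRNA_exon" if not tx.cds else None
        for s, e in tx.exons:
            if target:
                by_label[target].append((tx.chrom, s, e, tx.strand))
            by_label["antisense_exon"].append((tx.chrom, s, e, _OPPOSITE[tx.strand]))
        for s, e in tx.introns():
            by_label["intron"].append((tx.chrom, s, e, tx.strand))
            by_label["antisense_intron"].append((tx.chrom, s, e, _OPPOSITE[tx.strand]))
        if tx.cds:
            for s, e in tx.cds:
                by_label["CDS"].append((tx.chrom, s, e, tx.strand))
            u5, u3 = tx.utr_intervals()
            for s, e in u5:
                by_label["UTR5"].append((tx.chrom, s, e, tx.strand))
            for s, e in u3:
                by_label["UTR3"].append((tx.chrom, s, e, tx.strand))
    by_label["vlincRNA"].extend(vlincs)

    for label in _PAINT_ORDER:
        code = _LABEL_CODE[label]
        for chrom, s, e, strand in by_label[label]:
            if chrom not in arrays:
                continue
            plus, minus = arrays[chrom]
            (plus if strand == "+" else minus)[s:e] = code
    return arrays


def editable_background_counts(
    bundle: AnnotationBundle,
    config,
) -> Dict[str, int]:
    """Count editable background positions per context label.

    An editable position is a strand-resolved adenosine (A on '+', T on '-')
    outside repeats that passes the same mappability rules the candidate
    filters apply.  This is the default background for odds-ratio enrichment;
    the published analysis does not pin down its background, so the
    definition is a documented convention.
    """
    from .filters import MAP100_TOLERANCE

    contig_lengths = {c: bundle.contig_length(c) for c in bundle.map100}
    arrays = context_label_arrays(bundle.transcripts, bundle.vlincs, contig_lengths)

    counts = {label: 0 for label in CONTEXT_LABELS}
    window = 2 * config.map_window + 1
    kernel = np.ones(window, dtype=np.float64)
    for chrom, n in sorted(contig_lengths.items()):
        seq = np.frombuffer(str(bundle.genome[chrom][:]).upper().encode(), dtype="S1")
        is_a = seq == b"A"
        is_t = seq == b"T"

        not_repeat = np.ones(n, dtype=bool)
        for rchrom, s, e, _family in bundle.repeats:
            if rchrom == chrom:
                not_repeat[s:e] = False

        ok100 = bundle.map100[chrom] >= config.map100_required - MAP100_TOLERANCE
        means = np.convolve(bundle.map24[chrom].astype(np.float64), kernel, "same") / window
        map_ok = ok100 & (means > config.map24_mean_min)

        eligible = not_repeat & map_ok
        plus_codes, minus_codes = arrays[chrom]
        for label, code in _LABEL_CODE.items():
            counts[label] += int(
                ((plus_codes == code) & is_a & eligible).sum()
                + ((minus_codes == code) & is_t & eligible).sum()
            )
    return counts
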