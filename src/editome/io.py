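"""Readers and writers for every file format the pipeline touches.

Caller-native output formats are deliberately not parsed.  Candidate calls
enter through a single normalized header-defined TSV dialect (columns
``chrom, pos, strand, editing_level, coverage``, 1-based positions); thin
conversion from each caller's native output is a one-liner outside this
package.  Standard reference formats go through the usual libraries: pyfaidx
for FASTA, gffutils for GFF3 gene models, pysam for VCF variant lists.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import (
    AnnotationBundle,
    ConsensusSite,
    DbSites,
    FormatError,
    MethodCall,
    SampleEvidence,
    SiteKey,
    Transcript,
    ValidationRecord,
)

log = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "editing_level", "coverage"]

SITE_TABLE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "methods",
    "n_samples",
    "max_level",
    "annotated",
    "context",
    "final",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_method_calls(
    path: str, sample_id: str, method_id: str
) -> Tuple[List[MethodCall], int]:
    """Read one normalized call table for one sample/method pair.

    Returns ``(calls, n_rejected)``; rows violating record invariants
    (editing level outside [0,1], negative coverage, bad strand/position) are
    dropped and counted, not fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, CALL_COLUMNS, str(path))
    calls: List[MethodCall] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            call = MethodCall(
                key=SiteKey(str(row.chrom), int(row.pos), str(row.strand)),
                sample_id=sample_id,
                method_id=method_id,
                editing_level=float(row.editing_level),
                coverage=int(row.coverage),
            ).validate()
        except Exception:
            n_rejected += 1
            continue
        calls.append(call)
    if n_rejected:
        log.warning("%s: rejected %d malformed call record(s)", path, n_rejected)
    return calls, n_rejected


def discover_call_files(calls_dir: str) -> List[Tuple[str, str, str]]:
    """List call tables named ``<sample_id>.<method_id>.tsv`` in a directory.

    Returns (path, sample_id, method_id) sorted for determinism.
    """
    out = []
    for name in sorted(os.listdir(calls_dir)):
        if not name.endswith(".tsv"):
            continue
        stem = name[: -len(".tsv")]
        sample_id, sep, method_id = stem.partition(".")
        if not sep:
            raise FormatError(
                f"call file {name!r} is not named <sample>.<method>.tsv"
            )
        out.append((os.path.join(calls_dir, name), sample_id, method_id))
    return out


# ---------------------------------------------------------------------------
# Site tables


def write_site_table(sites: Iterable[ConsensusSite], path: str) -> None:
    """Write consensus/compendium sites as a TSV, sorted by (chrom, pos, strand).

    ``max_level`` is written with ``repr`` so the read-back round-trips the
    float exactly.
    """
    rows = []
    for s in sorted(sites, key=lambda s: (s.key.chrom, s.key.pos, s.key.strand)):
        rows.append(
            {
                "chrom": s.key.chrom,
                "pos": s.key.pos,
                "strand": s.key.strand,
                "methods": ",".join(sorted(s.methods_all)),
                "n_samples": s.n_samples,
                "max_level": repr(float(s.max_level)),
                "annotated": _flag(s.annotated),
                "context": s.context if s.context is not None else ".",
                "final": _flag(s.final),
            }
        )
    df = pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def _flag(value: Optional[bool]) -> str:
    if value is None:
        return "."
    return "1" if value else "0"


def _parse_flag(text: str) -> Optional[bool]:
    if text == ".":
        return None
    return text == "1"


def read_site_table(path: str) -> List[ConsensusSite]:
    """Re-parse a site table written by :func:`write_site_table`.

    Per-sample evidence is not serialized; the read-back site carries a single
    synthetic evidence entry per sample count so that ``n_samples``,
    ``methods_all`` and ``max_level`` round-trip exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, SITE_TABLE_COLUMNS, str(path))
    sites = []
    for row in df.itertuples(index=False):
        methods = frozenset(row.methods.split(",")) if row.methods else frozenset()
        n_samples = int(row.n_samples)
        level = float(row.max_level)
        per_sample = {
            f"_sample{i}": SampleEvidence(methods=methods, level=level)
            for i in range(n_samples)
        }
        sites.append(
            ConsensusSite(
                key=SiteKey(str(row.chrom), int(row.pos), str(row.strand)).validate(),
                per_sample=per_sample,
                annotated=_parse_flag(row.annotated),
                context=None if row.context == "." else row.context,
                final=_parse_flag(row.final),
                sanger_only=(n_samples == 0),
            )
        )
    return sites


def write_bed(sites: Iterable[ConsensusSite], path: str) -> None:
    """BED6 export of a site set; score = round(1000 * max_level)."""
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.key.chrom, s.key.pos, s.key.strand)):
            fh.write(
                "\t".join(
                    [
                        s.key.chrom,
                        str(s.key.pos - 1),
                        str(s.key.pos),
                        str(s.key),
                        str(int(round(1000 * s.max_level))),
                        s.key.strand,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Validation tables


def read_validation_table(path: str) -> List[ValidationRecord]:
    """Read Sanger validation outcomes.

    Columns: chrom, pos, strand, tested_sample, rna_outcome, gdna_outcome,
    status, adjacent_new_sites (comma-joined ``chrom:pos:strand``, or ``.``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df,
        [
            "chrom",
            "pos",
            "strand",
            "tested_sample",
            "rna_outcome",
            "gdna_outcome",
            "status",
            "adjacent_new_sites",
        ],
        str(path),
    )
    records = []
    for row in df.itertuples(index=False):
        adjacent: Tuple[SiteKey, ...] = ()
        if isinstance(row.adjacent_new_sites, str) and row.adjacent_new_sites != ".":
            adjacent = tuple(
                SiteKey.parse(tok) for tok in row.adjacent_new_sites.split(",")
            )
        records.append(
            ValidationRecord(
                key=SiteKey(str(row.chrom), int(row.pos), str(row.strand)).validate(),
                tested_sample=str(row.tested_sample),
                rna_outcome=str(row.rna_outcome),
                gdna_outcome=str(row.gdna_outcome),
                status=str(row.status),
                adjacent_new_sites=adjacent,
            ).validate()
        )
    return records


def write_validation_table(records: Iterable[ValidationRecord], path: str) -> None:
    rows = []
    for r in sorted(records, key=lambda r: (r.key.chrom, r.key.pos, r.key.strand)):
        rows.append(
            {
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "strand": r.key.strand,
                "tested_sample": r.tested_sample,
                "rna_outcome": r.rna_outcome,
                "gdna_outcome": r.gdna_outcome,
                "status": r.status,
                "adjacent_new_sites": ",".join(str(k) for k in r.adjacent_new_sites)
                or ".",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "strand",
            "tested_sample",
            "rna_outcome",
            "gdna_outcome",
            "status",
            "adjacent_new_sites",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation bundle


def load_gff3_transcripts(path: str) -> List[Transcript]:
    """Parse transcript models from GFF3 via gffutils (in-memory DB).

    Transcript features of type mRNA/transcript are protein_coding (or their
    ``biotype`` attribute), lnc_RNA/lncRNA are lncRNA.  Exons and CDS are
    taken from child features; a coding transcript lacking CDS rows simply
    ends up with an empty CDS tuple (its exonic bases are later classed as
    non-coding exon).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: List[Transcript] = []
    tx_types = ("mRNA", "transcript", "lnc_RNA", "lncRNA")
    for ftype in tx_types:
        for feat in db.features_of_type(ftype):
            biotype = feat.attributes.get("biotype", [None])[0]
            if biotype is None:
                biotype = "lncRNA" if ftype in ("lnc_RNA", "lncRNA") else "protein_coding"
            exons = tuple(
                sorted(
                    (c.start - 1, c.end)
                    for c in db.children(feat, featuretype="exon")
                )
            )
            cds = tuple(
                sorted(
                    (c.start - 1, c.end)
                    for c in db.children(feat, featuretype="CDS")
                )
            )
            gene_id = feat.attributes.get("Parent", [feat.id])[0]
            span_start, span_end = feat.start - 1, feat.end
            if not exons:  # single-exon transcript written without exon rows
                exons = ((span_start, span_end),)
            tx = Transcript(
                transcript_id=feat.id,
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=span_start,
                end=span_end,
                biotype=biotype,
                exons=exons,
                cds=cds,
            )
            _check_transcript(tx)
            transcripts.append(tx)
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return transcripts


def _check_transcript(tx: Transcript) -> None:
    for s, e in tx.exons + tx.cds:
        if not (tx.start <= s < e <= tx.end):
            raise FormatError(
                f"transcript {tx.transcript_id}: sub-interval [{s},{e}) outside span"
            )
    exons = sorted(tx.exons)
    for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
        if s1 < e0:
            raise FormatError(f"transcript {tx.transcript_id}: overlapping exons")
    if exons[0][0] != tx.start or exons[-1][1] != tx.end:
        raise FormatError(
            f"transcript {tx.transcript_id}: exons+introns do not tile the span"
        )


def load_bed_intervals(
    path: str, stranded: bool = False
) -> List[Tuple[str, int, int, str]]:
    """Read BED intervals as (chrom, start, end, name-or-strand).

    For ``stranded`` sets the 4th slot is the strand (column 6); otherwise it
    is the name/family label (column 4, '.' if absent).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: interval end <= start")
            if stranded:
                if len(parts) < 6 or parts[5] not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: stranded BED needs column 6")
                out.append((chrom, start, end, parts[5]))
            else:
                name = parts[3] if len(parts) > 3 else "."
                out.append((chrom, start, end, name))
    return out


def load_bedgraph_track(
    path: str, contig_lengths: Dict[str, int]
) -> Dict[str, np.ndarray]:
    """Load a BedGraph score track into per-contig float arrays.

    Positions with no BedGraph record hold 0.0 (undefined is treated as
    non-unique; this is the conservative reading for mappability filtering).
    """
    track = {c: np.zeros(n, dtype=np.float32) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            start_i, end_i = int(start), int(end)
            if end_i <= start_i:
                raise FormatError(f"{path}:{lineno}: interval end <= start")
            if chrom not in track:
                raise FormatError(
                    f"{path}:{lineno}: contig {chrom!r} absent from genome"
                )
            arr = track[chrom]
            arr[start_i : min(end_i, len(arr))] = float(value)
    return track


def load_variants(path: str) -> frozenset:
    """Load known DNA variant positions as a strandless (chrom, pos) set.

    Accepts a VCF (.vcf) via pysam or a 2-column TSV with header
    ``chrom\\tpos`` (1-based).
    """
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        import pysam

        positions = set()
        with pysam.VariantFile(path) as vf:
            for rec in vf.fetch() if vf.index is not None else vf:
                positions.add((rec.chrom, rec.pos))
        return frozenset(positions)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int})
    _require_columns(df, ["chrom", "pos"], path)
    return frozenset(zip(df["chrom"], df["pos"].astype(int)))


def load_db_sites(path: str) -> DbSites:
    """Load the annotated editing-site database.

    TSV with columns chrom, pos and optionally strand; a '.' or missing
    strand makes the record strandless (matches either strand).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["chrom", "pos"], path)
    has_strand = "strand" in df.columns
    by_pos: Dict[Tuple[str, int], frozenset] = {}
    for row in df.itertuples(index=False):
        keypos = (str(row.chrom), int(row.pos))
        strands = set(by_pos.get(keypos, frozenset()))
        if has_strand and isinstance(row.strand, str) and row.strand in ("+", "-"):
            strands.add(row.strand)
        by_pos[keypos] = frozenset(strands)
    return DbSites(by_pos=by_pos)


def read_annotation_bundle(
    fasta: str,
    gff3: str,
    repeats_bed: str,
    vlincs_bed: str,
    variants: str,
    map100_bedgraph: str,
    map24_bedgraph: str,
    db_sites_tsv: str,
) -> AnnotationBundle:
    """Assemble the full annotation bundle, checking contig consistency.

    Any contig referenced by the GFF3 or BED inputs but absent from the FASTA
    is a hard error listing the offending contigs.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(fasta), sequence_always_upper=True)
    contig_lengths = {name: len(genome[name]) for name in genome.keys()}

    transcripts = load_gff3_transcripts(gff3)
    repeats = load_bed_intervals(repeats_bed, stranded=False)
    vlincs = load_bed_intervals(vlincs_bed, stranded=True)

    unknown = sorted(
        {t.chrom for t in transcripts}
        .union(c for c, *_ in repeats)
        .union(c for c, *_ in vlincs)
        - set(contig_lengths)
    )
    if unknown:
        raise FormatError(
            "contig(s) referenced by annotation but absent from FASTA: "
            + ", ".join(unknown)
        )

    return AnnotationBundle(
        genome=genome,
        transcripts=transcripts,
        repeats=repeats,
        vlincs=vlincs,
        variants=load_variants(variants),
        map100=load_bedgraph_track(map100_bedgraph, contig_lengths),
        map24=load_bedgraph_track(map24_bedgraph, contig_lengths),
        db_sites=load_db_sites(db_sites_tsv),
    )


BUNDLE_FILENAMES = {
    "fasta": "genome.fa",
    "gff3": "genes.gff3",
    "repeats_bed": "repeats.bed",
    "vlincs_bed": "vlincs.bed",
    "variants": "variants.tsv",
    "map100_bedgraph": "map100.bedgraph",
    "map24_bedgraph": "map24.bedgraph",
    "db_sites_tsv": "db_sites.tsv",
}


def read_bundle_dir(input_dir: str) -> AnnotationBundle:
    """Read a bundle laid out with the conventional file names
    (as written by the synthetic-data generator)."""
    paths = {k: os.path.join(input_dir, v) for k, v in BUNDLE_FILENAMES.items()}
    return read_annotation_bundle(**paths)
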