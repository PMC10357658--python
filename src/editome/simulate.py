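"""Deterministic synthetic fixture generator.

Builds a toy genome with planted gene models, repeats, vlincRNAs,
mappability tracks, a known-variant list, a truth editome and per-sample
per-method call sets that carry the statistical structure the pipeline is
designed to handle:

* a truth editome placed on editable adenosines with a configurable uracil
  preference immediately 5' of the edited base and Beta-distributed editing
  levels;
* method-specific sensitivity, so callers disagree on which truth sites they
  recover in which sample;
* singleton false positives dominated by one caller, recurrent false-positive
  hotspots seen in two or more samples, and SNP contaminants called at level
  ~0.5 by every method in every sample — including "hidden" SNPs absent from
  the emitted variant list, which survive every sequence-level filter and can
  only be caught by validation against genomic DNA;
* an annotated-site database covering half of the truth editome plus half of
  the hotspots, so the annotated stratum also contains false positives.

Everything is driven by one integer seed through three independent
``numpy.random.default_rng`` streams (truth, calls, validation), so the same
seed yields byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import annotation, io
from .model import (
    ConsensusSite,
    EditomeError,
    RED_ML,
    REDITOOLS,
    SPRINT,
    SiteKey,
    Transcript,
    ValidationRecord,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_CONTEXT_WEIGHTS: Dict[str, float] = {
    "intron": 0.66,
    "UTR3": 0.10,
    "lncRNA_exon": 0.05,
    "vlincRNA": 0.04,
    "antisense_exon": 0.04,
    "antisense_intron": 0.04,
    "intergenic": 0.04,
    "UTR5": 0.02,
    "CDS": 0.01,
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Defaults emulate the structure of a multi-sample editome survey at toy
    scale: an intron-dominated truth editome, one caller (REDItools) with an
    order of magnitude more singleton false positives than the others,
    recurrent error hotspots, and SNP contamination.
    """

    rng_seed: int = 0
    genome_length: int = 2_000_000
    n_contigs: int = 2
    n_genes: int = 60
    coding_fraction: float = 0.7
    repeat_fraction: float = 0.4
    n_vlincs: int = 8
    n_samples: int = 12
    n_true_sites: int = 400
    context_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_WEIGHTS)
    )
    p_u_minus1: float = 0.5
    level_alpha: float = 2.0
    level_beta: float = 2.0
    sensitivity: Dict[str, float] = field(
        default_factory=lambda: {REDITOOLS: 0.6, RED_ML: 0.8, SPRINT: 0.5}
    )
    singleton_fp_per_sample: Dict[str, int] = field(
        default_factory=lambda: {REDITOOLS: 300, RED_ML: 30, SPRINT: 30}
    )
    recurrent_fp_count: int = 20
    hidden_snp_count: int = 15
    known_snp_count: int = 40
    low_mappability_patch_fraction: float = 0.05
    adjacent_site_fraction: float = 0.1

    def validate(self) -> "SimConfig":
        total = sum(self.context_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise EditomeError(f"context weights must sum to 1, got {total}")
        for name in ("p_u_minus1", "coding_fraction", "repeat_fraction",
                     "low_mappability_patch_fraction", "adjacent_site_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise EditomeError(f"{name} outside [0,1]: {value}")
        for method, p in self.sensitivity.items():
            if not 0.0 <= p <= 1.0:
                raise EditomeError(f"sensitivity[{method}] outside [0,1]")
        return self


@dataclass(frozen=True)
class TruthSite:
    key: SiteKey
    context: str
    base_level: float
    u_minus1: bool


@dataclass
class SimTruth:
    """Everything the downstream generators and tests need to know about the
    planted ground truth."""

    config: SimConfig
    contig_lengths: Dict[str, int]
    truth_sites: List[TruthSite]
    hidden_snps: List[SiteKey]
    known_snps: List[SiteKey]
    hotspots: List[SiteKey]
    db_truth_keys: Set[SiteKey]
    db_hotspot_keys: Set[SiteKey]
    outdir: str

    @property
    def truth_keys(self) -> Set[SiteKey]:
        return {t.key for t in self.truth_sites}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.rng_seed, stream])


def _place_transcripts(
    config: SimConfig, contig_lengths: Dict[str, int], rng: np.random.Generator
) -> List[Transcript]:
    transcripts: List[Transcript] = []
    contigs = sorted(contig_lengths)
    per_contig = int(np.ceil(config.n_genes / len(contigs)))
    gene_idx = 0
    for chrom in contigs:
        cursor = 5_000
        limit = int(contig_lengths[chrom] * 0.45)  # leave gene-free tail for vlincs
        for _ in range(per_contig):
            if gene_idx >= config.n_genes:
                break
            n_ex = int(rng.integers(3, 8))
            exon_lens = rng.integers(150, 400, n_ex)
            intron_lens = rng.integers(500, 3000, n_ex - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span > limit:
                break
            exons = []
            p = cursor
            for i in range(n_ex):
                exons.append((p, p + int(exon_lens[i])))
                p += int(exon_lens[i])
                if i < n_ex - 1:
                    p += int(intron_lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            coding = rng.random() < config.coding_fraction
            gene_idx += 1
            tid = f"tx{gene_idx:03d}"
            cds: Tuple[Tuple[int, int], ...] = ()
            if coding:
                total_ex = int(exon_lens.sum())
                u5 = int(rng.integers(80, 200))
                u3 = int(rng.integers(200, 500))
                if total_ex - u5 - u3 < 100:
                    u5, u3 = 50, 100
                left_cut, right_cut = (u5, u3) if strand == "+" else (u3, u5)
                cds = _exonic_slice(exons, left_cut, total_ex - right_cut)
            transcripts.append(
                Transcript(
                    transcript_id=tid,
                    gene_id=f"gene{gene_idx:03d}",
                    chrom=chrom,
                    strand=strand,
                    start=exons[0][0],
                    end=exons[-1][1],
                    biotype="protein_coding" if coding else "lncRNA",
                    exons=tuple(exons),
                    cds=cds,
                )
            )
            cursor = exons[-1][1] + int(rng.integers(3_000, 12_000))
    return transcripts


def _exonic_slice(
    exons: Sequence[Tuple[int, int]], a: int, b: int
) -> Tuple[Tuple[int, int], ...]:
    """Genomic intervals covering exonic offsets [a, b) in genomic order."""
    out = []
    offset = 0
    for s, e in exons:
        length = e - s
        lo = max(a, offset)
        hi = min(b, offset + length)
        if hi > lo:
            out.append((s + lo - offset, s + hi - offset))
        offset += length
    return tuple(out)


def _place_intervals(
    rng: np.random.Generator,
    contig_lengths: Dict[str, int],
    n: int,
    length_range: Tuple[int, int],
) -> List[Tuple[str, int, int]]:
    contigs = sorted(contig_lengths)
    sizes = np.array([contig_lengths[c] for c in contigs], dtype=float)
    out = []
    picks = rng.choice(len(contigs), size=n, p=sizes / sizes.sum())
    for idx in picks:
        chrom = contigs[idx]
        length = int(rng.integers(*length_range))
        start = int(rng.integers(0, contig_lengths[chrom] - length))
        out.append((chrom, start, start + length))
    return sorted(out)


def _merge(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _write_runs(path: str, runs: Dict[str, List[Tuple[int, int, float]]]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(runs):
            for s, e, v in runs[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def _track_runs(
    contig_lengths: Dict[str, int],
    patches: Dict[str, List[Tuple[int, int]]],
    base_value: float,
    patch_value: float,
) -> Dict[str, List[Tuple[int, int, float]]]:
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    for chrom, n in sorted(contig_lengths.items()):
        cursor = 0
        out = []
        for s, e in _merge(patches.get(chrom, [])):
            if s > cursor:
                out.append((cursor, s, base_value))
            out.append((s, min(e, n), patch_value))
            cursor = min(e, n)
        if cursor < n:
            out.append((cursor, n, base_value))
        runs[chrom] = out
    return runs


def _write_gff3(transcripts: Sequence[Transcript], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in transcripts:
            ftype = "mRNA" if tx.biotype == "protein_coding" else "lnc_RNA"
            fh.write(
                f"{tx.chrom}\tsim\tgene\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.gene_id}\n"
            )
            fh.write(
                f"{tx.chrom}\tsim\t{ftype}\t{tx.start + 1}\t{tx.end}\t.\t{tx.strand}\t.\t"
                f"ID={tx.transcript_id};Parent={tx.gene_id};biotype={tx.biotype}\n"
            )
            for i, (s, e) in enumerate(tx.exons, 1):
                fh.write(
                    f"{tx.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}\n"
                )
            for i, (s, e) in enumerate(tx.cds, 1):
                fh.write(
                    f"{tx.chrom}\tsim\tCDS\t{s + 1}\t{e}\t0\t{tx.strand}\t0\t"
                    f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}\n"
                )


def _write_fasta(seqs: Dict[str, np.ndarray], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seqs):
            fh.write(f">{chrom}\n")
            text = seqs[chrom].tobytes().decode()
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def generate_truth(config: SimConfig, outdir: str) -> SimTruth:
    """Generate the annotation bundle files and the planted truth editome.

    By construction every truth site's strand base is A, no truth site (or
    SNP contaminant, or hotspot) overlaps a repeat or a low-mappability
    patch, and the base immediately 5' of each truth site is uracil with
    probability ``p_u_minus1``.
    """
    config.validate()
    rng = _rng(config, 0)
    os.makedirs(outdir, exist_ok=True)

    per_contig = config.genome_length // config.n_contigs
    contig_lengths = {f"chr{i + 1}": per_contig for i in range(config.n_contigs)}
    seqs = {
        chrom: BASES[rng.integers(0, 4, size=n)].copy()
        for chrom, n in sorted(contig_lengths.items())
    }

    transcripts = _place_transcripts(config, contig_lengths, rng)

    # vlincRNAs in the gene-free tail of each contig
    vlincs: List[Tuple[str, int, int, str]] = []
    contigs = sorted(contig_lengths)
    tail_cursor = {c: int(contig_lengths[c] * 0.5) for c in contigs}
    for i in range(config.n_vlincs):
        chrom = contigs[i % len(contigs)]
        start = tail_cursor[chrom]
        available = contig_lengths[chrom] - 1_000 - start
        if available < 5_000:
            continue
        length = min(int(rng.integers(30_000, 80_000)), available)
        strand = "+" if rng.random() < 0.5 else "-"
        vlincs.append((chrom, start, start + length, strand))
        tail_cursor[chrom] = start + length + int(rng.integers(5_000, 15_000))
    vlincs.sort()

    n_repeats = int(config.repeat_fraction * config.genome_length / 300)
    repeat_spans = _place_intervals(rng, contig_lengths, n_repeats, (250, 350))
    families = rng.random(len(repeat_spans)) < 0.5
    repeats = [
        (c, s, e, "AluY" if alu else "L1")
        for (c, s, e), alu in zip(repeat_spans, families)
    ]

    n_patches = int(
        config.low_mappability_patch_fraction * config.genome_length / 2_000
    )
    patch_spans = _place_intervals(rng, contig_lengths, n_patches, (1_500, 2_500))
    patches: Dict[str, List[Tuple[int, int]]] = {}
    for c, s, e in patch_spans:
        patches.setdefault(c, []).append((s, e))

    # eligibility masks: outside repeats, outside low-mappability patches
    # (including the +/- window margin so window means stay above 0.5)
    clean = {c: np.ones(n, dtype=bool) for c, n in contig_lengths.items()}
    for c, s, e, _f in repeats:
        clean[c][s:e] = False
    margin = 160
    for c, spans in patches.items():
        for s, e in spans:
            clean[c][max(0, s - margin) : e + margin] = False
    for c, n in contig_lengths.items():
        clean[c][:margin] = False
        clean[c][n - margin :] = False

    label_arrays = annotation.context_label_arrays(transcripts, vlincs, contig_lengths)

    # candidate (chrom, pos0, strand) pools per context, and a pooled clean set
    code_of = {label: i for i, label in enumerate(annotation.CONTEXT_LABELS)}
    candidates: Dict[str, List[Tuple[str, int, str]]] = {
        label: [] for label in config.context_weights
    }
    clean_pool: List[Tuple[str, int, str]] = []
    for chrom in contigs:
        plus_codes, minus_codes = label_arrays[chrom]
        is_a = seqs[chrom] == b"A"
        is_t = seqs[chrom] == b"T"
        ok = clean[chrom]
        for label in config.context_weights:
            code = code_of[label]
            for pos0 in np.flatnonzero((plus_codes == code) & is_a & ok):
                candidates[label].append((chrom, int(pos0), "+"))
            for pos0 in np.flatnonzero((minus_codes == code) & is_t & ok):
                candidates[label].append((chrom, int(pos0), "-"))
        for pos0 in np.flatnonzero(is_a & ok):
            clean_pool.append((chrom, int(pos0), "+"))
        for pos0 in np.flatnonzero(is_t & ok):
            clean_pool.append((chrom, int(pos0), "-"))

    # largest-remainder apportionment of truth sites across contexts
    labels = sorted(config.context_weights)
    raw = {label: config.context_weights[label] * config.n_true_sites for label in labels}
    counts = {label: int(raw[label]) for label in labels}
    shortfall = config.n_true_sites - sum(counts.values())
    for label in sorted(labels, key=lambda l: raw[l] - counts[l], reverse=True)[:shortfall]:
        counts[label] += 1

    picked: List[Tuple[str, int, str, str]] = []
    for label in labels:
        if counts[label] == 0:
            continue
        pool = candidates[label]
        if len(pool) < counts[label]:
            raise EditomeError(
                f"cannot place {counts[label]} truth sites in context {label!r}: "
                f"only {len(pool)} editable candidate positions"
            )
        for idx in rng.choice(len(pool), size=counts[label], replace=False):
            chrom, pos0, strand = pool[idx]
            picked.append((chrom, pos0, strand, label))

    # enforce a minimum spacing so -1 mutations and motif windows cannot collide
    picked.sort()
    spaced: List[Tuple[str, int, str, str]] = []
    last: Dict[str, int] = {}
    for chrom, pos0, strand, label in picked:
        if chrom in last and pos0 - last[chrom] < 12:
            continue
        spaced.append((chrom, pos0, strand, label))
        last[chrom] = pos0

    truth_sites: List[TruthSite] = []
    occupied: Set[Tuple[str, int]] = set()
    for chrom, pos0, strand, label in spaced:
        u_minus1 = bool(rng.random() < config.p_u_minus1)
        if strand == "+":
            neighbor = pos0 - 1
            seqs[chrom][neighbor] = b"T" if u_minus1 else BASES[
                rng.choice([0, 1, 2])  # A, C or G: anything but T
            ]
        else:
            neighbor = pos0 + 1
            # on '-' the 5' neighbour is genomic pos0+1; minus-strand U means
            # genomic A there
            seqs[chrom][neighbor] = b"A" if u_minus1 else BASES[
                rng.choice([1, 2, 3])  # C, G or T: anything but A
            ]
        base_level = float(rng.beta(config.level_alpha, config.level_beta))
        truth_sites.append(
            TruthSite(
                key=SiteKey(chrom, pos0 + 1, strand),
                context=label,
                base_level=base_level,
                u_minus1=u_minus1,
            )
        )
        occupied.add((chrom, pos0))
        occupied.add((chrom, neighbor))

    def sample_clean(n: int) -> List[SiteKey]:
        out: List[SiteKey] = []
        taken: Set[int] = set()
        while len(out) < n:
            idx = int(rng.integers(0, len(clean_pool)))
            if idx in taken:
                continue
            chrom, pos0, strand = clean_pool[idx]
            if (chrom, pos0) in occupied:
                continue
            # re-check the strand base: a -1 mutation may have changed it
            base = seqs[chrom][pos0]
            if (strand == "+" and base != b"A") or (strand == "-" and base != b"T"):
                continue
            taken.add(idx)
            occupied.add((chrom, pos0))
            out.append(SiteKey(chrom, pos0 + 1, strand))
        return out

    hidden_snps = sample_clean(config.hidden_snp_count)
    known_snps = sample_clean(config.known_snp_count)
    hotspots = sample_clean(config.recurrent_fp_count)

    # annotated-site database: half of truth plus half of the hotspots
    n_db_truth = len(truth_sites) // 2
    db_truth_idx = rng.choice(len(truth_sites), size=n_db_truth, replace=False)
    db_truth_keys = {truth_sites[i].key for i in db_truth_idx}
    n_db_hot = len(hotspots) // 2
    db_hot_idx = rng.choice(len(hotspots), size=n_db_hot, replace=False)
    db_hotspot_keys = {hotspots[i] for i in db_hot_idx}

    # ---- write all files
    _write_fasta(seqs, os.path.join(outdir, "genome.fa"))
    _write_gff3(transcripts, os.path.join(outdir, "genes.gff3"))
    with open(os.path.join(outdir, "repeats.bed"), "w") as fh:
        for c, s, e, fam in repeats:
            fh.write(f"{c}\t{s}\t{e}\t{fam}\n")
    with open(os.path.join(outdir, "vlincs.bed"), "w") as fh:
        for i, (c, s, e, strand) in enumerate(vlincs, 1):
            fh.write(f"{c}\t{s}\t{e}\tvlinc{i}\t0\t{strand}\n")
    _write_runs(
        os.path.join(outdir, "map100.bedgraph"),
        _track_runs(contig_lengths, patches, 1.0, 0.0),
    )
    _write_runs(
        os.path.join(outdir, "map24.bedgraph"),
        _track_runs(contig_lengths, patches, 0.9, 0.15),
    )
    with open(os.path.join(outdir, "variants.tsv"), "w") as fh:
        fh.write("chrom\tpos\n")
        for key in sorted(known_snps):
            fh.write(f"{key.chrom}\t{key.pos}\n")
    with open(os.path.join(outdir, "db_sites.tsv"), "w") as fh:
        fh.write("chrom\tpos\tstrand\n")
        for key in sorted(db_truth_keys | db_hotspot_keys):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.strand}\n")
    with open(os.path.join(outdir, "truth_sites.tsv"), "w") as fh:
        fh.write("chrom\tpos\tstrand\tcontext\tbase_level\tu_minus1\n")
        for t in sorted(truth_sites, key=lambda t: t.key):
            fh.write(
                f"{t.key.chrom}\t{t.key.pos}\t{t.key.strand}\t{t.context}\t"
                f"{t.base_level!r}\t{int(t.u_minus1)}\n"
            )

    return SimTruth(
        config=config,
        contig_lengths=contig_lengths,
        truth_sites=truth_sites,
        hidden_snps=hidden_snps,
        known_snps=known_snps,
        hotspots=hotspots,
        db_truth_keys=db_truth_keys,
        db_hotspot_keys=db_hotspot_keys,
        outdir=outdir,
    )


def generate_method_calls(sim: SimTruth, calls_dir: Optional[str] = None) -> Dict[str, int]:
    """Emit per-sample per-method call tables under ``<outdir>/calls/``.

    Returns per-method counts of emitted truth-site observations (used for
    sensitivity-recovery checks).  Levels for truth sites are the site's base
    level plus per-observation noise; SNP contaminants are emitted by every
    method in every sample at level ~0.5.
    """
    config = sim.config
    rng = _rng(config, 1)
    calls_dir = calls_dir or os.path.join(sim.outdir, "calls")
    os.makedirs(calls_dir, exist_ok=True)
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    methods = sorted(config.sensitivity)

    # rows[(sample, method)] = {key: (level, coverage)}
    rows: Dict[Tuple[str, str], Dict[SiteKey, Tuple[float, int]]] = {
        (s, m): {} for s in samples for m in methods
    }

    def emit(sample: str, method: str, key: SiteKey, level: float) -> None:
        coverage = int(rng.poisson(30) + 5)
        rows[(sample, method)][key] = (float(np.clip(level, 0.01, 0.99)), coverage)

    truth_emitted = {m: 0 for m in methods}
    for t in sim.truth_sites:
        for sample in samples:
            for method in methods:
                if rng.random() < config.sensitivity[method]:
                    truth_emitted[method] += 1
                    emit(sample, method, t.key, t.base_level + rng.normal(0, 0.05))

    # recurrent false-positive hotspots: >= 2 samples each, method mix that
    # lets some survive the final decision rules
    for key in sim.hotspots:
        k = int(rng.integers(2, min(6, config.n_samples + 1)))
        chosen = rng.choice(len(samples), size=k, replace=False)
        u = rng.random()
        if u < 0.4:
            hot_methods = [REDITOOLS]
        elif u < 0.7:
            hot_methods = [RED_ML]
        elif u < 0.85:
            hot_methods = [SPRINT]
        else:
            hot_methods = [RED_ML, SPRINT]
        base = float(rng.beta(2, 2))
        for idx in chosen:
            for method in hot_methods:
                if method in methods:
                    emit(samples[idx], method, key, base + rng.normal(0, 0.05))

    # SNP contaminants (listed and hidden): every method, every sample, ~0.5
    for key in sim.known_snps + sim.hidden_snps:
        for sample in samples:
            for method in methods:
                emit(sample, method, key, rng.normal(0.5, 0.05))

    # singleton false positives at random editable positions anywhere in the
    # genome (including repeats and low-mappability patches)
    reserved = (
        sim.truth_keys
        | set(sim.hidden_snps)
        | set(sim.known_snps)
        | set(sim.hotspots)
    )
    contigs = sorted(sim.contig_lengths)
    for sample in samples:
        for method in methods:
            n_fp = config.singleton_fp_per_sample.get(method, 0)
            emitted = 0
            while emitted < n_fp:
                chrom = contigs[int(rng.integers(0, len(contigs)))]
                pos0 = int(rng.integers(5, sim.contig_lengths[chrom] - 5))
                strand = "+" if rng.random() < 0.5 else "-"
                key = SiteKey(chrom, pos0 + 1, strand)
                if key in reserved or key in rows[(sample, method)]:
                    continue
                emit(sample, method, key, rng.beta(1, 4))
                emitted += 1

    for (sample, method), calls in rows.items():
        path = os.path.join(calls_dir, f"{sample}.{method}.tsv")
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tstrand\tediting_level\tcoverage\n")
            for key in sorted(calls):
                level, coverage = calls[key]
                fh.write(
                    f"{key.chrom}\t{key.pos}\t{key.strand}\t{level!r}\t{coverage}\n"
                )
    return truth_emitted


def generate_validation_outcomes(
    final_sites: Sequence[ConsensusSite],
    sim: SimTruth,
    path: Optional[str] = None,
    genome=None,
) -> List[ValidationRecord]:
    """Emit Sanger validation outcomes for the pipeline's final sites.

    Truth sites validate; hidden-SNP contaminants show a genomic-DNA variant
    (status ``sequence_variant``); everything else fails.  A configurable
    fraction of validated sites yields one adjacent Sanger-only discovery at
    a nearby editable adenosine.
    """
    config = sim.config
    rng = _rng(config, 2)
    truth_keys = sim.truth_keys
    hidden = set(sim.hidden_snps)
    if genome is None:
        from pyfaidx import Fasta

        genome = Fasta(os.path.join(sim.outdir, "genome.fa"), sequence_always_upper=True)

    taken = {s.key for s in final_sites}
    records: List[ValidationRecord] = []
    for site in sorted(
        (s for s in final_sites if not s.sanger_only),
        key=lambda s: (s.key.chrom, s.key.pos, s.key.strand),
    ):
        sample = sorted(site.per_sample)[0] if site.per_sample else "S01"
        if site.key in truth_keys:
            adjacent: Tuple[SiteKey, ...] = ()
            if rng.random() < config.adjacent_site_fraction:
                neighbor = _find_adjacent(site.key, genome, sim, taken)
                if neighbor is not None:
                    adjacent = (neighbor,)
                    taken.add(neighbor)
            records.append(
                ValidationRecord(
                    key=site.key,
                    tested_sample=sample,
                    rna_outcome="edited",
                    gdna_outcome="homozygous_reference",
                    status="validated",
                    adjacent_new_sites=adjacent,
                )
            )
        elif site.key in hidden:
            records.append(
                ValidationRecord(
                    key=site.key,
                    tested_sample=sample,
                    rna_outcome="edited",
                    gdna_outcome="variant",
                    status="sequence_variant",
                )
            )
        else:
            records.append(
                ValidationRecord(
                    key=site.key,
                    tested_sample=sample,
                    rna_outcome="not_detected",
                    gdna_outcome="not_tested",
                    status="failed",
                )
            )
    if path is None:
        path = os.path.join(sim.outdir, "validation.tsv")
    io.write_validation_table(records, path)
    return records


def _find_adjacent(
    key: SiteKey, genome, sim: SimTruth, taken: Set[SiteKey]
) -> Optional[SiteKey]:
    """A nearby same-strand editable A not colliding with anything known."""
    db = sim.db_truth_keys | sim.db_hotspot_keys
    variants = {(k.chrom, k.pos) for k in sim.known_snps}
    want = "A" if key.strand == "+" else "T"
    contig = genome[key.chrom]
    for delta in (3, -3, 4, -4, 5, -5, 6, -6, 7, -7):
        pos = key.pos + delta
        if pos < 2 or pos > len(contig) - 1:
            continue
        candidate = SiteKey(key.chrom, pos, key.strand)
        if candidate in taken or candidate in db or candidate in sim.truth_keys:
            continue
        if (candidate.chrom, candidate.pos) in variants:
            continue
        if str(contig[pos - 1 : pos]).upper() == want:
            return candidate
    return None
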