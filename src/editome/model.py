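"""Core domain types for the editome-construction pipeline.

A candidate A-to-I editing site is identified by its genomic position and the
strand on which the edited base is an adenosine.  Inosine is read as guanosine
by sequencers, so a site on '+' appears as an A->G change on the forward strand
and a site on '-' as a T->C change.  Per-sample, per-caller observations of
such sites are merged into consensus sites, filtered, annotated with a genomic
context, and reduced to a final high-confidence compendium.

Coordinate conventions: site positions (``SiteKey.pos``) are 1-based, matching
the caller-output and table dialects.  All interval sets held by
:class:`AnnotationBundle` are 0-based half-open internally; a site at 1-based
``pos`` occupies internal offset ``pos - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

# Caller identifiers.  The three core methods participate in consensus
# decisions; HPC-REDItools evidence is carried through but treated as
# auxiliary (its exclusive sites are not used for decisions).
REDITOOLS = "REDItools"
RED_ML = "RED-ML"
SPRINT = "SPRINT"
HPC_REDITOOLS = "HPC-REDItools"

CORE_METHODS: FrozenSet[str] = frozenset({REDITOOLS, RED_ML, SPRINT})
ALL_METHODS: FrozenSet[str] = CORE_METHODS | {HPC_REDITOOLS}

STRANDS = ("+", "-")

# Mutually exclusive genomic-context labels, listed in decreasing precedence
# for classification (a site in a same-strand CDS that also lies in a vlincRNA
# is labelled CDS).
CONTEXT_LABELS = (
    "CDS",
    "UTR5",
    "UTR3",
    "lncRNA_exon",
    "intron",
    "vlincRNA",
    "antisense_exon",
    "antisense_intron",
    "intergenic",
)


class EditomeError(Exception):
    """Base class for pipeline errors."""


class FormatError(EditomeError):
    """A malformed or incomplete input file."""


class ContractViolation(EditomeError):
    """An operation was invoked outside its stated preconditions."""


class SiteKey(NamedTuple):
    """Identity of one candidate editing site.

    ``pos`` is the 1-based coordinate of the edited adenosine; ``strand`` is
    the strand on which the reference base is A.
    """

    chrom: str
    pos: int
    strand: str

    def validate(self) -> "SiteKey":
        if self.pos < 1:
            raise ContractViolation(f"site position must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ContractViolation(f"strand must be '+' or '-', got {self.strand!r}")
        return self

    def __str__(self) -> str:  # chrom:pos:strand, used in tables and messages
        return f"{self.chrom}:{self.pos}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "SiteKey":
        chrom, pos, strand = text.rsplit(":", 2)
        return cls(chrom, int(pos), strand).validate()


@dataclass(frozen=True)
class MethodCall:
    """One candidate editing observation: site x sample x caller."""

    key: SiteKey
    sample_id: str
    method_id: str
    editing_level: float
    coverage: int

    def validate(self) -> "MethodCall":
        self.key.validate()
        if not 0.0 <= self.editing_level <= 1.0:
            raise ContractViolation(
                f"editing level outside [0,1] at {self.key}: {self.editing_level}"
            )
        if self.coverage < 0:
            raise ContractViolation(f"negative coverage at {self.key}")
        if self.method_id not in ALL_METHODS:
            raise ContractViolation(f"unknown method {self.method_id!r}")
        return self


@dataclass(frozen=True)
class SampleEvidence:
    """Evidence for one site within one sample: calling methods and the
    aggregated (mean across methods) editing level."""

    methods: FrozenSet[str]
    level: float


@dataclass
class ConsensusSite:
    """A site merged across samples and methods.

    ``methods`` (decision methods) is the union of per-sample method sets
    restricted to the three core callers; ``methods_all`` additionally carries
    auxiliary HPC-REDItools evidence.  ``sanger_only`` marks sites added from
    validation electropherograms with no RNA-seq call evidence.
    """

    key: SiteKey
    per_sample: Dict[str, SampleEvidence] = field(default_factory=dict)
    annotated: Optional[bool] = None
    context: Optional[str] = None
    final: Optional[bool] = None
    sanger_only: bool = False

    @property
    def methods_all(self) -> FrozenSet[str]:
        out: set = set()
        for ev in self.per_sample.values():
            out |= ev.methods
        return frozenset(out)

    @property
    def methods(self) -> FrozenSet[str]:
        return self.methods_all & CORE_METHODS

    @property
    def n_samples(self) -> int:
        return len(self.per_sample)

    @property
    def max_level(self) -> float:
        if not self.per_sample:
            return 0.0
        return max(ev.level for ev in self.per_sample.values())


@dataclass(frozen=True)
class ValidationRecord:
    """Outcome of Sanger validation of one site in one RNA sample.

    A site is ``validated`` when the RNA trace shows an A/G mixture and the
    genomic DNA is homozygous reference; a ``sequence_variant`` is an apparent
    edit explained by a DNA variant (the hidden-SNP failure mode).
    ``adjacent_new_sites`` lists previously unknown sites read directly off
    the electropherogram next to the tested site.
    """

    key: SiteKey
    tested_sample: str
    rna_outcome: str  # {edited, not_detected}
    gdna_outcome: str  # {homozygous_reference, variant, not_tested}
    status: str  # {validated, failed, sequence_variant}
    adjacent_new_sites: Tuple[SiteKey, ...] = ()

    def validate(self) -> "ValidationRecord":
        if self.rna_outcome not in {"edited", "not_detected"}:
            raise ContractViolation(f"bad rna_outcome {self.rna_outcome!r}")
        if self.gdna_outcome not in {"homozygous_reference", "variant", "not_tested"}:
            raise ContractViolation(f"bad gdna_outcome {self.gdna_outcome!r}")
        if self.status not in {"validated", "failed", "sequence_variant"}:
            raise ContractViolation(f"bad status {self.status!r}")
        is_validated = (
            self.rna_outcome == "edited"
            and self.gdna_outcome == "homozygous_reference"
        )
        if (self.status == "validated") != is_validated:
            raise ContractViolation(
                f"status 'validated' inconsistent with outcomes at {self.key}"
            )
        if (self.status == "sequence_variant") != (self.gdna_outcome == "variant"):
            raise ContractViolation(
                f"status 'sequence_variant' inconsistent with gDNA outcome at {self.key}"
            )
        return self


@dataclass
class PipelineConfig:
    """Tunable thresholds of the pipeline.

    Defaults reproduce the published rules: sites are retained when the
    maximum per-sample aggregated editing level is strictly above 0.2 and the
    site is seen in at least two samples; mappability filtering requires a
    100mer alignability of exactly 1 at the site and a mean 24mer alignability
    strictly above 0.5 over a +/-150 bp window.
    """

    level_threshold: float = 0.2
    min_samples: int = 2
    map_window: int = 150
    map100_required: float = 1.0
    map24_mean_min: float = 0.5
    motif_halfwidth: int = 5
    rng_seed: int = 0


@dataclass(frozen=True)
class Transcript:
    """A transcript model with 0-based half-open sub-intervals.

    ``exons`` tile the span together with the derived introns; ``cds`` is
    empty for non-coding transcripts (and for coding transcripts lacking
    annotated CDS, whose exonic bases are then classed as non-coding exon).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str  # protein_coding | lncRNA
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...] = ()

    def introns(self) -> Tuple[Tuple[int, int], ...]:
        out = []
        exons = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return tuple(out)

    def utr_intervals(self) -> Tuple[Tuple[Tuple[int, int], ...], Tuple[Tuple[int, int], ...]]:
        """(UTR5 intervals, UTR3 intervals) derived from the CDS extent.

        Exonic bases upstream of the CDS in transcript orientation are 5' UTR,
        downstream are 3' UTR.  Empty for transcripts without CDS.
        """
        if not self.cds:
            return (), ()
        cds_lo = min(s for s, _ in self.cds)
        cds_hi = max(e for _, e in self.cds)
        left, right = [], []
        for s, e in sorted(self.exons):
            if s < cds_lo:
                left.append((s, min(e, cds_lo)))
            if e > cds_hi:
                right.append((max(s, cds_hi), e))
        if self.strand == "+":
            return tuple(left), tuple(right)
        return tuple(right), tuple(left)


@dataclass
class DbSites:
    """Annotated editing-site database: (chrom, pos) -> strands.

    An empty strand set means the record is strandless and matches a query on
    either strand (source databases differ in whether they report strand).
    """

    by_pos: Dict[Tuple[str, int], FrozenSet[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.by_pos)

    def contains(self, key: SiteKey) -> bool:
        strands = self.by_pos.get((key.chrom, key.pos))
        if strands is None:
            return False
        return not strands or key.strand in strands


@dataclass
class AnnotationBundle:
    """All reference inputs the pipeline consults.

    ``map100`` / ``map24`` are per-contig float arrays covering the contig;
    positions without a track record hold 0 (treated as non-unique, which is
    the conservative reading).  ``variants`` holds 1-based strandless
    positions of known DNA variants.
    """

    genome: object  # mapping chrom -> sequence with __getitem__/len semantics
    transcripts: List[Transcript]
    repeats: List[Tuple[str, int, int, str]]  # chrom, start, end, family
    vlincs: List[Tuple[str, int, int, str]]  # chrom, start, end, strand
    variants: frozenset  # of (chrom, pos) 1-based
    map100: Dict[str, np.ndarray]
    map24: Dict[str, np.ndarray]
    db_sites: DbSites

    def contig_length(self, chrom: str) -> int:
        return len(self.genome[chrom])


@dataclass
class FilterReport:
    """Tallies of the fixed-order pre-consensus filters
    (variants -> repeats -> mappability)."""

    n_input: int
    n_removed_variant: int
    n_removed_repeat: int
    repeat_alu_fraction: float
    n_removed_mappability: int
    n_pass: int

    def check(self) -> "FilterReport":
        total = (
            self.n_removed_variant
            + self.n_removed_repeat
            + self.n_removed_mappability
            + self.n_pass
        )
        if total != self.n_input:
            raise ContractViolation(
                f"filter tallies not conserved: {total} != {self.n_input}"
            )
        return self

    def as_dict(self) -> Dict[str, float]:
        return {
            "n_input": self.n_input,
            "n_removed_variant": self.n_removed_variant,
            "n_removed_repeat": self.n_removed_repeat,
            "repeat_alu_fraction": self.repeat_alu_fraction,
            "n_removed_mappability": self.n_removed_mappability,
            "n_pass": self.n_pass,
        }


@dataclass
class Stratum:
    """A group of sites for weighted validation-ratio arithmetic.

    ``population`` is the number of sites the stratum represents, ``tested``
    the number subjected to Sanger validation and ``positive`` the number
    confirmed.
    """

    label: str
    population: int
    tested: int
    positive: int

    def validate(self) -> "Stratum":
        if not 0 <= self.positive <= self.tested:
            raise ContractViolation(
                f"stratum {self.label!r}: need 0 <= positive <= tested"
            )
        if self.population < 0:
            raise ContractViolation(f"stratum {self.label!r}: negative population")
        return self

    @property
    def ratio(self) -> float:
        if self.tested == 0:
            raise ContractViolation(
                f"stratum {self.label!r} has tested = 0; ratio undefined"
            )
        return self.positive / self.tested


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 odds ratio for one genomic element: sites in/out of the element
    against background editable positions in/out of it."""

    element: str
    a: int  # sites in element
    b: int  # sites outside
    c: int  # background positions in element
    d: int  # background positions outside
    odds_ratio: float
    defined: bool = True


MOTIF_BASES = "ACGU"


@dataclass
class MotifProfile:
    """Per-position base fractions around edited adenosines.

    ``fractions`` has shape (2*halfwidth + 1, 4) over bases A, C, G, U in
    site-strand orientation; position index ``halfwidth`` is the edited base
    itself (always A).  ``n`` is the number of sequences profiled.
    """

    halfwidth: int
    fractions: np.ndarray
    n: int
    n_skipped_flank: int = 0
    n_non_adenosine: int = 0

    @property
    def positions(self) -> List[int]:
        return list(range(-self.halfwidth, self.halfwidth + 1))

    def fraction(self, offset: int, base: str) -> float:
        return float(
            self.fractions[offset + self.halfwidth, MOTIF_BASES.index(base)]
        )


@dataclass
class CompendiumResult:
    """Outcome of the final decision rules."""

    final_annotated: List[ConsensusSite]
    final_unannotated: List[ConsensusSite]
    excluded: Dict[SiteKey, str]
    sanger_added: List[ConsensusSite]

    @property
    def final_sites(self) -> List[ConsensusSite]:
        return self.final_annotated + self.final_unannotated
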