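# Methods

This note records the modelling assumptions, conventions and parameter
choices behind `editome`, in the spirit of a methods supplement: what the
pipeline computes, why the defaults are what they are, what the synthetic
benchmark does and does not emulate, and where genuinely open design choices
were resolved by convention.

## Site identity and coordinates

A site is `(chrom, pos, strand)` with `pos` 1-based and `strand` the strand
on which the reference base is adenosine. On `-`, the forward-strand base is
T and the observed forward-strand change is T→C. All user-facing tables and
the normalized call dialect are 1-based (VCF convention); interval sets are
held 0-based half-open internally, so a site at `pos` occupies internal
offset `pos − 1`. Round-tripping 1-based → internal → 1-based is the
identity and is tested.

Caller-native outputs are deliberately not parsed. The three upstream
callers emit mutually incompatible formats; a five-column TSV
(`chrom, pos, strand, editing_level, coverage`) is the single ingestion
dialect, and converting any caller's output to it is a one-line `awk`/pandas
job outside this package. Rows violating record invariants (level outside
[0,1], negative coverage) are dropped and counted rather than aborting the
ingest, because one corrupt row in a 130-sample ingest should not kill a run;
a missing *column* is a format error and fatal.

## Filters

Order is fixed — variants, repeats, mappability — and each input call is
assigned to exactly one bin, so the filter report tallies are conserved by
construction.

* **Variants.** Matching is strandless by position: a DNA variant affects
  both strands (dbSNP semantics).
* **Repeats.** Strandless interval overlap; repeat masking has no strand.
  The fraction of removed calls lying in Alu elements is reported, since Alu
  editing is the dominant repeat-associated signal and its share is a useful
  sanity check on inputs.
* **Mappability.** A call passes iff the 100mer alignability at its position
  equals 1 and the mean 24mer alignability over the inclusive ±150 bp window
  (301 positions) is strictly greater than 0.5. Three conventions here are
  ours, adopted once and documented: (1) "equals 1" is tested as
  ≥ 1 − 10⁻⁹ because BedGraph round-trips floats through text; (2) track
  positions with no BedGraph record score 0 — requiring *demonstrated*
  uniqueness is the conservative reading; (3) at contig ends the window is
  not renormalized: out-of-contig slots contribute 0 to a fixed 301-slot
  denominator, penalizing edge sites rather than favouring them. Whether the
  ±150 bp window includes the site position itself is not externally
  specified; the inclusive 301-position window is the adopted convention.

## Consensus

Within one sample, the editing level of a site detected by several callers
is the arithmetic mean of the per-caller levels. Retention requires the
maximum per-sample aggregated level to be **strictly** above 0.2 and
detection in at least two samples. The threshold is applied to the
aggregated level, not to any single caller's raw level: aggregation
precedes thresholding. A site found by RED-ML in one sample and SPRINT in
another counts as found by both methods, even if only one of those
observations clears the level threshold — method attribution is the union
of per-sample method sets.

HPC-REDItools evidence, when ingested, contributes to per-sample levels,
sample counts and exports, but is excluded from every method-combination
decision; its method-exclusive calls are not trusted. A site whose only
evidence is HPC-REDItools is labelled `auxiliary-only` by the
method-specificity classifier (the standard label set — X-specific /
multi-method — has no value for an empty core-method set) and is excluded
from the final compendium with reason `hpc_only`.

## Genomic context

Sense context labels require the site and feature strands to match;
antisense labels require overlap on the opposite strand only. Because real
annotations overlap heavily, each site receives exactly one label through a
fixed precedence: CDS > 5′UTR > 3′UTR > lncRNA exon > intron > vlincRNA >
antisense exon > antisense intron > intergenic. Two consequences worth
stating: a position exonic in one transcript and intronic in another is
labelled exonic (mature-mRNA impact is the analytically interesting case);
and an intronic site inside a same-strand vlincRNA is labelled intron, so
the vlincRNA class holds only sites not explainable by annotated-gene
transcription. The precedence order itself is a convention of this package
— pie-chart-style mutually exclusive categories force *some* deterministic
rule — and is exercised exhaustively in tests. The CDS/UTR partition comes
from GFF3 CDS features; exonic bases of coding transcripts without CDS rows
are classed as non-coding exon. Database matching ignores strand when the
database record is strandless, because the public editing databases differ
in whether they report strand.

Context classification is implemented twice on purpose: per-site interval
queries (the production path) and whole-genome label painting (used for
enrichment backgrounds); their agreement is a tested invariant.

## Final decision rules

Annotated sites are kept iff supported by RED-ML or SPRINT — equivalently,
REDItools-only sites are excluded (their validation ratio is 0). Unannotated
sites always require RED-ML, and outside introns and vlincRNAs additionally
SPRINT. We read "reliably callable by RED-ML alone in introns/vlincRNAs" as
*requiring* RED-ML in those branches rather than accepting any single
caller, because SPRINT-only sites validate at 0% and REDItools-only sites
barely above it; this is the conservative resolution of an ambiguity.
Sanger-adjacent discoveries are merged into the unannotated compendium as
`sanger_only` sites unless already present, already database-annotated, or
colliding with a known variant position (rejected with a warning).

## Statistics

* **Weighted validation ratio.** Σ N_g·(p_g/t_g) / Σ N_g over strata with
  population N_g, tested t_g, positive p_g. Equivalent to assigning every
  population member its stratum's observed ratio and averaging; this
  equivalence is the test oracle. Strata with t_g = 0 are contract
  violations, named in the error.
* **Minimal false fraction.** Two arms (tested and untested populations with
  fail rates); expected failures are rounded to the nearest integer per arm
  before summing, since such estimates are quoted on whole-site counts. The
  arms accept either a stratum (fail rate 1 − p/t) or a (population, rate)
  pair, because quoted rates are typically percentages already rounded to
  one decimal and re-deriving them from pseudo-counts would be dishonest.
* **Enrichment.** Odds ratio (a·d)/(b·c) per element; zero denominators are
  flagged, not raised. The default background is the set of strand-resolved
  adenosines (A on `+`, T on `-`) outside repeats that pass the same
  mappability rules as candidate calls — i.e. the positions at which the
  pipeline *could* have called a site. No external definition of the
  background exists for this statistic; this editable-position background is
  our documented convention and the background counts are a plain argument,
  so callers can substitute expressed-position or whole-genome backgrounds.
* **Motif profile.** Base fractions over ±5 bp in site-strand orientation,
  RNA alphabet (T reported as U); position 0 is the edited base and must be
  A — non-A sites are excluded and counted, as they indicate upstream
  corruption. Sites with flanks running off the contig are skipped with a
  warning. Profile differences subtract fraction matrices; per position the
  four base differences sum to zero.

## The synthetic benchmark

The generator builds, from one integer seed (three independent
`numpy.random.default_rng` streams for truth, calls and validation — same
seed, byte-identical files):

* a 2 Mb two-contig genome with 60 non-overlapping gene models (70 %
  coding, 3–7 exons each), 8 vlincRNAs in the gene-free contig tails,
  ~40 % repeat coverage (half Alu-labelled), and 5 % low-mappability
  patches reflected in both alignability tracks;
* 400 truth sites placed on editable adenosines with context weights
  dominated by introns (0.66, with 3′UTR 0.10, lncRNA exon 0.05, vlincRNA /
  antisense exon / antisense intron / intergenic 0.04 each, 5′UTR 0.02,
  CDS 0.01 — an intron-dominated, CDS-poor landscape), per-site base
  editing levels Beta(2,2), and the base immediately 5′ set to uracil with
  probability 0.5;
* per-sample (12 samples), per-caller call sets with sensitivities
  REDItools 0.6 / RED-ML 0.8 / SPRINT 0.5, singleton false positives of
  300 / 30 / 30 per sample (REDItools dominating, as observed for
  unannotated calls), 20 recurrent false-positive hotspots appearing in
  ≥ 2 samples, and 55 SNP contaminants called by every method in every
  sample at level ≈ 0.5 — 40 listed in the emitted variant file and 15
  "hidden" (absent from it, emulating variants missed by genome
  resequencing and the SNP databases);
* an annotated-site database covering half of the truth sites plus half of
  the hotspots, so the annotated stratum contains false positives too;
* Sanger outcomes for the pipeline's final sites (truth → validated, hidden
  SNP → sequence variant, otherwise failed), with 10 % of validated sites
  yielding one adjacent Sanger-only discovery.

These defaults are the benchmark's study conditions; they reproduce the
qualitative structure of a real survey (singleton-dominated false positives,
heavy caller disagreement, intron-dominated truth, database contamination),
not any particular dataset's counts. What the generator does **not**
emulate: read-level effects (coverage-dependent level noise is a single
Gaussian, not binomial sampling from reads), hyper-edited clusters,
expression-dependent detectability, caller-correlated errors beyond shared
SNP/hotspot positions, and Alu-hosted editing (truth sites avoid repeats by
construction, mirroring a non-repeat-focused analysis). Passing the
end-to-end tests therefore shows the integration logic is correct under the
modelled error structure, not that any specific real dataset would yield a
particular precision.

Scaled-down conditions (0.4 Mb genome, 4 samples, 80 truth sites) are used
for structural tests where only determinism or plumbing is at stake; all
distribution-recovery and precision properties run on the default
conditions.

## Numerical and degenerate-input choices

Strict inequalities are used exactly where stated (level > 0.2, window mean
> 0.5); boundary cases are pinned by tests. Levels written to tables use
`repr` so floats round-trip exactly. Empty inputs: an empty call directory
yields an empty (but valid) compendium; an empty stratum list, zero tested
counts, or an empty level set raise contract violations rather than
returning NaN. Alu fraction of zero removed calls is 0 by definition. The
apportionment of truth sites across context weights uses largest-remainder
rounding so counts are deterministic and sum exactly.

## Known limitations

* The pipeline consumes caller outputs; it cannot correct systematic biases
  shared by all callers (e.g. alignment artifacts at splice junctions).
* Validation outcomes are ingested as a table; electropherogram scoring is
  out of scope, so `validated` is whatever the table says it is.
* Enrichment odds ratios are point estimates; no confidence intervals are
  computed.
* Differential (per-condition) editing analysis is deliberately absent:
  single-sample calls are exactly the stratum the validation arithmetic
  shows to be unreliable.
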