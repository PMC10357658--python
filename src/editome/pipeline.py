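"""End-to-end orchestration: filters -> consensus -> annotation -> compendium
-> statistics, with a run manifest for reproducibility.

Input layout (as written by the synthetic generator, and the documented
convention for real data): an input directory containing the annotation
bundle files (``genome.fa``, ``genes.gff3``, ``repeats.bed``, ``vlincs.bed``,
``variants.tsv``, ``map100.bedgraph``, ``map24.bedgraph``, ``db_sites.tsv``),
a ``calls/`` directory of ``<sample>.<method>.tsv`` tables, and optionally a
``validation.tsv`` of Sanger outcomes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Dict, List, Optional

from . import annotation, compendium, consensus, filters, io, stats
from .model import (
    AnnotationBundle,
    CompendiumResult,
    ConsensusSite,
    MethodCall,
    PipelineConfig,
    ValidationRecord,
)

log = logging.getLogger(__name__)

__version__ = "0.1.0"


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_full_pipeline(
    input_dir: str,
    output_dir: str,
    config: Optional[PipelineConfig] = None,
    bundle: Optional[AnnotationBundle] = None,
) -> Dict:
    """Execute the full editome-construction pipeline; returns the manifest.

    Deterministic given identical inputs and config: outputs are sorted site
    tables, an exclusion audit, a filter report and a JSON manifest with
    per-stage counts and input digests.
    """
    config = config or PipelineConfig()
    os.makedirs(output_dir, exist_ok=True)

    if bundle is None:
        bundle = io.read_bundle_dir(input_dir)

    calls: List[MethodCall] = []
    n_rejected = 0
    calls_dir = os.path.join(input_dir, "calls")
    call_files = io.discover_call_files(calls_dir) if os.path.isdir(calls_dir) else []
    digests = {}
    for path, sample_id, method_id in call_files:
        file_calls, rejected = io.read_method_calls(path, sample_id, method_id)
        calls.extend(file_calls)
        n_rejected += rejected
        digests[os.path.basename(path)] = _digest(path)

    repeat_index = filters.build_repeat_index(bundle.repeats)
    passing, filter_report = filters.apply_filters(
        calls, bundle.variants, repeat_index, bundle.map100, bundle.map24, config
    )

    sites = consensus.build_consensus(passing)
    retained, rejected_sites = consensus.apply_reproducibility_thresholds(sites, config)

    annotated, unannotated = annotation.match_annotated_db(retained, bundle.db_sites)
    index = annotation.ContextIndex.from_bundle(bundle)
    context_counts = annotation.assign_contexts(retained, index)

    validation_path = os.path.join(input_dir, "validation.tsv")
    validation: List[ValidationRecord] = []
    if os.path.isfile(validation_path):
        validation = io.read_validation_table(validation_path)
        digests["validation.tsv"] = _digest(validation_path)

    result = compendium.build_compendium(
        annotated,
        unannotated,
        validation_records=validation,
        db_sites=bundle.db_sites,
        variants=bundle.variants,
    )
    for site in result.sanger_added:
        site.context = annotation.classify_context(site.key, index)

    final_sites = result.final_sites
    io.write_site_table(retained, os.path.join(output_dir, "consensus.tsv"))
    io.write_site_table(final_sites, os.path.join(output_dir, "compendium.tsv"))
    io.write_bed(final_sites, os.path.join(output_dir, "compendium.bed"))
    with open(os.path.join(output_dir, "excluded.tsv"), "w") as fh:
        fh.write("chrom\tpos\tstrand\treason\n")
        for key in sorted(result.excluded):
            fh.write(f"{key.chrom}\t{key.pos}\t{key.strand}\t{result.excluded[key]}\n")
    with open(os.path.join(output_dir, "filter_report.json"), "w") as fh:
        json.dump(filter_report.as_dict(), fh, indent=2)
        fh.write("\n")

    final_context_counts: Dict[str, int] = {}
    for site in final_sites:
        final_context_counts[site.context] = final_context_counts.get(site.context, 0) + 1

    manifest = {
        "tool_version": __version__,
        "seed": config.rng_seed,
        "config": dataclasses.asdict(config),
        "input_digests": dict(sorted(digests.items())),
        "counts": {
            "calls_ingested": len(calls),
            "calls_rejected": n_rejected,
            "filter_report": filter_report.as_dict(),
            "consensus_sites": len(sites),
            "retained": len(retained),
            "singleton_or_low": len(rejected_sites),
            "annotated": len(annotated),
            "unannotated": len(unannotated),
            "context_distribution": {
                k: v for k, v in sorted(context_counts.items()) if v
            },
            "final_annotated": len(result.final_annotated),
            "final_unannotated": len(result.final_unannotated),
            "sanger_added": len(result.sanger_added),
            "excluded": len(result.excluded),
            "final_total": len(final_sites),
            "final_context_distribution": dict(sorted(final_context_counts.items())),
        },
    }
    with open(os.path.join(output_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def compute_run_stats(
    output_dir: str, validation_path: Optional[str] = None
) -> Dict:
    """Validation statistics over a finished run.

    Builds annotated/unannotated strata from the compendium and the
    validation outcomes and reports per-stratum and weighted validation
    ratios.  Ratios are marked unavailable without a validation table.
    """
    sites = io.read_site_table(os.path.join(output_dir, "compendium.tsv"))
    annotated = [s for s in sites if s.annotated]
    unannotated = [s for s in sites if not s.annotated]
    out: Dict = {
        "n_final": len(sites),
        "n_annotated": len(annotated),
        "n_unannotated": len(unannotated),
    }
    if validation_path is None or not os.path.isfile(validation_path):
        out["validation"] = "not available"
        return out

    records = io.read_validation_table(validation_path)
    by_key = {r.key: r for r in records}
    strata = []
    for label, group in (("annotated", annotated), ("unannotated", unannotated)):
        tested = [by_key[s.key] for s in group if s.key in by_key]
        positive = sum(1 for r in tested if r.status == "validated")
        if tested and group:
            strata.append(
                stats.Stratum(
                    label=label,
                    population=len(group),
                    tested=len(tested),
                    positive=positive,
                )
            )
            out[f"{label}_validation_ratio"] = positive / len(tested)
    if strata:
        out["weighted_validation_ratio"] = stats.weighted_validation_ratio(strata)
    out["n_sequence_variant"] = sum(
        1 for r in records if r.status == "sequence_variant"
    )
    return out


def summarize_report(output_dir: str, validation_path: Optional[str] = None) -> str:
    """Human-readable run summary (context distribution, method combinations,
    validation ratios when available)."""
    manifest_path = os.path.join(output_dir, "manifest.json")
    if not os.path.isfile(manifest_path):
        raise FileNotFoundError(f"no manifest at {manifest_path}; run the pipeline first")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    counts = manifest["counts"]

    sites = io.read_site_table(os.path.join(output_dir, "compendium.tsv"))
    combo_counts: Dict[str, int] = {}
    for site in sites:
        label = (
            "sanger-only"
            if site.sanger_only
            else consensus.classify_method_specificity(site)
        )
        combo_counts[label] = combo_counts.get(label, 0) + 1

    lines = [
        f"editome run summary (v{manifest['tool_version']})",
        f"  calls ingested: {counts['calls_ingested']} "
        f"(rejected {counts['calls_rejected']})",
        f"  passed filters: {counts['filter_report']['n_pass']} "
        f"(variant {counts['filter_report']['n_removed_variant']}, "
        f"repeat {counts['filter_report']['n_removed_repeat']}, "
        f"mappability {counts['filter_report']['n_removed_mappability']})",
        f"  consensus sites: {counts['consensus_sites']} "
        f"(retained {counts['retained']}, singleton/low {counts['singleton_or_low']})",
        f"  final compendium: {counts['final_total']} "
        f"({counts['final_annotated']} annotated, "
        f"{counts['final_unannotated']} unannotated, "
        f"{counts['sanger_added']} Sanger-only)",
        "  final context distribution:",
    ]
    for label, n in sorted(counts["final_context_distribution"].items()):
        lines.append(f"    {label}: {n}")
    lines.append("  method combinations (final sites):")
    for label, n in sorted(combo_counts.items()):
        lines.append(f"    {label}: {n}")

    run_stats = compute_run_stats(output_dir, validation_path)
    if run_stats.get("validation") == "not available":
        lines.append("  validation ratios: not available (no validation table)")
    else:
        for key in (
            "annotated_validation_ratio",
            "unannotated_validation_ratio",
            "weighted_validation_ratio",
        ):
            if key in run_stats:
                lines.append(f"  {key.replace('_', ' ')}: {run_stats[key]:.1%}")
        lines.append(
            f"  sequence variants flagged by validation: "
            f"{run_stats['n_sequence_variant']}"
        )
    return "\n".join(lines)


def simulate_fixture(sim_config, outdir: str, with_validation: bool = True):
    """Generate a complete synthetic fixture directory.

    Writes the annotation bundle, truth tables and call sets; when
    ``with_validation`` is set, additionally runs the pipeline in memory on
    the generated calls and emits Sanger outcomes for its final sites, so a
    subsequent :func:`run_full_pipeline` on the fixture can exercise the
    Sanger-merge and sequence-variant paths.
    """
    from . import simulate as sim_mod

    sim = sim_mod.generate_truth(sim_config, outdir)
    sim_mod.generate_method_calls(sim)
    if with_validation:
        config = PipelineConfig(rng_seed=sim_config.rng_seed)
        bundle = io.read_bundle_dir(outdir)
        calls: List[MethodCall] = []
        for path, sample_id, method_id in io.discover_call_files(
            os.path.join(outdir, "calls")
        ):
            calls.extend(io.read_method_calls(path, sample_id, method_id)[0])
        repeat_index = filters.build_repeat_index(bundle.repeats)
        passing, _ = filters.apply_filters(
            calls, bundle.variants, repeat_index, bundle.map100, bundle.map24, config
        )
        retained, _ = consensus.apply_reproducibility_thresholds(
            consensus.build_consensus(passing), config
        )
        annotated, unannotated = annotation.match_annotated_db(
            retained, bundle.db_sites
        )
        annotation.assign_contexts(retained, annotation.ContextIndex.from_bundle(bundle))
        result = compendium.build_compendium(
            annotated, unannotated, db_sites=bundle.db_sites, variants=bundle.variants
        )
        sim_mod.generate_validation_outcomes(
            result.final_sites, sim, genome=bundle.genome
        )
    return sim
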