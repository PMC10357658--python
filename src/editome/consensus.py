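"""Merging candidate calls into consensus sites.

Within one sample, a site detected by several methods gets one aggregated
editing level: the arithmetic mean of the per-method levels.  Across samples,
the method set of a site is the union of the per-sample method sets — a site
found by RED-ML in one sample and by SPRINT in another counts as found by
both, even if only one sample's level clears the threshold.  Retention then
requires a maximum aggregated level strictly above the threshold (default
0.2) and detection in at least two samples.

HPC-REDItools evidence, when ingested, contributes to per-sample levels,
sample counts and exports, but is excluded from method-combination decisions
(its method-exclusive predictions validated poorly).
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Sequence, Tuple

from .model import (
    ConsensusSite,
    ContractViolation,
    MethodCall,
    PipelineConfig,
    SampleEvidence,
    SiteKey,
)


def aggregate_sample_level(levels: Sequence[float]) -> float:
    """Mean editing level across the methods that detected a site in one sample."""
    if not levels:
        raise ContractViolation("aggregate_sample_level requires at least one level")
    return sum(levels) / len(levels)


def build_consensus(calls: Iterable[MethodCall]) -> List[ConsensusSite]:
    """Group filtered calls into one ConsensusSite per distinct site key.

    Duplicate (site, sample, method) observations within one ingest violate
    the call-table contract and raise.
    """
    by_site_sample: Dict[SiteKey, Dict[str, Dict[str, float]]] = {}
    for call in calls:
        samples = by_site_sample.setdefault(call.key, {})
        methods = samples.setdefault(call.sample_id, {})
        if call.method_id in methods:
            raise ContractViolation(
                f"duplicate call for {call.key} sample={call.sample_id} "
                f"method={call.method_id}"
            )
        methods[call.method_id] = call.editing_level

    sites = []
    for key in sorted(by_site_sample, key=lambda k: (k.chrom, k.pos, k.strand)):
        per_sample = {
            sample: SampleEvidence(
                methods=frozenset(levels),
                level=aggregate_sample_level(list(levels.values())),
            )
            for sample, levels in sorted(by_site_sample[key].items())
        }
        sites.append(ConsensusSite(key=key, per_sample=per_sample))
    return sites


def apply_reproducibility_thresholds(
    sites: Iterable[ConsensusSite], config: PipelineConfig
) -> Tuple[List[ConsensusSite], List[ConsensusSite]]:
    """Partition sites into (retained, singleton_or_low).

    Retained iff max aggregated level is strictly above
    ``config.level_threshold`` and the site was called in at least
    ``config.min_samples`` samples.
    """
    retained, rejected = [], []
    for site in sites:
        if site.max_level > config.level_threshold and site.n_samples >= config.min_samples:
            retained.append(site)
        else:
            rejected.append(site)
    return retained, rejected


def classify_method_specificity(site: ConsensusSite) -> str:
    """Label a site by its core-method combination.

    ``X-specific`` when the decision-method set is exactly {X};
    ``multi-method`` for two or more core methods; ``auxiliary-only`` when the
    only evidence is HPC-REDItools (outside the published 4-label set, which
    has no value for that case).
    """
    methods = site.methods
    if not methods:
        return "auxiliary-only"
    if len(methods) == 1:
        return f"{next(iter(methods))}-specific"
    return "multi-method"
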