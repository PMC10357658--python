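"""Final decision rules producing the high-confidence editome.

Annotated sites (present in the editing databases) are kept when supported by
RED-ML or SPRINT — equivalently, REDItools-only sites are dropped, since
their validation ratio was 0%.  Unannotated sites need RED-ML support, and
outside introns and vlincRNAs additionally SPRINT support.  Sites read
directly off Sanger electropherograms adjacent to tested sites are merged
into the unannotated compendium.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Tuple

from .model import (
    CompendiumResult,
    ConsensusSite,
    DbSites,
    RED_ML,
    SPRINT,
    SiteKey,
    ValidationRecord,
)

log = logging.getLogger(__name__)

RELIABLE_SINGLE_METHOD_CONTEXTS = frozenset({"intron", "vlincRNA"})

# exclusion reason codes
REASON_REDITOOLS_ONLY = "reditools_only"
REASON_HPC_ONLY = "hpc_only"
REASON_NO_REDML = "no_redml"
REASON_NO_SPRINT = "no_sprint_outside_intron_vlinc"


def finalize_annotated(
    sites: Iterable[ConsensusSite],
) -> Tuple[List[ConsensusSite], Dict[SiteKey, str]]:
    """Keep annotated sites with RED-ML or SPRINT support."""
    kept: List[ConsensusSite] = []
    excluded: Dict[SiteKey, str] = {}
    for site in sites:
        if site.methods & {RED_ML, SPRINT}:
            site.final = True
            kept.append(site)
        else:
            site.final = False
            excluded[site.key] = (
                REASON_REDITOOLS_ONLY if site.methods else REASON_HPC_ONLY
            )
    return kept, excluded


def finalize_unannotated(
    sites: Iterable[ConsensusSite],
) -> Tuple[List[ConsensusSite], Dict[SiteKey, str]]:
    """Keep unannotated sites reliably callable given their genomic context.

    RED-ML support is always required; sites outside introns and vlincRNAs
    must additionally be predicted by SPRINT.
    """
    kept: List[ConsensusSite] = []
    excluded: Dict[SiteKey, str] = {}
    for site in sites:
        if site.context is None:
            raise ValueError(f"site {site.key} has no context assigned")
        if RED_ML not in site.methods:
            site.final = False
            excluded[site.key] = REASON_NO_REDML
        elif site.context in RELIABLE_SINGLE_METHOD_CONTEXTS or SPRINT in site.methods:
            site.final = True
            kept.append(site)
        else:
            site.final = False
            excluded[site.key] = REASON_NO_SPRINT
    return kept, excluded


def merge_sanger_discovered(
    kept_unannotated: List[ConsensusSite],
    records: Iterable[ValidationRecord],
    db_sites: Optional[DbSites] = None,
    variants: frozenset = frozenset(),
) -> Tuple[List[ConsensusSite], List[ConsensusSite]]:
    """Union the kept unannotated sites with adjacent Sanger-only discoveries.

    Adjacent sites already present, already in the annotated database, or
    colliding with a known variant position are not added (the last with a
    warning).  Returns (final_unannotated, sanger_added).
    """
    present = {site.key for site in kept_unannotated}
    added: List[ConsensusSite] = []
    for record in records:
        for key in record.adjacent_new_sites:
            if key in present:
                continue
            if db_sites is not None and db_sites.contains(key):
                continue
            if (key.chrom, key.pos) in variants:
                log.warning(
                    "Sanger-adjacent site %s collides with a known variant; rejected",
                    key,
                )
                continue
            site = ConsensusSite(
                key=key, annotated=False, final=True, sanger_only=True
            )
            added.append(site)
            present.add(key)
    added.sort(key=lambda s: (s.key.chrom, s.key.pos, s.key.strand))
    return kept_unannotated + added, added


def build_compendium(
    annotated: List[ConsensusSite],
    unannotated: List[ConsensusSite],
    validation_records: Iterable[ValidationRecord] = (),
    db_sites: Optional[DbSites] = None,
    variants: frozenset = frozenset(),
) -> CompendiumResult:
    """Apply all decision rules and assemble the final compendium."""
    kept_ann, excl_ann = finalize_annotated(annotated)
    kept_unann, excl_unann = finalize_unannotated(unannotated)
    final_unann, sanger_added = merge_sanger_discovered(
        kept_unann, validation_records, db_sites=db_sites, variants=variants
    )
    excluded = {**excl_ann, **excl_unann}
    return CompendiumResult(
        final_annotated=kept_ann,
        final_unannotated=final_unann,
        excluded=excluded,
        sanger_added=sanger_added,
    )
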