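"""Pre-consensus candidate filters.

Candidate calls pass through three filters in a fixed order: known DNA
variants (strandless position match, dbSNP semantics), RepeatMasker repeats
(strandless interval overlap), and mappability (unique 100mer alignability at
the site plus mean 24mer alignability strictly above 0.5 in a +/-150 bp
window).  Each input call lands in exactly one bin, so the report tallies are
conserved.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Tuple

import numpy as np
from intervaltree import IntervalTree

from .model import FilterReport, MethodCall, PipelineConfig

log = logging.getLogger(__name__)

MAP100_TOLERANCE = 1e-9  # "score of 1" tested as >= 1 - eps (text-float round trip)


def filter_variants(
    calls: Iterable[MethodCall], variants: frozenset
) -> Tuple[List[MethodCall], List[MethodCall]]:
    """Remove calls whose (chrom, pos) is a known DNA variant.

    Matching is strandless: a DNA variant affects both strands.
    """
    passing, removed = [], []
    for call in calls:
        if (call.key.chrom, call.key.pos) in variants:
            removed.append(call)
        else:
            passing.append(call)
    return passing, removed


def build_repeat_index(
    repeats: Iterable[Tuple[str, int, int, str]]
) -> Dict[str, IntervalTree]:
    """Index repeat intervals (0-based half-open) per contig for point queries."""
    trees: Dict[str, IntervalTree] = {}
    for chrom, start, end, family in repeats:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, family)
    return trees


def filter_repeats(
    calls: Iterable[MethodCall],
    repeat_index: Dict[str, IntervalTree],
) -> Tuple[List[MethodCall], List[MethodCall], float]:
    """Remove calls inside any repeat interval (strand ignored).

    Returns (passing, removed, fraction of removed calls lying in Alu
    elements).  A position exactly at an interval's half-open end is outside
    it.
    """
    passing, removed = [], []
    n_alu = 0
    for call in calls:
        tree = repeat_index.get(call.key.chrom)
        hits = tree[call.key.pos - 1] if tree is not None else set()
        if hits:
            removed.append(call)
            if any(iv.data.startswith("Alu") for iv in hits):
                n_alu += 1
        else:
            passing.append(call)
    alu_fraction = n_alu / len(removed) if removed else 0.0
    return passing, removed, alu_fraction


def window_mean(track: np.ndarray, pos0: int, halfwidth: int) -> float:
    """Mean track score over the inclusive window [pos0-w, pos0+w].

    The denominator is always the full ``2w+1`` slots; out-of-contig slots
    (and undefined track positions, stored as 0) contribute 0, so sites near
    contig ends are penalized rather than silently favoured.
    """
    lo = max(0, pos0 - halfwidth)
    hi = min(len(track), pos0 + halfwidth + 1)
    total = float(track[lo:hi].sum()) if hi > lo else 0.0
    return total / (2 * halfwidth + 1)


def filter_mappability(
    calls: Iterable[MethodCall],
    map100: Dict[str, np.ndarray],
    map24: Dict[str, np.ndarray],
    config: PipelineConfig,
) -> Tuple[List[MethodCall], List[MethodCall]]:
    """Keep calls at uniquely alignable positions.

    A call passes iff the 100mer alignability at its position equals
    ``config.map100_required`` (within a round-trip tolerance) and the mean
    24mer alignability over ``pos +/- config.map_window`` is strictly greater
    than ``config.map24_mean_min``.  Contigs absent from the tracks are
    treated as all-undefined (score 0) with a warning.
    """
    passing, removed = [], []
    warned: set = set()
    for call in calls:
        chrom, pos0 = call.key.chrom, call.key.pos - 1
        t100 = map100.get(chrom)
        t24 = map24.get(chrom)
        if t100 is None or t24 is None:
            if chrom not in warned:
                log.warning("contig %s absent from mappability tracks; sites removed", chrom)
                warned.add(chrom)
            removed.append(call)
            continue
        score100 = float(t100[pos0]) if pos0 < len(t100) else 0.0
        ok100 = score100 >= config.map100_required - MAP100_TOLERANCE
        ok24 = window_mean(t24, pos0, config.map_window) > config.map24_mean_min
        if ok100 and ok24:
            passing.append(call)
        else:
            removed.append(call)
    return passing, removed


def apply_filters(
    calls: List[MethodCall],
    variants: frozenset,
    repeat_index: Dict[str, IntervalTree],
    map100: Dict[str, np.ndarray],
    map24: Dict[str, np.ndarray],
    config: PipelineConfig,
) -> Tuple[List[MethodCall], FilterReport]:
    """Run the fixed-order filter chain and tally a conserved report."""
    after_var, removed_var = filter_variants(calls, variants)
    after_rep, removed_rep, alu_fraction = filter_repeats(after_var, repeat_index)
    after_map, removed_map = filter_mappability(after_rep, map100, map24, config)
    report = FilterReport(
        n_input=len(calls),
        n_removed_variant=len(removed_var),
        n_removed_repeat=len(removed_rep),
        repeat_alu_fraction=alu_fraction,
        n_removed_mappability=len(removed_map),
        n_pass=len(after_map),
    ).check()
    return after_map, report
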