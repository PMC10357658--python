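"""Validation-ratio arithmetic, false-positive estimation, enrichment and
motif profiling.

The central statistic is the population-weighted validation ratio: Sanger
testing covers only a sample of each stratum of sites, so each stratum's
observed ratio p/t is extrapolated to its full population N and the strata
are combined as sum(N_g * p_g/t_g) / sum(N_g).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np

from .model import (
    ContractViolation,
    EnrichmentResult,
    MOTIF_BASES,
    MotifProfile,
    SiteKey,
    Stratum,
)

log = logging.getLogger(__name__)


def weighted_validation_ratio(strata: Sequence[Stratum]) -> float:
    """Population-weighted mean of stratum validation ratios.

    Equals the mean outcome if every population member were assigned its
    stratum's observed ratio.  Requires tested > 0 in every stratum.
    """
    if not strata:
        raise ContractViolation("weighted_validation_ratio needs at least one stratum")
    total_n = 0
    total = 0.0
    for stratum in strata:
        stratum.validate()
        if stratum.population <= 0:
            raise ContractViolation(
                f"stratum {stratum.label!r} has population {stratum.population}"
            )
        total += stratum.population * stratum.ratio
        total_n += stratum.population
    return total / total_n


def population_weighted_ratio(pairs: Sequence[Tuple[int, float]]) -> float:
    """Population-weighted mean of already-computed stratum ratios.

    Same semantics as :func:`weighted_validation_ratio` but for ratios quoted
    directly (e.g. printed percentages) instead of positive/tested counts.
    """
    if not pairs:
        raise ContractViolation("population_weighted_ratio needs at least one pair")
    total_n = sum(n for n, _ in pairs)
    if total_n <= 0:
        raise ContractViolation("total population must be positive")
    return sum(n * r for n, r in pairs) / total_n


PopulationRate = Tuple[int, float]  # (population, fail rate in [0,1])


def _as_population_fail_rate(arm: Union[Stratum, PopulationRate]) -> PopulationRate:
    if isinstance(arm, Stratum):
        return arm.population, 1.0 - arm.ratio
    population, rate = arm
    if population <= 0:
        raise ContractViolation("population must be positive")
    if not 0.0 <= rate <= 1.0:
        raise ContractViolation(f"fail rate outside [0,1]: {rate}")
    return int(population), float(rate)


def estimate_min_false_fraction(
    tested: Union[Stratum, PopulationRate],
    untested: Union[Stratum, PopulationRate],
) -> float:
    """Minimal fraction of a site population expected to fail validation.

    Each arm is a Stratum (fail rate 1 - p/t) or a (population, fail_rate)
    pair for rates quoted as rounded percentages.  Expected failure counts
    are rounded to the nearest integer per arm before summing, matching how
    such estimates are reported on whole-site counts.
    """
    n1, r1 = _as_population_fail_rate(tested)
    n2, r2 = _as_population_fail_rate(untested)
    fails = round(n1 * r1) + round(n2 * r2)
    return fails / (n1 + n2)


def odds_ratio_enrichment(
    site_counts: Dict[str, int],
    background_counts: Dict[str, int],
    elements: Iterable[str] = None,
) -> List[EnrichmentResult]:
    """Per-element odds ratios of site enrichment over a background.

    For each element, a/b are sites inside/outside it and c/d background
    positions inside/outside; OR = (a*d)/(b*c).  A zero denominator yields a
    flagged undefined result instead of a crash.
    """
    if elements is None:
        elements = sorted(site_counts)
    total_sites = sum(site_counts.values())
    total_bg = sum(background_counts.values())
    results = []
    for element in elements:
        a = site_counts.get(element, 0)
        b = total_sites - a
        c = background_counts.get(element, 0)
        d = total_bg - c
        if b * c == 0:
            results.append(
                EnrichmentResult(element, a, b, c, d, float("nan"), defined=False)
            )
        else:
            results.append(
                EnrichmentResult(element, a, b, c, d, (a * d) / (b * c), defined=True)
            )
    return results


def _site_sequence(genome, key: SiteKey, halfwidth: int) -> str:
    """Site-strand sequence over [pos-h, pos+h]; None if flanks run off the contig."""
    contig = genome[key.chrom]
    start0 = key.pos - 1 - halfwidth
    end0 = key.pos + halfwidth  # half-open
    if start0 < 0 or end0 > len(contig):
        return None
    seq = str(contig[start0:end0]).upper()
    if key.strand == "-":
        from Bio.Seq import Seq

        seq = str(Seq(seq).reverse_complement())
    return seq


def motif_profile(
    sites: Iterable[SiteKey], genome, halfwidth: int = 5
) -> MotifProfile:
    """Per-position base-fraction matrix around edited adenosines.

    Sequences are taken in site-strand orientation (reverse-complemented for
    '-' sites) and reported in RNA alphabet (T as U), so position 0 is always
    A for a genuine editing site.  Sites with flanks running off the contig
    are skipped with a warning; sites whose strand base is not A are excluded
    and counted (they signal upstream corruption).
    """
    width = 2 * halfwidth + 1
    counts = np.zeros((width, len(MOTIF_BASES)), dtype=np.int64)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    n = 0
    n_skipped = 0
    n_non_a = 0
    for key in sites:
        seq = _site_sequence(genome, key, halfwidth)
        if seq is None:
            n_skipped += 1
            continue
        if seq[halfwidth] != "A":
            n_non_a += 1
            continue
        for i, base in enumerate(seq):
            j = base_index.get(base)
            if j is not None:
                counts[i, j] += 1
        n += 1
    if n_skipped:
        log.warning("motif_profile: skipped %d site(s) with short flanks", n_skipped)
    if n_non_a:
        log.warning(
            "motif_profile: excluded %d site(s) whose strand base is not A", n_non_a
        )
    if n > 0:
        fractions = counts / counts.sum(axis=1, keepdims=True)
    else:
        fractions = np.zeros((width, len(MOTIF_BASES)))
    return MotifProfile(
        halfwidth=halfwidth,
        fractions=fractions,
        n=n,
        n_skipped_flank=n_skipped,
        n_non_adenosine=n_non_a,
    )


def motif_difference(
    profile_pos: MotifProfile, profile_neg: MotifProfile
) -> np.ndarray:
    """Per-position, per-base fraction differences (positive minus negative).

    Positive values mean enrichment in the positive set; at each position the
    four base differences sum to zero.
    """
    if profile_pos.halfwidth != profile_neg.halfwidth:
        raise ContractViolation("motif_difference requires equal halfwidths")
    return profile_pos.fractions - profile_neg.fractions


def motif_profile_table(profile: MotifProfile):
    """Motif profile as a tidy DataFrame (position x base), for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        profile.fractions,
        index=pd.Index(profile.positions, name="position"),
        columns=list(MOTIF_BASES),
    )
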