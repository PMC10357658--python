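"""Weighted validation-ratio arithmetic on printed stratum counts.

Sanger validation covers only a sample of each group of candidate editing
sites, so group-level ratios are extrapolated to the full populations with
population-size weights.  This example reproduces the kind of worked
arithmetic an editome survey reports: how reproducibility (detection in >= 2
samples) changes the expected fraction of true sites, and a minimal
false-positive estimate for database-annotated sites.
"""

from editome.model import Stratum
from editome.stats import (
    estimate_min_false_fraction,
    population_weighted_ratio,
    weighted_validation_ratio,
)

# Sites detected in at least two samples: the annotated stratum holds 3196
# sites of which 110 were Sanger-tested and 69 confirmed; the unannotated
# stratum 8724 sites with 52/215 confirmed.
multi = weighted_validation_ratio(
    [
        Stratum("annotated, >=2 samples", population=3196, tested=110, positive=69),
        Stratum("unannotated, >=2 samples", population=8724, tested=215, positive=52),
    ]
)
print(f"weighted validation ratio, >=2-sample sites: {100 * multi:.1f}%")

# Sites detected in a single sample validate far worse; the unannotated
# population dwarfs the annotated one, dragging the weighted mean down.
single = weighted_validation_ratio(
    [
        Stratum("annotated, 1 sample", population=2630, tested=34, positive=8),
        Stratum("unannotated, 1 sample", population=178618, tested=103, positive=1),
    ]
)
print(f"weighted validation ratio, single-sample sites: {100 * single:.1f}%")

# Final compendium: 3160 annotated sites at 74.5% and 989 unannotated at
# 73.5% combine into the overall ratio.
overall = population_weighted_ratio([(3160, 0.745), (989, 0.735)])
print(f"overall compendium validation ratio: {100 * overall:.0f}%")

# Minimal fraction of annotated sites expected to fail validation: the 3160
# multi-sample sites fail at 25.5%, and the 2630 single-sample annotated
# sites are assumed to fail at 76.5% (from the single-sample validation).
false_fraction = estimate_min_false_fraction((3160, 0.255), (2630, 0.765))
print(f"minimal false fraction of annotated sites: {100 * false_fraction:.1f}%")
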