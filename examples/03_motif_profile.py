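"""Sequence context around planted editing sites.

ADAR enzymes prefer uracil immediately 5' of the edited adenosine.  The
generator plants that preference with probability 0.5, and the motif profile
recovers it: the U fraction at position -1 sits near 0.5, well above the
~0.25 background, while position 0 is always A by construction.
"""

import os
import tempfile

from pyfaidx import Fasta

from editome.simulate import SimConfig, generate_truth
from editome.stats import motif_profile, motif_profile_table

with tempfile.TemporaryDirectory() as workdir:
    sim = generate_truth(SimConfig(rng_seed=1), workdir)
    genome = Fasta(os.path.join(workdir, "genome.fa"), sequence_always_upper=True)

    profile = motif_profile([t.key for t in sim.truth_sites], genome, halfwidth=5)
    print(f"profiled {profile.n} truth sites")
    print(motif_profile_table(profile).to_string(float_format=lambda x: f"{x:.3f}"))
    print()
    print(f"U fraction at -1: {profile.fraction(-1, 'U'):.3f} "
          f"(planted probability {sim.config.p_u_minus1})")
    print(f"A fraction at 0:  {profile.fraction(0, 'A'):.3f} (edited base, always A)")
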