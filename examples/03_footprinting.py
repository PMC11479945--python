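"""Footprint scoring: a planted 50% cut-density dip at motif cores.

Builds two Poisson cut-count tracks — one with a protein-protection dip
over every motif core, one without — and scores the aggregate
flank-vs-core depletion plus its z score against a shuffled-position null.
"""

import numpy as np

from tetdormancy.footprints import (
    CutTrack,
    MotifOccurrence,
    differential_footprint,
    footprint_score,
)
from tetdormancy.intervals import GenomicInterval, IntervalSet

rng = np.random.default_rng(0)
n_occ, L, spacing, rate, depth = 200, 10, 200, 5.0, 0.5
size = 200 + n_occ * spacing
occ = [
    MotifOccurrence(GenomicInterval("chr1", 100 + i * spacing,
                                    100 + i * spacing + L), "+", 1.0)
    for i in range(n_occ)
]
lam = np.full(size, rate)
for o in occ:
    lam[o.region.start:o.region.end] *= (1 - depth)
bound = CutTrack({"chr1": rng.poisson(lam).astype(float)})
unbound = CutTrack({"chr1": rng.poisson(np.full(size, rate)).astype(float)})
host = IntervalSet([GenomicInterval("chr1", 60, size - 60)])

sb = footprint_score(bound, occ, flank=50)
su = footprint_score(unbound, occ, flank=50)
diff = differential_footprint(bound, unbound, occ, host, n_shuffles=100, seed=1)

print(f"bound-condition score:   {sb.score:.3f}  (planted depth {depth})")
print(f"unbound-condition score: {su.score:.3f}")
print(f"differential delta:      {diff['delta']:.3f}   z = {diff['z']:.1f}")
print(
    "\nThe score is (flank - core)/flank cut density over the aggregate "
    "profile: ~0.5 recovers the planted 50% protection, ~0 means no "
    "footprint, and a z far above 3 says random same-length windows never "
    "produce such a difference."
)
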