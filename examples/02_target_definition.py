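"""The target definition at its decision boundary, on a constructed table.

Three candidate regions with hand-set methylation rates illustrate the
two inclusive criteria: WT gain <= 10% (protection) and DKO-vs-WT gain
>= 10% at 72 h.
"""

import pandas as pd

from tetdormancy import TargetParams, call_targets

cand = pd.DataFrame({
    "chrom": ["chr1"] * 3,
    "start": [0, 1000, 2000],
    "end": [500, 1500, 2500],
    "tet1_bound": [True] * 3,
    "tet2_bound": [False] * 3,
    "binding_class": ["tet1_only"] * 3,
})


def meth(rates):
    out = cand[["chrom", "start", "end"]].copy()
    out["n_cpgs"] = 8
    out["rate"] = rates
    return out


out = call_targets(
    cand,
    meth_wt0=meth([0.10, 0.10, 0.10]),
    meth_wt_t=meth([0.12, 0.12, 0.25]),   # region 3 gains 15% in WT
    meth_dko_t=meth([0.22, 0.2199, 0.40]),
    params=TargetParams(),
)
print(out[["start", "wt_delta", "dko_vs_wt_delta", "is_target"]].to_string(index=False))
print(
    "\nRegion 1 gains exactly 10% in the DKO only -> target (inclusive "
    "boundary). Region 2 gains 9.99% -> not a target. Region 3 gains "
    "methylation in WT too -> not protected, not a target."
)
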