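"""Simulate a miniature dormancy-transition dataset and call TET-dormancy targets.

Generates a small synthetic multi-omic dataset with planted ground truth
(TET-bound regions kept unmethylated in wild type but gaining methylation
in the Tet1/2 double knockout), runs the full pipeline, and scores the
calls against the planted truth.
"""

import json
import tempfile
from pathlib import Path

from tetdormancy import SimConfig, simulate_dataset
from tetdormancy.pipeline import config_from_sim_dir, run_pipeline

cfg = SimConfig(
    seed=42,
    chrom_length=400_000,
    n_tet1_peaks=70, n_tet2_peaks=50, frac_cobound=0.5,
    n_planted_targets=20,
    n_enhancers=12, n_primed_enhancers=16, n_promoters=15, n_l1md=40,
    n_decoy_p300=5, n_tfe3_standalone=20, n_tfe3_on_targets=8,
    n_footprint_regions=30, n_genes=60,
)

with tempfile.TemporaryDirectory() as tmp:
    sim_dir = Path(tmp) / "sim"
    simulate_dataset(cfg, sim_dir)
    report = run_pipeline(config_from_sim_dir(sim_dir, Path(tmp) / "run", seed=1))

print("target summary:")
print(json.dumps(report["target_summary"], indent=1, sort_keys=True))
print("\nrecovery vs planted truth:")
print(json.dumps(report["truth_recovery"], indent=1, sort_keys=True))
print(
    "\nEach candidate is a TET1/TET2-bound region; a target must stay "
    "methylation-protected in WT (gain <= 10%) while gaining >= 10% in the "
    "DKO at 72 h. Precision/recall near 1 show the caller recovers the "
    "planted biology from noisy beta-binomial methylation calls."
)
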