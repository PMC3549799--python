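"""Positional T->C conversion statistics over identified target sites.

Crosslink-induced conversions concentrate where the protein contacts the
mRNA — target-site positions pairing miRNA positions 8-14, just outside
seed complementarity — while positions 1-7 stay near background.  The
one-tailed two-sample Student's t-test on per-position pooled ratios
quantifies the contrast.
"""

import tempfile
from pathlib import Path

import numpy as np

from clipmti.pipeline import PipelineConfig, run_pipeline
from clipmti.preprocess import PreprocessParams
from clipmti.simulate import SimulationConfig, write_simulation

workdir = Path(tempfile.mkdtemp())
sim = SimulationConfig(seed=11)
paths = write_simulation(sim, workdir / "sim")
result = run_pipeline(
    PipelineConfig(preprocess=PreprocessParams(adapter=sim.adapter)),
    paths["reads"], paths["utrs"], paths["mirnas"], workdir / "out",
    expression_path=paths["expression"],
    conservation_path=paths["conservation"],
)

profile = result.profile
print("position  covering  converted  ratio")
for k in range(1, profile.n_positions + 1):
    r = profile.ratio[k - 1]
    print(f"{k:8d}  {profile.covering[k-1]:8d}  {profile.converted[k-1]:9d}  "
          f"{'NA' if np.isnan(r) else f'{r:.3f}'}")

print(f"\nseed-paired region (1-7) mean ratio:  {np.nanmean(profile.ratio[:7]):.3f}")
print(f"effector region (8-14) mean ratio:    {np.nanmean(profile.ratio[7:]):.3f}")
print(f"one-tailed t-test (8-14 > 1-7): t = {result.summary['region_t']:.2f}, "
      f"p = {result.summary['region_p']:.3g}")
print("\nStratified by UTR conservation (C/N) and seed length (7/8):")
print(result.strata[result.strata["mirna_set"] == "all"].to_string(index=False))
print(
    "\nSmall p-values mean conversions are significantly enriched in the\n"
    "region 3'-adjacent to the seed on the miRNA, the crosslink footprint."
)
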