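"""Simulate a PAR-CLIP experiment and run the full pipeline on it.

Generates a small synthetic library (3'UTRs with implanted miRNA target
sites, conversion-bearing reads, adapters, background), runs all six
stages, and prints the run summary plus the top-ranked target sites.
"""

import tempfile
from pathlib import Path

import pandas as pd

from clipmti.pipeline import PipelineConfig, run_pipeline
from clipmti.preprocess import PreprocessParams
from clipmti.simulate import SimulationConfig, write_simulation

workdir = Path(tempfile.mkdtemp())
sim = SimulationConfig(seed=7, n_utrs=12, background_read_count=80)
paths = write_simulation(sim, workdir / "sim")

config = PipelineConfig(mode="parclip", preprocess=PreprocessParams(adapter=sim.adapter))
result = run_pipeline(
    config,
    reads_path=paths["reads"],
    utrs_path=paths["utrs"],
    mirnas_path=paths["mirnas"],
    out_dir=workdir / "out",
    expression_path=paths["expression"],
    validated_path=paths["validated"],
    conservation_path=paths["conservation"],
)

print("Run summary (raw-read units; input = discarded + unmapped + mapped):")
for key, value in result.summary.items():
    print(f"  {key}: {value}")

sites = pd.read_csv(workdir / "out" / "sites.tsv", sep="\t")
print("\nTop 5 ranked miRNA target sites (1-based inclusive coordinates):")
print(sites.head(5).to_string(index=False))
print(
    "\nEach row is a seed-complementary site inside a read cluster; validated\n"
    "interactions rank first, then higher miRNA expression, stronger seed\n"
    "type (8mer > 7mer-m8 > 7mer-A1) and deeper read support."
)
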