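#!/usr/bin/env python
"""Step 1 — simulate the aging experiment.

Generates the synthetic two-species dataset at the study's design
conditions: 300 ortholog pairs at 12% per-site divergence, oocytes aged 2,
8 and 12 days in triplicate, footprint + mRNA assays, true bulk-translation
factors 1.0 / 0.595 / 0.427, ~2% spike-in read mass, 2e5 thirty-nt reads
per sample.  Writes FASTAs, FASTQs, the sample sheet, ground truth and a
checksummed manifest under scratch/simulation/ (large, regenerable).

Run from the repository root:  python analysis/01_simulate.py
"""

from pathlib import Path

from ooribo.pipeline import run_simulate
from ooribo.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
SIM_DIR = ROOT / "scratch" / "simulation"
SEED = 2026


def main():
    cfg = SimulationConfig(seed=SEED)
    manifest = run_simulate(cfg, SIM_DIR)
    print(f"simulated {manifest['n_samples']} samples "
          f"({cfg.n_genes} genes, {cfg.reads_per_sample} reads/sample, seed {SEED})")
    print(f"design: timepoints {cfg.timepoints} x {cfg.n_replicates} replicates x 2 assays")
    print(f"true bulk factors: {dict(zip(cfg.timepoints, cfg.bulk_factors))}")
    print(f"wrote {len(manifest['checksums'])} files under {SIM_DIR}")


if __name__ == "__main__":
    main()
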