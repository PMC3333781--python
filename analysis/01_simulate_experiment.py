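"""Simulate one DAP-chip experiment with planted ground truth.

Builds the default 100-kb operon-structured genome, tiles it with 50-mer
probes (4-bp step intergenic / 30-bp step coding), plants a palindromic
regulator motif and sigma54 promoters upstream of ten isolated target
operons, marks those promoter regions as fold-4 bound regions, and
simulates the enriched/input log2-ratio track with sd-0.3 channel noise.

Writes the complete input bundle under results/experiment/.
"""

import sys
from pathlib import Path

from dapmap.pipeline import PipelineConfig, run_pipeline

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "experiment"
SEED = 1


def main() -> int:
    cfg = PipelineConfig(seed=SEED)
    result = run_pipeline(cfg, outdir=OUTDIR)
    truth = result.truth
    print(f"genome: {sum(result.annotation.replicons.values()):,} bp, "
          f"{len(result.annotation.genes)} genes in {len(result.annotation.operons)} operons")
    print(f"probes: {len(result.probes):,} "
          f"({(result.probes.table['context'] == 'intergenic').sum():,} intergenic @4 bp, "
          f"{(result.probes.table['context'] == 'coding').sum():,} coding @30 bp)")
    print(f"planted: {len(truth.bound_regions)} fold-{cfg.sim.enrichment_fold:g} bound regions, "
          f"{len(truth.motif_sites)} motif sites, {len(truth.sigma54_sites)} sigma54 promoters")
    print(f"wrote bundle to {OUTDIR}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
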