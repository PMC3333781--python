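"""Spike-in recovery benchmark across seeds.

Runs the full pipeline at the default study conditions (fold 4, channel
noise 0.3, 10 planted regions, 20 randomizations) over ten seeds and on
matched signal-free null tracks, reporting per-stage recall/precision and
the high-confidence false-positive load. Writes
results/recovery_benchmark.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from dapmap.peaks import call_peaks, classify_peaks, estimate_fdr
from dapmap.pipeline import PipelineConfig, recovery_report, run_pipeline
from dapmap.simulate import SimParams, TruthSet, design_probes, generate_genome, simulate_dapchip_track

ROOT = Path(__file__).resolve().parent.parent / "results"
N_SEEDS = 10


def main() -> int:
    rows = []
    for seed in range(N_SEEDS):
        res = run_pipeline(PipelineConfig(seed=seed))
        rep = recovery_report(res)
        for _, r in rep.iterrows():
            rows.append({"seed": seed, **r})
    df = pd.DataFrame(rows)
    ROOT.mkdir(exist_ok=True)
    df.to_csv(ROOT / "recovery_benchmark.tsv", sep="\t", index=False)

    null_counts = []
    for seed in range(N_SEEDS):
        params = SimParams(seed=seed)
        ann, _ = generate_genome(params)
        probes = design_probes(ann)
        track = simulate_dapchip_track(probes, TruthSet(), params, seed=seed + 10_000)
        peaks = call_peaks(track)
        estimate_fdr(track, peaks, n_rand=20, seed=seed + 20_000)
        classify_peaks(peaks)
        null_counts.append(sum(p.confidence == "high" for p in peaks))

    summary = df.groupby("stage")[["recall", "precision"]].mean()
    print(f"mean over {N_SEEDS} seeds:")
    print(summary.round(3).to_string())
    print(f"null tracks: {np.mean(null_counts):.2f} high-confidence peaks/track "
          f"(counts: {null_counts})")
    print("note: peak-stage recall reflects the permutation-FDR ceiling "
          "discussed in docs/methods.md; targets recover via motif support")
    return 0


if __name__ == "__main__":
    sys.exit(main())
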