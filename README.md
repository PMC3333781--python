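# dapmap

Peak calling, target mapping and binding-site scanning for **DAP-chip**
experiments — in-vitro DNA-affinity purification of a bacterial response
regulator (RR) bound to sheared genomic DNA, read out on a two-colour
tiling microarray. The package reimplements the complete dry-lab side of
such a study for the two-component signal-transduction network of a
sulfate-reducing bacterium: from per-probe log2(enriched/input) ratios to a
curated list of regulated operons with binding-site motifs and σ54 promoter
predictions. A first-class synthetic-data generator plants ground truth
(bound regions, motif sites, promoters) so every stage can be benchmarked
without any array download.

## The method

**Peak calling.** Scaled log2R ratios are scanned with a 500-bp sliding
window for runs of more than four probes above a cutoff. The cutoff is a
percentage of the *hypothetical maximum* ratio,

> hmax = mean(log2R) + 6·sd(log2R),

stepped from 90% down to 15% in 1-point steps; windows sharing probes
merge. Each peak carries

- **score** — the log2R of its 4th-highest member probe,
- **cutoff_p** — the most stringent percentage at which it is detectable,
- **FDR** — from re-calling peaks on 20 within-replicon permutations of
  the ratio track: for a peak of score *s*,
  `fdr(s) = mean_r [#random peaks ≥ s] / [#observed peaks ≥ s]`.

FDR ≤ 0.05 marks a high-confidence binding site; up to 0.2 a candidate.

**Target mapping and curation.** Peaks are assigned to the upstream
intervals (≤ 300 bp, truncated at the neighbouring gene) of operon leaders.
Retained are upstream, high-confidence, non-promiscuous calls; peaks in
coding sequence, recurring across many RR datasets ("sticky" DNA), or of
low confidence are dropped *unless they carry a validated binding-site
motif*.

**Motifs and σ54 promoters.** Binding sites (typically 4–6-bp inverted
repeats with 3–8-bp spacers) are modelled as log2-odds position weight
matrices with a background-weighted pseudocount,
`w[i,b] = log2((n_ib + p·q_b) / (N + p) / q_b)`,
scanned over both strands; the σ54 (−24/−12) promoter element is handled as
one contiguous matrix. qPCR enrichment uses
`ΔCt = Ct(input) − Ct(enriched)`, `fold = 2^ΔCt`.

## Worked example

`analysis/` holds the numbered drivers of the full synthetic study; run
them in order from the repository root:

```bash
python analysis/01_simulate_experiment.py
python analysis/02_call_peaks.py
python analysis/03_scan_motifs.py
python analysis/04_map_targets.py
python analysis/05_qpcr_enrichment.py
python analysis/06_recovery_benchmark.py
```

Step 01 builds a 100-kb genome (100 genes in 35 operons, 3,895 probes) and
plants ten fold-4 bound regions. Step 02 then reports

```
hypothetical maximum log2R: 3.942 (15% cutoff = 0.591)
10 peaks called; 6 high-confidence (FDR <= 0.05)
  chr:65487-66723 score=2.47 cutoff_p=62 fdr=0.000 high
  chr:87327-88264 score=2.45 cutoff_p=61 fdr=0.000 high
  ...
```

— every planted promoter region yields a peak whose score sits near
log2(4) = 2 plus the upper order statistics of the channel noise, and the
strongest peaks are detectable already at 57–62% of hmax. Step 04 maps the
peaks onto operons and curates:

```
10 target calls from 10 peaks; 10 operons retained
planted targets recovered: 10/10; spurious: 0
  op025    upstream   fdr=0.000 motif=y -> kept (upstream high-confidence)
  op018    upstream   fdr=0.062 motif=y -> kept (motif rescue)
  ...
```

Peaks whose permutation FDR lands in the candidate band are rescued by the
planted motif — the same rule the curation applies to real data. Step 06
aggregates ten seeds: peak-stage recall 0.89 at a matched-null load of 0.20
high-confidence peaks per signal-free track, and target/motif/σ54 recovery
of 1.00 (see `docs/methods.md` for why peak-stage recall saturates below
1).

The same stages are available as a CLI
(`dapmap simulate|callpeaks|maptargets|scanmotif|scan54|qpcr|run`), e.g.

```bash
dapmap run --seed 1 --outdir results/run
```

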