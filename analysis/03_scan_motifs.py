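"""Build the regulator PWM, refine it, and scan upstream regions.

Starts from the planted (EMSA-validated, in the wet-lab analogy) binding
sites recorded in the truth sidecar, builds a log-odds PWM, extracts each
target's best-matching site and refines the matrix on the pooled set, then
scans every operon's upstream interval for the motif and for sigma54
(-24/-12) promoter elements. Writes motif.meme, motif_hits.tsv and
sigma54_hits.tsv under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from dapmap import io as dio
from dapmap.annotation import build_upstream_index
from dapmap.motifs import build_pwm, refine_motif, scan_sigma54, scan_sequence, sigma54_matrix, write_meme
from dapmap.pipeline import _write_hits
from dapmap.simulate import revcomp
from dapmap.motifs import scan_upstream_regions

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> int:
    exp = ROOT / "experiment"
    genome = dio.read_fasta(exp / "genome.fasta")
    annotation = dio.read_gff3(exp / "annotation.gff3")
    truth = dio.read_truth(exp / "truth.tsv", annotation)
    index = build_upstream_index(annotation)

    site_seqs = [s.sequence for s in truth.motif_sites]
    initial = build_pwm(site_seqs, name="rr_motif")
    extracted = []
    for site in truth.motif_sites:
        ivl = index[site.feature_id]
        region = genome[ivl.replicon][ivl.start : ivl.end]
        hits = scan_sequence(initial, region, initial.min_score, seq_id=site.feature_id)
        if hits:
            best = max(hits, key=lambda h: h.score)
            extracted.append(best.sequence if best.strand == "+" else revcomp(best.sequence))
    pwm = refine_motif(initial, extracted)
    write_meme([pwm], ROOT / "motif.meme")

    threshold = min(pwm.score(s) for s in site_seqs)
    motif_hits = scan_upstream_regions(pwm, genome, index, threshold)
    _write_hits(motif_hits, ROOT / "motif_hits.tsv")

    s54 = sigma54_matrix()
    s54_threshold = min(s54.score(s.sequence) for s in truth.sigma54_sites)
    sigma54_hits = scan_sigma54(s54, genome, index, s54_threshold)
    _write_hits(sigma54_hits, ROOT / "sigma54_hits.tsv")

    print(f"PWM: width {pwm.width}, {pwm.nsites} sites, consensus {pwm.consensus}")
    print(f"motif scan threshold {threshold:.2f} (max {pwm.max_score:.2f}): "
          f"{len(motif_hits)} hits in {len({h.feature for h in motif_hits})} upstream regions")
    print(f"sigma54 scan: {len(sigma54_hits)} predictions "
          f"({len({h.feature for h in sigma54_hits})} operons)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
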