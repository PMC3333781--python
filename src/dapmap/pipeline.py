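"""End-to-end orchestration: simulate -> ratios -> peaks -> FDR -> targets ->
motif and sigma54 scans, from a single declarative config.

In synthetic mode the pipeline builds its own genome, selects isolated
operon leaders as planted targets (their upstream intervals at least one
fragment length away from any other promoter-search interval, so enrichment
leaking off a bound region cannot reach a bystander's promoter), plants
binding-site motifs and sigma54 promoters, simulates the ratio track, and
runs the full analysis. Every output is a pure function of config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation, UpstreamIndex, build_upstream_index
from .motifs import MotifHit, PWM, build_pwm, pwm_from_consensus, refine_motif, scan_sequence, scan_sigma54, scan_upstream_regions, write_meme, SIGMA54_CONSENSUS
from .peaks import (
    DEFAULT_MIN_PROBES,
    DEFAULT_WINDOW,
    Peak,
    ProbeRatioTrack,
    call_peaks,
    classify_peaks,
    estimate_fdr,
)
from .qpcr import enrichment_decision, fold_enrichment
from .simulate import (
    BoundRegion,
    ProbeDesign,
    SimParams,
    TruthSet,
    design_probes,
    generate_genome,
    plant_motif_sites,
    plant_sigma54_promoters,
    simulate_dapchip_track,
    simulate_qpcr,
)
from .targets import TargetCall, curate_targets, map_peaks_to_targets

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "recovery_report", "select_isolated_targets"]

# the validated binding-site style used for planted regulator motifs: a 4-bp
# inverted repeat separated by a 4-bp spacer
DEFAULT_MOTIF_CONSENSUS = "GGCANNNNTGCC"


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    window: int = DEFAULT_WINDOW
    min_probes: int = DEFAULT_MIN_PROBES
    cutoff_start: int = 90
    cutoff_stop: int = 15
    cutoff_step: int = 1
    n_rand: int = 20
    fdr_high: float = 0.05
    fdr_candidate: float = 0.2
    motif_score_frac: float = 0.8
    min_fold: float = 2.0
    n_targets: int = 10
    n_sigma54: int = 3
    motif_consensus: str = DEFAULT_MOTIF_CONSENSUS
    sigma54_consensus: str = SIGMA54_CONSENSUS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_high <= self.fdr_candidate <= 1:
            raise ValueError("FDR bands must satisfy 0 < high <= candidate <= 1")
        if self.cutoff_stop > self.cutoff_start or self.cutoff_step < 1:
            raise ValueError("cutoff schedule must decrease from start to stop")
        if min(self.window, self.min_probes, self.n_rand, self.n_targets) < 1:
            raise ValueError("window, min_probes, n_rand, n_targets must be positive")
        if self.n_sigma54 > self.n_targets:
            raise ValueError("n_sigma54 cannot exceed n_targets")

    @property
    def schedule(self) -> tuple[int, ...]:
        return tuple(range(self.cutoff_start, self.cutoff_stop - 1, -self.cutoff_step))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        if isinstance(sim, dict):
            for key in ("operon_size", "gene_length", "intra_operon_gap", "intergenic_gap"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimParams(**sim)
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    config: PipelineConfig
    annotation: GenomeAnnotation
    genome: dict[str, str]
    probes: ProbeDesign
    upstream_index: UpstreamIndex
    truth: TruthSet
    track: ProbeRatioTrack
    peaks: list[Peak]
    calls: list[TargetCall]
    curated: list[TargetCall]
    motif_pwm: PWM | None
    motif_hits: list[MotifHit]
    sigma54_hits: list[MotifHit]
    top20: pd.DataFrame
    qpcr: dict
    manifest: dict


def select_isolated_targets(
    index: UpstreamIndex,
    n_targets: int,
    min_length: int = 100,
    min_isolation: int | None = None,
) -> list[str]:
    """Operon ids whose upstream intervals are long enough and farthest from
    every other promoter-search interval, most isolated first.

    Intervals overlapping another interval (shared divergent gaps) are
    excluded. Deterministic: ties break on feature id.
    """
    ivls = [iv for iv in index if iv.length >= min_length]
    chosen = []
    for iv in ivls:
        dmin = None
        overlap = False
        for other in index:
            if other.feature_id == iv.feature_id or other.length == 0:
                continue
            if other.replicon != iv.replicon:
                continue
            if other.start < iv.end and iv.start < other.end:
                overlap = True
                break
            d = other.start - iv.end if other.start >= iv.end else iv.start - other.end
            dmin = d if dmin is None else min(dmin, d)
        if overlap:
            continue
        chosen.append((-(dmin if dmin is not None else 10**9), iv.feature_id))
    chosen.sort()
    if min_isolation is not None:
        chosen = [c for c in chosen if -c[0] >= min_isolation]
    if len(chosen) < n_targets:
        raise ValueError(
            f"only {len(chosen)} sufficiently isolated upstream regions for {n_targets} targets; "
            "increase genome size or reduce n_targets"
        )
    return [fid for _negd, fid in chosen[:n_targets]]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic DAP-chip analysis; optionally write all outputs.

    Reruns with the same config are byte-identical: every random stream is
    seeded from ``config.seed`` with fixed offsets.
    """
    timings: dict[str, float] = {}
    current_stage = "setup"

    def _stage(name):
        nonlocal current_stage
        current_stage = name
        timings[name] = time.perf_counter()

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s: %.2fs", name, timings[name])

    seed = config.seed
    params = replace(config.sim, seed=seed)

    try:
        _stage("simulate")
        annotation, genome = generate_genome(params)
        probes = design_probes(annotation)
        index = build_upstream_index(annotation, cap=params.upstream_cap)
        target_ops = select_isolated_targets(
            index, config.n_targets,
            min_length=max(50, params.bound_region_width, 2 * len(config.motif_consensus)),
        )
        target_leaders = [index[op].leader_gene for op in target_ops]
        genome, sigma54_sites = plant_sigma54_promoters(
            genome, annotation, config.sigma54_consensus, target_leaders[: config.n_sigma54],
            seed=seed + 3, upstream_cap=params.upstream_cap, proximal=True,
        )
        genome, motif_sites = plant_motif_sites(
            genome, annotation, config.motif_consensus, target_leaders,
            seed=seed + 4, upstream_cap=params.upstream_cap, center=True,
        )
        # the bound region is the regulator-occupied stretch of the promoter:
        # bound_region_width bp centred on the planted site, clipped to the
        # upstream interval (a regulator footprint cannot extend into the
        # neighbouring coding sequence it regulates)
        bound = []
        for site in motif_sites[: params.n_bound_regions]:
            ivl = index[site.feature_id]
            mid = site.position + len(site.sequence) // 2
            half = params.bound_region_width // 2
            start = max(ivl.start, mid - half)
            end = min(ivl.end, mid - half + params.bound_region_width)
            bound.append(BoundRegion(replicon=ivl.replicon, start=start, end=end, fold=params.enrichment_fold))
        truth = TruthSet(bound_regions=bound, motif_sites=motif_sites, sigma54_sites=sigma54_sites)
        track = simulate_dapchip_track(probes, truth, params, seed=seed + 1)
        _done("simulate")

        _stage("qpcr")
        pos = simulate_qpcr(params.enrichment_fold, noise_sd=0.2, seed=seed + 5, target_id=target_ops[0])
        neg = simulate_qpcr(1.0, noise_sd=0.2, seed=seed + 6, target_id="negative_control")
        _dct_pos, fold_pos = fold_enrichment(pos)
        _dct_neg, fold_neg = fold_enrichment(neg)
        qpcr_result = {
            "positive_target": target_ops[0],
            "positive_fold": round(fold_pos, 4),
            "negative_fold": round(fold_neg, 4),
            "decision": enrichment_decision(fold_pos, fold_neg, config.min_fold),
        }
        _done("qpcr")

        _stage("peaks")
        peaks = call_peaks(track, window=config.window, min_probes=config.min_probes, schedule=config.schedule)
        estimate_fdr(track, peaks, n_rand=config.n_rand, seed=seed + 2,
                     window=config.window, min_probes=config.min_probes, schedule=config.schedule)
        classify_peaks(peaks, high=config.fdr_high, candidate=config.fdr_candidate)
        _done("peaks")

        _stage("targets")
        calls = map_peaks_to_targets(peaks, index, annotation)
        _done("targets")

        _stage("motifs")
        site_seqs = [s.sequence for s in motif_sites]
        initial_pwm = build_pwm(site_seqs, name="rr_motif")
        extracted = []
        for op in target_ops:
            ivl = index[op]
            region = genome[ivl.replicon][ivl.start : ivl.end]
            hits = scan_sequence(initial_pwm, region, initial_pwm.min_score, seq_id=op)
            if hits:
                best = max(hits, key=lambda h: h.score)
                seq = best.sequence if best.strand == "+" else _revcomp(best.sequence)
                extracted.append(seq)
        motif_pwm = refine_motif(initial_pwm, extracted)
        # threshold calibrated on the validated (planted) sites
        threshold = min(motif_pwm.score(s) for s in site_seqs)
        motif_hits = scan_upstream_regions(motif_pwm, genome, index, threshold)
        sigma54_pwm = pwm_from_consensus(config.sigma54_consensus, nsites=80, name="sigma54")
        s54_threshold = min(
            (sigma54_pwm.score(s.sequence) for s in sigma54_sites),
            default=sigma54_pwm.threshold(config.motif_score_frac),
        )
        sigma54_hits = scan_sigma54(sigma54_pwm, genome, index, s54_threshold)
        _done("motifs")

        _stage("curate")
        motif_intervals = [(h.seq_id, h.position, h.position + motif_pwm.width) for h in motif_hits]
        curated = curate_targets(calls, motif_hits=motif_intervals)
        top20 = _top_peaks_table(peaks, n=20)
        _done("curate")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{current_stage}' failed: {exc}") from exc

    manifest = {
        "package": "dapmap",
        "version": __version__,
        "seed": seed,
        "config": config.to_dict(),
        "qpcr": qpcr_result,
        "n_probes": len(probes),
        "n_peaks": len(peaks),
        "n_targets_retained": len({c.target_id for c in curated if c.retained}),
    }

    result = PipelineResult(
        config=config, annotation=annotation, genome=genome, probes=probes,
        upstream_index=index, truth=truth, track=track, peaks=peaks,
        calls=calls, curated=curated, motif_pwm=motif_pwm,
        motif_hits=motif_hits, sigma54_hits=sigma54_hits, top20=top20,
        qpcr=qpcr_result, manifest=manifest,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _revcomp(seq: str) -> str:
    from .simulate import revcomp

    return revcomp(seq)


def _top_peaks_table(peaks: list[Peak], n: int = 20) -> pd.DataFrame:
    rows = [
        {
            "rank": 0, "replicon": pk.replicon, "start": pk.start, "end": pk.end,
            "n_probes": pk.n_probes, "score": round(pk.score, 6), "cutoff_p": pk.cutoff_p,
            "fdr": None if pk.fdr is None else round(pk.fdr, 6), "confidence": pk.confidence,
        }
        for pk in sorted(peaks, key=lambda p: -p.score)[:n]
    ]
    df = pd.DataFrame(rows, columns=["rank", "replicon", "start", "end", "n_probes", "score", "cutoff_p", "fdr", "confidence"])
    df["rank"] = range(1, len(df) + 1)
    return df


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    from . import io as dio

    outdir.mkdir(parents=True, exist_ok=True)
    files = {
        "genome.fasta": lambda p: dio.write_fasta(result.genome, p),
        "annotation.gff3": lambda p: dio.write_gff3(result.annotation, p),
        "probes.bed": lambda p: dio.write_probes_bed(result.probes, p),
        "track.tsv": lambda p: dio.write_track_tab(result.track, p),
        "track.wig": lambda p: dio.write_wig(result.track, p),
        "truth.tsv": lambda p: dio.write_truth(result.truth, p),
        "peaks.bed": lambda p: dio.write_peaks_bed(result.peaks, p),
        "peaks.tsv": lambda p: dio.write_peaks_table(result.peaks, p),
        "targets.tsv": lambda p: dio.write_targets_table(result.curated, p),
        "top20_peaks.tsv": lambda p: result.top20.to_csv(p, sep="\t", index=False),
        "motif.meme": lambda p: write_meme([result.motif_pwm], p) if result.motif_pwm else None,
        "motif_hits.tsv": lambda p: _write_hits(result.motif_hits, p),
        "sigma54_hits.tsv": lambda p: _write_hits(result.sigma54_hits, p),
    }
    hashes = {}
    for name, writer in files.items():
        path = outdir / name
        writer(path)
        if path.exists():
            hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest = dict(result.manifest, outputs=hashes)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _write_hits(hits: list[MotifHit], path) -> None:
    pd.DataFrame(
        [
            {
                "replicon": h.seq_id, "position": h.position, "strand": h.strand,
                "score": round(h.score, 6), "sequence": h.sequence,
                "feature": h.feature or "", "kind": h.kind,
            }
            for h in hits
        ],
        columns=["replicon", "position", "strand", "score", "sequence", "feature", "kind"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# recovery against ground truth
# ---------------------------------------------------------------------------

def recovery_report(result: PipelineResult, truth: TruthSet | None = None) -> pd.DataFrame:
    """Per-stage recall/precision of planted features.

    Stages: high-confidence peaks vs bound regions, curated targets vs
    planted target features, motif scan hits vs planted motif sites,
    sigma54 predictions vs planted promoters. Precision is NaN when the
    truth set for a stage is empty.
    """
    truth = truth if truth is not None else result.truth
    rows = []

    high = [pk for pk in result.peaks if pk.confidence == "high"]

    def overlaps(pk, region):
        return pk.replicon == region.replicon and pk.start < region.end and region.start < pk.end

    recovered = sum(1 for r in truth.bound_regions if any(overlaps(pk, r) for pk in high))
    true_pos = sum(1 for pk in high if any(overlaps(pk, r) for r in truth.bound_regions))
    rows.append(_row("peaks", len(truth.bound_regions), recovered, len(high), true_pos))

    truth_targets = {s.feature_id for s in truth.motif_sites}
    called = {c.target_id for c in result.curated if c.retained}
    rows.append(_row("targets", len(truth_targets), len(truth_targets & called), len(called), len(called & truth_targets)))

    planted = {(s.replicon, s.position) for s in truth.motif_sites}
    hit_pos = {(h.seq_id, h.position) for h in result.motif_hits}
    rows.append(_row("motif_sites", len(planted), len(planted & hit_pos), len(hit_pos), len(hit_pos & planted)))

    planted54 = {(s.replicon, s.position) for s in truth.sigma54_sites}
    hit54 = {(h.seq_id, h.position) for h in result.sigma54_hits}
    rows.append(_row("sigma54_sites", len(planted54), len(planted54 & hit54), len(hit54), len(hit54 & planted54)))

    return pd.DataFrame(rows, columns=["stage", "n_truth", "n_recovered", "recall", "n_called", "n_false", "precision"])


def _row(stage: str, n_truth: int, n_recovered: int, n_called: int, n_true_pos: int) -> dict:
    return {
        "stage": stage,
        "n_truth": n_truth,
        "n_recovered": n_recovered,
        "recall": n_recovered / n_truth if n_truth else np.nan,
        "n_called": n_called,
        "n_false": n_called - n_true_pos,
        "precision": n_true_pos / n_called if n_called else np.nan,
    }
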