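"""Synthetic DAP-chip experiments with known ground truth.

The generator builds an operon-structured bacterial genome, tiles it with
50-mer probes the way the real array was designed (46-bp overlap between
intergenic probes, 20-bp overlap between coding probes), plants regulator
binding sites and sigma54 promoters into upstream regions, and simulates the
enriched/input log2 ratio track that affinity purification of sheared
(~500 bp) genomic fragments would produce over the bound loci.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, Operon, build_upstream_index

logger = logging.getLogger(__name__)

__all__ = [
    "SimParams",
    "ProbeDesign",
    "BoundRegion",
    "PlantedSite",
    "TruthSet",
    "generate_genome",
    "design_probes",
    "plant_motif_sites",
    "plant_sigma54_promoters",
    "fragment_overlap_weight",
    "expected_log2_ratio",
    "simulate_dapchip_track",
    "simulate_qpcr",
]

PROBE_LENGTH = 50
INTERGENIC_STEP = PROBE_LENGTH - 46  # 46-bp overlap between neighbouring probes
CODING_STEP = PROBE_LENGTH - 20  # 20-bp overlap

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT", "X": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNX", "TGCAYRSWMKVHDBNX")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic DAP-chip experiment.

    Lengths in bp; noise on the log2-ratio scale. Defaults describe a
    desk-scale bacterial chromosome: 100-kb replicon, 35 operons of 1-4
    genes (400-1200 bp each), operon-separating intergenic gaps of
    100-160 bp, near-contiguous genes within operons (5-40 bp spacers),
    80-bp regulator-occupied bound regions enriched 4-fold, fragments
    sheared to a 500-bp average, and channel noise of 0.3 on the log2
    scale.
    """

    genome_length: int = 100_000
    n_operons: int = 35
    operon_size: tuple[int, int] = (1, 4)
    gene_length: tuple[int, int] = (400, 1200)
    intra_operon_gap: tuple[int, int] = (5, 40)
    intergenic_gap: tuple[int, int] = (100, 160)
    upstream_cap: int = 300
    fragment_length: int = 500
    noise_sd: float = 0.3
    enrichment_fold: float = 4.0
    n_bound_regions: int = 10
    bound_region_width: int = 80
    gc: float = 0.5
    replicon_name: str = "chr"
    seed: int = 0

    def __post_init__(self) -> None:
        positives = [
            self.genome_length, self.upstream_cap, self.fragment_length,
            self.enrichment_fold, self.bound_region_width,
        ]
        if any(v <= 0 for v in positives):
            raise ValueError("all SimParams lengths/folds must be positive")
        if self.noise_sd < 0 or not 0 < self.gc < 1:
            raise ValueError("noise_sd must be >= 0 and gc in (0,1)")
        if self.n_operons < 0 or self.operon_size[0] < 1:
            raise ValueError("operon counts must be non-negative, sizes >= 1")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment fold must be >= 1")


@dataclass
class ProbeDesign:
    """Tiling probes sorted by (replicon, start); context is 'intergenic' or
    'coding', decided by the region the probe was tiled in."""

    table: pd.DataFrame  # columns: probe_id, replicon, start, length, context

    def __post_init__(self) -> None:
        required = {"probe_id", "replicon", "start", "length", "context"}
        if not required <= set(self.table.columns):
            raise ValueError(f"probe table missing columns {required - set(self.table.columns)}")
        self.table = self.table.sort_values(["replicon", "start"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class BoundRegion:
    replicon: str
    start: int
    end: int
    fold: float

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("enrichment fold must be >= 1")


@dataclass(frozen=True)
class PlantedSite:
    gene_id: str  # target gene (operon leader)
    feature_id: str  # operon id
    replicon: str
    position: int  # genomic 0-based start of the site
    strand: str
    sequence: str  # motif-strand sequence (reverse-complemented on '-')
    offset: int  # position relative to the leader's translational start (negative)


@dataclass
class TruthSet:
    bound_regions: list[BoundRegion] = field(default_factory=list)
    motif_sites: list[PlantedSite] = field(default_factory=list)
    sigma54_sites: list[PlantedSite] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def generate_genome(params: SimParams) -> tuple[GenomeAnnotation, dict[str, str]]:
    """Random operon-structured genome.

    Operons are laid left to right with intergenic gaps drawn from
    ``params.intergenic_gap``; each operon gets a random strand, and its gene
    list is returned in transcription order (reversed coordinates on '-').

    Raises ``ValueError`` if the requested operons do not fit.
    """
    rng = np.random.default_rng(params.seed)
    L = params.genome_length
    seq = _random_sequence(rng, L, params.gc)
    n = params.n_operons

    # draw the whole layout first, then absorb any leftover length into the
    # gene bodies so the replicon stays gene-dense end to end (intergenic
    # gaps keep their drawn sizes; bacterial genomes are mostly coding)
    gaps = [int(rng.integers(params.intergenic_gap[0], params.intergenic_gap[1] + 1)) for _ in range(n + 1)]
    structures = []
    for _ in range(n):
        n_genes = int(rng.integers(params.operon_size[0], params.operon_size[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        lengths = [int(rng.integers(params.gene_length[0], params.gene_length[1] + 1)) for _ in range(n_genes)]
        intra = [
            int(rng.integers(params.intra_operon_gap[0], params.intra_operon_gap[1] + 1))
            for _ in range(n_genes - 1)
        ]
        structures.append((strand, lengths, intra))
    span = sum(gaps) + sum(sum(lengths) + sum(intra) for _s, lengths, intra in structures)
    leftover = L - span
    if leftover < 0:
        raise ValueError(
            f"genome length {L} too short for {n} operons (layout needs {span} bp)"
        )
    total_genes = sum(len(lengths) for _s, lengths, _i in structures)
    if total_genes:
        extra, rem = divmod(leftover, total_genes)
        k = 0
        for _strand, lengths, _intra in structures:
            for j in range(len(lengths)):
                lengths[j] += extra + (1 if k < rem else 0)
                k += 1
    else:
        gaps[-1] += leftover

    genes: list[Gene] = []
    operons: list[Operon] = []
    pos = gaps[0]
    gi = 0
    for oi, (strand, lengths, intra) in enumerate(structures):
        members: list[Gene] = []
        for k, length in enumerate(lengths):
            gi += 1
            members.append(
                Gene(id=f"g{gi:04d}", replicon=params.replicon_name, start=pos, end=pos + length, strand=strand)
            )
            pos += length
            if k < len(lengths) - 1:
                pos += intra[k]
        ordered = members if strand == "+" else members[::-1]
        operons.append(Operon(id=f"op{oi + 1:03d}", gene_ids=tuple(g.id for g in ordered)))
        genes.extend(members)
        pos += gaps[oi + 1]

    annotation = GenomeAnnotation(replicons={params.replicon_name: L}, genes=genes, operons=operons)
    return annotation, {params.replicon_name: seq}


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


# ---------------------------------------------------------------------------
# probe design
# ---------------------------------------------------------------------------

def design_probes(annotation: GenomeAnnotation) -> ProbeDesign:
    """Tile every coding and intergenic region with 50-mers.

    Step is 4 bp in intergenic regions (46-bp overlap) and 30 bp in coding
    regions (20-bp overlap). The final probe of a region is shifted left so
    it still fits; regions shorter than 50 bp get no probes.
    """
    rows = []
    idx = 0
    for replicon, rep_len in annotation.replicons.items():
        spans = [(g.start, g.end) for g in annotation.genes_by_replicon(replicon)]
        regions: list[tuple[int, int, str]] = []
        cursor = 0
        for s, e in spans:
            if s > cursor:
                regions.append((cursor, s, "intergenic"))
            regions.append((s, e, "coding"))
            cursor = e
        if cursor < rep_len:
            regions.append((cursor, rep_len, "intergenic"))
        for rs, re_, context in regions:
            step = INTERGENIC_STEP if context == "intergenic" else CODING_STEP
            if re_ - rs < PROBE_LENGTH:
                continue
            starts = list(range(rs, re_ - PROBE_LENGTH + 1, step))
            last_fit = re_ - PROBE_LENGTH
            if starts[-1] != last_fit:
                starts.append(last_fit)
            for s in starts:
                idx += 1
                rows.append((f"P{idx:06d}", replicon, s, PROBE_LENGTH, context))
    table = pd.DataFrame(rows, columns=["probe_id", "replicon", "start", "length", "context"])
    return ProbeDesign(table=table)


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def _instantiate(rng: np.random.Generator, consensus: str) -> str:
    out = []
    for ch in consensus.upper():
        try:
            choices = _IUPAC[ch]
        except KeyError:
            raise ValueError(f"unsupported consensus character {ch!r}") from None
        out.append(choices[int(rng.integers(len(choices)))] if len(choices) > 1 else choices)
    return "".join(out)


def _plant_sites(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    consensus: str,
    target_genes: list[str],
    seed: int,
    upstream_cap: int = 300,
    center: bool = False,
) -> tuple[dict[str, str], list[PlantedSite]]:
    if not annotation.genes:
        raise ValueError("cannot plant sites: annotation has no genes")
    rng = np.random.default_rng(seed)
    index = build_upstream_index(annotation, cap=upstream_cap)
    by_gene = {ivl.leader_gene: ivl for ivl in index}
    width = len(consensus)
    mutable = {name: list(s) for name, s in genome.items()}
    sites: list[PlantedSite] = []
    for gene_id in target_genes:
        ivl = by_gene.get(gene_id)
        if ivl is None:
            op = annotation.operon_of(gene_id)
            if op is None:
                raise ValueError(f"gene {gene_id}: not an operon leader, no upstream region")
            ivl = index[op.id]
        if ivl.length < width:
            raise ValueError(
                f"gene {gene_id}: upstream region ({ivl.length} bp) shorter than motif ({width} bp)"
            )
        if center:
            pos = ivl.start + (ivl.length - width) // 2
        else:
            pos = int(rng.integers(ivl.start, ivl.end - width + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site_seq = _instantiate(rng, consensus)
        written = site_seq if strand == "+" else revcomp(site_seq)
        mutable[ivl.replicon][pos : pos + width] = list(written)
        leader = annotation.gene(ivl.leader_gene)
        offset = pos - leader.start if leader.strand == "+" else leader.end - (pos + width)
        sites.append(
            PlantedSite(
                gene_id=ivl.leader_gene,
                feature_id=ivl.feature_id,
                replicon=ivl.replicon,
                position=pos,
                strand=strand,
                sequence=site_seq,
                offset=offset,
            )
        )
    edited = {name: "".join(chars) for name, chars in mutable.items()}
    return edited, sites


def plant_motif_sites(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    motif_spec: str,
    target_genes: list[str],
    seed: int = 0,
    upstream_cap: int = 300,
    center: bool = False,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Write one instantiation of an IUPAC consensus into each target's
    upstream region, on a random strand, and record where it went."""
    return _plant_sites(genome, annotation, motif_spec, target_genes, seed, upstream_cap, center)


def plant_sigma54_promoters(
    genome: dict[str, str],
    annotation: GenomeAnnotation,
    consensus: str,
    target_genes: list[str],
    seed: int = 0,
    upstream_cap: int = 300,
    proximal: bool = False,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Plant sigma54 promoter consensus sites upstream of target genes.

    Promoters are written on the coding strand of the target (transcription
    requires the -24/-12 element in a fixed orientation relative to the
    gene). With ``proximal`` the site goes flush against the translational
    start instead of a random upstream position.
    """
    if not target_genes:
        return genome, []
    rng = np.random.default_rng(seed)
    index = build_upstream_index(annotation, cap=upstream_cap)
    by_gene = {ivl.leader_gene: ivl for ivl in index}
    width = len(consensus)
    mutable = {name: list(s) for name, s in genome.items()}
    sites: list[PlantedSite] = []
    for gene_id in target_genes:
        ivl = by_gene.get(gene_id)
        if ivl is None or ivl.length < width:
            raise ValueError(f"gene {gene_id}: no upstream room for a {width}-bp promoter")
        if proximal:
            pos = ivl.end - width if ivl.strand == "+" else ivl.start
        else:
            pos = int(rng.integers(ivl.start, ivl.end - width + 1))
        strand = annotation.gene(ivl.leader_gene).strand
        site_seq = _instantiate(rng, consensus)
        written = site_seq if strand == "+" else revcomp(site_seq)
        mutable[ivl.replicon][pos : pos + width] = list(written)
        leader = annotation.gene(ivl.leader_gene)
        offset = pos - leader.start if leader.strand == "+" else leader.end - (pos + width)
        sites.append(
            PlantedSite(
                gene_id=ivl.leader_gene,
                feature_id=ivl.feature_id,
                replicon=ivl.replicon,
                position=pos,
                strand=strand,
                sequence=site_seq,
                offset=offset,
            )
        )
    return {name: "".join(chars) for name, chars in mutable.items()}, sites


# ---------------------------------------------------------------------------
# ratio-track simulation
# ---------------------------------------------------------------------------

def fragment_overlap_weight(center: float, start: int, end: int, fragment_length: int = 500) -> float:
    """Fraction of mean-length fragments covering a probe centre that also
    overlap the bound region [start, end): a triangular kernel that is 1
    inside the region and decays to 0 over one fragment length outside it."""
    if start <= center < end:
        return 1.0
    d = start - center if center < start else center - end
    return max(0.0, 1.0 - d / fragment_length)


def expected_log2_ratio(
    probes: ProbeDesign, truth: TruthSet, params: SimParams
) -> np.ndarray:
    """Noise-free expected log2(enriched/input) per probe, before centring.

    Enrichment contributed by each bound region is (fold-1)*w with w the
    fragment-overlap weight at the probe centre; contributions add.
    """
    t = probes.table
    centers = t["start"].to_numpy(float) + t["length"].to_numpy(float) / 2.0
    excess = np.zeros(len(t))
    rep = t["replicon"].to_numpy()
    for region in truth.bound_regions:
        mask = rep == region.replicon
        if not mask.any():
            continue
        c = centers[mask]
        w = np.where(
            (c >= region.start) & (c < region.end),
            1.0,
            np.maximum(0.0, 1.0 - np.where(c < region.start, region.start - c, c - region.end) / params.fragment_length),
        )
        excess[mask] += (region.fold - 1.0) * w
    return np.log2(1.0 + excess)


def simulate_dapchip_track(
    probes: ProbeDesign,
    truth: TruthSet,
    params: SimParams,
    seed: int | None = None,
    return_intensities: bool = False,
):
    """Simulated median-centred log2-ratio track over a probe design.

    With ``return_intensities`` the raw two-channel intensities are also
    returned (log-normal input channel; enriched = input * 2**signal+noise),
    so the ratio-computation step can be exercised end to end.
    """
    from .peaks import ProbeRatioTrack, compute_log2_ratios

    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    expected = expected_log2_ratio(probes, truth, params)
    noise = rng.normal(0.0, params.noise_sd, size=len(expected)) if params.noise_sd > 0 else np.zeros_like(expected)
    log2r = expected + noise
    t = probes.table
    if return_intensities:
        input_ch = np.exp(rng.normal(np.log(1000.0), 0.3, size=len(expected)))
        enriched_ch = input_ch * np.power(2.0, log2r)
        track = compute_log2_ratios(probes, enriched_ch, input_ch)
        return track, enriched_ch, input_ch
    centered = log2r - np.median(log2r)
    return ProbeRatioTrack.from_arrays(
        probe_id=t["probe_id"].to_numpy(),
        replicon=t["replicon"].to_numpy(),
        start=t["start"].to_numpy(int),
        length=t["length"].to_numpy(int),
        log2r=centered,
    )


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(
    fold: float,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    input_ct: float = 25.0,
    target_id: str = "target",
):
    """Triplicate Ct values for input and enriched fractions of a locus
    enriched ``fold``-fold: enriched Ct = input Ct - log2(fold) + noise."""
    from .qpcr import QpcrMeasurement

    if fold <= 0:
        raise ValueError("fold must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    inp = input_ct + rng.normal(0.0, noise_sd, size=n_replicates)
    enr = input_ct - np.log2(fold) + rng.normal(0.0, noise_sd, size=n_replicates)
    return QpcrMeasurement(target_id=target_id, input_ct=tuple(inp), enriched_ct=tuple(enr))
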