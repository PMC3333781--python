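"""Peak-to-gene target mapping and curation.

Peaks are mapped to the upstream (promoter-search) intervals of operon
leaders; peaks wholly inside a gene body are flagged as coding, and peaks
in divergent intergenic regions are assigned to both flanking features.
Curation then applies the mechanical retention rules: keep upstream,
high-confidence, non-promiscuous calls, and rescue anything — coding peaks
included — that carries a validated binding-site motif.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .annotation import GenomeAnnotation, UpstreamIndex, build_upstream_index
from .peaks import Peak

__all__ = [
    "TargetCall",
    "build_upstream_index",
    "map_peaks_to_targets",
    "pool_replicates",
    "curate_targets",
    "DEFAULT_PROMISCUITY_LIMIT",
]

# a peak interval recurring in this many distinct RR datasets is treated as
# promiscuous ("sticky") DNA rather than a specific target
DEFAULT_PROMISCUITY_LIMIT = 3


@dataclass(frozen=True)
class TargetCall:
    peak: Peak
    target_id: str | None  # operon id (upstream calls) or gene id (coding calls)
    genes: tuple[str, ...]  # all genes reported for the target (operon members)
    relation: str  # upstream | coding | intergenic-unassigned
    motif_support: bool = False
    n_datasets: int = 1
    retained: bool | None = None
    reason: str | None = None


def map_peaks_to_targets(
    peaks: list[Peak],
    index: UpstreamIndex,
    annotation: GenomeAnnotation,
) -> list[TargetCall]:
    """One TargetCall per (peak, feature) relation.

    A peak overlapping an upstream interval yields an upstream call for that
    operon (one call per feature when a divergent region is shared); a peak
    wholly within a gene span yields a coding call; anything else is
    intergenic-unassigned.
    """
    calls: list[TargetCall] = []
    ops_by_id = {op.id: op for op in annotation.operons}
    for pk in peaks:
        if pk.replicon not in annotation.replicons:
            raise ValueError(f"peak on unknown replicon {pk.replicon!r}")
        hits = index.overlapping(pk.replicon, pk.start, pk.end)
        if hits:
            for ivl in sorted(hits, key=lambda v: v.start):
                genes = ops_by_id[ivl.feature_id].gene_ids if ivl.feature_id in ops_by_id else (ivl.leader_gene,)
                calls.append(TargetCall(peak=pk, target_id=ivl.feature_id, genes=genes, relation="upstream"))
            continue
        host = next(
            (g for g in annotation.genes_by_replicon(pk.replicon) if g.start <= pk.start and pk.end <= g.end),
            None,
        )
        if host is not None:
            calls.append(TargetCall(peak=pk, target_id=host.id, genes=(host.id,), relation="coding"))
        else:
            calls.append(TargetCall(peak=pk, target_id=None, genes=(), relation="intergenic-unassigned"))
    return calls


def pool_replicates(peak_lists: list[list[TargetCall]]) -> list[TargetCall]:
    """Common hits across replicate DAP-chip runs.

    Targets are keyed by feature id (replicate peak boundaries jitter); only
    features called in every replicate are retained. A single list passes
    through unchanged.
    """
    if not peak_lists:
        raise ValueError("need at least one replicate call list")
    if len(peak_lists) == 1:
        return list(peak_lists[0])
    common = set.intersection(
        *({c.target_id for c in calls if c.target_id is not None} for calls in peak_lists)
    )
    return [c for c in peak_lists[0] if c.target_id in common]


def _overlaps(peak: Peak, intervals) -> bool:
    return any(
        r == peak.replicon and s < peak.end and peak.start < e for r, s, e in intervals
    )


def curate_targets(
    calls: list[TargetCall],
    motif_hits=None,
    cross_dataset_counts: dict[str, int] | None = None,
    promiscuity_limit: int = DEFAULT_PROMISCUITY_LIMIT,
) -> list[TargetCall]:
    """Apply the mechanical retention rules, recording a reason per call.

    ``motif_hits`` is an iterable of (replicon, start, end) intervals of
    validated binding-site motif occurrences; a call whose peak overlaps one
    gains motif support. ``cross_dataset_counts`` maps target feature id to
    the number of RR datasets whose peak lists contain it.

    Retain iff (relation is upstream AND confidence is high AND the target
    appears in at most ``promiscuity_limit`` datasets) OR the call has motif
    support.
    """
    motif_intervals = [tuple(iv) for iv in (motif_hits or [])]
    counts = cross_dataset_counts or {}
    curated: list[TargetCall] = []
    for call in calls:
        n_datasets = counts.get(call.target_id, call.n_datasets)
        motif = call.motif_support or _overlaps(call.peak, motif_intervals)
        confidence = call.peak.confidence
        specific = call.relation == "upstream" and confidence == "high" and n_datasets <= promiscuity_limit
        if specific:
            retained, reason = True, "upstream high-confidence"
        elif motif:
            retained, reason = True, "motif rescue"
        elif call.relation == "coding":
            retained, reason = False, "coding region"
        elif call.relation != "upstream":
            retained, reason = False, "unassigned"
        elif n_datasets > promiscuity_limit:
            retained, reason = False, "promiscuous"
        else:
            retained, reason = False, "low confidence"
        curated.append(
            replace(call, motif_support=motif, n_datasets=n_datasets, retained=retained, reason=reason)
        )
    return curated
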