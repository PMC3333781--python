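"""Genome annotation containers: replicons, genes, operons, upstream regions.

Coordinates are 0-based half-open throughout, matching BED conventions.
Operons are ordered in transcription order, so the first gene of an operon
is its leader — the gene whose upstream intergenic sequence carries the
promoter and any regulator binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Gene",
    "Operon",
    "GenomeAnnotation",
    "UpstreamInterval",
    "UpstreamIndex",
    "build_upstream_index",
]


@dataclass(frozen=True)
class Gene:
    id: str
    replicon: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.id}: invalid interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Operon:
    id: str
    gene_ids: tuple[str, ...]  # transcription order; first gene is the leader

    @property
    def leader(self) -> str:
        return self.gene_ids[0]


@dataclass
class GenomeAnnotation:
    """Replicon sizes plus non-overlapping genes grouped into co-stranded operons."""

    replicons: dict[str, int]
    genes: list[Gene] = field(default_factory=list)
    operons: list[Operon] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        by_id = {}
        for g in self.genes:
            if g.id in by_id:
                raise ValueError(f"duplicate gene id {g.id}")
            if g.replicon not in self.replicons:
                raise ValueError(f"gene {g.id}: unknown replicon {g.replicon}")
            if g.end > self.replicons[g.replicon]:
                raise ValueError(f"gene {g.id}: exceeds replicon bounds")
            by_id[g.id] = g
        for name in self.replicons:
            spans = sorted((g.start, g.end) for g in self.genes if g.replicon == name)
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping genes on {name} near {s2}")
        seen: set[str] = set()
        for op in self.operons:
            members = [by_id[i] for i in op.gene_ids]
            if len({g.strand for g in members}) != 1:
                raise ValueError(f"operon {op.id}: genes not co-stranded")
            if len({g.replicon for g in members}) != 1:
                raise ValueError(f"operon {op.id}: genes on multiple replicons")
            if seen & set(op.gene_ids):
                raise ValueError(f"operon {op.id}: gene assigned to two operons")
            seen |= set(op.gene_ids)
            # transcription order must be contiguous on the genome: coordinate
            # order for + operons, reverse coordinate order for - operons
            coords = [g.start for g in members]
            ordered = coords == sorted(coords) if members[0].strand == "+" else coords == sorted(coords, reverse=True)
            if not ordered:
                raise ValueError(f"operon {op.id}: genes not in transcription order")

    # -- lookups -------------------------------------------------------------

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def operon_of(self, gene_id: str) -> Operon | None:
        for op in self.operons:
            if gene_id in op.gene_ids:
                return op
        return None

    def genes_by_replicon(self, replicon: str) -> list[Gene]:
        return sorted((g for g in self.genes if g.replicon == replicon), key=lambda g: g.start)

    @property
    def leaders(self) -> dict[str, Gene]:
        """Operon id -> leader gene."""
        by_id = {g.id: g for g in self.genes}
        return {op.id: by_id[op.leader] for op in self.operons}


@dataclass(frozen=True)
class UpstreamInterval:
    feature_id: str  # operon id
    leader_gene: str
    replicon: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UpstreamIndex:
    """Promoter-search intervals: up to `cap` bp 5' of each operon leader,
    truncated at the nearest neighbouring gene."""

    intervals: dict[str, UpstreamInterval]
    cap: int = 300

    def __iter__(self):
        return iter(self.intervals.values())

    def __getitem__(self, feature_id: str) -> UpstreamInterval:
        return self.intervals[feature_id]

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, replicon: str, start: int, end: int) -> list[UpstreamInterval]:
        return [
            ivl
            for ivl in self.intervals.values()
            if ivl.replicon == replicon and ivl.start < end and start < ivl.end and ivl.length > 0
        ]


def build_upstream_index(annotation: GenomeAnnotation, cap: int = 300) -> UpstreamIndex:
    """Upstream interval per operon leader.

    + strand leader at [s, e): interval [max(prev_gene_end, s - cap), s).
    - strand leader at [s, e): interval [e, min(next_gene_start, e + cap)).
    A leader flush against the replicon edge gets an empty interval.
    """
    intervals: dict[str, UpstreamInterval] = {}
    leaders = annotation.leaders
    for op_id, leader in leaders.items():
        neighbours = annotation.genes_by_replicon(leader.replicon)
        if leader.strand == "+":
            prev_end = max((g.end for g in neighbours if g.end <= leader.start and g.id != leader.id), default=0)
            start = max(prev_end, leader.start - cap)
            end = leader.start
        else:
            rep_len = annotation.replicons[leader.replicon]
            next_start = min(
                (g.start for g in neighbours if g.start >= leader.end and g.id != leader.id), default=rep_len
            )
            start = leader.end
            end = min(next_start, leader.end + cap)
        intervals[op_id] = UpstreamInterval(
            feature_id=op_id,
            leader_gene=leader.id,
            replicon=leader.replicon,
            start=start,
            end=max(start, end),
            strand=leader.strand,
        )
    return UpstreamIndex(intervals=intervals, cap=cap)
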