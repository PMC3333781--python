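"""Readers and writers for the standard formats the pipeline exchanges.

FASTA via Biopython, GFF3 via gffutils (in-memory db) on the way in and a
plain writer on the way out, BED for probes and peaks, variableStep WIG and
tab-delimited tables for ratio tracks, and tab-delimited truth/target/qPCR
tables. All coordinates are 0-based half-open internally; GFF3 and WIG are
converted to their 1-based conventions at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import Gene, GenomeAnnotation, Operon
from .peaks import Peak, ProbeRatioTrack
from .simulate import BoundRegion, PlantedSite, ProbeDesign, TruthSet

__all__ = [
    "write_fasta", "read_fasta",
    "write_gff3", "read_gff3",
    "write_probes_bed", "read_probes_bed",
    "write_track_tab", "read_track_tab",
    "write_wig", "read_wig",
    "write_peaks_bed", "write_peaks_table", "read_peaks_table",
    "write_targets_table", "write_truth", "read_truth",
]


# -- FASTA ------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# -- GFF3 -------------------------------------------------------------------

def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Genes as gene features (1-based inclusive), operon id as an attribute."""
    op_of = {gid: op.id for op in annotation.operons for gid in op.gene_ids}
    lines = ["##gff-version 3"]
    for name, length in sorted(annotation.replicons.items()):
        lines.append(f"##sequence-region {name} 1 {length}")
    for g in sorted(annotation.genes, key=lambda g: (g.replicon, g.start)):
        attrs = f"ID={g.id}"
        if g.id in op_of:
            attrs += f";operon={op_of[g.id]}"
        lines.append(
            "\t".join([g.replicon, "dapmap", "gene", str(g.start + 1), str(g.end), ".", g.strand, ".", attrs])
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> GenomeAnnotation:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True, keep_order=True)
    replicons: dict[str, int] = {}
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            _, name, _one, end = directive.split()
            replicons[name] = int(end)
    genes: list[Gene] = []
    operon_members: dict[str, list[tuple[int, str, str]]] = {}
    for feat in db.features_of_type("gene"):
        gid = feat.attributes["ID"][0]
        genes.append(Gene(id=gid, replicon=feat.seqid, start=feat.start - 1, end=feat.end, strand=feat.strand))
        if "operon" in feat.attributes:
            operon_members.setdefault(feat.attributes["operon"][0], []).append((feat.start - 1, feat.strand, gid))
    if not replicons:
        replicons = {g.replicon: max(x.end for x in genes if x.replicon == g.replicon) for g in genes}
    operons = []
    for op_id, members in sorted(operon_members.items()):
        members.sort()
        if members[0][1] == "-":
            members = members[::-1]
        operons.append(Operon(id=op_id, gene_ids=tuple(gid for _s, _st, gid in members)))
    return GenomeAnnotation(replicons=replicons, genes=genes, operons=operons)


# -- probes -----------------------------------------------------------------

def write_probes_bed(probes: ProbeDesign, path) -> None:
    df = probes.table
    bed = pd.DataFrame(
        {
            "chrom": df["replicon"],
            "start": df["start"],
            "end": df["start"] + df["length"],
            "name": df["probe_id"],
            "score": 0,
            "strand": ".",
            "context": df["context"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_probes_bed(path) -> ProbeDesign:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "context"],
    )
    return ProbeDesign(
        table=pd.DataFrame(
            {
                "probe_id": bed["name"],
                "replicon": bed["chrom"],
                "start": bed["start"],
                "length": bed["end"] - bed["start"],
                "context": bed["context"].fillna("intergenic"),
            }
        )
    )


# -- ratio tracks -----------------------------------------------------------

def write_track_tab(track: ProbeRatioTrack, path) -> None:
    df = track.to_dataframe()
    df["log2r"] = df["log2r"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_track_tab(path) -> ProbeRatioTrack:
    return ProbeRatioTrack.from_dataframe(pd.read_csv(path, sep="\t"))


def write_wig(track: ProbeRatioTrack, path, name: str = "log2R") -> None:
    """variableStep WIG (1-based positions, span = probe length)."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for rep, sl in track.replicon_slices().items():
            span = int(track.length[sl][0])
            fh.write(f"variableStep chrom={rep} span={span}\n")
            for s, v in zip(track.start[sl], track.log2r[sl]):
                fh.write(f"{int(s) + 1} {v:.6f}\n")


def read_wig(track_probes: ProbeDesign, path) -> ProbeRatioTrack:
    """Read a variableStep WIG written by ``write_wig`` back onto a design."""
    values: dict[tuple[str, int], float] = {}
    chrom = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                continue
            if line.startswith("variableStep"):
                chrom = dict(tok.split("=") for tok in line.split()[1:])["chrom"]
                continue
            pos, val = line.split()
            values[(chrom, int(pos) - 1)] = float(val)
    t = track_probes.table
    log2r = np.array([values[(r, int(s))] for r, s in zip(t["replicon"], t["start"])])
    return ProbeRatioTrack.from_arrays(
        probe_id=t["probe_id"].to_numpy(), replicon=t["replicon"].to_numpy(),
        start=t["start"].to_numpy(int), length=t["length"].to_numpy(int), log2r=log2r,
    )


# -- peaks ------------------------------------------------------------------

def write_peaks_bed(peaks: list[Peak], path) -> None:
    """BED5 with score = peak score x 100, capped at 1000."""
    with open(path, "w") as fh:
        for i, pk in enumerate(peaks, 1):
            score = min(1000, max(0, int(round(pk.score * 100))))
            fh.write(f"{pk.replicon}\t{pk.start}\t{pk.end}\tpeak{i:04d}\t{score}\n")


def write_peaks_table(peaks: list[Peak], path) -> None:
    rows = [
        {
            "replicon": pk.replicon, "start": pk.start, "end": pk.end,
            "n_probes": pk.n_probes, "score": round(pk.score, 6),
            "cutoff_p": pk.cutoff_p,
            "fdr": "" if pk.fdr is None else round(pk.fdr, 6),
            "confidence": pk.confidence or "",
            "probes": ",".join(pk.probe_ids),
        }
        for pk in peaks
    ]
    pd.DataFrame(
        rows, columns=["replicon", "start", "end", "n_probes", "score", "cutoff_p", "fdr", "confidence", "probes"]
    ).to_csv(path, sep="\t", index=False)


def read_peaks_table(path, track: ProbeRatioTrack | None = None) -> list[Peak]:
    df = pd.read_csv(path, sep="\t")
    id_to_idx = (
        {pid: i for i, pid in enumerate(track.probe_id)} if track is not None else {}
    )
    peaks = []
    for _, row in df.iterrows():
        probe_ids = tuple(str(row["probes"]).split(","))
        peaks.append(
            Peak(
                replicon=str(row["replicon"]), start=int(row["start"]), end=int(row["end"]),
                member_idx=tuple(id_to_idx[p] for p in probe_ids if p in id_to_idx),
                probe_ids=probe_ids, score=float(row["score"]), cutoff_p=int(row["cutoff_p"]),
                fdr=None if pd.isna(row["fdr"]) else float(row["fdr"]),
                confidence=None if pd.isna(row["confidence"]) else str(row["confidence"]),
            )
        )
    return peaks


# -- targets & truth --------------------------------------------------------

def write_targets_table(calls, path, rr_id: str = "RR") -> None:
    rows = [
        {
            "rr": rr_id,
            "target": c.target_id or "",
            "genes": ",".join(c.genes),
            "relation": c.relation,
            "peak_start": c.peak.start,
            "peak_end": c.peak.end,
            "score": round(c.peak.score, 6),
            "cutoff_p": c.peak.cutoff_p,
            "fdr": "" if c.peak.fdr is None else round(c.peak.fdr, 6),
            "motif_support": int(c.motif_support),
            "n_datasets": c.n_datasets,
            "retained": "" if c.retained is None else int(c.retained),
            "reason": c.reason or "",
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=[
            "rr", "target", "genes", "relation", "peak_start", "peak_end",
            "score", "cutoff_p", "fdr", "motif_support", "n_datasets", "retained", "reason",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthSet, path) -> None:
    rows = []
    for r in truth.bound_regions:
        rows.append({"kind": "bound_region", "replicon": r.replicon, "start": r.start,
                     "end": r.end, "value": r.fold, "feature": "", "strand": "", "sequence": ""})
    for kind, sites in (("motif_site", truth.motif_sites), ("sigma54_site", truth.sigma54_sites)):
        for s in sites:
            rows.append({"kind": kind, "replicon": s.replicon, "start": s.position,
                         "end": s.position + len(s.sequence), "value": s.offset,
                         "feature": s.feature_id, "strand": s.strand, "sequence": s.sequence})
    pd.DataFrame(rows, columns=["kind", "replicon", "start", "end", "value", "feature", "strand", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_truth(path, annotation: GenomeAnnotation | None = None) -> TruthSet:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    truth = TruthSet()
    leaders = {op.id: op.leader for op in annotation.operons} if annotation else {}
    for _, row in df.iterrows():
        if row["kind"] == "bound_region":
            truth.bound_regions.append(
                BoundRegion(replicon=row["replicon"], start=int(row["start"]), end=int(row["end"]), fold=float(row["value"]))
            )
        else:
            site = PlantedSite(
                gene_id=leaders.get(row["feature"], ""), feature_id=row["feature"],
                replicon=row["replicon"], position=int(row["start"]), strand=row["strand"],
                sequence=row["sequence"], offset=int(float(row["value"])),
            )
            (truth.motif_sites if row["kind"] == "motif_site" else truth.sigma54_sites).append(site)
    return truth
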