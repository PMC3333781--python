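"""Tiling-array peak calling with a stepped-cutoff schedule and permutation FDR.

The detection rule mirrors the vendor analysis of two-colour tiling arrays:
scaled log2 ratios are scanned with a 500-bp sliding window for runs of more
than four probes above a cutoff; the cutoff is a percentage of the
"hypothetical maximum" ratio (mean + 6 sd of the track) stepped from 90%
down to 15% in 1-point steps. Each final peak carries the log2 ratio of its
4th-highest probe as its score, the most stringent cutoff percentage at
which it was detectable (cutoff_p), and a false-discovery estimate from
re-calling peaks on 20 within-replicon permutations of the ratio track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProbeRatioTrack",
    "Detection",
    "Peak",
    "compute_log2_ratios",
    "hypothetical_max",
    "detect_peaks_at_cutoff",
    "call_peaks",
    "estimate_fdr",
    "classify_confidence",
    "classify_peaks",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_PROBES",
    "DEFAULT_SCHEDULE",
    "FDR_HIGH",
    "FDR_CANDIDATE",
]

DEFAULT_WINDOW = 500  # bp, sliding-window span constraint
DEFAULT_MIN_PROBES = 5  # "more than four probes"
DEFAULT_SCHEDULE = tuple(range(90, 14, -1))  # percent of hypothetical max
FDR_HIGH = 0.05
FDR_CANDIDATE = 0.2


@dataclass
class ProbeRatioTrack:
    """Ordered probes with scaled log2(enriched/input) values.

    Sorted by (replicon, start); values must be finite.
    """

    probe_id: np.ndarray
    replicon: np.ndarray
    start: np.ndarray
    length: np.ndarray
    log2r: np.ndarray

    def __post_init__(self) -> None:
        order = np.lexsort((self.start, self.replicon))
        for name in ("probe_id", "replicon", "start", "length", "log2r"):
            setattr(self, name, np.asarray(getattr(self, name))[order])
        self.start = self.start.astype(np.int64)
        self.length = self.length.astype(np.int64)
        self.log2r = self.log2r.astype(np.float64)
        if not np.all(np.isfinite(self.log2r)):
            raise ValueError("log2R values must be finite")
        # contiguous index ranges per replicon (track is sorted)
        self._slices: dict[str, slice] = {}
        names, starts_idx = np.unique(self.replicon, return_index=True)
        bounds = np.append(np.sort(starts_idx), len(self.replicon))
        for name, lo, hi in zip(names[np.argsort(starts_idx)], np.sort(starts_idx), bounds[1:]):
            self._slices[str(name)] = slice(int(lo), int(hi))

    @classmethod
    def from_arrays(cls, probe_id, replicon, start, length, log2r) -> "ProbeRatioTrack":
        return cls(
            probe_id=np.asarray(probe_id),
            replicon=np.asarray(replicon),
            start=np.asarray(start),
            length=np.asarray(length),
            log2r=np.asarray(log2r, dtype=float),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ProbeRatioTrack":
        return cls.from_arrays(df["probe_id"], df["replicon"], df["start"], df["length"], df["log2r"])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": self.probe_id,
                "replicon": self.replicon,
                "start": self.start,
                "length": self.length,
                "log2r": self.log2r,
            }
        )

    def __len__(self) -> int:
        return len(self.log2r)

    def replicon_slices(self) -> dict[str, slice]:
        return dict(self._slices)

    def with_values(self, log2r: np.ndarray) -> "ProbeRatioTrack":
        return ProbeRatioTrack(
            probe_id=self.probe_id,
            replicon=self.replicon,
            start=self.start,
            length=self.length,
            log2r=np.asarray(log2r, dtype=float),
        )


@dataclass(frozen=True)
class Detection:
    """A raw detection at one cutoff: a maximal run of in-peak probes."""

    replicon: str
    start: int
    end: int
    member_idx: tuple[int, ...]  # indices into the track


@dataclass
class Peak:
    replicon: str
    start: int
    end: int
    member_idx: tuple[int, ...]
    probe_ids: tuple[str, ...]
    score: float  # log2R of the 4th-highest member probe
    cutoff_p: int  # most stringent percent cutoff detecting this peak
    fdr: float | None = None
    confidence: str | None = None

    @property
    def n_probes(self) -> int:
        return len(self.member_idx)


def compute_log2_ratios(probes, enriched: np.ndarray, input_: np.ndarray) -> ProbeRatioTrack:
    """Scaled log2(enriched/input) per probe, median-centred across the track.

    ``probes`` is a ProbeDesign or a DataFrame with probe_id/replicon/
    start/length columns, in the same order as the intensity arrays.
    """
    table = probes.table if hasattr(probes, "table") else probes
    enriched = np.asarray(enriched, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if len(enriched) != len(table) or len(input_) != len(table):
        raise ValueError("channel arrays and probe table must have equal length")
    bad = np.nonzero((enriched <= 0) | (input_ <= 0))[0]
    if bad.size:
        pid = table["probe_id"].iloc[int(bad[0])]
        raise ValueError(f"non-positive intensity at probe {pid}")
    ratios = np.log2(enriched / input_)
    ratios = ratios - np.median(ratios)
    return ProbeRatioTrack.from_arrays(
        probe_id=table["probe_id"].to_numpy(),
        replicon=table["replicon"].to_numpy(),
        start=table["start"].to_numpy(int),
        length=table["length"].to_numpy(int),
        log2r=ratios,
    )


def hypothetical_max(track: ProbeRatioTrack | np.ndarray) -> float:
    """Hypothetical maximum log2R ratio: mean + 6 sample standard deviations."""
    values = track.log2r if isinstance(track, ProbeRatioTrack) else np.asarray(track, float)
    if values.size < 2:
        raise ValueError("hypothetical maximum needs at least 2 probes")
    return float(values.mean() + 6.0 * values.std(ddof=1))


def _detect_in_replicon(
    starts: np.ndarray,
    lengths: np.ndarray,
    values: np.ndarray,
    cutoff_value: float,
    window: int,
    min_probes: int,
) -> list[tuple[int, int, np.ndarray]]:
    """Peak intervals among qualifying probes of one replicon.

    A probe qualifies if its value >= cutoff. Every window of `min_probes`
    consecutive qualifying probes whose genomic span (last start + last
    length - first start) <= `window` is a raw detection; windows sharing a
    probe merge, and each merged component becomes one peak whose members
    are the qualifying probes its windows cover.
    """
    qidx = np.nonzero(values >= cutoff_value)[0]
    n = qidx.size
    if n < min_probes:
        return []
    first = starts[qidx[: n - min_probes + 1]]
    last = qidx[min_probes - 1 :]
    span = starts[last] + lengths[last] - first
    ok = np.nonzero(span <= window)[0]
    if ok.size == 0:
        return []
    # merge overlapping windows: window i covers qualifying indices
    # i..i+min_probes-1, so windows share a probe iff their start indices
    # differ by < min_probes; connected components become peaks
    breaks = np.nonzero(np.diff(ok) >= min_probes)[0] + 1
    out = []
    for grp in np.split(ok, breaks):
        members = qidx[grp[0] : grp[-1] + min_probes]
        out.append((int(starts[members[0]]), int(starts[members[-1]] + lengths[members[-1]]), members))
    return out


def detect_peaks_at_cutoff(
    track: ProbeRatioTrack,
    cutoff_value: float,
    window: int = DEFAULT_WINDOW,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> list[Detection]:
    """All peak intervals at one absolute cutoff value (per replicon).

    A peak is a region of enrichment, so only positive cutoffs can detect
    one: with cutoff_value <= 0 (e.g. a constant centred track, hmax = 0)
    nothing is returned.
    """
    if cutoff_value <= 0:
        return []
    detections: list[Detection] = []
    for rep, sl in track.replicon_slices().items():
        runs = _detect_in_replicon(
            track.start[sl], track.length[sl], track.log2r[sl], cutoff_value, window, min_probes
        )
        for s, e, members in runs:
            detections.append(Detection(replicon=rep, start=s, end=e, member_idx=tuple(int(m) + sl.start for m in members)))
    return detections


def call_peaks(
    track: ProbeRatioTrack,
    window: int = DEFAULT_WINDOW,
    min_probes: int = DEFAULT_MIN_PROBES,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    assign_cutoff_p: bool = True,
) -> list[Peak]:
    """Peak calls over the full stepped-cutoff schedule.

    The final peak set is the detection at the most permissive cutoff
    (the schedule floor); each peak's cutoff_p is the most stringent
    percentage at which any detection overlaps it. The peak score is the
    log2R of its 4th-highest member probe.
    """
    hmax = hypothetical_max(track)
    floor = min(schedule)
    final = detect_peaks_at_cutoff(track, floor / 100.0 * hmax, window, min_probes)
    if not final:
        return []
    peaks: list[Peak] = []
    for det in final:
        vals = np.sort(track.log2r[list(det.member_idx)])[::-1]
        score = float(vals[min(3, vals.size - 1)])
        peaks.append(
            Peak(
                replicon=det.replicon,
                start=det.start,
                end=det.end,
                member_idx=det.member_idx,
                probe_ids=tuple(str(p) for p in track.probe_id[list(det.member_idx)]),
                score=score,
                cutoff_p=floor,
            )
        )
    if assign_cutoff_p:
        assigned = [False] * len(peaks)
        max_val = float(track.log2r.max())
        for p in sorted(set(schedule), reverse=True):
            if p == floor:
                break
            if all(assigned):
                break
            cutoff = p / 100.0 * hmax
            if cutoff > max_val:
                continue
            for det in detect_peaks_at_cutoff(track, cutoff, window, min_probes):
                for i, pk in enumerate(peaks):
                    if assigned[i] or pk.replicon != det.replicon:
                        continue
                    if det.start < pk.end and pk.start < det.end:
                        pk.cutoff_p = p
                        assigned[i] = True
    return peaks


def estimate_fdr(
    track: ProbeRatioTrack,
    peaks: list[Peak],
    n_rand: int = 20,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    min_probes: int = DEFAULT_MIN_PROBES,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
) -> dict[int, float]:
    """Per-peak FDR from re-calling peaks on permuted ratio tracks.

    Each randomization permutes log2R values uniformly over probe positions
    within each replicon and reruns the full peak caller. For an observed
    peak of score s,

        fdr(s) = mean over randomizations of
                 (# random peaks with score >= s) / (# observed peaks with score >= s),

    clipped to [0, 1]. Ties count inclusively. Sets ``peak.fdr`` in place and
    returns {peak index: fdr}.
    """
    if n_rand < 1:
        raise ValueError("need at least one randomization")
    if not peaks:
        return {}
    rng = np.random.default_rng(seed)
    obs_scores = np.array([p.score for p in peaks])
    rand_counts = np.zeros((n_rand, len(peaks)))
    slices = track.replicon_slices()
    for r in range(n_rand):
        permuted = track.log2r.copy()
        for sl in slices.values():
            permuted[sl] = rng.permutation(permuted[sl])
        rand_peaks = call_peaks(
            track.with_values(permuted), window=window, min_probes=min_probes,
            schedule=schedule, assign_cutoff_p=False,
        )
        if rand_peaks:
            rand_scores = np.array([p.score for p in rand_peaks])
            rand_counts[r] = (rand_scores[:, None] >= obs_scores[None, :]).sum(axis=0)
    n_obs_ge = (obs_scores[:, None] >= obs_scores[None, :]).sum(axis=0)
    fdr = np.clip((rand_counts / n_obs_ge[None, :]).mean(axis=0), 0.0, 1.0)
    result = {}
    for i, pk in enumerate(peaks):
        pk.fdr = float(fdr[i])
        result[i] = pk.fdr
    return result


def classify_confidence(fdr: float, high: float = FDR_HIGH, candidate: float = FDR_CANDIDATE) -> str:
    """FDR <= 0.05: high-confidence binding site; <= 0.2: candidate; else reject."""
    if fdr is None or not np.isfinite(fdr):
        raise ValueError("peak has no FDR estimate")
    if fdr <= high:
        return "high"
    if fdr <= candidate:
        return "candidate"
    return "reject"


def classify_peaks(peaks: list[Peak], high: float = FDR_HIGH, candidate: float = FDR_CANDIDATE) -> list[Peak]:
    for pk in peaks:
        pk.confidence = classify_confidence(pk.fdr, high, candidate)
    return peaks
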