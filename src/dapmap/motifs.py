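"""Position weight matrices for regulator binding sites and sigma54 promoters.

PWMs are built from aligned equal-length sites with a background-weighted
pseudocount and scored as log2 odds. Scanning reports every position (both
strands by default) scoring at or above a threshold, which is usually
expressed as a fraction of the matrix's maximum attainable score. The
sigma54 machinery treats the bipartite -24/-12 promoter element as one
contiguous matrix with a fixed spacer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation import UpstreamIndex
from .simulate import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MotifHit",
    "build_pwm",
    "pwm_from_consensus",
    "scan_sequence",
    "scan_upstream_regions",
    "refine_motif",
    "scan_sigma54",
    "sigma54_matrix",
    "SIGMA54_CONSENSUS",
    "write_meme",
    "read_meme",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
UNIFORM_BG = np.full(4, 0.25)

# -24/-12 promoter element recognized by the sigma54 holoenzyme, written as
# one contiguous 16-bp consensus with the canonical 4-bp spacer
SIGMA54_CONSENSUS = "TGGCACGNNNNTTGCW"


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix over {A, C, G, T}.

    ``counts`` holds per-position base counts from the source alignment;
    log-odds weights are derived as
    log2((count + pseudocount * bg) / (nsites + pseudocount) / bg).
    """

    counts: np.ndarray  # (width, 4)
    background: np.ndarray  # (4,)
    pseudocount: float
    nsites: int
    name: str = "motif"
    sites: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be (width, 4)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """(width, 4) log2-odds scores."""
        num = self.counts + self.pseudocount * self.background[None, :]
        probs = num / (self.nsites + self.pseudocount)
        return np.log2(probs / self.background[None, :])

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.weights.argmax(axis=1))

    def score(self, seq: str) -> float:
        """Log-odds score of one width-length A/C/G/T sequence.

        Uses the same numpy summation as the scanner, so re-scoring a
        reported hit reproduces its score bit-exactly.
        """
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != motif width {self.width}")
        try:
            idx = np.array([_BASE_INDEX[b] for b in seq.upper()])
        except KeyError as exc:
            raise ValueError(f"non-ACGT base {exc} in sequence") from None
        return float(self.weights[np.arange(self.width), idx].sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            counts=self.counts[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            nsites=self.nsites,
            name=self.name + "_rc",
            sites=tuple(revcomp(s) for s in self.sites),
        )

    def threshold(self, fraction: float = 0.8) -> float:
        """Absolute score threshold at a fraction of the maximum score."""
        return fraction * self.max_score


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    position: int  # 0-based, forward-strand coordinate of the window start
    strand: str
    score: float
    sequence: str  # forward-strand window sequence
    feature: str | None = None
    kind: str = "motif"


def build_pwm(
    aligned_sites,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "motif",
) -> PWM:
    """Count matrix + log-odds PWM from >= 2 aligned equal-length A/C/G/T sites.

    The pseudocount is a single total distributed over bases by the
    background (0.25 per base under the uniform default).
    """
    sites = [s.upper() for s in aligned_sites]
    if len(sites) < 2:
        raise ValueError("need at least 2 aligned sites")
    width = len(sites[0])
    if width == 0 or any(len(s) != width for s in sites):
        raise ValueError("sites must be non-empty and of equal length")
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 4))
    for s in sites:
        for i, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise ValueError(f"non-ACGT base {b!r} in site {s}")
            counts[i, _BASE_INDEX[b]] += 1
    return PWM(
        counts=counts, background=bg, pseudocount=pseudocount,
        nsites=len(sites), name=name, sites=tuple(sites),
    )


def pwm_from_consensus(consensus: str, nsites: int = 20, pseudocount: float = 1.0, name: str = "motif") -> PWM:
    """Deterministic PWM for an IUPAC consensus: each position's count mass
    is split evenly over the allowed bases. Useful for planted-site scans and
    for a synthetic stand-in promoter matrix."""
    from .simulate import _IUPAC

    counts = np.zeros((len(consensus), 4))
    for i, ch in enumerate(consensus.upper()):
        allowed = _IUPAC.get(ch)
        if allowed is None:
            raise ValueError(f"unsupported consensus character {ch!r}")
        for b in allowed:
            counts[i, _BASE_INDEX[b]] += nsites / len(allowed)
    return PWM(counts=counts, background=UNIFORM_BG, pseudocount=pseudocount, nsites=nsites, name=name)


def sigma54_matrix() -> PWM:
    """Synthetic sigma54 (-24/-12) promoter matrix built from the canonical
    TGGCACG-N4-TTGCW consensus; a stand-in constructed here, not a database
    download."""
    return pwm_from_consensus(SIGMA54_CONSENSUS, nsites=80, name="sigma54")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3; anything non-ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(encoded: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores for every window; second array flags windows with invalid bases."""
    w = weights.shape[0]
    n = encoded.size - w + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = np.take_along_axis(
        np.broadcast_to(weights.T[None], (n, 4, w)), safe[:, None, :], axis=1
    )[:, 0, :].sum(axis=1)
    return scores, valid


def scan_sequence(
    pwm: PWM,
    sequence: str,
    threshold: float,
    both_strands: bool = True,
    seq_id: str = "seq",
    kind: str = "motif",
) -> list[MotifHit]:
    """Every position/strand scoring >= threshold.

    Reverse-strand hits are scored on the reverse complement but reported at
    their forward-strand window start. Windows containing non-ACGT characters
    are skipped and counted in the log.
    """
    if len(sequence) < pwm.width:
        raise ValueError("sequence shorter than motif width")
    encoded = _encode(sequence)
    hits: list[MotifHit] = []
    strands = [("+", pwm.weights)]
    if both_strands:
        strands.append(("-", pwm.reverse_complement().weights))
    n_skipped = 0
    for strand, weights in strands:
        scores, valid = _window_scores(encoded, weights)
        n_skipped += int((~valid).sum())
        for pos in np.nonzero(valid & (scores >= threshold))[0]:
            window = sequence[pos : pos + pwm.width].upper()
            hits.append(
                MotifHit(
                    seq_id=seq_id, position=int(pos), strand=strand,
                    score=float(scores[pos]), sequence=window, kind=kind,
                )
            )
    if n_skipped:
        logger.warning("%s: skipped %d windows containing non-ACGT bases", seq_id, n_skipped // len(strands))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_upstream_regions(
    pwm: PWM,
    genome: dict[str, str],
    upstream_index: UpstreamIndex,
    threshold: float,
    both_strands: bool = True,
    kind: str = "motif",
) -> list[MotifHit]:
    """Hits restricted to upstream intervals, in genomic coordinates, tagged
    with the owning feature. Features can be ranked by their best hit."""
    hits: list[MotifHit] = []
    for ivl in upstream_index:
        if ivl.length < pwm.width:
            continue
        region = genome[ivl.replicon][ivl.start : ivl.end]
        for h in scan_sequence(pwm, region, threshold, both_strands=both_strands, seq_id=ivl.replicon, kind=kind):
            hits.append(
                MotifHit(
                    seq_id=ivl.replicon, position=h.position + ivl.start, strand=h.strand,
                    score=h.score, sequence=h.sequence, feature=ivl.feature_id, kind=kind,
                )
            )
    hits.sort(key=lambda h: -h.score)
    return hits


def rank_features(hits: list[MotifHit]) -> list[tuple[str, float]]:
    """Features ordered by their best hit score."""
    best: dict[str, float] = {}
    for h in hits:
        if h.feature is not None and (h.feature not in best or h.score > best[h.feature]):
            best[h.feature] = h.score
    return sorted(best.items(), key=lambda kv: -kv[1])


def refine_motif(initial_pwm: PWM, target_sites) -> PWM:
    """Rebuild the PWM from the pooled site set (original sites plus
    best-hit sites extracted from DAP-chip targets)."""
    if not initial_pwm.sites:
        raise ValueError("initial PWM carries no source sites to pool with")
    new = [s.upper() for s in target_sites]
    if any(len(s) != initial_pwm.width for s in new):
        raise ValueError("target sites must match motif width")
    pooled = list(initial_pwm.sites) + [s for s in new if s not in initial_pwm.sites]
    return build_pwm(
        pooled, pseudocount=initial_pwm.pseudocount,
        background=initial_pwm.background, name=initial_pwm.name,
    )


def scan_sigma54(
    matrix: PWM,
    genome: dict[str, str],
    upstream_index: UpstreamIndex,
    threshold: float,
) -> list[MotifHit]:
    """Sigma54 promoter predictions: upstream-region scan with the promoter
    matrix, tagged kind='sigma54'."""
    return scan_upstream_regions(matrix, genome, upstream_index, threshold, both_strands=True, kind="sigma54")


# ---------------------------------------------------------------------------
# MEME minimal motif text format
# ---------------------------------------------------------------------------

def write_meme(pwms: list[PWM], path) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", ""]
    bg = pwms[0].background if pwms else UNIFORM_BG
    lines.append("Background letter frequencies")
    lines.append(" ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)))
    lines.append("")
    for pwm in pwms:
        probs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
        lines.append(f"MOTIF {pwm.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= {pwm.nsites} E= 0"
        )
        for row in probs:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_meme(path, pseudocount: float = 1.0) -> list[PWM]:
    """Parse MEME minimal format back into PWMs (counts = probs * nsites)."""
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh]
    bg = UNIFORM_BG.copy()
    pwms: list[PWM] = []
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[2 * _BASE_INDEX[b] + 1]) for b in ALPHABET])
            i += 2
            continue
        if ln.startswith("MOTIF"):
            name = ln.split()[1] if len(ln.split()) > 1 else "motif"
            i += 1
            header = lines[i]
            width = int(_field(header, "w"))
            nsites = int(_field(header, "nsites"))
            rows = []
            for j in range(width):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            counts = np.array(rows) * nsites
            pwms.append(PWM(counts=counts, background=bg, pseudocount=pseudocount, nsites=nsites, name=name))
            i += 1 + width
            continue
        i += 1
    return pwms


def _field(header: str, key: str) -> float:
    toks = header.replace("=", " = ").split()
    for k, tok in enumerate(toks):
        if tok == key:
            return float(toks[k + 2])
    raise ValueError(f"missing {key} in MEME header: {header}")
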