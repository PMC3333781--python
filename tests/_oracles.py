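"""Independent brute-force oracles used to cross-check vectorized code.

Deliberately written as plain loops, structurally unrelated to the
implementations they verify.
"""

from __future__ import annotations

import numpy as np


def brute_force_detections(starts, lengths, values, cutoff, window=500, min_probes=5):
    """Enumerate every window of `min_probes` consecutive qualifying probes,
    keep those whose genomic span fits, merge windows sharing a probe, and
    return (start, end, member_tuple) per merged component."""
    qual = [i for i, v in enumerate(values) if v >= cutoff]
    wins = []
    for k in range(len(qual) - min_probes + 1):
        idx = qual[k : k + min_probes]
        span = starts[idx[-1]] + lengths[idx[-1]] - starts[idx[0]]
        if span <= window:
            wins.append(set(idx))
    merged: list[set] = []
    for w in wins:
        attached = None
        for grp in merged:
            if grp & w:
                grp |= w
                attached = grp
                break
        if attached is None:
            merged.append(set(w))
        else:  # transitive merges
            changed = True
            while changed:
                changed = False
                for i in range(len(merged)):
                    for j in range(i + 1, len(merged)):
                        if merged[i] & merged[j]:
                            merged[i] |= merged.pop(j)
                            changed = True
                            break
                    if changed:
                        break
    out = []
    for grp in merged:
        members = tuple(sorted(grp))
        out.append(
            (
                int(starts[members[0]]),
                int(starts[members[-1]] + lengths[members[-1]]),
                members,
            )
        )
    return sorted(out)


def brute_force_scan(weights_fwd, weights_rev, encoded, threshold, both_strands=True):
    """Score every window on both strands with explicit loops.

    Returns sorted (position, strand, score) with invalid windows skipped.
    """
    w = len(weights_fwd)
    hits = []
    strands = [("+", weights_fwd)] + ([("-", weights_rev)] if both_strands else [])
    for pos in range(len(encoded) - w + 1):
        window = encoded[pos : pos + w]
        if any(b < 0 for b in window):
            continue
        for strand, weights in strands:
            s = 0.0
            for i, b in enumerate(window):
                s += weights[i][b]
            if s >= threshold:
                hits.append((pos, strand, s))
    return sorted(hits)


def random_track_arrays(rng, n_max=500):
    """A random probe layout mixing dense and sparse steps plus a few value
    spikes, for oracle-equivalence testing."""
    n = int(rng.integers(10, n_max))
    steps = rng.choice([4, 30, 100], size=n, p=[0.5, 0.4, 0.1])
    starts = np.cumsum(steps) - steps[0]
    lengths = np.full(n, 50)
    values = rng.normal(0, 1, size=n)
    spikes = rng.integers(0, n, size=max(1, n // 20))
    values[spikes] += rng.uniform(1, 4, size=len(spikes))
    return starts.astype(np.int64), lengths, values
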