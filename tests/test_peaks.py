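import numpy as np
import pytest

from dapmap.peaks import (
    call_peaks,
    classify_confidence,
    compute_log2_ratios,
    detect_peaks_at_cutoff,
    estimate_fdr,
    hypothetical_max,
)
from dapmap.simulate import SimParams, design_probes, generate_genome

from _oracles import brute_force_detections, random_track_arrays
from conftest import make_track


class TestLog2Ratios:
    def _probes(self, n=11):
        import pandas as pd

        from dapmap.simulate import ProbeDesign

        return ProbeDesign(
            table=pd.DataFrame(
                {
                    "probe_id": [f"P{i}" for i in range(n)],
                    "replicon": "chr",
                    "start": np.arange(n) * 30,
                    "length": 50,
                    "context": "coding",
                }
            )
        )

    def test_equal_channels_give_zero(self):
        probes = self._probes()
        track = compute_log2_ratios(probes, np.full(11, 500.0), np.full(11, 500.0))
        assert np.allclose(track.log2r, 0.0)

    def test_fourfold_probe_is_two_after_centring(self):
        probes = self._probes()
        enriched = np.full(11, 300.0)
        enriched[4] = 1200.0
        track = compute_log2_ratios(probes, enriched, np.full(11, 300.0))
        assert track.log2r[4] == pytest.approx(2.0)
        assert np.allclose(np.delete(track.log2r, 4), 0.0)

    def test_global_channel_scaling_cancels(self):
        probes = self._probes()
        rng = np.random.default_rng(0)
        enriched = rng.uniform(100, 1000, 11)
        input_ = rng.uniform(100, 1000, 11)
        t1 = compute_log2_ratios(probes, enriched, input_)
        t2 = compute_log2_ratios(probes, enriched * 7.3, input_)
        assert np.allclose(t1.log2r, t2.log2r)

    def test_nonpositive_intensity_names_probe(self):
        probes = self._probes()
        bad = np.full(11, 200.0)
        bad[6] = 0.0
        with pytest.raises(ValueError, match="P6"):
            compute_log2_ratios(probes, bad, np.full(11, 200.0))


class TestHypotheticalMax:
    def test_constant_track_returns_constant(self):
        track = make_track(np.arange(5) * 100, np.full(5, 1.7))
        assert hypothetical_max(track) == pytest.approx(1.7)

    def test_two_values_formula(self):
        track = make_track([0, 100], [0.0, 2.0])
        assert hypothetical_max(track) == pytest.approx(1 + 6 * np.sqrt(2))

    def test_single_probe_raises(self):
        with pytest.raises(ValueError):
            hypothetical_max(make_track([0], [1.0]))


class TestDetection:
    def test_five_qualifying_in_window_form_one_peak(self):
        track = make_track([0, 100, 200, 300, 400], np.full(5, 2.0))
        dets = detect_peaks_at_cutoff(track, 1.0)
        assert len(dets) == 1
        assert dets[0].member_idx == (0, 1, 2, 3, 4)
        assert (dets[0].start, dets[0].end) == (0, 450)

    def test_four_qualifying_probes_are_not_enough(self):
        track = make_track([0, 100, 200, 300], np.full(4, 2.0))
        assert detect_peaks_at_cutoff(track, 1.0) == []

    def test_window_span_violation_blocks_peak(self):
        track = make_track([0, 150, 300, 450, 600], np.full(5, 2.0))
        # span = 600 + 50 - 0 = 650 > 500
        assert detect_peaks_at_cutoff(track, 1.0) == []

    def test_nonqualifying_probe_between_members_is_excluded(self):
        starts = [0, 50, 100, 150, 200, 250]
        values = [2, 2, 0.1, 2, 2, 2]
        track = make_track(starts, values)
        dets = detect_peaks_at_cutoff(track, 1.0)
        assert len(dets) == 1
        assert dets[0].member_idx == (0, 1, 3, 4, 5)

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_bruteforce_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        starts, lengths, values = random_track_arrays(rng, n_max=300)
        cutoff = float(rng.uniform(0.0, 2.0))
        track = make_track(starts, values)
        got = sorted((d.start, d.end, d.member_idx) for d in detect_peaks_at_cutoff(track, cutoff))
        expected = brute_force_detections(starts, lengths, values, cutoff)
        assert got == [(s, e, m) for s, e, m in expected]


class TestCallPeaks:
    def _spiked_track(self, seed=0, n=400, spike_at=200, spike_len=8, spike=5.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 0.2, n)
        values[spike_at : spike_at + spike_len] = spike + rng.normal(0, 0.1, spike_len)
        return make_track(np.arange(n) * 10, values)

    def test_score_is_fourth_highest_member(self):
        values = np.zeros(100)
        values[40:45] = [5.0, 4.0, 3.0, 2.0, 1.5]
        track = make_track(np.arange(100) * 50, values)
        peaks = call_peaks(track)
        assert len(peaks) == 1
        assert peaks[0].member_idx == (40, 41, 42, 43, 44)
        assert peaks[0].score == pytest.approx(2.0)

    def test_cutoff_schedule_detections_are_nested(self):
        track = self._spiked_track(seed=5)
        hmax = hypothetical_max(track)
        prev = None
        for p in range(90, 14, -1):
            dets = detect_peaks_at_cutoff(track, p / 100.0 * hmax)
            if prev is not None:
                for d in prev:  # every stricter detection lies inside a looser one
                    assert any(
                        d2.start <= d.start and d.end <= d2.end for d2 in dets
                    ), f"detection at {p+1}% not contained at {p}%"
            prev = dets

    def test_isolated_strong_cluster_gets_cutoff_p_90(self):
        track = self._spiked_track(seed=7, spike=8.0)
        peaks = call_peaks(track)
        spike_peaks = [pk for pk in peaks if pk.start <= 2000 < pk.end]
        assert spike_peaks and spike_peaks[0].cutoff_p == 90

    def test_peak_invariants(self):
        peaks = call_peaks(self._spiked_track(seed=9))
        for pk in peaks:
            assert pk.n_probes >= 5
            assert pk.score <= max(pk.score for pk in peaks)
            assert 15 <= pk.cutoff_p <= 90


class TestFdr:
    def test_no_peaks_empty_map(self):
        track = make_track(np.arange(10) * 100, np.zeros(10))
        assert estimate_fdr(track, [], seed=0) == {}

    def test_nrand_must_be_positive(self):
        track = make_track(np.arange(10) * 100, np.zeros(10))
        with pytest.raises(ValueError):
            estimate_fdr(track, [], n_rand=0, seed=0)

    def test_constant_centred_track_yields_no_peaks(self):
        # a centred constant track is identically zero; no positive cutoff
        # can be exceeded, so the FDR question is vacuous
        track = make_track(np.arange(20) * 10, np.zeros(20))
        assert call_peaks(track) == []

    def test_single_strong_spike_gets_fdr_zero(self):
        rng = np.random.default_rng(3)
        n = 600
        values = rng.normal(0, 0.2, n)
        values[300:308] = 6.0
        track = make_track(np.arange(n) * 10, values)
        peaks = call_peaks(track)
        fdr = estimate_fdr(track, peaks, n_rand=20, seed=1)
        spike = [i for i, pk in enumerate(peaks) if pk.start <= 3000 < pk.end]
        assert spike and fdr[spike[0]] == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 0.3, 500)
        values[100:110] += 3
        track = make_track(np.arange(500) * 10, values)
        peaks1 = call_peaks(track)
        peaks2 = call_peaks(track)
        f1 = estimate_fdr(track, peaks1, seed=77)
        f2 = estimate_fdr(track, peaks2, seed=77)
        assert f1 == f2


class TestConfidence:
    @pytest.mark.parametrize(
        "fdr,expected",
        [(0.0, "high"), (0.03, "high"), (0.05, "high"), (0.15, "candidate"), (0.2, "candidate"), (0.5, "reject")],
    )
    def test_bands(self, fdr, expected):
        assert classify_confidence(fdr) == expected


class TestNullExchangeability:
    def test_permuted_tracks_score_like_the_fdr_null(self):
        """Re-permuting an already permuted track yields score distributions
        statistically indistinguishable from the first permutation's."""
        p = SimParams(genome_length=30_000, n_operons=10, seed=2)
        ann, _ = generate_genome(p)
        probes = design_probes(ann)
        rng = np.random.default_rng(12)
        values = rng.normal(0, 0.3, len(probes))
        values[rng.integers(0, len(probes), 40)] += 2.0
        t = probes.table
        track = make_track(t["start"].to_numpy(), values)
        scores = []
        for _ in range(2):
            perm = track.with_values(rng.permutation(track.log2r))
            scores.append(sorted(pk.score for pk in call_peaks(perm, assign_cutoff_p=False)))
        from scipy import stats

        if min(len(s) for s in scores) >= 5:
            assert stats.ks_2samp(*scores).pvalue > 0.001
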