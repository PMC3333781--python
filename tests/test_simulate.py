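import re
import tempfile
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

from dapmap import io as dio
from dapmap.annotation import build_upstream_index
from dapmap.peaks import ProbeRatioTrack
from dapmap.qpcr import fold_enrichment
from dapmap.simulate import (
    BoundRegion,
    SimParams,
    TruthSet,
    design_probes,
    expected_log2_ratio,
    generate_genome,
    plant_motif_sites,
    plant_sigma54_promoters,
    revcomp,
    simulate_dapchip_track,
    simulate_qpcr,
)


class TestGenerateGenome:
    def test_layout_properties(self, small_params):
        ann, genome = generate_genome(small_params)
        assert len(genome["chr"]) == small_params.genome_length
        assert len(ann.operons) == 5
        spans = sorted((g.start, g.end) for g in ann.genes)
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert s2 >= e1
        for op in ann.operons:
            strands = {ann.gene(g).strand for g in op.gene_ids}
            assert len(strands) == 1
        assert all(0 <= g.start < g.end <= small_params.genome_length for g in ann.genes)

    def test_zero_operons_gives_bare_sequence(self):
        p = SimParams(genome_length=10_000, n_operons=0, seed=3)
        ann, genome = generate_genome(p)
        assert ann.genes == [] and len(genome["chr"]) == 10_000

    def test_oversized_request_raises(self):
        p = SimParams(genome_length=3_000, n_operons=10, seed=0)
        with pytest.raises(ValueError, match="too short"):
            generate_genome(p)

    def test_deterministic_fasta_and_gff(self, small_params, tmp_path):
        files = []
        for run in ("a", "b"):
            ann, genome = generate_genome(small_params)
            fa, gff = tmp_path / f"{run}.fa", tmp_path / f"{run}.gff3"
            dio.write_fasta(genome, fa)
            dio.write_gff3(ann, gff)
            files.append((fa.read_bytes(), gff.read_bytes()))
        assert files[0] == files[1]


class TestDesignProbes:
    def test_intergenic_step_is_4(self):
        from dapmap.annotation import GenomeAnnotation

        ann = GenomeAnnotation(replicons={"chr": 1000}, genes=[], operons=[])
        t = design_probes(ann).table
        starts = t["start"].tolist()
        assert starts[:4] == [0, 4, 8, 12]
        assert set(np.diff(starts[:-1])) == {4}
        assert starts[-1] == 950  # last probe shifted to fit
        assert set(t["context"]) == {"intergenic"}

    def test_coding_step_is_30(self):
        from dapmap.annotation import Gene, GenomeAnnotation, Operon

        ann = GenomeAnnotation(
            replicons={"chr": 920},
            genes=[Gene(id="g", replicon="chr", start=0, end=920, strand="+")],
            operons=[Operon(id="op", gene_ids=("g",))],
        )
        t = design_probes(ann).table
        inner = t[t["context"] == "coding"]["start"].tolist()
        assert inner[:3] == [0, 30, 60]
        assert set(np.diff(inner[:-1])) == {30}

    def test_too_short_region_gets_no_probes(self):
        from dapmap.annotation import GenomeAnnotation

        ann = GenomeAnnotation(replicons={"chr": 40}, genes=[], operons=[])
        assert len(design_probes(ann)) == 0


class TestPlanting:
    def test_planted_consensus_matches_pattern(self, small_params):
        ann, genome = generate_genome(small_params)
        index = build_upstream_index(ann)
        leaders = [ivl.leader_gene for ivl in index if ivl.length >= 50][:3]
        edited, sites = plant_motif_sites(genome, ann, "GGCANNNNTGCC", leaders, seed=5)
        assert len(sites) == 3
        pat = re.compile("GGCA[ACGT]{4}TGCC")
        for s in sites:
            extracted = edited[s.replicon][s.position : s.position + 12]
            oriented = extracted if s.strand == "+" else revcomp(extracted)
            assert pat.fullmatch(oriented), (extracted, s)
            assert oriented == s.sequence

    def test_site_inside_upstream_interval_and_offset_negative(self, small_params):
        ann, genome = generate_genome(small_params)
        index = build_upstream_index(ann)
        leaders = [ivl.leader_gene for ivl in index if ivl.length >= 50][:2]
        _, sites = plant_sigma54_promoters(genome, ann, "TGGCACGNNNNTTGCW", leaders, seed=5)
        by_gene = {ivl.leader_gene: ivl for ivl in index}
        for s in sites:
            ivl = by_gene[s.gene_id]
            assert ivl.start <= s.position and s.position + 16 <= ivl.end
            assert s.offset < 0

    def test_empty_genome_raises(self):
        from dapmap.annotation import GenomeAnnotation

        ann = GenomeAnnotation(replicons={"chr": 1000}, genes=[], operons=[])
        with pytest.raises(ValueError, match="no genes"):
            plant_motif_sites({"chr": "A" * 1000}, ann, "GGCANNNNTGCC", ["g1"], seed=0)

    def test_same_seed_same_instantiation(self, small_params):
        ann, genome = generate_genome(small_params)
        index = build_upstream_index(ann)
        leaders = [ivl.leader_gene for ivl in index if ivl.length >= 50][:3]
        _, s1 = plant_motif_sites(genome, ann, "GGCANNNNTGCC", leaders, seed=9)
        _, s2 = plant_motif_sites(genome, ann, "GGCANNNNTGCC", leaders, seed=9)
        assert s1 == s2

    def test_empty_target_list_gives_empty_sites(self, small_params):
        ann, genome = generate_genome(small_params)
        out, sites = plant_sigma54_promoters(genome, ann, "TGGCACGNNNNTTGCW", [], seed=0)
        assert sites == [] and out is genome


class TestTrackSimulation:
    def test_null_noise_free_track_is_zero(self, small_params):
        probes = design_probes(generate_genome(small_params)[0])
        p = replace(small_params, noise_sd=0.0)
        track = simulate_dapchip_track(probes, TruthSet(), p, seed=1)
        assert np.allclose(track.log2r, 0.0)

    def test_plateau_probe_equals_log2_fold(self, small_params):
        """A probe centred inside a fold-4 region has log2R = 2 before centring."""
        ann, _ = generate_genome(small_params)
        probes = design_probes(ann)
        t = probes.table
        target = t.iloc[100]
        region = BoundRegion(
            replicon=target["replicon"],
            start=int(target["start"]) - 10,
            end=int(target["start"]) + 60,
            fold=4.0,
        )
        expected = expected_log2_ratio(probes, TruthSet(bound_regions=[region]), small_params)
        assert expected[100] == pytest.approx(2.0)

    def test_kernel_half_distance_value(self, small_params):
        """250 bp outside the edge of a fold-4 region: w = 0.5, log2(1+3*0.5)."""
        ann, _ = generate_genome(small_params)
        probes = design_probes(ann)
        t = probes.table
        center = float(t["start"].iloc[50]) + 25.0
        region = BoundRegion(replicon=t["replicon"].iloc[50], start=int(center + 250), end=int(center + 330), fold=4.0)
        expected = expected_log2_ratio(probes, TruthSet(bound_regions=[region]), small_params)
        assert expected[50] == pytest.approx(np.log2(2.5), abs=1e-2)

    def test_noise_free_track_matches_closed_form(self, small_params):
        ann, _ = generate_genome(small_params)
        probes = design_probes(ann)
        region = BoundRegion(replicon="chr", start=5000, end=5200, fold=3.0)
        truth = TruthSet(bound_regions=[region])
        p = replace(small_params, noise_sd=0.0)
        track = simulate_dapchip_track(probes, truth, p, seed=4)
        expected = expected_log2_ratio(probes, truth, p)
        assert np.allclose(track.log2r, expected - np.median(expected))

    def test_raw_intensities_reproduce_track(self, small_params):
        ann, _ = generate_genome(small_params)
        probes = design_probes(ann)
        truth = TruthSet(bound_regions=[BoundRegion("chr", 4000, 4300, 4.0)])
        track, enriched, input_ = simulate_dapchip_track(
            probes, truth, small_params, seed=2, return_intensities=True
        )
        assert isinstance(track, ProbeRatioTrack)
        ratios = np.log2(enriched / input_)
        assert np.allclose(track.log2r, ratios - np.median(ratios))


class TestSimulateQpcr:
    def test_noise_free_fold_recovered_exactly(self):
        m = simulate_qpcr(8.0, noise_sd=0.0, seed=0)
        delta_ct, fold = fold_enrichment(m)
        assert delta_ct == pytest.approx(3.0) and fold == pytest.approx(8.0)

    def test_fold_one_gives_zero_delta(self):
        delta_ct, fold = fold_enrichment(simulate_qpcr(1.0, noise_sd=0.0, seed=0))
        assert delta_ct == pytest.approx(0.0) and fold == pytest.approx(1.0)

    def test_monte_carlo_mean_within_three_standard_errors(self):
        m = simulate_qpcr(4.0, noise_sd=0.2, n_replicates=1000, seed=42)
        delta_ct, _ = fold_enrichment(m)
        se = 0.2 * np.sqrt(2 / 1000)  # both fractions carry noise
        assert abs(delta_ct - 2.0) < 3 * se
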