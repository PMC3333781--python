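import numpy as np
import pytest

from dapmap.annotation import Gene, GenomeAnnotation, Operon
from dapmap.peaks import ProbeRatioTrack
from dapmap.simulate import SimParams


@pytest.fixture
def small_params():
    """A genome small enough for fast tests but large enough to lay out
    five operons with room for upstream planting."""
    return SimParams(
        genome_length=12_000,
        n_operons=5,
        operon_size=(1, 2),
        gene_length=(300, 600),
        intergenic_gap=(150, 250),
        seed=11,
    )


@pytest.fixture
def toy_annotation():
    """Two-operon annotation with a divergent promoter region:
    gene a (-) at [200,1000) and gene b (+) at [1400,2200) share the
    intergenic stretch [1000,1400); gene c (+) at [2300,3000) follows b."""
    return GenomeAnnotation(
        replicons={"chr": 3500},
        genes=[
            Gene(id="a", replicon="chr", start=200, end=1000, strand="-"),
            Gene(id="b", replicon="chr", start=1400, end=2200, strand="+"),
            Gene(id="c", replicon="chr", start=2300, end=3000, strand="+"),
        ],
        operons=[
            Operon(id="opA", gene_ids=("a",)),
            Operon(id="opB", gene_ids=("b",)),
            Operon(id="opC", gene_ids=("c",)),
        ],
    )


def make_track(starts, values, length=50, replicon="chr"):
    starts = np.asarray(starts)
    return ProbeRatioTrack.from_arrays(
        probe_id=np.array([f"P{i:04d}" for i in range(len(starts))]),
        replicon=np.full(len(starts), replicon),
        start=starts,
        length=np.full(len(starts), length),
        log2r=np.asarray(values, dtype=float),
    )


@pytest.fixture
def track_factory():
    return make_track
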