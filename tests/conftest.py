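import numpy as np
import pytest

from shallowcn import bins, counts, simulate


@pytest.fixture
def toy_grid():
    """Two tiny chromosomes, 4-bp bins (bin arithmetic is size-agnostic)."""
    return bins.make_bins([("1", 12), ("2", 8)], bin_size=4)


@pytest.fixture
def flat_annotation():
    """Annotation factory: fully characterized bins with given gc/map."""

    def build(n, gc=50.0, mapp=100.0):
        return bins.BinAnnotation(
            gc=np.full(n, float(gc)),
            char_frac=np.ones(n),
            mappability=np.full(n, float(mapp)),
        )

    return build


@pytest.fixture
def poisson_pipeline():
    """Small end-to-end simulation: spec, grid, annotation, adjusted counts."""

    def build(seed=0, n_bins_per_chrom=800, bias="plane", **kwargs):
        L = n_bins_per_chrom * 15000
        spec = simulate.SimSpec(
            seed=seed,
            chrom_lengths=[("1", L), ("2", L)],
            bias=simulate.BiasModel(kind=bias),
            **kwargs,
        )
        grid = spec.grid()
        ann = simulate.truth_annotation(spec, grid)
        raw = simulate.simulate_counts(spec, ann)
        adjusted = counts.adjust_partial_bins(raw, ann)
        return spec, grid, ann, raw, adjusted

    return build
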