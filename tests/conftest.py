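import numpy as np
import pytest

from ystrpop.io import (
    Dataset,
    Haplotype,
    YFILER17,
    view_from_matrix,
    ViewMode,
)


def make_dataset(rows, panel=YFILER17, regions=None):
    """Build a Dataset from (sample_id, population, allele-list) tuples."""
    haps = []
    for k, (sid, pop, alleles) in enumerate(rows):
        region = regions[k] if regions else None
        haps.append(
            Haplotype(
                sample_id=sid,
                population=pop,
                region=region,
                alleles=dict(zip(panel.loci, [float(a) if a is not None else None for a in alleles])),
            )
        )
    return Dataset(panel=panel, haplotypes=haps)


@pytest.fixture
def base_alleles():
    """A plausible complete 17-locus haplotype (repeat counts)."""
    return [14, 13, 30, 24, 10, 11, 13, 11, 14, 15, 10, 12, 19, 15, 16, 23, 12]


@pytest.fixture
def tiny_dataset(base_alleles):
    """Four individuals, two populations, small allele perturbations."""
    a = base_alleles
    b = list(a); b[0] += 1
    c = list(a); c[3] += 2
    return make_dataset(
        [("S1", "PopA", a), ("S2", "PopA", b), ("S3", "PopB", c), ("S4", "PopB", a)]
    )


@pytest.fixture
def toy_view():
    """Helper to build ad-hoc AnalysisViews from matrices."""
    return view_from_matrix


def two_pop_fixed_difference_view():
    """The worked toy: alleles {10, 10} vs {12, 12} at one locus."""
    return view_from_matrix(
        [[10], [10], [12], [12]],
        loci=("L1",),
        populations=("A", "A", "B", "B"),
        mode=ViewMode.DISTANCE,
    )
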