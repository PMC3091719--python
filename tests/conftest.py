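import numpy as np
import pytest

from ssrbinmap import SimConfig, run_binmapping
from ssrbinmap.bin_builder import Bin, BinMap


@pytest.fixture(scope="session")
def study_run():
    """One full bin-mapping experiment at study scale (12 groups x 75 cM,
    64 framework markers per parental map, 278 offspring, 5% missing, 1%
    error, k = 14, 250 test markers, validation on 92 extended progeny)."""
    return run_binmapping(SimConfig(seed=1))


@pytest.fixture(scope="session")
def clean_run():
    """Same design without genotyping noise (error and missing rates 0)."""
    return run_binmapping(
        SimConfig(seed=3, missing_rate=0.0, error_rate=0.0),
        n_test_markers=80, validate=False,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def _bin(parent, lg, index, start, end, sig):
    return Bin(parent=parent, lg=lg, index=index, code=f"{lg}.{index}",
               start=start, end=end, signature=tuple(float(s) for s in sig))


@pytest.fixture()
def toy_binmap():
    """Hand-written two-group bin map over 12 individuals.

    Group 1 bins change genotype at individuals 0, then 1; the single bin
    of group 2 duplicates bin 1.1's signature so that a perfect match to
    it is genuinely ambiguous.
    """
    k = 12
    sig11 = [0.0] * k
    sig12 = [1.0, 1.0] + [0.0] * (k - 2)   # inds 0 and 1 recombine together
    sig13 = [1.0, 1.0, 1.0] + [0.0] * (k - 3)
    sig21 = [0.0] * k                      # clone of 1.1 on another group
    bins = [
        _bin("F", 1, 1, 0.0, 20.0, sig11),
        _bin("F", 1, 2, 20.0, 50.0, sig12),
        _bin("F", 1, 3, 50.0, 75.0, sig13),
        _bin("F", 2, 1, 0.0, 75.0, sig21),
    ]
    return BinMap(parent="F", individuals=tuple(f"i{j}" for j in range(k)),
                  bins=bins, group_lengths={1: 75.0, 2: 75.0})
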