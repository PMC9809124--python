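import numpy as np
import pandas as pd
import pytest

from pigsurv.popsim import MarkerMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def two_locus_map(distance_cm: float) -> MarkerMap:
    """Single chromosome with two marker loci ``distance_cm`` apart."""
    return MarkerMap(
        chrom=np.array([1, 1]),
        pos_cm=np.array([0.0, distance_cm]),
        is_qtl=np.array([False, False]),
        ids=np.array(["m0", "m1"], dtype=object),
    )


def pedigree_frame(rows):
    """Build a pedigree DataFrame from (id, sire, dam, sex, gen, litter, alive)."""
    return pd.DataFrame(
        rows,
        columns=["id", "sire", "dam", "sex", "generation", "litter", "alive"],
    )
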