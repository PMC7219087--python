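import numpy as np
import pytest

from promotif.motifs import MotifCountMatrix, build_weight_matrix
from promotif.promoters import PromoterRecord, PromoterUniverse
from promotif.simulate import example_motifs, high_information_pfm


@pytest.fixture
def gbox_pfm():
    return example_motifs()[0]


@pytest.fixture
def gbox_wm(gbox_pfm):
    return build_weight_matrix(gbox_pfm)


@pytest.fixture
def tiny_pfm():
    """A 3-column matrix with simple integer counts (consensus ACG)."""
    return MotifCountMatrix(
        motif_id="TINY",
        motif_name="tiny",
        counts=np.array(
            [
                [8.0, 1.0, 0.0],
                [1.0, 6.0, 2.0],
                [0.0, 2.0, 7.0],
                [1.0, 1.0, 1.0],
            ]
        ),
    )


@pytest.fixture
def tiny_wm(tiny_pfm):
    return build_weight_matrix(tiny_pfm, pseudocount=1.0)


def random_promoter(rng, length, with_n=False):
    bases = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(bases), size=length, p=probs))


@pytest.fixture
def small_universe():
    rng = np.random.default_rng(123)
    recs = [
        PromoterRecord(gene_id=f"g{i}", sequence=random_promoter(rng, 80))
        for i in range(20)
    ]
    return PromoterUniverse.from_records(recs)


@pytest.fixture
def sharp_pfm():
    # consensus chosen with negligible self/reverse-complement shift overlap
    # so planted-offset recovery is not confounded by equivalent hits
    return high_information_pfm("ACTGGCTTAC", "SHARP", dominance=0.97)
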