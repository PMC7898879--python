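import numpy as np
import pytest

from habprof import SynthConfig, gen_abundance_matrix, toy_taxonomy


@pytest.fixture(scope="session")
def tree():
    """Two-domain toy taxonomy, branching factor 2 at every rank."""
    return toy_taxonomy()


@pytest.fixture(scope="session")
def small_dataset():
    """A small habitat-structured count matrix plus its ground truth."""
    cfg = SynthConfig(
        samples_per_habitat=6, depth_range=(5000, 5000), seed=11
    )
    return gen_abundance_matrix(cfg)


def nodf_bruteforce(m: np.ndarray) -> float:
    """Independent NODF oracle: explicit enumeration of all row pairs and
    column pairs, paired contribution 100*overlap/fill(sparser) only under
    strictly decreasing fill."""
    from itertools import combinations

    def axis(mm):
        total, pairs = 0.0, 0
        for i, j in combinations(range(mm.shape[0]), 2):
            pairs += 1
            fi, fj = mm[i].sum(), mm[j].sum()
            shared = np.logical_and(mm[i], mm[j]).sum()
            if fi > fj > 0:
                total += 100.0 * shared / fj
            elif fj > fi > 0:
                total += 100.0 * shared / fi
        return total, pairs

    rs, rp = axis(np.asarray(m))
    cs, cp = axis(np.asarray(m).T)
    return (rs + cs) / (rp + cp)
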