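import numpy as np
import pandas as pd
import pytest

from promvol.synthetic import SimulationConfig, simulate_dataset, write_fixtures


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete ground-truthed dataset shared across tests."""
    cfg = SimulationConfig(n_promoters_per_class=15, seed=0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fixture_dir(small_dataset, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixtures")
    write_fixtures(small_dataset, d)
    return d


@pytest.fixture(scope="session")
def alignment_index(small_dataset):
    from promvol.alignment import AlignmentIndex

    return AlignmentIndex(small_dataset.blocks)


def brute_force_overlap(qs, qe, ts, te):
    """O(n*m) interval-overlap oracle used by several tests."""
    out = np.zeros(len(qs), dtype=bool)
    for i, (a, b) in enumerate(zip(qs, qe)):
        for c, d in zip(ts, te):
            if max(a, c) < min(b, d):
                out[i] = True
                break
    return out


def hypergeom_fisher_p(table):
    """Exhaustive two-sided Fisher p by enumerating all tables with the
    observed margins and summing hypergeometric probabilities <= observed."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    n1, n2, m1 = a + b, c + d, a + c
    N = n1 + n2
    p_obs = hypergeom.pmf(a, N, n1, m1)
    total = 0.0
    for x in range(max(0, m1 - n2), min(n1, m1) + 1):
        px = hypergeom.pmf(x, N, n1, m1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)
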