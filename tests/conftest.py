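import numpy as np
import pandas as pd
import pytest

import phosdim as P


@pytest.fixture(scope="session")
def brd4():
    return P.load_brd4()


@pytest.fixture(scope="session")
def study():
    """Two-state demo system with its peptide map and protocol (seed 1)."""
    construct, model = P.demo_system(seed=1)
    protocol = P.LabelingProtocol(seed=1)
    pmap = P.generate_peptide_map(construct, seed=1)
    return construct, model, protocol, pmap


@pytest.fixture(scope="session")
def uptake_table(study):
    construct, model, protocol, pmap = study
    return pd.concat(
        [P.simulate_uptake(model, pmap, protocol, s) for s in model.states],
        ignore_index=True,
    )


def random_construct(rng: np.random.Generator, n: int, with_prolines: bool = True):
    alphabet = list("ACDEFGHIKLMNQRSTVWY")
    seq = [str(rng.choice(alphabet)) for _ in range(n)]
    if with_prolines:
        for i in rng.choice(n, size=max(1, n // 20), replace=False):
            if 0 < i < n - 1:
                seq[i] = "P"
    return P.Construct(f"rand{n}", "".join(seq))
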