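import numpy as np
import pandas as pd
import pytest

from spatialprev import AreaMap, default_truth, make_lattice_map, simulate_survey
from spatialprev.synthetic import TruthSet


def line_map(n: int, spacing: float = 1.0) -> AreaMap:
    """n areas on a line with chain adjacency (1-2, 2-3, ...)."""
    ids = tuple(str(i + 1) for i in range(n))
    cent = np.array([(float(i) * spacing, 0.0) for i in range(n)])
    nbrs = {ids[i]: set() for i in range(n)}
    for i in range(n - 1):
        nbrs[ids[i]].add(ids[i + 1])
        nbrs[ids[i + 1]].add(ids[i])
    return AreaMap(ids, cent, {a: frozenset(s) for a, s in nbrs.items()})


def zero_truth(area_map: AreaMap, beta0: float = 0.0,
               beta: dict | None = None) -> TruthSet:
    """Truth with no area effects (for clean fixed-effect checks)."""
    z = np.zeros(area_map.n_areas)
    return TruthSet(beta0=beta0, beta=beta or {}, f_s=z, f_u=z)


@pytest.fixture(scope="session")
def lattice20() -> AreaMap:
    return make_lattice_map(5, 4)


@pytest.fixture(scope="session")
def survey20(lattice20) -> pd.DataFrame:
    """A medium simulated survey on a 20-area lattice with spatial structure."""
    truth = default_truth(lattice20, seed=11)
    return simulate_survey(
        lattice20, truth,
        design={"psus_per_area": 3, "respondents_per_psu": 20},
        seed=12,
    )
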