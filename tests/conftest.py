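import numpy as np
import pandas as pd
import pytest

import floatcatch as fc


@pytest.fixture
def toy_times():
    """3 block groups x 2 facilities; hand-checkable travel times."""
    return pd.DataFrame(
        [[5.0, 25.0], [15.0, 15.0], [35.0, 5.0]],
        index=pd.Index(["b1", "b2", "b3"], name="bg_id"),
        columns=pd.Index(["f1", "f2"], name="fac_id"),
    )


@pytest.fixture
def toy_supply():
    return pd.Series([1.0, 1.0], index=["f1", "f2"])


@pytest.fixture
def toy_population():
    return pd.Series([100.0, 100.0, 100.0], index=["b1", "b2", "b3"])


@pytest.fixture(scope="session")
def region200():
    """Shared 200-block-group synthetic region with OD matrix and scores."""
    spec = fc.RegionSpec(n_blockgroups=200, n_facilities=20, seed=7)
    blockgroups, facilities, network = fc.generate_region(spec)
    times = fc.od_matrix(network, blockgroups, facilities)
    access = fc.compute_all_measures(times, fc.machine_columns(facilities),
                                     blockgroups["population"])
    return {"spec": spec, "blockgroups": blockgroups, "facilities": facilities,
            "network": network, "times": times, "access": access}


@pytest.fixture(scope="session")
def grid10():
    """10 x 10 lattice of unit-spaced points with rook contiguity pairs."""
    ids = [(i, j) for i in range(10) for j in range(10)]
    coords = pd.DataFrame(
        {"x": [i for i, _ in ids], "y": [j for _, j in ids]},
        index=pd.Index([f"c{i}{j}" for i, j in ids]),
    )
    pairs = []
    for i, j in ids:
        if i + 1 < 10:
            pairs.append((f"c{i}{j}", f"c{i+1}{j}"))
        if j + 1 < 10:
            pairs.append((f"c{i}{j}", f"c{i}{j+1}"))
    return coords, pairs


def random_od_instance(rng, n_bg=None, n_fac=None):
    """Random small accessibility instance for oracle comparisons."""
    n_bg = n_bg or rng.integers(3, 21)
    n_fac = n_fac or rng.integers(1, 6)
    times = pd.DataFrame(
        rng.uniform(0, 45, size=(n_bg, n_fac)),
        index=[f"b{i}" for i in range(n_bg)],
        columns=[f"f{j}" for j in range(n_fac)],
    )
    machines = pd.Series(rng.integers(1, 6, n_fac).astype(float), index=times.columns)
    pops = pd.Series(rng.integers(50, 2000, n_bg).astype(float), index=times.index)
    return times, machines, pops
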