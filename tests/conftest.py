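import numpy as np
import pandas as pd
import pytest

import histoplex as hp


@pytest.fixture(scope="session")
def demo_cells() -> pd.DataFrame:
    """One full-scale simulated sample with nests, border infiltrate and a GC."""
    return hp.simulate_tissue(hp.demo_tissue_config(7))


@pytest.fixture(scope="session")
def demo_config():
    return hp.demo_tissue_config(7)


def make_cells(xy, phenotypes, sample_id="S1") -> pd.DataFrame:
    """Minimal hand-built cell table for spatial tests."""
    xy = np.asarray(xy, float)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(xy))],
            "sample_id": sample_id,
            "x_px": xy[:, 0],
            "y_px": xy[:, 1],
            "phenotype": list(phenotypes),
        }
    )


def random_cells(rng, n, width=500.0, types=("A", "B", "C")) -> pd.DataFrame:
    xy = rng.random((n, 2)) * width
    phen = rng.choice(list(types), size=n)
    return make_cells(xy, phen)


def brute_force_statistic(cells, radius):
    """O(n^2) neighbor statistic oracle: mean B-neighbors per A cell."""
    xy = cells[["x_px", "y_px"]].to_numpy(float)
    lab = cells["phenotype"].to_numpy(object)
    types = sorted(set(lab))
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    within = (d <= radius) & ~np.eye(len(xy), dtype=bool)
    stat = pd.DataFrame(0.0, index=types, columns=types)
    for a in types:
        sel_a = lab == a
        for b in types:
            stat.loc[a, b] = within[np.ix_(sel_a, lab == b)].sum() / sel_a.sum()
    return stat
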