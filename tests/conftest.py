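import numpy as np
import pandas as pd
import pytest

from metstab import METDataset, SimulationSpec, generate_met


def met_from_means(means, r: int = 1, rng=None, noise_sd: float = 0.0) -> METDataset:
    """Build a METDataset whose cell means are exactly the given matrix.

    With r > 1 the replicates are the cell mean plus zero-sum
    perturbations (optionally noisy draws re-centered per cell), so the
    cell means stay exact.
    """
    means = np.asarray(means, dtype=float)
    g, e = means.shape
    rows = []
    for i in range(g):
        for j in range(e):
            if r == 1:
                devs = np.zeros(1)
            elif noise_sd > 0:
                devs = rng.normal(0, noise_sd, r)
                devs -= devs.mean()
            else:
                # deterministic zero-sum perturbations that vary by cell so
                # they are not absorbed by the block term (error SS > 0)
                devs = np.linspace(-1.0, 1.0, r) * ((i + 2 * j) % 3 + 1)
                devs -= devs.mean()
            for k in range(r):
                rows.append((f"G{i + 1}", f"E{j + 1}", f"R{k + 1}", means[i, j] + devs[k]))
    frame = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "yield"])
    return METDataset.from_frame(frame)


@pytest.fixture(scope="session")
def default_trial():
    """One seeded trial at the default study conditions (16 x 8 x 3)."""
    return generate_met(SimulationSpec(seed=42))
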