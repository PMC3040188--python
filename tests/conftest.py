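import numpy as np
import pandas as pd
import pytest

from poolscan import PipelineConfig, PoolDesign, RasMatrix, SimulationConfig
from poolscan.simulate import simulate_dataset


def make_design(
    groups=("case", "control"), n_pools=4, n_replicates=3, pool_size=33
) -> PoolDesign:
    rows = []
    for g in groups:
        for p in range(1, n_pools + 1):
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "array_id": f"{g}_p{p}_r{r}",
                        "group": g,
                        "pool": p,
                        "replicate": r,
                        "pool_size": pool_size,
                    }
                )
    return PoolDesign(pd.DataFrame(rows).set_index("array_id"))


@pytest.fixture(scope="session")
def design24() -> PoolDesign:
    return make_design()


@pytest.fixture(scope="session")
def small_dataset():
    """A 600-probe simulated cohort with three strong planted blocks."""
    cfg = SimulationConfig(
        n_probes=600,
        n_chromosomes=2,
        n_effect_blocks=3,
        effect_delta=0.25,
        tau=0.02,
        sigma=0.02,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_ras(design: PoolDesign, n_probes: int, rng, missing_frac=0.0) -> RasMatrix:
    vals = rng.random((n_probes, len(design.array_ids)))
    if missing_frac:
        mask = rng.random(vals.shape) < missing_frac
        vals = np.where(mask, np.nan, vals)
    return RasMatrix(
        pd.DataFrame(
            vals,
            index=[f"p{i:04d}" for i in range(n_probes)],
            columns=design.array_ids,
        )
    )
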