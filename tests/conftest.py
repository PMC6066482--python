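import numpy as np
import pandas as pd
import pytest

from rewardnet.atlas import default_atlas
from rewardnet.pipeline import PipelineConfig, run_pipeline
from rewardnet.simulate import SimulationConfig, simulate_cohort

#: printed case-control genotype counts for rs279858 (AA, AG, GG)
HA_COUNTS = (202, 511, 319)
HC_COUNTS = (688, 1409, 766)


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic cohort reused by read-only tests."""
    cfg = SimulationConfig(n_per_group=12, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at the default study scale (n=40/group)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig.from_dict({
        "seed": 11, "n_per_group": 40,
        "permutations": 10_000, "bootstraps": 1000,
    })
    result = run_pipeline(cfg, out)
    return cfg, out, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def two_group_frame(rng, n_per_group=20):
    """Subjects table shaped like the cohort: group, age, cigarettes/day."""
    n = 2 * n_per_group
    idx = [f"s{i:03d}" for i in range(n)]
    groups = pd.Series(["HA"] * n_per_group + ["HC"] * n_per_group, index=idx,
                       name="group")
    covs = pd.DataFrame({
        "age": rng.normal(37, 4.5, n),
        "cigarettes_per_day": np.clip(
            np.where(np.arange(n) < n_per_group,
                     rng.normal(26, 9, n), rng.normal(9, 9, n)),
            0, None),
    }, index=idx)
    return groups, covs
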