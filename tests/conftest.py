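import logging

import numpy as np
import pytest

import screenweight as sw
from screenweight.simulate import SimulationConfig, simulate_dataset

logging.getLogger("screenweight").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic questionnaire shared across IO/pipeline tests."""
    cfg = SimulationConfig(n_groups=2, n_per_group=300, n_scales=3,
                           cier_proportion=0.10, seed=42)
    return simulate_dataset(cfg)


def draw_gpcm_data(seed, n, items, group_means, group_sds):
    """Responses from a known multi-group GPCM; n per group."""
    rng = np.random.default_rng(seed)
    thetas, groups = [], []
    for g, (m, s) in enumerate(zip(group_means, group_sds)):
        thetas.append(rng.normal(m, s, n))
        groups.append(np.full(n, g))
    theta = np.concatenate(thetas)
    group = np.concatenate(groups)
    resp = np.empty((theta.size, len(items)), dtype=int)
    for j, it in enumerate(items):
        p = sw.gpcm_category_probs(it, theta)
        u = rng.uniform(size=theta.size)
        resp[:, j] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return sw.ResponseMatrix(resp, group), theta, rng


def random_items(rng, n_items, n_steps):
    return [sw.GpcmItemParams(float(np.exp(rng.normal(0, 0.2))),
                              np.sort(rng.normal(rng.normal(0, 0.5), 0.7,
                                                 n_steps)))
            for _ in range(n_items)]
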