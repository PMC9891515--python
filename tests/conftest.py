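import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from cecselect.datamodel import MetaboliteMatrix
from cecselect.simulate import SimulationConfig, simulate_study

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: desk-scale study used by most module tests (fast; same structure as the
#: full-size default config)
SMALL_CONFIG = SimulationConfig(
    n_sites=4, n_events_per_site=4, n_analytes=40, frac_never_detected=0.5,
    n_active_contaminants=6, n_samples_per_site=6, n_metabolites=40,
    n_responsive_metabolites=10, n_latent_factors=2, effect_size=2.0,
    lod_quantile=0.25, block_effect_sd=0.2, noise_sd=0.3, seed=11,
)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(SimulationConfig(seed=5))


def make_matrix(values, sites, normalized=False, blocks=None):
    n = len(values)
    idx = pd.Index([f"s{i + 1}" for i in range(n)], name="sample_id")
    vdf = pd.DataFrame(np.asarray(values, dtype=float), index=idx,
                       columns=[f"M{j + 1}" for j in range(np.shape(values)[1])])
    return MetaboliteMatrix(
        values=vdf,
        site_of=pd.Series(list(sites), index=idx, name="site"),
        normalized=normalized,
        block_of=None if blocks is None else pd.Series(list(blocks), index=idx),
    )
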