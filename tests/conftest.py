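import numpy as np
import pandas as pd
import pytest

from tractwise.profiles import ProfileMatrix, TractLabel, _node_columns
from tractwise.simulate import TractSpec, default_spec, simulate_behavior, simulate_profiles


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cohort():
    """Default 40-subject cohort with the standard missingness pattern."""
    return simulate_behavior(default_spec(seed=11))


def single_tract_spec(
    seed=0, n=35, ell=5.0, noise_sd=0.05, availability=1.0, effects=(),
    hemisphere="left", segment="direct",
):
    """One-tract simulation spec used across statistical tests."""
    spec = default_spec(seed=seed)
    spec.n_subjects = n
    spec.missing_rules = []
    spec.tract_specs = [
        TractSpec(
            label=TractLabel(hemisphere, segment),
            noise_sd=noise_sd,
            corr_length=ell,
            availability=availability,
        )
    ]
    spec.effects = list(effects)
    spec.validate()
    return spec


def null_dataset(seed, ell=5.0, n=35, **kw):
    """Cohort + one 100-node profile with no embedded effect."""
    spec = single_tract_spec(seed=seed, n=n, ell=ell, **kw)
    c = simulate_behavior(spec, seed=seed)
    pm = simulate_profiles(spec, c, seed=seed)[0]
    return c, pm


def profile_matrix_from_array(values, hemisphere="left", segment="direct", ids=None):
    """Wrap an (n_subjects, n_nodes) array as a ProfileMatrix."""
    label = TractLabel(hemisphere, segment)
    values = np.asarray(values, dtype=float)
    ids = ids or [f"S{i:03d}" for i in range(1, values.shape[0] + 1)]
    df = pd.DataFrame(
        values, index=pd.Index(ids, name="subject_id"), columns=_node_columns(label.n_nodes)
    )
    return ProfileMatrix(label, df, list(ids))
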