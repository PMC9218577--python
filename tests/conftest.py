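import numpy as np
import pytest

from expodet.datamodel import DesignMatrix
from expodet.mcmc import McmcSettings
from expodet.simulate import SimulationConfig, generate_study

#: Short chain schedule for unit tests; full-scale defaults are exercised
#: only through their dataclass defaults.
FAST = McmcSettings(burn_in=400, kept_iterations=500, thin=2, seed=11)


@pytest.fixture(scope="session")
def default_study():
    """One default diacetyl study (606 samples, 17 facilities), shared."""
    return generate_study(SimulationConfig.default("diacetyl", seed=20240905))


@pytest.fixture(scope="session")
def demo_study():
    """Default study plus known nonzero process-level effects."""
    return generate_study(SimulationConfig.demo_effects("diacetyl", seed=77))


def make_design(y, X, columns, censored=None, bound=None, subjects=None):
    """Hand-build a DesignMatrix for sampler-level tests."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    censored = np.zeros(n, bool) if censored is None else np.asarray(censored, bool)
    bound = y.copy() if bound is None else np.asarray(bound, dtype=float)
    if subjects is None:
        subjects = np.arange(n)
    subjects = np.asarray(subjects)
    labels = list(dict.fromkeys(subjects.tolist()))
    index = np.array([labels.index(s) for s in subjects])
    return DesignMatrix(
        response=y,
        bound=bound,
        censored=censored,
        X=np.asarray(X, dtype=float),
        columns=list(columns),
        subject_index=index,
        subject_labels=[str(s) for s in labels],
        block_map={c: [c] for c in columns},
        record_ids=[str(i) for i in range(n)],
    )
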