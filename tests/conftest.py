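import numpy as np
import pandas as pd
import pytest

import methylscape as ms


@pytest.fixture(scope="session")
def small_cohort():
    """Three 10-sample groups, 3,000 probes: A and B planted identically,
    C carries its own signature plus a planted pair against A."""
    cfg = ms.SyntheticConfig(
        n_probes=3000,
        groups=[
            ms.GroupSpec("A", 10, signature_probes=100, signature_delta=0.35),
            ms.GroupSpec("B", 10, share_signature_with="A"),
            ms.GroupSpec("C", 10, signature_probes=100, signature_delta=0.35),
        ],
        planted_dmps={("A", "C"): (50, 0.35)},
        noise_sd=0.1,
        bad_samples=[("A_01", 0.2)],
        seed=101,
    )
    return ms.generate_cohort(cfg)


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Three fully distinct groups with zero noise: every downstream stage
    must recover the planted structure exactly."""
    cfg = ms.SyntheticConfig(
        n_probes=1500,
        groups=[
            ms.GroupSpec("A", 8, signature_probes=80, signature_delta=0.35),
            ms.GroupSpec("B", 8, signature_probes=80, signature_delta=0.35),
            ms.GroupSpec("C", 8, signature_probes=80, signature_delta=0.35),
        ],
        noise_sd=0.0,
        seed=7,
    )
    return ms.generate_cohort(cfg)


@pytest.fixture(scope="session")
def signature4():
    return ms.generate_reference_signature(4, 25, seed=1)


@pytest.fixture(scope="session")
def dirichlet_mixtures(signature4):
    rng = np.random.default_rng(42)
    fractions = pd.DataFrame(
        rng.dirichlet([1.0] * 4, size=50),
        columns=signature4.columns,
        index=[f"s{i:02d}" for i in range(50)],
    )
    noise_sd = 0.05 * float(signature4.to_numpy().std())
    activity = ms.generate_mixtures(signature4, fractions, noise_sd=noise_sd, seed=2)
    return activity, fractions
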