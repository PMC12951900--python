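import numpy as np
import pytest

import score2pro as sp


@pytest.fixture(scope="session")
def small_cohort():
    """5,000 participants, 30 proteins, three planted effects (one
    female-conditional); prepared with the median imputer."""
    cfg = sp.SimConfig(
        n_participants=5000, n_proteins=30, seed=11,
        effects=(
            sp.PlantedEffect(0, 0.55),
            sp.PlantedEffect(1, -0.45),
            sp.PlantedEffect(2, 0.6, subgroup="female"),
        ),
        missing_rate_proteins=0.02, missing_rate_clinical=0.02,
    )
    raw = sp.simulate_cohort(cfg)
    raw = sp.apply_missingness(raw, cfg, seed=12)
    prepared, report = sp.prepare(
        raw, sp.PrepConfig(imputation_method="median", split_seed=11))
    return {"config": cfg, "raw": raw, "prepared": prepared,
            "report": report}


@pytest.fixture(scope="session")
def null_cohort():
    """3,000 participants, 20 pure-noise proteins, no clinical hazards."""
    cfg = sp.SimConfig(n_participants=3000, n_proteins=20, seed=7)
    prepared, _ = sp.prepare(
        sp.simulate_cohort(cfg),
        sp.PrepConfig(imputation_method="median", split_seed=7))
    return prepared


def binary_fixture(seed, n=500, betas=(0.8,), n_features=1, prevalence=0.25):
    """Logistic-model binary outcome with the first len(betas) features
    informative; returns (X, y)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, max(n_features, len(betas))))
    lp = X[:, :len(betas)] @ np.asarray(betas)
    icept = np.log(prevalence / (1 - prevalence))
    y = (rng.random(n) < 1 / (1 + np.exp(-(icept + lp)))).astype(int)
    return X, y
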