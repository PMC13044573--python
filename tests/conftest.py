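import numpy as np
import pytest

from cmgipd import IPDDataset, McmcSettings, SimulationSetting

# reduced chain profile for unit-level distributional checks
UNIT_MCMC = McmcSettings(n_chains=2, n_iter=900, burn_in=400, thin=1)

# small synthetic meta-analysis used by the cheaper model-fitting tests
TINY_SETTING = SimulationSetting(
    variability="none",
    sparsity="high",
    correlation="none",
    strength="strong",
    I=3,
    n_range=(40, 50),
    p=2,
    beta=(1.0, -0.5),
    sigma=(2.0, 2.0, 2.0),
    tau_mu=1.0,
    tau_alpha=1.0,
)


@pytest.fixture
def toy_csv(tmp_path):
    """6-row CSV: 2 studies, 1 covariate."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "study,y,treat,age\n"
        "1,10.0,1,30\n"
        "1,11.5,0,40\n"
        "1,9.0,1,35\n"
        "2,12.0,0,50\n"
        "2,13.5,1,45\n"
        "2,8.0,0,55\n"
    )
    return path


@pytest.fixture
def single_study_dataset():
    """One study, one covariate, a genuine moderation signal."""
    rng = np.random.default_rng(42)
    n = 200
    x = rng.normal(size=n)
    t = np.zeros(n, dtype=int)
    t[: n // 2] = 1
    rng.shuffle(t)
    y = 1.0 + 0.5 * t + 0.3 * x + 0.8 * t * (x - x.mean()) + rng.normal(size=n)
    return IPDDataset(
        study_id=np.ones(n, dtype=int), y=y, t=t, X=x[:, None]
    )
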