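"""Synthetic IPD-MA data generation.

Datasets are generated from the moderation model itself: five trials with
100–150 participants each, eight correlated standard-normal baseline
covariates, a 1:1 randomized treatment, study-level random effects on the
intercept, the treatment effect, and (optionally) every moderation effect,
and study-specific Gaussian noise. The grid of 36 study conditions crosses

* between-trial moderation variability: tau_k in (1.5, 2.5) (high),
  (0.5, 1.5) (medium), or 0 (none);
* model sparsity: 2 (high), 4 (medium) or 6 (low) of the 8 covariates are
  true moderators;
* covariate correlation: none (identity) or high (pairwise correlations
  drawn from (0.5, 0.9));
* moderator strength: gamma_k = 1.5 (strong, 50% of the conditional
  treatment effect alpha = 3) or 0.75 (weak).

Fixed truths shared by all settings: mu = 2, alpha = 3,
beta = (1.8, 2.7, 2.3, 1.5, 1.7, 2.2, 1.3, 2.6),
(sigma_1..sigma_5) = (3.5, 2.5, 2.1, 2.8, 3), tau_mu = tau_alpha = 1.5.

Within a variability range the tau_k are assigned equally spaced across
the moderators (deterministically, given the setting), so the true mean
structure is fixed across replicates as the risk metrics require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterator

import numpy as np

from .data_model import IPDDataset

__all__ = [
    "SimulationSetting",
    "SimulatedTruth",
    "settings_grid",
    "generate_dataset",
    "replicate",
]

_SPARSITY_COUNT = {"high": 2, "medium": 4, "low": 6}
_STRENGTH_VALUE = {"strong": 1.5, "weak": 0.75}
_VARIABILITY_RANGE = {"high": (1.5, 2.5), "medium": (0.5, 1.5), "none": (0.0, 0.0)}

_DEFAULT_BETA = (1.8, 2.7, 2.3, 1.5, 1.7, 2.2, 1.3, 2.6)
_DEFAULT_SIGMA = (3.5, 2.5, 2.1, 2.8, 3.0)


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of the simulation grid, plus all fixed true parameters."""

    variability: str = "high"
    sparsity: str = "high"
    correlation: str = "high"
    strength: str = "weak"
    I: int = 5
    n_range: tuple[int, int] = (100, 150)
    p: int = 8
    mu: float = 2.0
    alpha: float = 3.0
    beta: tuple[float, ...] = _DEFAULT_BETA
    sigma: tuple[float, ...] = _DEFAULT_SIGMA
    tau_mu: float = 1.5
    tau_alpha: float = 1.5
    corr_range: tuple[float, float] = (0.5, 0.9)

    def __post_init__(self) -> None:
        if self.variability not in _VARIABILITY_RANGE:
            raise ValueError(f"unknown variability level {self.variability!r}")
        if self.sparsity not in _SPARSITY_COUNT:
            raise ValueError(f"unknown sparsity level {self.sparsity!r}")
        if self.correlation not in ("none", "high"):
            raise ValueError(f"unknown correlation level {self.correlation!r}")
        if self.strength not in _STRENGTH_VALUE:
            raise ValueError(f"unknown strength level {self.strength!r}")
        if len(self.beta) != self.p:
            raise ValueError("beta must have one coefficient per covariate")
        if len(self.sigma) != self.I:
            raise ValueError("sigma must have one noise SD per study")
        if self.n_true_moderators > self.p:
            raise ValueError("more true moderators than covariates")

    @property
    def n_true_moderators(self) -> int:
        return _SPARSITY_COUNT[self.sparsity]

    @property
    def gamma_value(self) -> float:
        return _STRENGTH_VALUE[self.strength]

    @property
    def true_gamma(self) -> np.ndarray:
        """True moderation effects: the first 2/4/6 covariates moderate."""
        g = np.zeros(self.p)
        g[: self.n_true_moderators] = self.gamma_value
        return g

    @property
    def tau_k(self) -> np.ndarray:
        """Between-trial moderation SDs, equally spaced over the range."""
        lo, hi = _VARIABILITY_RANGE[self.variability]
        if hi == 0.0:
            return np.zeros(self.p)
        return np.linspace(lo, hi, self.p)

    def label(self) -> str:
        return (
            f"var={self.variability},sparsity={self.sparsity},"
            f"corr={self.correlation},strength={self.strength}"
        )


@dataclass
class SimulatedTruth:
    """Realized true parameters and random effects of one dataset."""

    gamma: np.ndarray
    tau_k: np.ndarray
    mu: float
    alpha: float
    beta: np.ndarray
    sigma: np.ndarray
    tau_mu: float
    tau_alpha: float
    n_i: np.ndarray
    corr: list[np.ndarray]
    u_mu: np.ndarray
    u_alpha: np.ndarray
    u_mod: np.ndarray
    seed: object = None
    extras: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "gamma": self.gamma.tolist(),
            "tau_k": self.tau_k.tolist(),
            "mu": self.mu,
            "alpha": self.alpha,
            "beta": self.beta.tolist(),
            "sigma": self.sigma.tolist(),
            "tau_mu": self.tau_mu,
            "tau_alpha": self.tau_alpha,
            "n_i": self.n_i.tolist(),
            "seed": str(self.seed),
        }


def settings_grid() -> list[SimulationSetting]:
    """The 36-cell grid: variability x sparsity x correlation x strength."""
    grid = [
        SimulationSetting(
            variability=v, sparsity=s, correlation=c, strength=g
        )
        for v, s, c, g in product(
            ("high", "medium", "none"),
            ("high", "medium", "low"),
            ("none", "high"),
            ("strong", "weak"),
        )
    ]
    assert len(grid) == 36
    return grid


def _random_correlation(rng, p: int, lo: float, hi: float) -> np.ndarray:
    """Random high-correlation matrix: U(lo, hi) off-diagonals, symmetrized,
    eigenvalue-clipped to the nearest positive definite form with unit
    diagonal restored."""
    R = np.eye(p)
    iu = np.triu_indices(p, k=1)
    vals = rng.uniform(lo, hi, size=len(iu[0]))
    R[iu] = vals
    R.T[iu] = vals
    w, V = np.linalg.eigh(R)
    if w.min() <= 1e-8:
        w = np.clip(w, 1e-8, None)
        R = (V * w) @ V.T
        s = np.sqrt(np.diag(R))
        R = R / np.outer(s, s)
    return R


def generate_dataset(
    setting: SimulationSetting, seed=None
) -> tuple[IPDDataset, SimulatedTruth]:
    """Simulate one IPD-MA dataset under a setting.

    Study sizes are drawn uniformly on the integer range; covariates are
    multivariate normal with unit SDs and the setting's correlation
    (matrices drawn once per study per replicate under high correlation);
    treatment is a balanced permutation within study; random effects and
    noise are Gaussian with the setting's true variabilities.
    """
    rng = np.random.default_rng(seed)
    I, p = setting.I, setting.p
    lo_n, hi_n = setting.n_range
    n_i = rng.integers(lo_n, hi_n + 1, size=I)
    gamma = setting.true_gamma
    tau_k = setting.tau_k
    beta = np.asarray(setting.beta)
    sigma = np.asarray(setting.sigma)
    u_mu = rng.normal(0.0, setting.tau_mu, size=I)
    u_alpha = rng.normal(0.0, setting.tau_alpha, size=I)
    u_mod = rng.normal(0.0, 1.0, size=(I, p)) * tau_k[None, :]
    ys, ts, Xs, sids, corrs = [], [], [], [], []
    for i in range(I):
        n = int(n_i[i])
        if setting.correlation == "high":
            R = _random_correlation(rng, p, *setting.corr_range)
        else:
            R = np.eye(p)
        corrs.append(R)
        L = np.linalg.cholesky(R)
        X = rng.standard_normal((n, p)) @ L.T
        t = np.zeros(n, dtype=np.int64)
        t[: n // 2] = 1
        rng.shuffle(t)
        xem = t[:, None] * X
        mean = (
            setting.mu
            + t * setting.alpha
            + X @ beta
            + xem @ gamma
            + u_mu[i]
            + t * u_alpha[i]
            + xem @ u_mod[i]
        )
        y = mean + rng.normal(0.0, sigma[i], size=n)
        ys.append(y)
        ts.append(t)
        Xs.append(X)
        sids.append(np.full(n, i + 1))
    data = IPDDataset(
        study_id=np.concatenate(sids),
        y=np.concatenate(ys),
        t=np.concatenate(ts),
        X=np.vstack(Xs),
    )
    truth = SimulatedTruth(
        gamma=gamma,
        tau_k=tau_k,
        mu=setting.mu,
        alpha=setting.alpha,
        beta=beta,
        sigma=sigma,
        tau_mu=setting.tau_mu,
        tau_alpha=setting.tau_alpha,
        n_i=n_i,
        corr=corrs,
        u_mu=u_mu,
        u_alpha=u_alpha,
        u_mod=u_mod,
        seed=seed,
    )
    return data, truth


def replicate(
    setting: SimulationSetting, n_reps: int, base_seed=None
) -> Iterator[tuple[IPDDataset, SimulatedTruth]]:
    """Stream of independent replicate datasets with logged child seeds.

    Child streams are spawned from ``numpy.random.SeedSequence(base_seed)``
    so the replicate sequence is fully determined by the base seed and
    replicates are statistically independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    root = (
        base_seed
        if isinstance(base_seed, np.random.SeedSequence)
        else np.random.SeedSequence(base_seed)
    )
    children = root.spawn(n_reps)
    for child in children:
        yield generate_dataset(setting, seed=child)
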