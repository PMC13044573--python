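"""Estimation-risk metrics, DIC, and the scaled neighborhood criterion.

The replicate-level metrics compare posterior means gamma_hat^(r) of the
moderation effects against the fixed truth gamma over R replicate
datasets, each relative to the mean absolute true effect:

    ARRMSE  = sqrt( sum_{r,k} (gamma_hat_k^(r) − gamma_k)^2 / (R d) )
              / ( sum_k |gamma_k| / d )
    AARBias = ( sum_k | mean_r gamma_hat_k^(r) − gamma_k | / d )
              / ( sum_k |gamma_k| / d )
    ARSD    = sqrt( sum_{r,k} (gamma_hat_k^(r) − bar gamma_k)^2 / (R d) )
              / ( sum_k |gamma_k| / d )

Participant-level risk uses the treatment-arm linear predictor:

    PSRMSE     = sum_r ‖ (t alpha + Xem gamma) − (t alpha_hat^(r)
                 + Xem gamma_hat^(r)) ‖ / (R N)
    PSRMSE(EM) = sum_r ‖ Xem gamma − Xem gamma_hat^(r) ‖ / (R N)

with ‖·‖ the Euclidean norm. Smaller is better throughout. Per moderator
k the exact decomposition MSE_k = Var_k + Bias_k^2 holds before the
relative aggregation; the aggregated ARRMSE/ARSD ratio does not obey a
general ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import IPDDataset, ModelConfig, build_design
from .sampler import PosteriorDraws

__all__ = [
    "EstimateSet",
    "ModeratorReport",
    "arrmse",
    "aarbias",
    "arsd",
    "psrmse",
    "dic",
    "scaled_neighborhood",
    "moderator_report",
]


@dataclass
class EstimateSet:
    """Per-replicate posterior means plus the fixed truth and design.

    ``gamma_hat`` is (R, d); ``alpha_hat`` is (R,). ``Xem`` and ``t`` are
    needed only for the participant-level metrics.
    """

    gamma_hat: np.ndarray
    gamma_true: np.ndarray
    alpha_hat: np.ndarray | None = None
    alpha_true: float | None = None
    Xem: np.ndarray | None = None
    t: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma_hat = np.atleast_2d(np.asarray(self.gamma_hat, dtype=float))
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        if self.gamma_hat.shape[1] != self.gamma_true.shape[0]:
            raise ValueError("gamma_hat and gamma_true dimension mismatch")
        if self.alpha_hat is not None:
            self.alpha_hat = np.atleast_1d(np.asarray(self.alpha_hat, dtype=float))
            if self.alpha_hat.shape[0] != self.gamma_hat.shape[0]:
                raise ValueError("alpha_hat must have one value per replicate")

    @property
    def R(self) -> int:
        return int(self.gamma_hat.shape[0])

    @property
    def d(self) -> int:
        return int(self.gamma_true.shape[0])


def _denominator(est: EstimateSet) -> float:
    denom = float(np.mean(np.abs(est.gamma_true)))
    if denom == 0.0:
        raise ValueError(
            "relative metrics are undefined for an all-zero true gamma"
        )
    return denom


def arrmse(est: EstimateSet) -> float:
    """Average relative root mean squared error of the moderation effects."""
    err = est.gamma_hat - est.gamma_true[None, :]
    rmse = float(np.sqrt(np.sum(err**2) / (est.R * est.d)))
    return rmse / _denominator(est)


def aarbias(est: EstimateSet) -> float:
    """Average absolute relative bias of the moderation effects."""
    bias = np.abs(est.gamma_hat.mean(axis=0) - est.gamma_true)
    return float(np.mean(bias)) / _denominator(est)


def arsd(est: EstimateSet) -> float:
    """Average relative standard deviation of the moderation estimates."""
    if est.R < 2:
        raise ValueError("ARSD requires at least 2 replicates")
    dev = est.gamma_hat - est.gamma_hat.mean(axis=0, keepdims=True)
    sd = float(np.sqrt(np.sum(dev**2) / (est.R * est.d)))
    return sd / _denominator(est)


def psrmse(est: EstimateSet, include_em_only: bool = False) -> float:
    """Participant-specific root mean squared error of the treatment-arm
    linear predictor; with ``include_em_only`` only the moderation part
    Xem gamma enters (PSRMSE(EM))."""
    if est.Xem is None:
        raise ValueError("participant-level metrics need the Xem design")
    Xem = np.asarray(est.Xem, dtype=float)
    N = Xem.shape[0]
    if Xem.shape[1] != est.d:
        raise ValueError("Xem column count must match gamma dimension")
    total = 0.0
    for r in range(est.R):
        err = Xem @ (est.gamma_true - est.gamma_hat[r])
        if not include_em_only:
            if est.t is None or est.alpha_hat is None or est.alpha_true is None:
                raise ValueError("PSRMSE needs t, alpha_true and alpha_hat")
            t = np.asarray(est.t, dtype=float)
            if t.shape[0] != N:
                raise ValueError("t must have one entry per participant")
            err = err + t * (est.alpha_true - est.alpha_hat[r])
        total += float(np.linalg.norm(err))
    return total / (est.R * N)


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------

def dic(draws: PosteriorDraws, data: IPDDataset, config: ModelConfig) -> float:
    """Deviance information criterion, DIC = D_bar + pD, pD = D_bar − D(theta_bar).

    Uses the conditional deviance (likelihood conditional on the random
    effects), with the plug-in evaluated at the posterior means of all
    parameters including random effects and noise variances. Non-finite
    deviance draws are excluded with a warning.
    """
    design = build_design(data, config)
    y = data.y
    W = design.W
    srow = np.empty(design.N, dtype=np.int64)
    for i, rows in enumerate(design.study_rows):
        srow[rows] = i
    d = design.d
    # pooled draws
    parts = []
    if config.include_main_effects:
        parts += [
            draws.pooled("mu")[:, None],
            draws.pooled("alpha")[:, None],
            draws.pooled("beta"),
        ]
    if d > 0:
        parts.append(draws.pooled("gamma"))
    theta = np.hstack(parts)  # (S, q)
    S = theta.shape[0]
    mean = W @ theta.T  # (N, S)
    if "u_mu" in draws.params:
        u_mu = draws.pooled("u_mu")  # (S, I)
        u_alpha = draws.pooled("u_alpha")
        for i, rows in enumerate(design.study_rows):
            mean[rows] += u_mu[:, i][None, :]
            mean[rows] += design.t[rows][:, None] * u_alpha[:, i][None, :]
    if "u_mod" in draws.params:
        u_mod = draws.pooled("u_mod")  # (S, I, d)
        for i, rows in enumerate(design.study_rows):
            mean[rows] += design.Xem[rows] @ u_mod[:, i, :].T
    sigma2 = draws.pooled("sigma2")  # (S, I)
    inv = 1.0 / sigma2[:, srow].T  # (N, S)
    logdet = np.log(2.0 * np.pi * sigma2[:, srow].T)
    dev = (logdet + (y[:, None] - mean) ** 2 * inv).sum(axis=0)  # (S,)
    finite = np.isfinite(dev)
    if not finite.all():
        warnings.warn(
            f"excluded {int((~finite).sum())} non-finite deviance draw(s)",
            stacklevel=2,
        )
        dev = dev[finite]
    d_bar = float(dev.mean())
    # plug-in deviance at posterior means
    theta_bar = theta.mean(axis=0)
    mean_bar = W @ theta_bar
    if "u_mu" in draws.params:
        um, ua = draws.mean("u_mu"), draws.mean("u_alpha")
        for i, rows in enumerate(design.study_rows):
            mean_bar[rows] += um[i] + design.t[rows] * ua[i]
    if "u_mod" in draws.params:
        uk = draws.mean("u_mod")
        for i, rows in enumerate(design.study_rows):
            mean_bar[rows] += design.Xem[rows] @ uk[i]
    s2_bar = draws.mean("sigma2")
    dev_bar = float(
        np.sum(
            np.log(2.0 * np.pi * s2_bar[srow])
            + (y - mean_bar) ** 2 / s2_bar[srow]
        )
    )
    p_d = d_bar - dev_bar
    return d_bar + p_d


# ---------------------------------------------------------------------------
# scaled neighborhood criterion
# ---------------------------------------------------------------------------

def scaled_neighborhood(
    gamma_draws, threshold: float = 0.5
) -> tuple[float, bool]:
    """Scaled neighborhood criterion for one moderation effect.

    Computes p = P(|gamma_k| < SD(gamma_k | y) | y), the posterior
    probability that the effect lies inside one posterior SD of zero,
    estimated from the same draws. A small probability indicates an
    important moderator; the flag is ``p < threshold``.
    """
    x = np.asarray(gamma_draws, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        if np.all(x == 0.0):
            return 1.0, False
        raise ValueError("degenerate draws with zero posterior SD")
    p = float(np.mean(np.abs(x) < sd))
    return p, p < threshold


@dataclass
class ModeratorReport:
    """Per-moderator posterior summary plus the scaled neighborhood flag."""

    table: pd.DataFrame
    threshold: float = 0.5


def moderator_report(
    draws: PosteriorDraws,
    names: list[str] | None = None,
    level: float = 0.95,
    threshold: float = 0.5,
) -> ModeratorReport:
    """Posterior mean, SD, credible interval and p_gamma per moderator."""
    g = draws.pooled("gamma")
    d = g.shape[1]
    if names is None:
        names = [f"gamma[{k}]" for k in range(d)]
    lo = (1 - level) / 2
    rows = []
    for k in range(d):
        p, flag = scaled_neighborhood(g[:, k], threshold)
        rows.append(
            {
                "moderator": names[k],
                "mean": float(g[:, k].mean()),
                "sd": float(g[:, k].std(ddof=1)),
                "lower": float(np.quantile(g[:, k], lo)),
                "upper": float(np.quantile(g[:, k], 1 - lo)),
                "p_gamma": p,
                "important": flag,
            }
        )
    return ModeratorReport(pd.DataFrame(rows), threshold)
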