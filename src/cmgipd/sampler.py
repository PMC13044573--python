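"""Posterior inference for the IPD-MA moderation model.

A Metropolis-within-Gibbs sampler for the linear mixed model

    y_ij = mu + t_ij*alpha + x_ij' beta + xem_ij' gamma
           + u_mu_i + t_ij*u_alpha_i + xem_ij' u_i + eps_ij,
    eps_ij ~ N(0, sigma_i^2),

under any of the registered priors for gamma. Nuisance parameters carry
the noninformative prior pi(mu, alpha, beta, sigma_i^2) ∝ 1/sigma_i^2
(independent Jeffreys per study) and half-Cauchy priors on the
between-study SDs tau.

Update scheme
-------------
* (mu, alpha, beta, gamma): exact joint Gaussian full conditional;
* study random effects: exact Gaussian full conditional per study;
* tau^2: half-Cauchy via the inverse-gamma parameter-expansion identity
  (tau ~ C+(0, A)  <=>  tau^2 | a ~ IG(1/2, 1/a), a ~ IG(1/2, 1/A^2));
* sigma_i^2: conjugate inverse-gamma draw; under g-priors the prior
  precision of gamma depends on sigma_i^2, so the conjugate draw is used
  as an independence proposal and accepted with the ratio of the g-prior
  terms — the extra term is included exactly;
* g_k: exact conjugate inverse-gamma draw for ZS/CZS; log-scale
  random-walk Metropolis for the Beta-shrinkage hyperpriors;
* p_i, b_k: uniform independence Metropolis on their bounded supports;
* horseshoe scales: conjugate inverse-gamma chain through the standard
  auxiliary-variable representation of the half-Cauchy;
* SSVS indicators: exact Bernoulli full conditional; eta by slice
  sampling on (0, c).

All randomness flows through one NumPy generator per chain derived from
the user seed, so runs are exactly reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .data_model import IPDDataset, ModelConfig, build_design
from .priors import (
    PriorSpec,
    g_log_density,
    tuning_function,
    tuning_support,
)

__all__ = [
    "McmcSettings",
    "FULL_MCMC",
    "TEST_MCMC",
    "PosteriorDraws",
    "fit",
    "posterior_summary",
    "convergence_report",
]


@dataclass(frozen=True)
class McmcSettings:
    """MCMC run configuration.

    The default profile runs two chains of 20,000 iterations each,
    discarding the first 10,000 as burn-in and retaining every 10th
    sample. ``TEST_MCMC`` is a reduced profile for continuous-integration
    scale runs. ``fixed_sigma2`` and ``fixed_g`` freeze the noise
    variances / shrinkage parameter for conjugate diagnostics.
    """

    n_chains: int = 2
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    fixed_sigma2: tuple | None = None
    fixed_g: float | None = None
    g_step: float = 1.0  # log-scale RW step for non-conjugate g updates

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


FULL_MCMC = McmcSettings()
TEST_MCMC = McmcSettings(n_chains=2, n_iter=2000, burn_in=1000, thin=2)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws with shape (n_chains, n_kept, ...) per key."""

    params: dict[str, np.ndarray]
    settings: McmcSettings
    seed: int | None
    spec_name: str
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.settings.n_chains

    @property
    def n_kept(self) -> int:
        return self.settings.n_kept

    def names(self) -> list[str]:
        return list(self.params)

    def pooled(self, name: str) -> np.ndarray:
        """Draws pooled over chains, shape (n_chains * n_kept, ...)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def mean(self, name: str) -> np.ndarray:
        return self.pooled(name).mean(axis=0)

    def sd(self, name: str) -> np.ndarray:
        return self.pooled(name).std(axis=0, ddof=1)

    def ci(self, name: str, level: float = 0.95) -> np.ndarray:
        if not 0 < level < 1:
            raise ValueError("credible level must lie in (0, 1)")
        lo = (1 - level) / 2
        return np.quantile(self.pooled(name), [lo, 1 - lo], axis=0)

    def scalar_frame(self):
        """All draws flattened to scalar columns, pooled over chains."""
        import pandas as pd

        cols = {}
        for name, arr in self.params.items():
            flat = self.pooled(name)
            if flat.ndim == 1:
                cols[name] = flat
            else:
                flat2 = flat.reshape(flat.shape[0], -1)
                shape = arr.shape[2:]
                for j in range(flat2.shape[1]):
                    idx = np.unravel_index(j, shape)
                    label = name + "".join(f"[{i}]" for i in idx)
                    cols[label] = flat2[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.scalar_frame().to_csv(path, index=False)

    def to_inference_data(self):
        """Export to an arviz InferenceData with chain/draw dimensions."""
        import arviz as az

        return az.from_dict(
            posterior={k: v for k, v in self.params.items()}
        )


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _invgamma(rng, shape, scale):
    """Draw from IG(shape, scale) with density ∝ x^(−shape−1) e^(−scale/x)."""
    return scale / rng.gamma(shape, size=np.shape(scale) or None)


def _chol_draw(rng, A, rhs, block: str):
    """Sample from N(A^{-1} rhs, A^{-1}); A must be positive definite."""
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as err:
        raise RuntimeError(
            f"conditional covariance for block {block!r} is not positive definite"
        ) from err
    tmp = linalg.solve_triangular(L, rhs, lower=True)
    mean = linalg.solve_triangular(L.T, tmp, lower=False)
    z = rng.standard_normal(A.shape[0])
    return mean + linalg.solve_triangular(L.T, z, lower=False)


class _ChainState:
    """Mutable state of one chain; precomputed design quantities shared."""

    def __init__(self, pre, spec, config, mcmc, rng):
        self.rng = rng
        d, I, m = pre.d, pre.I, pre.m
        self.theta = pre.theta0.copy()
        self.U = np.zeros((I, m))
        self.tau2 = np.ones(m)
        self.tau_aux = np.ones(m)
        self.sigma2 = (
            np.asarray(mcmc.fixed_sigma2, dtype=float).copy()
            if mcmc.fixed_sigma2 is not None
            else pre.sigma2_0.copy()
        )
        self.re_contrib = np.zeros(pre.N)
        # shrinkage state
        if spec.is_g_family:
            if mcmc.fixed_g is not None:
                self.g = np.full(d, float(mcmc.fixed_g))
            elif spec.family == "nmg" and spec.g_rule == "UIP":
                self.g = np.full(d, float(pre.N_total))
            elif spec.family == "cmg" and spec.shrink == "CUIP":
                self.g = np.ones(d)
            else:
                self.g = np.ones(d)
            self.b = np.full(
                d, spec.b_fixed if spec.b_fixed is not None else 1.0
            )
            if spec.has_tuning:
                lo, hi = tuning_support(spec.tuning, pre.n_i)
                self.p = 0.5 * (lo + hi)
                self.f = tuning_function(spec.tuning, pre.n_i, self.p)
            else:
                self.p = np.empty(0)
                self.f = (
                    np.full(I, float(pre.N_total))
                    if spec.family == "cmg"
                    else np.ones(I)
                )
        if spec.family == "horseshoe":
            self.lambda2 = np.ones(d)
            self.nu = np.ones(d)
            self.tau2_hs = 1.0
            self.xi = 1.0
        if spec.family == "ssvs":
            self.ind = np.ones(d, dtype=np.int64)
            self.eta = spec.c / 2.0


class _Precomputed:
    def __init__(self, design, config, y):
        self.W = design.W
        self.y = y
        self.N = design.N
        self.N_total = design.N
        self.I = design.I
        self.d = design.d
        self.n_i = np.asarray(design.n_i, dtype=float)
        self.rows = design.study_rows
        self.srow = np.empty(self.N, dtype=np.int64)
        for i, r in enumerate(self.rows):
            self.srow[r] = i
        self.q = design.W.shape[1]
        self.gamma_slice = design.gamma_slice
        self.G = np.stack([design.W[r].T @ design.W[r] for r in self.rows])
        self.c_ss = design.interaction_ss_by_study()  # (I, d)
        # random-effect design per study
        self.main_re = config.include_main_random_effects
        self.mod_re = config.include_moderation_random_effects and self.d > 0
        self.m = (2 if self.main_re else 0) + (self.d if self.mod_re else 0)
        self.Z = []
        self.H = []
        if self.m > 0:
            for i, r in enumerate(self.rows):
                cols = []
                if self.main_re:
                    cols.append(np.ones((len(r), 1)))
                    cols.append(design.t[r][:, None])
                if self.mod_re:
                    cols.append(design.Xem[r])
                Z_i = np.hstack(cols)
                self.Z.append(Z_i)
                self.H.append(Z_i.T @ Z_i)
        # least-squares start for theta, residual variances for sigma2
        theta0, *_ = np.linalg.lstsq(self.W, y, rcond=None)
        self.theta0 = theta0
        resid = y - self.W @ theta0
        s2 = np.array(
            [max(float(np.var(resid[r])), 1e-3) for r in self.rows]
        )
        self.sigma2_0 = s2


def _gamma_prior_precision(pre, spec, st, mcmc):
    """Diagonal prior precision of gamma under the current hyperstate."""
    d = pre.d
    if d == 0:
        return np.empty(0)
    if spec.family == "flat":
        return np.zeros(d)
    if spec.family == "horseshoe":
        return 1.0 / (st.lambda2 * st.tau2_hs)
    if spec.family == "ssvs":
        v = st.eta**2 * np.where(st.ind == 1, spec.h_k, 1.0)
        return 1.0 / v
    # g families: Q_k / g_k with Q_k = sum_i c_ik / (sigma_i^2 f_i)
    Q = _qnum(pre, st)
    return Q / st.g


def _qnum(pre, st):
    invsf = 1.0 / (st.sigma2 * st.f)
    return invsf @ pre.c_ss


def _log_g_target(spec, g, Q, gamma, *, N, b):
    """Log full conditional of g_k (vectorized), up to constants."""
    lp = g_log_density(spec, g, N=N, b=b)
    return lp - 0.5 * np.log(g) - Q * gamma**2 / (2.0 * g)


def _slice_sample_bounded(rng, x0, logf, lo, hi, max_shrink=100):
    """Shrinkage slice sampler on a bounded interval (Neal 2003)."""
    y = logf(x0) - rng.exponential()
    left, right = lo, hi
    for _ in range(max_shrink):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


# ---------------------------------------------------------------------------
# main fitting routine
# ---------------------------------------------------------------------------

def fit(
    data: IPDDataset,
    config: ModelConfig,
    spec: PriorSpec,
    mcmc: McmcSettings = FULL_MCMC,
    seed: int | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of the moderation model.

    Parameters
    ----------
    data, config : the dataset and model configuration.
    spec : PriorSpec
        Prior for the moderation effects gamma.
    mcmc : McmcSettings
        Chain configuration; defaults to the full two-chain profile.
    seed : int, optional
        Master seed; chains receive independent child streams.
    """
    design = build_design(data, config)
    if spec.is_g_family and design.d < 1 and spec.family != "flat":
        raise ValueError("shrinkage priors require at least one moderator")
    pre = _Precomputed(design, config, data.y)
    if mcmc.fixed_sigma2 is not None and len(np.atleast_1d(mcmc.fixed_sigma2)) != pre.I:
        raise ValueError("fixed_sigma2 must provide one value per study")
    if not np.all(np.isfinite(data.y)):
        raise RuntimeError("non-finite outcome values; likelihood undefined")

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(mcmc.n_chains)
    store = _allocate_store(pre, spec, config, mcmc)
    for c in range(mcmc.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        _run_chain(pre, spec, config, mcmc, rng, store, c)
    return PosteriorDraws(
        params=store,
        settings=mcmc,
        seed=seed,
        spec_name=spec.name,
        meta={
            "I": pre.I,
            "d": pre.d,
            "N": pre.N,
            "column_names": design.column_names,
        },
    )


def _allocate_store(pre, spec, config, mcmc):
    C, S = mcmc.n_chains, mcmc.n_kept
    d, I = pre.d, pre.I
    store: dict[str, np.ndarray] = {}
    if config.include_main_effects:
        store["mu"] = np.empty((C, S))
        store["alpha"] = np.empty((C, S))
        p = pre.q - 2 - d
        store["beta"] = np.empty((C, S, p))
    if d > 0:
        store["gamma"] = np.empty((C, S, d))
    if pre.main_re:
        store["u_mu"] = np.empty((C, S, I))
        store["u_alpha"] = np.empty((C, S, I))
        store["tau2_mu"] = np.empty((C, S))
        store["tau2_alpha"] = np.empty((C, S))
    if pre.mod_re:
        store["u_mod"] = np.empty((C, S, I, d))
        store["tau2_mod"] = np.empty((C, S, d))
    store["sigma2"] = np.empty((C, S, I))
    if spec.is_g_family:
        store["g"] = np.empty((C, S, d))
        if spec.has_tuning:
            store["p_tune"] = np.empty((C, S, I))
        if spec.has_random_b:
            store["b"] = np.empty((C, S, d))
    if spec.family == "horseshoe":
        store["lambda_hs"] = np.empty((C, S, d))
        store["tau_hs"] = np.empty((C, S))
    if spec.family == "ssvs":
        store["ssvs_ind"] = np.empty((C, S, d))
        store["eta"] = np.empty((C, S))
    return store


def _run_chain(pre, spec, config, mcmc, rng, store, chain):
    st = _ChainState(pre, spec, config, mcmc, rng)
    y, W = pre.y, pre.W
    d, I, m = pre.d, pre.I, pre.m
    gslc = pre.gamma_slice
    N_tot = pre.N_total
    A_hc2 = config.half_cauchy_scale**2
    g_random = (
        spec.is_g_family and not spec.g_is_fixed and mcmc.fixed_g is None
    )
    sigma_free = mcmc.fixed_sigma2 is None
    kept = 0
    inv_s2_long = 1.0 / st.sigma2[pre.srow]

    for it in range(1, mcmc.n_iter + 1):
        # ---- (mu, alpha, beta, gamma) joint Gaussian block ------------
        prec_g = _gamma_prior_precision(pre, spec, st, mcmc)
        A = np.einsum("i,iab->ab", 1.0 / st.sigma2, pre.G).copy()
        if d > 0:
            idx = np.arange(gslc.start, gslc.stop)
            A[idx, idx] += prec_g
        rhs = W.T @ ((y - st.re_contrib) * inv_s2_long)
        st.theta = _chol_draw(rng, A, rhs, "fixed effects")
        fix_mean = W @ st.theta
        gamma = st.theta[gslc] if d > 0 else np.empty(0)

        # ---- study random effects ------------------------------------
        if m > 0:
            resid_fix = y - fix_mean
            inv_tau2 = 1.0 / st.tau2
            for i in range(I):
                P = pre.H[i] / st.sigma2[i]
                P[np.diag_indices(m)] += inv_tau2
                rhs_i = pre.Z[i].T @ resid_fix[pre.rows[i]] / st.sigma2[i]
                st.U[i] = _chol_draw(rng, P, rhs_i, f"random effects study {i + 1}")
                st.re_contrib[pre.rows[i]] = pre.Z[i] @ st.U[i]
            # ---- between-study variances (half-Cauchy via PX) --------
            ssu = np.sum(st.U**2, axis=0)
            st.tau2 = _invgamma(
                rng, (I + 1) / 2.0, 1.0 / st.tau_aux + ssu / 2.0
            )
            st.tau_aux = _invgamma(rng, 1.0, 1.0 / st.tau2 + 1.0 / A_hc2)

        # ---- study noise variances -----------------------------------
        resid = y - fix_mean - st.re_contrib
        if sigma_free:
            ssr = np.bincount(pre.srow, weights=resid**2, minlength=I)
            if spec.is_g_family and d > 0:
                Q = _qnum(pre, st)
                for i in range(I):
                    prop = _invgamma(rng, pre.n_i[i] / 2.0, ssr[i] / 2.0)
                    dinv = 1.0 / (prop * st.f[i]) - 1.0 / (
                        st.sigma2[i] * st.f[i]
                    )
                    Qp = Q + pre.c_ss[i] * dinv
                    delta = float(
                        np.sum(
                            0.5 * (np.log(Qp) - np.log(Q))
                            - gamma**2 / (2.0 * st.g) * (Qp - Q)
                        )
                    )
                    if math.log(rng.uniform()) < delta:
                        st.sigma2[i] = prop
                        Q = Qp
            else:
                st.sigma2 = _invgamma(rng, pre.n_i / 2.0, ssr / 2.0)
            inv_s2_long = 1.0 / st.sigma2[pre.srow]

        # ---- shrinkage hyperparameters -------------------------------
        if spec.is_g_family and d > 0:
            Q = _qnum(pre, st)
            if g_random:
                if spec.g_is_conjugate_ig:
                    s0 = N_tot / 2.0 if spec.family == "nmg" else 0.5
                    st.g = _invgamma(rng, 1.0, s0 + Q * gamma**2 / 2.0)
                else:
                    prop = st.g * np.exp(
                        mcmc.g_step * rng.standard_normal(d)
                    )
                    cur_lp = _log_g_target(
                        spec, st.g, Q, gamma, N=N_tot, b=st.b
                    )
                    new_lp = _log_g_target(
                        spec, prop, Q, gamma, N=N_tot, b=st.b
                    )
                    accept = np.log(rng.uniform(size=d)) < (
                        new_lp - cur_lp + np.log(prop) - np.log(st.g)
                    )
                    st.g = np.where(accept, prop, st.g)
            if spec.has_tuning:
                lo, hi = tuning_support(spec.tuning, pre.n_i)
                for i in range(I):
                    pnew = rng.uniform(lo[i], hi[i])
                    if spec.tuning == "log" and pre.n_i[i] * pnew <= 1.0:
                        continue
                    fnew = float(
                        tuning_function(spec.tuning, pre.n_i[i], pnew)
                    )
                    dinv = 1.0 / (st.sigma2[i] * fnew) - 1.0 / (
                        st.sigma2[i] * st.f[i]
                    )
                    Qp = Q + pre.c_ss[i] * dinv
                    delta = float(
                        np.sum(
                            0.5 * (np.log(Qp) - np.log(Q))
                            - gamma**2 / (2.0 * st.g) * (Qp - Q)
                        )
                    )
                    if math.log(rng.uniform()) < delta:
                        st.p[i] = pnew
                        st.f[i] = fnew
                        Q = Qp
            if spec.has_random_b:
                bprop = rng.uniform(0.0, 2.0, size=d)
                cur = g_log_density(spec, st.g, N=N_tot, b=st.b)
                new = g_log_density(spec, st.g, N=N_tot, b=bprop)
                accept = np.log(rng.uniform(size=d)) < (new - cur)
                st.b = np.where(accept, bprop, st.b)
        elif spec.family == "horseshoe" and d > 0:
            st.lambda2 = _invgamma(
                rng, 1.0, 1.0 / st.nu + gamma**2 / (2.0 * st.tau2_hs)
            )
            st.nu = _invgamma(rng, 1.0, 1.0 + 1.0 / st.lambda2)
            st.tau2_hs = float(
                _invgamma(
                    rng,
                    (d + 1) / 2.0,
                    1.0 / st.xi + float(np.sum(gamma**2 / st.lambda2)) / 2.0,
                )
            )
            st.xi = float(_invgamma(rng, 1.0, 1.0 + 1.0 / st.tau2_hs))
        elif spec.family == "ssvs" and d > 0:
            h = spec.h_k
            lo0 = -0.5 * gamma**2 / st.eta**2 - math.log(st.eta)
            lo1 = -0.5 * gamma**2 / (h * st.eta**2) - math.log(
                st.eta * math.sqrt(h)
            )
            p1 = 1.0 / (1.0 + np.exp(lo0 - lo1))
            st.ind = (rng.uniform(size=d) < p1).astype(np.int64)
            v = np.where(st.ind == 1, h, 1.0)
            ssq = float(np.sum(gamma**2 / v))

            def _eta_logf(e, _ssq=ssq, _d=d):
                return -_d * math.log(e) - _ssq / (2.0 * e**2)

            st.eta = _slice_sample_bounded(
                rng, st.eta, _eta_logf, 1e-8, spec.c
            )

        # ---- store ----------------------------------------------------
        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            _store_draw(store, chain, kept, pre, spec, config, st)
            kept += 1


def _store_draw(store, chain, s, pre, spec, config, st):
    d = pre.d
    off = 0
    if config.include_main_effects:
        store["mu"][chain, s] = st.theta[0]
        store["alpha"][chain, s] = st.theta[1]
        p = pre.q - 2 - d
        store["beta"][chain, s] = st.theta[2 : 2 + p]
    if d > 0:
        store["gamma"][chain, s] = st.theta[pre.gamma_slice]
    if pre.main_re:
        store["u_mu"][chain, s] = st.U[:, 0]
        store["u_alpha"][chain, s] = st.U[:, 1]
        store["tau2_mu"][chain, s] = st.tau2[0]
        store["tau2_alpha"][chain, s] = st.tau2[1]
        off = 2
    if pre.mod_re:
        store["u_mod"][chain, s] = st.U[:, off:]
        store["tau2_mod"][chain, s] = st.tau2[off:]
    store["sigma2"][chain, s] = st.sigma2
    if spec.is_g_family:
        store["g"][chain, s] = st.g
        if spec.has_tuning:
            store["p_tune"][chain, s] = st.p
        if spec.has_random_b:
            store["b"][chain, s] = st.b
    if spec.family == "horseshoe":
        store["lambda_hs"][chain, s] = np.sqrt(st.lambda2)
        store["tau_hs"][chain, s] = math.sqrt(st.tau2_hs)
    if spec.family == "ssvs":
        store["ssvs_ind"][chain, s] = st.ind
        store["eta"][chain, s] = st.eta


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------

def posterior_summary(draws: PosteriorDraws, level: float = 0.95):
    """Posterior mean, SD and equal-tailed credible interval per parameter.

    Means and SDs are over the pooled retained draws; the interval is the
    equal-tailed empirical quantile interval at the stated level.
    """
    import pandas as pd

    if not 0 < level < 1:
        raise ValueError("credible level must lie in (0, 1)")
    frame = draws.scalar_frame()
    if len(frame) < 2:
        raise ValueError("at least 2 retained draws required")
    lo = (1 - level) / 2
    out = pd.DataFrame(
        {
            "mean": frame.mean(),
            "sd": frame.std(ddof=1),
            "lower": frame.quantile(lo),
            "upper": frame.quantile(1 - lo),
        }
    )
    out.index.name = "parameter"
    return out


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    Each chain is split in half; identical constant chains give exactly
    1.0, chains stuck at different constants give +inf.
    """
    C, n = chains.shape
    half = n // 2
    if half < 1:
        return np.nan
    halves = chains[:, : 2 * half].reshape(2 * C, half)
    within = halves.var(axis=1, ddof=1).mean()
    between = half * halves.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else np.inf
    var_hat = (half - 1) / half * within + between / half
    return float(np.sqrt(var_hat / within))


def _param_labels(name: str, shape: tuple) -> list[str]:
    if not shape:
        return [name]
    return [
        name + "".join(f"[{i}]" for i in np.unravel_index(j, shape))
        for j in range(int(np.prod(shape)))
    ]


def convergence_report(draws: PosteriorDraws, rhat_threshold: float = 1.1):
    """Split-chain scale reduction and effective sample size per parameter.

    With a single chain the between-chain (rhat) column is absent.
    Parameters whose scale reduction exceeds ``rhat_threshold`` are
    flagged.
    """
    import arviz as az
    import pandas as pd

    idata = draws.to_inference_data()
    rows: dict[str, dict] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ess = az.ess(idata)
    for name in draws.names():
        arr = draws.params[name]
        shape = arr.shape[2:]
        labels = _param_labels(name, shape)
        e = np.asarray(ess[name]).ravel()
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        for j, lab in enumerate(labels):
            rows[lab] = {"ess": float(e[j])}
            if draws.n_chains >= 2:
                rows[lab]["rhat"] = _split_rhat(flat[:, :, j])
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "parameter"
    if "rhat" in out.columns:
        out["flagged"] = ~(out["rhat"] <= rhat_threshold)
    return out
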