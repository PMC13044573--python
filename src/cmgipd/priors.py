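"""Prior specifications for moderation effects in IPD-MA.

Twenty interchangeable prior families are provided for the moderation
coefficients gamma_k:

* ``Flat`` — pi(gamma_k) ∝ 1 (the non-shrinkage reference);
* ``HS`` — the classical horseshoe, gamma_k ~ N(0, lambda_k^2 tau_hs^2)
  with half-Cauchy local and global scales;
* ``SSVS`` — stochastic search variable selection, a two-component normal
  mixture with a Bernoulli(0.5) inclusion indicator;
* naive mixtures of g-priors (NMG): per-moderator g-priors
  gamma_k ~ N(0, g_k [(t∘x[k])' Λ (t∘x[k])]^{-1}) with the study-noise
  weighting Λ = diag(sigma_i^{-2} 1_{n_i}) and the UIP, ZS, HG (a = 3, 4)
  and HGN (a = 3, 4) rules for g_k;
* calibrated mixtures of g-priors (CMG): the same structure with the
  calibrated weighting Λ* = diag(sigma_i^{-2} f(n_i)^{-1} 1_{n_i}), where
  f(n_i | p_i) is a study-specific sample-size tuning function (linear,
  logarithmic or fractional-power form), combined with the shrinkage
  hyperpriors S1/S2/S3 on g_k/(1+g_k) or the CUIP/CZS rules.

The inverse-gamma convention used throughout is IG(shape, scale) with
density ∝ g^(−shape−1) exp(−scale/g); thus ZS means g_k ~ IG(1/2, N/2) and
CZS means g_k ~ IG(1/2, 1/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

__all__ = [
    "PriorSpec",
    "ShrinkageState",
    "METHOD_NAMES",
    "method_spec",
    "tuning_function",
    "tuning_support",
    "prior_precision_nmg",
    "prior_precision_cmg",
    "hyperprior_logpdf",
    "g_log_density",
    "expected_prior_shrinkage",
    "baseline_prior_logpdf",
]


@dataclass(frozen=True)
class PriorSpec:
    """Tagged description of one prior family for the moderation effects.

    ``family`` is one of ``flat``, ``horseshoe``, ``ssvs``, ``nmg``,
    ``cmg``. NMG specs carry ``g_rule`` in {UIP, ZS, HG, HGN} with ``a`` in
    {3, 4} for HG/HGN. CMG specs carry ``shrink`` in {S1, S2, S3, CUIP,
    CZS} and ``tuning`` in {n, log, pow, none}. ``b_fixed`` freezes the
    Beta shape b_k of the S1/S3 hyperpriors instead of the default
    b_k ~ Uniform(0, 2).
    """

    family: str
    g_rule: str | None = None
    a: int | None = None
    shrink: str | None = None
    tuning: str | None = None
    h_k: float = 100.0
    c: float = 5.0
    b_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("flat", "horseshoe", "ssvs", "nmg", "cmg"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.family == "nmg":
            if self.g_rule not in ("UIP", "ZS", "HG", "HGN"):
                raise ValueError(f"unknown NMG g rule {self.g_rule!r}")
            if self.g_rule in ("HG", "HGN"):
                if self.a is None or self.a <= 2:
                    raise ValueError("HG/HGN require a > 2")
        if self.family == "cmg":
            if self.shrink not in ("S1", "S2", "S3", "CUIP", "CZS"):
                raise ValueError(f"unknown CMG shrinkage {self.shrink!r}")
            if self.shrink == "CUIP":
                if self.tuning not in (None, "none"):
                    raise ValueError("CUIP uses tuning='none'")
                object.__setattr__(self, "tuning", "none")
            elif self.shrink == "CZS":
                if self.tuning not in (None, "n"):
                    raise ValueError("CZS uses the linear tuning form")
                object.__setattr__(self, "tuning", "n")
            elif self.tuning not in ("n", "log", "pow"):
                raise ValueError(f"unknown tuning form {self.tuning!r}")
            if self.b_fixed is not None and not (0 < self.b_fixed <= 2):
                raise ValueError("fixed b_k must lie in (0, 2]")

    # ---- predicates used by the sampler -------------------------------
    @property
    def is_g_family(self) -> bool:
        return self.family in ("nmg", "cmg")

    @property
    def g_is_fixed(self) -> bool:
        """g_k prespecified (UIP: g=N; CUIP: g=1) rather than random."""
        return (self.family == "nmg" and self.g_rule == "UIP") or (
            self.family == "cmg" and self.shrink == "CUIP"
        )

    @property
    def g_is_conjugate_ig(self) -> bool:
        """g_k has an inverse-gamma hyperprior (ZS / CZS) => exact update."""
        return (self.family == "nmg" and self.g_rule == "ZS") or (
            self.family == "cmg" and self.shrink == "CZS"
        )

    @property
    def has_tuning(self) -> bool:
        """Study-level tuning parameters p_i present (CMG, non-CUIP)."""
        return self.family == "cmg" and self.tuning in ("n", "log", "pow")

    @property
    def has_random_b(self) -> bool:
        return (
            self.family == "cmg"
            and self.shrink in ("S1", "S3")
            and self.b_fixed is None
        )

    @property
    def name(self) -> str:
        return _spec_name(self)


def _spec_name(spec: PriorSpec) -> str:
    if spec.family == "flat":
        return "Flat"
    if spec.family == "horseshoe":
        return "HS"
    if spec.family == "ssvs":
        return "SSVS"
    if spec.family == "nmg":
        return spec.g_rule + (str(spec.a) if spec.g_rule in ("HG", "HGN") else "")
    if spec.shrink in ("CUIP", "CZS"):
        return spec.shrink
    return f"CMG-{spec.shrink}-{spec.tuning}"


def _build_registry() -> dict[str, PriorSpec]:
    reg: dict[str, PriorSpec] = {
        "Flat": PriorSpec("flat"),
        "HS": PriorSpec("horseshoe"),
        "SSVS": PriorSpec("ssvs"),
        "UIP": PriorSpec("nmg", g_rule="UIP"),
        "ZS": PriorSpec("nmg", g_rule="ZS"),
        "HG3": PriorSpec("nmg", g_rule="HG", a=3),
        "HG4": PriorSpec("nmg", g_rule="HG", a=4),
        "HGN3": PriorSpec("nmg", g_rule="HGN", a=3),
        "HGN4": PriorSpec("nmg", g_rule="HGN", a=4),
        "CUIP": PriorSpec("cmg", shrink="CUIP"),
        "CZS": PriorSpec("cmg", shrink="CZS"),
    }
    for s in ("S1", "S2", "S3"):
        for f in ("n", "log", "pow"):
            reg[f"CMG-{s}-{f}"] = PriorSpec("cmg", shrink=s, tuning=f)
    return reg


_REGISTRY = _build_registry()
METHOD_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def method_spec(name: str, **overrides) -> PriorSpec:
    """Resolve one of the 20 registered method names to its PriorSpec."""
    try:
        spec = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown method {name!r}; available: {', '.join(METHOD_NAMES)}"
        ) from None
    return replace(spec, **overrides) if overrides else spec


@dataclass
class ShrinkageState:
    """Current values of all shrinkage hyperparameters during sampling."""

    g: np.ndarray | None = None  # (d,) moderator-level shrinkage
    p: np.ndarray | None = None  # (I,) study-level tuning parameters
    b: np.ndarray | None = None  # (d,) Beta shapes of S1/S3
    lambda_hs: np.ndarray | None = None  # (d,) horseshoe local scales
    tau_hs: float | None = None  # horseshoe global scale
    indicators: np.ndarray | None = None  # (d,) SSVS inclusion flags
    eta: float | None = None  # SSVS baseline scale
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# tuning functions f(n_i | p_i)
# ---------------------------------------------------------------------------

def tuning_support(form: str, n_i) -> tuple[np.ndarray, np.ndarray]:
    """Support (lo, hi) of the tuning parameter p_i per study."""
    n_i = np.asarray(n_i, dtype=float)
    if form in ("n", "log"):
        lo = 1.0 / n_i
    elif form == "pow":
        lo = np.zeros_like(n_i)
    else:
        raise ValueError(f"unknown tuning form {form!r}")
    return lo, np.ones_like(n_i)


def tuning_function(form: str, n_i, p_i):
    """Study-specific sample-size tuning f(n_i | p_i).

    ``n``   -> n_i * p_i          with p_i in [1/n_i, 1]
    ``log`` -> log(n_i * p_i)     with p_i in (1/n_i, 1]   (f must be > 0)
    ``pow`` -> n_i ** p_i         with p_i in [0, 1]

    All forms satisfy 1 <= f(n_i) <= n_i at the support endpoints except
    the log form, whose value ranges in (0, log n_i].
    """
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    if form == "n":
        if np.any(p_i < 1.0 / n_i - 1e-12) or np.any(p_i > 1 + 1e-12):
            raise ValueError("linear form requires p_i in [1/n_i, 1]")
        return n_i * p_i
    if form == "log":
        if np.any(p_i < 1.0 / n_i - 1e-12) or np.any(p_i > 1 + 1e-12):
            raise ValueError("log form requires p_i in [1/n_i, 1]")
        f = np.log(n_i * p_i)
        if np.any(f <= 0):
            raise ValueError("log form requires n_i * p_i > 1 so that f > 0")
        return f
    if form == "pow":
        if np.any(p_i < -1e-12) or np.any(p_i > 1 + 1e-12):
            raise ValueError("power form requires p_i in [0, 1]")
        return n_i**p_i
    raise ValueError(f"unknown tuning form {form!r}")


# ---------------------------------------------------------------------------
# prior precisions under Λ and Λ*
# ---------------------------------------------------------------------------

def _interaction_ss(design, k: int) -> np.ndarray:
    col = design.interaction_column(k)
    if not np.any(col != 0):
        raise ValueError(
            f"interaction column {k} is identically zero; g-prior precision singular"
        )
    return np.array([np.sum(col[rows] ** 2) for rows in design.study_rows])


def prior_precision_nmg(k: int, design, sigma2, g_k: float) -> float:
    """Gaussian prior precision of gamma_k under the naive weighting Λ.

    Returns (t∘x[k])' Λ (t∘x[k]) / g_k with Λ = diag(sigma_i^{-2} 1_{n_i});
    the prior variance of gamma_k is the reciprocal.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    ss = _interaction_ss(design, k)
    return float(np.sum(ss / sigma2) / g_k)


def prior_precision_cmg(
    k: int, design, sigma2, g_k: float, p, spec: PriorSpec
) -> float:
    """Gaussian prior precision of gamma_k under the calibrated weighting Λ*.

    Study i's block of Λ* is sigma_i^{-2} f(n_i)^{-1} I_{n_i}; for CUIP the
    tuning collapses to the constant f(n_i) = N.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("sigma2 must be positive")
    ss = _interaction_ss(design, k)
    n_i = np.asarray(design.n_i, dtype=float)
    if spec.tuning == "none":  # CUIP: overall sample-size adjustment
        f = np.full_like(n_i, n_i.sum())
    else:
        f = np.asarray(tuning_function(spec.tuning, n_i, p), dtype=float)
    if np.any(f <= 0):
        raise ValueError("tuning function must be positive")
    return float(np.sum(ss / (sigma2 * f)) / g_k)


# ---------------------------------------------------------------------------
# hyperprior log-densities
# ---------------------------------------------------------------------------

def _ig_logpdf(g, shape: float, scale: float):
    g = np.asarray(g, dtype=float)
    return shape * math.log(scale) - special.gammaln(shape) - (shape + 1) * np.log(
        g
    ) - scale / g


def g_log_density(spec: PriorSpec, g, *, N: float | None = None, b=None):
    """Log hyperprior density of g_k (vectorized over moderators).

    Densities are expressed on the g scale and include the Jacobian of the
    shrinkage-factor transforms w = g/(1+g) and v = g/(g+N). Out-of-support
    values map to −inf.
    """
    g = np.asarray(g, dtype=float)
    out = np.full(np.shape(g), -np.inf, dtype=float)
    ok = g > 0
    if not np.any(ok):
        return out if out.ndim else float(out)
    gv = np.where(ok, g, 1.0)
    if spec.family == "nmg":
        if spec.g_rule == "UIP":
            raise ValueError("UIP fixes g_k = N; it has no hyperprior density")
        if spec.g_rule == "ZS":
            if N is None:
                raise ValueError("ZS requires the total sample size N")
            val = _ig_logpdf(gv, 0.5, N / 2.0)
        elif spec.g_rule == "HG":
            val = math.log((spec.a - 2) / 2.0) - (spec.a / 2.0) * np.log1p(gv)
        else:  # HGN
            if N is None:
                raise ValueError("HGN requires the total sample size N")
            val = math.log((spec.a - 2) / (2.0 * N)) - (spec.a / 2.0) * np.log1p(
                gv / N
            )
    elif spec.family == "cmg":
        if spec.shrink == "CUIP":
            raise ValueError("CUIP fixes g_k = 1; it has no hyperprior density")
        if spec.shrink == "CZS":
            val = _ig_logpdf(gv, 0.5, 0.5)
        elif spec.shrink == "S2":
            val = -2.0 * np.log1p(gv)
        else:
            bb = np.asarray(
                spec.b_fixed if b is None and spec.b_fixed is not None else b,
                dtype=float,
            )
            if bb is None or np.any(np.isnan(bb)):
                raise ValueError("S1/S3 need b_k values")
            if np.any((bb <= 0) | (bb > 2)):
                return out if out.ndim else float(out)
            if spec.shrink == "S1":  # w ~ Beta(2, b)
                val = (
                    np.log(gv)
                    - (bb + 2.0) * np.log1p(gv)
                    - special.betaln(2.0, bb)
                )
            else:  # S3: w ~ Beta(b, 2)
                val = (
                    (bb - 1.0) * np.log(gv)
                    - (bb + 2.0) * np.log1p(gv)
                    - special.betaln(bb, 2.0)
                )
    else:
        raise ValueError(f"{spec.family!r} is not a g-prior family")
    out = np.where(ok, val, -np.inf)
    return out if out.ndim else float(out)


def hyperprior_logpdf(
    spec: PriorSpec,
    state: ShrinkageState,
    *,
    N: float | None = None,
    n_i=None,
) -> float:
    """Joint log-density of all shrinkage hyperparameters of a g-prior spec.

    Sums the g_k log-densities with, where present, the b_k ~ Uniform(0, 2)
    and p_i uniform tuning-parameter densities. Correct up to a
    state-independent constant; out-of-support states return −inf.
    """
    if not spec.is_g_family:
        raise ValueError("hyperprior_logpdf applies to NMG/CMG specs only")
    total = 0.0
    if not spec.g_is_fixed:
        if state.g is None:
            raise ValueError("state.g required")
        lp = g_log_density(spec, state.g, N=N, b=state.b)
        total += float(np.sum(lp))
    if spec.shrink in ("S1", "S3") and spec.b_fixed is None:
        if state.b is None:
            raise ValueError("state.b required for random b_k")
        b = np.asarray(state.b, dtype=float)
        if np.any((b <= 0) | (b > 2)):
            return -np.inf
        total += -len(b) * math.log(2.0)
    if spec.has_tuning:
        if state.p is None or n_i is None:
            raise ValueError("state.p and n_i required for tuned CMG specs")
        p = np.asarray(state.p, dtype=float)
        n = np.asarray(n_i, dtype=float)
        if spec.tuning in ("n", "log"):
            if np.any(p < 1.0 / n) or np.any(p > 1):
                return -np.inf
            if spec.tuning == "log" and np.any(n * p <= 1):
                return -np.inf
            total += float(np.sum(-np.log(1.0 - 1.0 / n)))
        else:  # pow
            if np.any(p < 0) or np.any(p > 1):
                return -np.inf
    return total


# ---------------------------------------------------------------------------
# expected prior shrinkage
# ---------------------------------------------------------------------------

def expected_prior_shrinkage(
    spec: PriorSpec,
    n_draws: int = 1_000_000,
    seed: int | None = None,
    *,
    N: float | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the expected prior shrinkage E[g/(1+g)].

    Marginalizes b_k ~ Uniform(0, 2) when it is random. Returns
    ``(estimate, standard_error)``. Under the default hyperpriors the S1,
    S2 and S3 families have E[g/(1+g)] = ln 2, 1/2 and 1 − ln 2
    respectively (average prior shrinkage toward zero of 31%, 50% and 69%).
    """
    if not spec.is_g_family:
        raise ValueError("expected_prior_shrinkage applies to NMG/CMG specs only")
    rng = np.random.default_rng(seed)
    if spec.family == "nmg" and spec.g_rule == "UIP":
        if N is None:
            raise ValueError("UIP requires N")
        return N / (1.0 + N), 0.0
    if spec.family == "cmg" and spec.shrink == "CUIP":
        return 0.5, 0.0
    if spec.g_is_conjugate_ig:
        scale = (N / 2.0) if spec.family == "nmg" else 0.5
        if spec.family == "nmg" and N is None:
            raise ValueError("ZS requires N")
        g = scale / rng.gamma(0.5, size=n_draws)
        w = g / (1.0 + g)
    elif spec.family == "nmg" and spec.g_rule == "HG":
        w = rng.beta(1.0, spec.a / 2.0 - 1.0, size=n_draws)
    elif spec.family == "nmg" and spec.g_rule == "HGN":
        if N is None:
            raise ValueError("HGN requires N")
        v = rng.beta(1.0, spec.a / 2.0 - 1.0, size=n_draws)
        g = N * v / (1.0 - v)
        w = g / (1.0 + g)
    elif spec.shrink == "S2":
        w = rng.beta(1.0, 1.0, size=n_draws)
    else:  # S1 / S3
        if spec.b_fixed is not None:
            b = np.full(n_draws, spec.b_fixed)
        else:
            b = rng.uniform(0.0, 2.0, size=n_draws)
        if spec.shrink == "S1":
            w = rng.beta(2.0, b)
        else:
            w = rng.beta(b, 2.0)
    est = float(np.mean(w))
    se = float(np.std(w, ddof=1) / math.sqrt(n_draws))
    return est, se


# ---------------------------------------------------------------------------
# baseline (non-g) prior log-densities
# ---------------------------------------------------------------------------

def baseline_prior_logpdf(
    spec: PriorSpec, gamma, state: ShrinkageState | None = None
) -> float:
    """Log prior density of gamma under the Flat / horseshoe / SSVS priors.

    The horseshoe density is conditional on the local scales lambda_k and
    global scale tau_hs; the SSVS density is conditional on the inclusion
    indicators I_k and scale eta.
    """
    gamma = np.atleast_1d(np.asarray(gamma, dtype=float))
    if spec.family == "flat":
        return 0.0
    if state is None:
        raise ValueError("horseshoe/SSVS densities need a ShrinkageState")
    if spec.family == "horseshoe":
        lam = np.asarray(state.lambda_hs, dtype=float)
        tau = float(state.tau_hs)
        if np.any(lam <= 0) or tau <= 0:
            return -np.inf
        return float(np.sum(stats.norm.logpdf(gamma, scale=lam * tau)))
    if spec.family == "ssvs":
        ind = np.asarray(state.indicators)
        eta = float(state.eta)
        if eta <= 0 or eta > spec.c:
            return -np.inf
        sd = eta * np.where(ind == 1, math.sqrt(spec.h_k), 1.0)
        return float(np.sum(stats.norm.logpdf(gamma, scale=sd)))
    raise ValueError(f"{spec.family!r} is not a baseline prior family")
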