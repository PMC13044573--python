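"""Data containers and design-matrix construction for one-stage IPD-MA.

The participant-level model is a linear mixed-effects regression

    y_ij = mu + t_ij*alpha + x_ij' beta + xem_ij' gamma
           + u_mu_i + t_ij*u_alpha_i + xem_ij' u_i + eps_ij,

where i indexes studies, j participants within study, t_ij in {0,1} is the
treatment indicator, x_ij are centered baseline covariates and
xem_ij = t_ij * x_ij[moderators] are the covariate-by-treatment interaction
terms whose coefficients gamma are the moderation effects of interest.

This module holds the validated participant-level container
(:class:`IPDDataset`), the model configuration (:class:`ModelConfig`), the
design matrices (:class:`DesignMatrices`) and readers/writers for the plain
CSV dialect used throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IPDDataset",
    "ModelConfig",
    "DesignMatrices",
    "SchemaError",
    "ValidationError",
    "read_ipd",
    "write_ipd",
    "build_design",
]


class SchemaError(ValueError):
    """A required column is absent or the schema mapping is inconsistent."""


class ValidationError(ValueError):
    """The data violate a contract (e.g., non-binary treatment coding)."""


@dataclass
class IPDDataset:
    """Participant-level IPD-MA data.

    Attributes
    ----------
    study_id : (N,) int array
        Study labels remapped to 1..I in order of first appearance.
    y : (N,) float array
        Continuous outcome.
    t : (N,) int array
        Treatment indicator, 1 = treatment, 0 = control.
    X : (N, p) float array
        Baseline covariates (uncentered; centering happens in
        :func:`build_design`).
    covariate_names : list of str
    rejected_rows : int
        Number of input rows dropped for missing values (mirrors the
        complete-case rule used for participant-level covariates).
    """

    study_id: np.ndarray
    y: np.ndarray
    t: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    rejected_rows: int = 0

    def __post_init__(self) -> None:
        self.study_id = np.asarray(self.study_id, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.t = np.asarray(self.t)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if self.X.shape[0] != self.y.shape[0] and self.X.shape[1] == self.y.shape[0]:
            self.X = self.X.T
        if not self.covariate_names:
            self.covariate_names = [f"x{k + 1}" for k in range(self.X.shape[1])]
        self._validate()

    def _validate(self) -> None:
        n = self.y.shape[0]
        if not (self.study_id.shape[0] == self.t.shape[0] == self.X.shape[0] == n):
            raise ValidationError("study_id, y, t, X must have one row per participant")
        tvals = np.unique(self.t)
        if not np.all(np.isin(tvals, [0, 1])):
            raise ValidationError(
                f"treatment must be coded 0 (control) / 1 (treatment); found {tvals}"
            )
        self.t = self.t.astype(np.int64)
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValidationError("missing values must be removed before construction")
        # remap study ids to 1..I in order of first appearance
        _, first_idx = np.unique(self.study_id, return_index=True)
        order = self.study_id[np.sort(first_idx)]
        mapping = {old: new + 1 for new, old in enumerate(order)}
        self.study_id = np.array([mapping[s] for s in self.study_id], dtype=np.int64)
        counts = np.bincount(self.study_id)[1:]
        if (counts < 2).any():
            raise ValidationError("every study must contribute at least 2 participants")
        for i in range(1, len(counts) + 1):
            arms = np.unique(self.t[self.study_id == i])
            if len(arms) < 2:
                warnings.warn(
                    f"study {i} contains a single treatment arm", stacklevel=3
                )

    @property
    def I(self) -> int:  # noqa: E743 - field name from the model
        return int(self.study_id.max())

    @property
    def n_i(self) -> np.ndarray:
        return np.bincount(self.study_id)[1:]

    @property
    def N(self) -> int:
        return int(self.y.shape[0])

    @property
    def p(self) -> int:
        return int(self.X.shape[1])

    def study_indices(self) -> list[np.ndarray]:
        """Row indices per study, in study order 1..I."""
        return [np.flatnonzero(self.study_id == i + 1) for i in range(self.I)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"study": self.study_id, "y": self.y, "treat": self.t})
        for k, name in enumerate(self.covariate_names):
            df[name] = self.X[:, k]
        return df


@dataclass
class ModelConfig:
    """Configuration of the moderation model fitted to an :class:`IPDDataset`.

    Parameters
    ----------
    moderator_indices : tuple of int
        0-based covariate columns whose treatment interactions enter the
        model (the d moderation effects). ``None`` means all covariates.
    include_moderation_random_effects : bool
        Whether the study-level random effects u_i on the moderation terms
        are included (they can be dropped to reduce model complexity).
    include_main_random_effects : bool
        Whether the random intercept and random treatment effect are
        included. Disabled only for single-study/diagnostic fits.
    include_main_effects : bool
        Whether the fixed intercept, treatment and covariate main-effect
        columns are included. Disabled only for conjugate diagnostics where
        the model reduces to y = Xem * gamma + eps.
    centering : {"grand_mean", "per_study"}
        Covariate centering convention applied before interactions are
        formed. Grand-mean centering keeps gamma interpretable as a common
        interaction across studies and is the default.
    half_cauchy_scale : float
        Scale of the half-Cauchy priors on the between-study SDs.
    """

    moderator_indices: tuple[int, ...] | None = None
    include_moderation_random_effects: bool = True
    include_main_random_effects: bool = True
    include_main_effects: bool = True
    centering: str = "grand_mean"
    half_cauchy_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.centering not in ("grand_mean", "per_study"):
            raise ValueError(f"unknown centering convention {self.centering!r}")
        if self.moderator_indices is not None:
            idx = tuple(int(k) for k in self.moderator_indices)
            if len(set(idx)) != len(idx):
                raise ValueError("moderator_indices must be distinct")
            if any(k < 0 for k in idx):
                raise ValueError("moderator_indices must be nonnegative")
            self.moderator_indices = idx

    def resolve_moderators(self, p: int) -> tuple[int, ...]:
        if self.moderator_indices is None:
            return tuple(range(p))
        if any(k >= p for k in self.moderator_indices):
            raise ValueError("moderator index out of range")
        return self.moderator_indices


@dataclass
class DesignMatrices:
    """Fixed-effect design and bookkeeping for one model fit.

    ``W`` stacks (in order) the intercept column, treatment, the centered
    covariates, and the d interaction columns t ∘ x[k]; when
    ``include_main_effects`` is off only the interaction block is present.
    """

    W: np.ndarray
    column_names: list[str]
    Xc: np.ndarray
    Xem: np.ndarray
    t: np.ndarray
    moderator_indices: tuple[int, ...]
    study_rows: list[np.ndarray]
    n_i: np.ndarray
    include_main_effects: bool

    @property
    def d(self) -> int:
        return int(self.Xem.shape[1])

    @property
    def N(self) -> int:
        return int(self.W.shape[0])

    @property
    def I(self) -> int:  # noqa: E743
        return len(self.study_rows)

    @property
    def gamma_slice(self) -> slice:
        q = self.W.shape[1]
        return slice(q - self.d, q)

    def interaction_column(self, k: int) -> np.ndarray:
        """The k-th moderation column t ∘ x[k] over all participants."""
        return self.Xem[:, k]

    def interaction_ss_by_study(self) -> np.ndarray:
        """(I, d) per-study sums of squares of the interaction columns."""
        out = np.empty((self.I, self.d))
        for i, rows in enumerate(self.study_rows):
            out[i] = np.sum(self.Xem[rows] ** 2, axis=0)
        return out


def read_ipd(
    path,
    schema: dict | None = None,
) -> IPDDataset:
    """Read an IPD CSV into a validated :class:`IPDDataset`.

    The dialect is a UTF-8 header CSV with required columns ``study``,
    ``y`` and ``treat`` (renameable through ``schema``); every remaining
    numeric column is treated as a covariate unless ``schema['covariates']``
    restricts the set. Empty fields and ``NA`` are missing values; rows with
    any missing value are dropped and counted in ``rejected_rows``.

    Parameters
    ----------
    path : path-like
    schema : dict, optional
        Mapping with optional keys ``study``, ``y``, ``treat`` (column
        names in the file) and ``covariates`` (list of columns to keep).
    """
    schema = dict(schema or {})
    study_col = schema.get("study", "study")
    y_col = schema.get("y", "y")
    t_col = schema.get("treat", "treat")
    df = pd.read_csv(path, na_values=["NA"], float_precision="round_trip")
    for col in (study_col, y_col, t_col):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    cov_cols = schema.get("covariates")
    if cov_cols is None:
        cov_cols = [c for c in df.columns if c not in (study_col, y_col, t_col)]
    else:
        missing = [c for c in cov_cols if c not in df.columns]
        if missing:
            raise SchemaError(f"covariate columns not found: {missing}")
    # coerce two-level categorical covariates to 0/1 (sorted level order)
    for c in cov_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            levels = sorted(df[c].dropna().unique())
            if len(levels) != 2:
                raise ValidationError(
                    f"covariate {c!r} is non-numeric with {len(levels)} levels; "
                    "only binary categorical covariates are coerced"
                )
            df[c] = df[c].map({levels[0]: 0.0, levels[1]: 1.0})
    use = df[[study_col, y_col, t_col] + list(cov_cols)]
    complete = use.dropna()
    n_rejected = len(use) - len(complete)
    if n_rejected:
        warnings.warn(
            f"rejected {n_rejected} row(s) with missing values", stacklevel=2
        )
    tvals = np.unique(complete[t_col].to_numpy())
    if not np.all(np.isin(tvals, [0, 1])):
        raise ValidationError(
            f"treatment column {t_col!r} must be coded 0/1; found {tvals}"
        )
    return IPDDataset(
        study_id=complete[study_col].to_numpy(),
        y=complete[y_col].to_numpy(dtype=float),
        t=complete[t_col].to_numpy(dtype=int),
        X=complete[list(cov_cols)].to_numpy(dtype=float),
        covariate_names=list(cov_cols),
        rejected_rows=n_rejected,
    )


def write_ipd(data: IPDDataset, path) -> None:
    """Write a dataset in the package CSV dialect at full precision."""
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def build_design(data: IPDDataset, config: ModelConfig) -> DesignMatrices:
    """Construct the fixed-effect design matrices for the moderation model.

    Covariates are centered per ``config.centering`` before the interaction
    block is formed, so that each interaction column equals the Hadamard
    product of the treatment indicator with the centered covariate.

    Raises
    ------
    ValidationError
        If a selected moderator column is constant over the whole dataset
        (its g-prior precision would be singular).
    """
    mods = config.resolve_moderators(data.p)
    Xc = data.X.astype(float).copy()
    if config.centering == "grand_mean":
        Xc -= Xc.mean(axis=0, keepdims=True)
    else:  # per_study
        for rows in data.study_indices():
            Xc[rows] -= Xc[rows].mean(axis=0, keepdims=True)
    for k in mods:
        if np.allclose(data.X[:, k], data.X[0, k]):
            raise ValidationError(
                f"moderator column {data.covariate_names[k]!r} is constant; "
                "its prior precision would be singular"
            )
    t = data.t.astype(float)
    Xem = t[:, None] * Xc[:, list(mods)] if mods else np.empty((data.N, 0))
    names: list[str] = []
    blocks: list[np.ndarray] = []
    if config.include_main_effects:
        blocks += [np.ones((data.N, 1)), t[:, None], Xc]
        names += ["intercept", "treat"] + list(data.covariate_names)
    blocks.append(Xem)
    names += [f"treat:{data.covariate_names[k]}" for k in mods]
    W = np.hstack(blocks) if blocks else np.empty((data.N, 0))
    return DesignMatrices(
        W=W,
        column_names=names,
        Xc=Xc,
        Xem=Xem,
        t=data.t.astype(float),
        moderator_indices=mods,
        study_rows=data.study_indices(),
        n_i=data.n_i,
        include_main_effects=config.include_main_effects,
    )
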