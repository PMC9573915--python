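"""Poisson count model with an intrinsic CAR (ICAR) spatial field.

The model for region ``i``::

    y_i ~ Poisson(E_i * lambda_i)
    log lambda_i = beta0 + x_i . beta + s_i
    eta_i = log E_i + log lambda_i

with the spatial field ``s`` carrying the improper ICAR density

    p(s | tau)  ∝  exp( - s' Q s / (2 tau^2) ),      Q = D_w - W.

``Q`` annihilates constants on each connected component, so the density is
proper only on the subspace where ``s`` sums to zero within every component;
there its normalizing constant involves the pseudo-determinant of ``Q``
(product of the ``n - k`` positive eigenvalues, ``k`` components).

The joint negative log-likelihood drops the data-constant ``log(y_i!)``
throughout, so reported values differ from the full Poisson likelihood by a
constant that does not depend on any parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import GraphInputError, SpatialGraph

__all__ = [
    "ModelData",
    "ICARParams",
    "LatentField",
    "linear_predictor",
    "icar_quadratic",
    "icar_log_density",
    "joint_nll",
    "relative_risk",
    "model_data_from_csv",
    "log_pdet_Q",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class ModelInputError(ValueError):
    pass


class EvaluationError(FloatingPointError):
    pass


@dataclass(frozen=True)
class ModelData:
    """Counts, offsets and covariates bound to a contiguity graph."""

    y: np.ndarray
    E: np.ndarray
    X: np.ndarray  # (n_regions, p); p may be 0
    graph: SpatialGraph

    def __post_init__(self):
        n = self.graph.n_regions
        y = np.asarray(self.y, dtype=float)
        E = np.asarray(self.E, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(n, -1) if X.size else X.reshape(n, 0)
        if y.shape != (n,):
            raise ModelInputError(f"y has shape {y.shape}, expected ({n},)")
        if E.shape != (n,):
            raise ModelInputError(f"E has shape {E.shape}, expected ({n},)")
        if X.shape[0] != n:
            raise ModelInputError(f"X has {X.shape[0]} rows, expected {n}")
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ModelInputError("y must be nonnegative integers")
        if np.any(E <= 0) or not np.all(np.isfinite(E)):
            raise ModelInputError("all offsets E must be positive and finite")
        if not np.all(np.isfinite(X)):
            raise ModelInputError("covariates must be finite")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "X", X)

    @property
    def n_regions(self) -> int:
        return self.graph.n_regions

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def smr(self) -> np.ndarray:
        """Raw standardized morbidity ratio y / E."""
        return self.y / self.E


@dataclass(frozen=True)
class ICARParams:
    """Fixed-effect parameters: intercept, covariate coefficients, log tau.

    ``tau`` is the dispersion scale multiplying the ICAR field (the quantity
    whose inverse square scales the quadratic penalty); optimization is over
    its unconstrained log.
    """

    beta0: float
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    log_tau: float = 0.0

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "beta", beta)
        if not (np.isfinite(self.beta0) and np.isfinite(self.log_tau) and np.all(np.isfinite(beta))):
            raise ModelInputError("parameters must be finite")

    @property
    def tau(self) -> float:
        return float(np.exp(self.log_tau))

    @property
    def tau2(self) -> float:
        return float(np.exp(2.0 * self.log_tau))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.beta0], self.beta, [self.log_tau]])

    @classmethod
    def from_vector(cls, theta: Sequence[float]) -> "ICARParams":
        theta = np.asarray(theta, dtype=float)
        return cls(beta0=float(theta[0]), beta=theta[1:-1], log_tau=float(theta[-1]))

    @property
    def names(self) -> list[str]:
        return ["beta0"] + [f"beta{j + 1}" for j in range(len(self.beta))] + ["log_tau"]


@dataclass(frozen=True)
class LatentField:
    """Spatial field values, optionally with conditional SDs from a fit."""

    s: np.ndarray
    conditional_sd: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        object.__setattr__(self, "s", s)
        if not np.all(np.isfinite(s)):
            raise ModelInputError("latent field must be finite")
        if self.conditional_sd is not None:
            sd = np.asarray(self.conditional_sd, dtype=float)
            if sd.shape != s.shape:
                raise ModelInputError("conditional_sd shape mismatch")
            object.__setattr__(self, "conditional_sd", sd)

    def component_sums(self, graph: SpatialGraph) -> np.ndarray:
        return np.array([self.s[list(c)].sum() for c in graph.components])


# ---------------------------------------------------------------------------
# Likelihood pieces
# ---------------------------------------------------------------------------

def _field_vector(field, n: int) -> np.ndarray:
    s = field.s if isinstance(field, LatentField) else np.asarray(field, dtype=float)
    if s.shape != (n,):
        raise ModelInputError(f"latent field has shape {s.shape}, expected ({n},)")
    if not np.all(np.isfinite(s)):
        raise ModelInputError("latent field must be finite")
    return s


def log_risk(data: ModelData, params: ICARParams, field) -> np.ndarray:
    """``log lambda = beta0 + X beta + s`` (no offset)."""
    s = _field_vector(field, data.n_regions)
    if len(params.beta) != data.n_covariates:
        raise ModelInputError(
            f"{len(params.beta)} coefficients for {data.n_covariates} covariates"
        )
    out = params.beta0 + s
    if data.n_covariates:
        out = out + data.X @ params.beta
    return out


def linear_predictor(data: ModelData, params: ICARParams, field) -> np.ndarray:
    """``eta_i = log E_i + beta0 + x_i . beta + s_i``."""
    return np.log(data.E) + log_risk(data, params, field)


def relative_risk(params: ICARParams, field, data: ModelData) -> np.ndarray:
    """``lambda_i = exp(beta0 + x_i . beta + s_i)``; fitted mean is E*lambda."""
    return np.exp(log_risk(data, params, field))


def icar_quadratic(field, graph: SpatialGraph) -> float:
    """``s' Q s``, identically the sum of squared neighbour differences."""
    s = _field_vector(field, graph.n_regions)
    return graph.quadratic(s)


def log_pdet_Q(graph: SpatialGraph) -> float:
    """Log pseudo-determinant of Q (sum of logs of positive eigenvalues).

    Computed once per graph by dense symmetric eigendecomposition and cached.
    The number of (numerically) zero eigenvalues always equals the number of
    connected components.
    """
    cache = graph._cache
    if "log_pdet_Q" not in cache:
        n, k = graph.n_regions, graph.n_components
        if n > 5000:
            raise ModelInputError("dense eigendecomposition guard: n > 5000")
        if n == k:  # edgeless graph: Q = 0
            cache["log_pdet_Q"] = 0.0
        else:
            eigs = np.linalg.eigvalsh(graph.Q.toarray())
            positive = eigs[k:]
            if positive.min() <= 0:
                raise EvaluationError("Q has fewer positive eigenvalues than rank")
            cache["log_pdet_Q"] = float(np.log(positive).sum())
    return cache["log_pdet_Q"]


def icar_normalizing_constant(graph: SpatialGraph, log_tau: float) -> float:
    """Log normalizing constant of the ICAR density on the constrained subspace.

    ``-(n-k)/2 log(2 pi) + 1/2 log pdet(Q) - (n-k) log tau``; the ``log tau``
    term is what keeps the dispersion estimable, the rest is theta-free.
    """
    r = graph.rank_Q
    return -0.5 * r * _LOG_2PI + 0.5 * log_pdet_Q(graph) - r * log_tau


def icar_log_density(
    field, graph: SpatialGraph, log_tau: float, normalized: bool = True
) -> float:
    """Log ICAR density ``-s'Qs / (2 tau^2)`` (+ normalizing constant).

    The normalized value is the proper Gaussian log-density of ``s`` with
    respect to Lebesgue measure on the per-component sum-to-zero subspace.
    """
    s = _field_vector(field, graph.n_regions)
    tau2 = np.exp(2.0 * log_tau)
    val = -graph.quadratic(s) / (2.0 * tau2)
    if normalized:
        val += icar_normalizing_constant(graph, log_tau)
    return float(val)


def poisson_nll_terms(data: ModelData, params: ICARParams, field) -> float:
    """``-sum_i [ y_i eta_i - E_i exp(beta0 + X beta + s)_i ]`` (no log y!)."""
    lr = log_risk(data, params, field)
    eta = np.log(data.E) + lr
    with np.errstate(over="raise"):
        try:
            mu = data.E * np.exp(lr)
        except FloatingPointError:
            bad = int(np.argmax(lr))
            raise EvaluationError(
                f"overflow in exp(linear predictor) at region index {bad} "
                f"({data.graph.region_labels[bad]!r}, log-risk {lr[bad]:.2f})"
            ) from None
    return float(-(data.y @ eta - mu.sum()))


def joint_nll(
    data: ModelData, params: ICARParams, field, normalized: bool = True
) -> float:
    """Joint negative log-likelihood of counts and spatial field.

    Poisson terms (log y! dropped) plus the ICAR quadratic penalty
    ``s'Qs / (2 tau^2)``; with ``normalized=True`` (default) the
    tau-dependent ICAR normalizing constant is included, which is required
    for the marginal likelihood in tau to have a finite maximizer.
    """
    s = _field_vector(field, data.n_regions)
    val = poisson_nll_terms(data, params, s)
    val += data.graph.quadratic(s) / (2.0 * params.tau2)
    if normalized:
        val -= icar_normalizing_constant(data.graph, params.log_tau)
    return float(val)


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------

def model_data_from_csv(
    path: str | Path,
    graph: SpatialGraph,
    label_col: str = "region_label",
    y_col: str = "y",
    E_col: str = "E",
    covariate_cols: Sequence[str] = (),
) -> ModelData:
    """Join a (region_label, y, E, covariates...) CSV to a graph by label.

    Rows are reordered to the graph's vertex order; any label mismatch in
    either direction is a hard error listing the offending labels.
    """
    df = pd.read_csv(path)
    for col in [label_col, y_col, E_col, *covariate_cols]:
        if col not in df.columns:
            raise ModelInputError(f"{path}: missing column {col!r}")
    df = df.copy()
    df[label_col] = df[label_col].astype(str)
    if df[label_col].duplicated().any():
        dups = sorted(df[label_col][df[label_col].duplicated()])
        raise ModelInputError(f"{path}: duplicate region labels {dups}")
    have = set(df[label_col])
    want = set(graph.region_labels)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ModelInputError(
            f"{path}: label mismatch with graph; missing from file: {missing}; "
            f"not in graph: {extra}"
        )
    df = df.set_index(label_col).loc[list(graph.region_labels)]
    X = df[list(covariate_cols)].to_numpy(dtype=float) if covariate_cols else np.empty(
        (graph.n_regions, 0)
    )
    return ModelData(
        y=df[y_col].to_numpy(), E=df[E_col].to_numpy(), X=X, graph=graph
    )
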