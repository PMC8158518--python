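"""Simultaneous decomposition of several networks into shared prototypes.

COVSCA (covariance simultaneous component analysis) approximates K symmetric
matrices S_k as nonnegative combinations of L shared low-rank prototypes:

    S_k  ~=  sum_l  c_kl  Z_l Z_l',     c_kl >= 0,

with Z_l of size m x R_l.  The coefficients c_k are the low-dimensional
representation of network k (the score plot coordinates); the prototype
loadings say which variables carry the differences in correlation structure
across the networks.

Fitting minimizes the summed squared Frobenius residual by alternating:
(a) per-k nonnegative least squares for the coefficients given the
prototypes, and (b) for each prototype, the best positive-semidefinite
rank-R_l approximation (clipped eigendecomposition) of the coefficient-
weighted residual aggregate.  Both half-steps solve their subproblem
exactly, so the loss is non-increasing; several random starts guard against
local minima.  Goodness of fit is reported on a 0-100% scale
(100 - 100 * residual / total sum of squares).

Reported prototypes are normalized so each Z_l Z_l' has unit Frobenius norm,
with the scale absorbed into the coefficients; the fitted product is
invariant under this convention.  The order of the L dimensions is
arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls


@dataclass
class CovscaParams:
    n_prototypes: int = 2
    ranks: list[int] = field(default_factory=lambda: [2, 2])
    max_iter: int = 500
    tol: float = 1e-10
    n_starts: int = 10

    def __post_init__(self) -> None:
        if len(self.ranks) != self.n_prototypes:
            raise ValueError("ranks must list one rank per prototype")
        if any(r < 1 for r in self.ranks):
            raise ValueError("prototype ranks must be positive")


@dataclass
class CovscaModel:
    """Fitted model: prototypes, nonnegative coefficients, fit quality."""

    prototypes: list[np.ndarray]   # Z_l, m x R_l, unit-Frobenius Z_l Z_l'
    coefficients: np.ndarray       # K x L, >= 0
    gof: float                     # percent, <= 100
    loss_trace: list[float]        # loss per iteration of the winning start
    matrix_labels: list[str]

    @property
    def L(self) -> int:
        return len(self.prototypes)

    def reconstruct(self, k: int) -> np.ndarray:
        return sum(
            self.coefficients[k, l] * self.prototypes[l] @ self.prototypes[l].T
            for l in range(self.L)
        )


def _loss(S_list, coeff, protos) -> float:
    total = 0.0
    for k, S in enumerate(S_list):
        res = S - sum(
            coeff[k, l] * protos[l] @ protos[l].T for l in range(len(protos))
        )
        total += np.sum(res**2)
    return total


def _coefficient_step(S_list, protos) -> np.ndarray:
    """Per-matrix NNLS over the vectorized prototype outer products."""
    G = np.column_stack([(z @ z.T).ravel() for z in protos])
    coeff = np.empty((len(S_list), len(protos)))
    for k, S in enumerate(S_list):
        coeff[k], _ = nnls(G, S.ravel())
    return coeff


def _prototype_step(S_list, coeff, protos, ranks) -> list[np.ndarray]:
    """Update each Z_l as the clipped-eigen best PSD rank-R_l approximation
    of its coefficient-weighted residual aggregate."""
    protos = [z.copy() for z in protos]
    L = len(protos)
    for l in range(L):
        c = coeff[:, l]
        denom = np.sum(c**2)
        if denom == 0:
            continue  # unused prototype: leave as is
        M = np.zeros_like(S_list[0])
        for k, S in enumerate(S_list):
            if c[k] == 0:
                continue
            res = S - sum(
                coeff[k, j] * protos[j] @ protos[j].T for j in range(L) if j != l
            )
            M += c[k] * res
        M /= denom
        M = (M + M.T) / 2
        evals, evecs = np.linalg.eigh(M)
        order = np.argsort(evals)[::-1][: ranks[l]]
        lam = np.clip(evals[order], 0.0, None)
        protos[l] = evecs[:, order] * np.sqrt(lam)
    return protos


def _normalize(coeff, protos):
    coeff = coeff.copy()
    out = []
    for l, z in enumerate(protos):
        nrm = np.linalg.norm(z @ z.T, "fro")
        if nrm > 0:
            out.append(z / nrm**0.5)
            coeff[:, l] *= nrm
        else:
            out.append(z)
    return coeff, out


def fit_covsca(
    S_list,
    L: int = 2,
    ranks: list[int] | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
    n_starts: int = 10,
    seed: int | None = None,
    matrix_labels: list[str] | None = None,
) -> CovscaModel:
    """Fit the prototype model to K symmetric matrices by alternating
    minimization with multiple random starts; best start kept."""
    ranks = ranks if ranks is not None else [2] * L
    if len(ranks) != L:
        raise ValueError("ranks must have length L")
    S_list = [np.asarray(S, dtype=float) for S in S_list]
    m = S_list[0].shape[0]
    for k, S in enumerate(S_list):
        if S.shape != (m, m):
            raise ValueError("all matrices must share the same dimension")
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError(f"matrix {k} is not symmetric")
    if all(np.all(S == 0) for S in S_list):
        raise ValueError("all matrices are zero")
    if m < max(ranks):
        raise ValueError("prototype rank exceeds the matrix dimension")

    rng = np.random.default_rng(seed)
    total_ss = sum(np.sum(S**2) for S in S_list)
    best = None
    for _ in range(n_starts):
        protos = [rng.standard_normal((m, r)) for r in ranks]
        trace: list[float] = []
        prev = np.inf
        for _ in range(max_iter):
            coeff = _coefficient_step(S_list, protos)
            protos = _prototype_step(S_list, coeff, protos, ranks)
            cur = _loss(S_list, coeff, protos)
            trace.append(cur)
            if prev - cur < tol * max(prev, 1e-30):
                break
            prev = cur
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], coeff, protos, trace)

    loss, coeff, protos, trace = best
    coeff, protos = _normalize(coeff, protos)
    gof = 100.0 * (1.0 - loss / total_ss)
    labels = matrix_labels or [f"S{k}" for k in range(len(S_list))]
    return CovscaModel(
        prototypes=protos,
        coefficients=coeff,
        gof=float(gof),
        loss_trace=trace,
        matrix_labels=list(labels),
    )


def covsca_scores(model: CovscaModel) -> pd.DataFrame:
    """K x L coefficient table — the score-plot coordinates per network."""
    return pd.DataFrame(
        model.coefficients,
        index=model.matrix_labels,
        columns=[f"dim{l + 1}" for l in range(model.L)],
    )


def loading_table(model: CovscaModel, node_names=None) -> pd.DataFrame:
    """Prototype loadings, one column per (dimension, rank) pair."""
    cols = {}
    for l, z in enumerate(model.prototypes):
        for r in range(z.shape[1]):
            cols[f"dim{l + 1}_r{r + 1}"] = z[:, r]
    idx = node_names if node_names is not None else range(
        model.prototypes[0].shape[0]
    )
    return pd.DataFrame(cols, index=idx)


def prune_loadings(
    model: CovscaModel, z_min: float = 1.0, node_names=None
) -> pd.DataFrame:
    """Zero out loadings with |z| below ``z_min`` (z across the m entries).

    Loadings are signed, so the pruning is two-sided.  ``z_min = 0`` keeps
    everything.  A constant loading column has no z-scores; it prunes to all
    zeros with a warning.
    """
    table = loading_table(model, node_names)
    pruned = table.copy()
    for col in table.columns:
        v = table[col].to_numpy()
        sd = v.std(ddof=1)
        if sd == 0:
            warnings.warn(f"constant loading column {col!r}: all pruned",
                          stacklevel=2)
            if z_min > 0:
                pruned[col] = 0.0
            continue
        z = (v - v.mean()) / sd
        pruned[col] = np.where(np.abs(z) >= z_min, v, 0.0)
    return pruned
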