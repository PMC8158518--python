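"""PCA and Tracy-Widom counting of signal-bearing principal components.

The number of "real" components is estimated by sequentially testing the
largest remaining eigenvalue of the sample correlation matrix against the
null of uncorrelated variables: under that null, the suitably centered and
scaled largest eigenvalue of a white Wishart matrix follows the Tracy-Widom
law of order 1 (TW1).  Testing proceeds greatest-first, shrinking the
effective dimension by one per accepted component, and stops at the first
non-significant eigenvalue.

The TW1 distribution is evaluated from its Painleve II representation:
with q the Hastings-McLeod solution of q'' = s q + 2 q^3 (q ~ Ai(s) as
s -> +inf),

    F2(s) = exp(-int_s^inf (x - s) q(x)^2 dx),
    F1(s) = sqrt(F2(s)) * exp(-0.5 * int_s^inf q(x) dx).

The ODE system (q, q', and the two integrals) is integrated once, downward
from s = 10, and cached as an interpolant; accuracy in the tail used here
is ~1e-6, well inside the 1e-2 agreement required against published
critical values (0.9793 / 2.0234 / 3.2724 at the 95/99/99.9 percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, interpolate, optimize, special

from .preprocess import ValidationError


# --------------------------------------------------------------------------
# Tracy-Widom (beta = 1) distribution
# --------------------------------------------------------------------------

class TracyWidom1:
    """TW1 distribution via Painleve II, integrated once and memoized."""

    _S_MAX = 10.0
    _S_MIN = -10.0

    def __init__(self) -> None:
        s0 = self._S_MAX
        ai, aip, _, _ = special.airy(s0)
        # integrals of Ai and (x - s0) Ai^2 on [s0, inf)
        i0 = 1.0 / 3.0 - special.itairy(s0)[0]
        r0 = aip**2 - s0 * ai**2
        t0 = integrate.quad(
            lambda x: (x - s0) * special.airy(x)[0] ** 2, s0, np.inf
        )[0]

        def rhs(s, y):
            q, qp, _, r, _ = y
            return [qp, s * q + 2.0 * q**3, -q, -(q**2), -r]

        grid = np.linspace(s0, self._S_MIN, 2001)
        sol = integrate.solve_ivp(
            rhs,
            (s0, self._S_MIN),
            [ai, aip, i0, r0, t0],
            t_eval=grid,
            rtol=1e-11,
            atol=1e-13,
            method="RK45",
        )
        s = sol.t[::-1]
        iq = sol.y[2][::-1]
        tq = sol.y[4][::-1]
        cdf = np.exp(-0.5 * tq - 0.5 * iq)
        cdf = np.clip(cdf, 0.0, 1.0)
        self._cdf = interpolate.CubicSpline(s, cdf)

    def cdf(self, s):
        s = np.asarray(s, dtype=float)
        out = np.where(
            s <= self._S_MIN, 0.0,
            np.where(s >= self._S_MAX, 1.0, self._cdf(np.clip(s, self._S_MIN, self._S_MAX))),
        )
        return np.clip(out, 0.0, 1.0)

    def sf(self, s):
        return 1.0 - self.cdf(s)

    def ppf(self, p: float) -> float:
        if not 0 < p < 1:
            raise ValueError("p must lie in (0, 1)")
        return float(
            optimize.brentq(lambda s: self.cdf(s) - p, self._S_MIN, self._S_MAX)
        )


_TW1: TracyWidom1 | None = None


def tw1() -> TracyWidom1:
    """Shared TW1 instance (built on first use)."""
    global _TW1
    if _TW1 is None:
        _TW1 = TracyWidom1()
    return _TW1


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass
class PcaModel:
    """Eigendecomposition of the sample covariance of (autoscaled) data."""

    scores: np.ndarray      # samples x components
    loadings: np.ndarray    # variables x components (orthonormal columns)
    eigenvalues: np.ndarray  # descending, >= 0


def fit_pca(matrix) -> PcaModel:
    """PCA by eigendecomposition of the sample covariance matrix.

    Input is expected autoscaled, in which case the covariance equals the
    correlation matrix and the eigenvalues sum to the number of variables.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("PCA needs at least two samples")
    cov = np.cov(x, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    return PcaModel(scores=x @ evecs, loadings=evecs, eigenvalues=evals)


# --------------------------------------------------------------------------
# sequential Tracy-Widom test
# --------------------------------------------------------------------------

@dataclass
class TwReport:
    """Sequential largest-eigenvalue test report.

    ``n_significant`` components passed at level ``alpha``; per-component
    arrays cover every eigenvalue (the test stops at the first failure, but
    statistics and p-values are reported for all of them).
    """

    eigenvalues: np.ndarray
    statistics: np.ndarray
    p_values: np.ndarray
    n_significant: int
    alpha: float


def tracy_widom_count(
    eigenvalues, n: int, m: int | None = None, alpha: float = 0.001
) -> TwReport:
    """Count signal components by sequential Tracy-Widom testing.

    For the k-th test the remaining eigenvalues are treated as coming from
    a white Wishart of effective dimension ``p = m - k + 1`` with ``n``
    samples: the leading eigenvalue is rescaled to ``n * lam / mean(remaining)``,
    centered with the Johnstone constants

        mu = (sqrt(n - 1) + sqrt(p))^2,
        sigma = (sqrt(n - 1) + sqrt(p)) * (1/sqrt(n - 1) + 1/sqrt(p))^(1/3),

    and compared to TW1.  Counting stops at the first non-significant
    component.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-10):
        raise ValidationError("eigenvalues must be in descending order")
    m = lam.size if m is None else m
    dist = tw1()
    stats_out = np.full(lam.size, np.nan)
    pvals = np.full(lam.size, np.nan)
    count = 0
    counting = True
    for k in range(lam.size):
        remaining = lam[k:]
        if remaining.sum() <= 0:
            break
        p_eff = m - k
        if p_eff < 1:
            break
        ell = n * remaining[0] / remaining.mean()
        sq_n = np.sqrt(n - 1)
        sq_p = np.sqrt(p_eff)
        mu = (sq_n + sq_p) ** 2
        sigma = (sq_n + sq_p) * (1.0 / sq_n + 1.0 / sq_p) ** (1.0 / 3.0)
        stat = (ell - mu) / sigma
        pv = float(dist.sf(stat))
        stats_out[k] = stat
        pvals[k] = pv
        if counting:
            if pv < alpha:
                count += 1
            else:
                counting = False
    return TwReport(
        eigenvalues=lam,
        statistics=stats_out,
        p_values=pvals,
        n_significant=count,
        alpha=alpha,
    )
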