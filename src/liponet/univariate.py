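"""Group-difference testing and single-variable ROC characterization.

Each lipoprotein fraction is compared between two groups with the
Mann-Whitney-Wilcoxon rank-sum test, Bonferroni-corrected over the panel.
ROC analysis uses the U-statistic identity AUC = U / (n1 * n2), stratified
bootstrap percentile confidence intervals, and a Youden-J operating
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .profile import LipidProfileTable


def wilcoxon_test(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test of two independent samples.

    Returns ``(U, p)`` where ``U`` counts pairs ``(a, b)`` with ``a > b``
    plus half the ties (the U statistic of the first sample).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: multiply by the number of tests, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    if m < p.size:
        raise ValueError(f"test count m={m} smaller than the number of p-values")
    return np.minimum(1.0, p * m)


def auc_from_u(U: float, n1: int, n2: int) -> float:
    """AUC from the rank-sum statistic: AUC = U / (n1 * n2)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if U > n1 * n2 or U < 0:
        raise ValueError("U outside [0, n1*n2]")
    return float(U) / (n1 * n2)


@dataclass
class RocResult:
    """Single-variable ROC summary for one fraction.

    ``auc`` is oriented to be >= 0.5 (``auc_raw`` keeps the unoriented
    value and ``direction`` records which group tends higher); the CI is a
    stratified-bootstrap percentile interval on the oriented AUC; the
    threshold maximizes Youden's J, at which accuracy, specificity and
    sensitivity are reported.
    """

    auc: float
    auc_raw: float
    direction: str
    ci_lower: float
    ci_upper: float
    threshold: float
    accuracy: float
    specificity: float
    sensitivity: float
    p_value: float


def _oriented_auc(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    u, _ = wilcoxon_test(x, y)
    raw = auc_from_u(u, x.size, y.size)
    return max(raw, 1 - raw), raw


def roc_analysis(
    x, y, n_boot: int = 2000, seed: int | None = None, ci: float = 0.95
) -> RocResult:
    """ROC analysis of one variable between group A (``x``) and B (``y``).

    The bootstrap is stratified: each replicate resamples within the two
    groups separately, preserving their sizes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per group")
    u, p = wilcoxon_test(x, y)
    raw = auc_from_u(u, x.size, y.size)
    auc = max(raw, 1 - raw)
    direction = "A>B" if raw >= 0.5 else "B>A"

    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("constant variable: AUC fixed at 0.5", stacklevel=2)
        return RocResult(0.5, 0.5, direction, 0.5, 0.5, float(x[0]), 0.5, 0.0, 1.0, p)

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        xb = rng.choice(x, size=x.size, replace=True)
        yb = rng.choice(y, size=y.size, replace=True)
        boot[b], _ = _oriented_auc(xb, yb)
    alpha = 1 - ci
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])

    # Youden-J threshold over the observed cut-points; positive class is the
    # group the oriented AUC says tends higher.
    labels = np.concatenate([np.ones(x.size), np.zeros(y.size)])
    if direction == "B>A":
        labels = 1 - labels
    values = np.concatenate([x, y])
    fpr, tpr, thr = roc_curve(labels, values)
    j = tpr - fpr
    best = int(np.argmax(j))
    threshold = float(thr[best])
    if not np.isfinite(threshold):
        threshold = float(values.max())
    pred = values >= threshold
    pos = labels == 1
    sensitivity = float(pred[pos].mean())
    specificity = float((~pred[~pos]).mean())
    accuracy = float((pred == pos).mean())
    return RocResult(
        auc=auc,
        auc_raw=raw,
        direction=direction,
        ci_lower=float(lo),
        ci_upper=float(hi),
        threshold=threshold,
        accuracy=accuracy,
        specificity=specificity,
        sensitivity=sensitivity,
        p_value=p,
    )


# --------------------------------------------------------------------------
# per-panel tables
# --------------------------------------------------------------------------

def univariate_table(
    table: LipidProfileTable,
    mask_a,
    mask_b,
    group_names: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Concentration comparison of every fraction between two groups.

    Columns: per-group median concentration (mg/dL), U statistic, raw and
    Bonferroni-adjusted p, and a significance flag at family-wise ``alpha``.
    Tests run on raw concentrations (rank-based, transform-invariant).
    """
    a = table.concentrations.loc[mask_a]
    b = table.concentrations.loc[mask_b]
    rows = []
    for name in table.fraction_names:
        u, p = wilcoxon_test(a[name], b[name])
        rows.append(
            {
                "fraction": name,
                f"median_{group_names[0]}": float(np.median(a[name])),
                f"median_{group_names[1]}": float(np.median(b[name])),
                "U": u,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("fraction")
    out["p_adjusted"] = bonferroni(out["p_value"].to_numpy())
    out["significant"] = out["p_adjusted"] < alpha
    return out


def roc_table(
    table: LipidProfileTable,
    mask_a,
    mask_b,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-fraction ROC analysis between two groups (one row per fraction)."""
    a = table.concentrations.loc[mask_a]
    b = table.concentrations.loc[mask_b]
    rng = np.random.default_rng(seed)
    rows = []
    for name in table.fraction_names:
        r = roc_analysis(
            a[name], b[name], n_boot=n_boot,
            seed=int(rng.integers(2**31 - 1)),
        )
        rows.append(
            {
                "fraction": name,
                "auc": r.auc,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "threshold": r.threshold,
                "accuracy": r.accuracy,
                "specificity": r.specificity,
                "sensitivity": r.sensitivity,
                "p_value": r.p_value,
                "auc_raw": r.auc_raw,
                "direction": r.direction,
            }
        )
    out = pd.DataFrame(rows).set_index("fraction")
    out["p_adjusted"] = bonferroni(out["p_value"].to_numpy())
    return out
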