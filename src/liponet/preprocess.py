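"""Variance stabilization, scaling, and age-group stratification.

The preprocessing chain applied before any multivariate step is: square-root
transform of the concentrations (variance stabilization for right-skewed,
positive data) followed by autoscaling (centering to zero mean, unit sample
variance per column).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profile import LipidProfileTable, ValidationError

#: Group labels: sexes and age strata within sex (Y = young, O = old).
GROUP_LABELS = ("W", "M", "YM", "OM", "YW", "OW")


@dataclass
class StratifiedGroups:
    """Sex and age-group membership for every sample.

    ``labels`` maps each group label to a boolean membership mask over the
    table index.  Young/old strata within a sex are disjoint; samples in the
    middle tertile of the within-sex age distribution belong to the sex-level
    group only.  ``boundaries`` records the (lower, upper) percentile ages
    used per sex.
    """

    labels: dict[str, pd.Series]
    boundaries: dict[str, tuple[float, float]]

    def members(self, group: str) -> pd.Index:
        return self.labels[group].index[self.labels[group]]


def sqrt_transform(table: LipidProfileTable) -> LipidProfileTable:
    """Element-wise square root of the concentrations; metadata untouched."""
    values = table.concentrations.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValidationError("negative concentration: square root undefined")
    return LipidProfileTable(np.sqrt(table.concentrations), table.sex, table.age)


def autoscale(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Center each column to mean zero and scale to unit sample variance.

    Uses the n-1 denominator.  A zero-variance column is an error (it cannot
    carry unit variance), reported by name/position.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("autoscale needs a 2-D matrix with >= 2 rows")
    sd = values.std(axis=0, ddof=1)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        name = matrix.columns[j] if isinstance(matrix, pd.DataFrame) else j
        raise ValidationError(f"zero-variance column {name!r} cannot be autoscaled")
    out = (values - values.mean(axis=0)) / sd
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def preprocess_matrix(table: LipidProfileTable) -> pd.DataFrame:
    """Full chain: square-root transform then autoscale (in that order)."""
    return autoscale(sqrt_transform(table).concentrations)


def stratify_by_age(
    table: LipidProfileTable,
    lower: float = 0.33,
    upper: float = 0.67,
) -> StratifiedGroups:
    """Split each sex into young/old strata by within-sex age percentiles.

    Per sex, the boundaries are the ``lower`` (default 33%) and ``upper``
    (default 67%) linear-interpolation percentiles of that sex's age
    distribution.  Young = strictly below the lower boundary, old = strictly
    above the upper boundary; the middle tertile is assigned to neither
    stratum but stays in the sex-level group.
    """
    labels: dict[str, pd.Series] = {}
    boundaries: dict[str, tuple[float, float]] = {}
    index = table.concentrations.index
    for sex in ("M", "W"):
        in_sex = table.sex == sex
        ages = table.age[in_sex]
        if in_sex.sum() == 0:
            # sex absent from this table: all its groups are empty
            prefix = {"M": ("M", "YM", "OM"), "W": ("W", "YW", "OW")}[sex]
            for label in prefix:
                labels[label] = pd.Series(False, index=index)
            boundaries[sex] = (np.nan, np.nan)
            continue
        if in_sex.sum() < 3:
            raise ValidationError(
                f"sex group {sex!r} has {int(in_sex.sum())} subjects; need >= 3"
            )
        lo = float(np.quantile(ages, lower))
        hi = float(np.quantile(ages, upper))
        boundaries[sex] = (lo, hi)
        young = in_sex & (table.age < lo)
        old = in_sex & (table.age > hi)
        if not young.any() and not old.any():
            warnings.warn(
                f"degenerate age distribution for sex {sex!r}: both strata empty",
                stacklevel=2,
            )
        labels[sex] = pd.Series(in_sex, index=index)
        prefix = {"M": ("YM", "OM"), "W": ("YW", "OW")}[sex]
        labels[prefix[0]] = pd.Series(young, index=index)
        labels[prefix[1]] = pd.Series(old, index=index)
    return StratifiedGroups(labels=labels, boundaries=boundaries)
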