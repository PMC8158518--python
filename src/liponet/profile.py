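"""The samples-by-fractions concentration table used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_CODES = ("M", "W")


class ValidationError(ValueError):
    """Raised when an input table violates the profile-table contract."""


@dataclass
class LipidProfileTable:
    """Lipoprotein main-fraction concentrations with per-sample metadata.

    Parameters
    ----------
    concentrations
        ``n_samples x m`` DataFrame of non-negative concentrations (mg/dL);
        columns are the fraction names (``m = 21`` for the standard panel),
        index holds the sample identifiers.
    sex
        Per-sample sex code, ``"M"`` (men) or ``"W"`` (women), aligned with
        the concentration index.
    age
        Per-sample age in years, aligned with the concentration index.
    """

    concentrations: pd.DataFrame
    sex: pd.Series
    age: pd.Series

    def __post_init__(self) -> None:
        conc = self.concentrations
        if conc.shape[0] == 0 or conc.shape[1] == 0:
            raise ValidationError("profile table is empty")
        if len(self.sex) != len(conc) or len(self.age) != len(conc):
            raise ValidationError(
                "sex/age metadata length does not match the concentration table"
            )
        self.sex = pd.Series(np.asarray(self.sex, dtype=object), index=conc.index)
        self.age = pd.Series(np.asarray(self.age, dtype=float), index=conc.index)
        bad_sex = set(self.sex.unique()) - set(SEX_CODES)
        if bad_sex:
            raise ValidationError(f"unknown sex code(s): {sorted(map(str, bad_sex))}")
        if any(not isinstance(c, str) or not c for c in conc.columns):
            raise ValidationError("missing or non-string fraction name in header")
        values = conc.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing concentration at row {conc.index[r]!r}, "
                f"column {conc.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative concentration at row {conc.index[r]!r}, "
                f"column {conc.columns[c]!r}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_id(self) -> list[str]:
        return [str(i) for i in self.concentrations.index]

    @property
    def fraction_names(self) -> list[str]:
        return list(self.concentrations.columns)

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_fractions(self) -> int:
        return self.concentrations.shape[1]

    def values(self) -> np.ndarray:
        """Concentration matrix as a float array (samples x fractions)."""
        return self.concentrations.to_numpy(dtype=float)

    def subset(self, mask) -> "LipidProfileTable":
        """Row subset by boolean mask or index array, metadata kept aligned."""
        return LipidProfileTable(
            self.concentrations.loc[mask],
            self.sex.loc[mask],
            self.age.loc[mask],
        )
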