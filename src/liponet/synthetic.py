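"""Synthetic cohorts and model-generated inputs with known ground truth.

Three generators live here:

* :func:`generate_cohort` draws a donor cohort whose group sizes, age strata
  and per-fraction median shifts follow the default study design (844
  subjects, 661 men / 183 women, within-sex age tertiles), with
  class-structured correlation between fractions.  The construction is
  Gaussian on the square-root concentration scale, so the package's
  variance-stabilizing transform exactly Gaussianizes the data.
* :func:`generate_from_planted_network` samples from a multivariate normal
  whose precision matrix realizes a known partial-correlation network —
  the ground truth for network-recovery tests.
* :func:`generate_covsca_instances` builds covariance-like matrices exactly
  from the low-rank prototype model, the ground truth for the COVSCA fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fractions import FRACTION_NAMES, GROUP_MEDIANS, fraction_class
from .profile import LipidProfileTable


# --------------------------------------------------------------------------
# cohort design
# --------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Design of a synthetic donor cohort.

    Attributes
    ----------
    group_sizes
        Number of subjects per sex, e.g. ``{"M": 661, "W": 183}``.
    strata_sizes
        Number of subjects in the young/old stratum per sex,
        e.g. ``{"YM": 216, "OM": 213, "YW": 56, "OW": 60}``; the remainder
        of each sex fills the middle tertile.
    age_medians
        Target median age (years) per stratum label (YM, OM, YW, OW).
    strata_boundaries
        Per sex, the (young-upper, old-lower) boundary ages in years.
    age_range
        Overall (min, max) donor age.
    group_medians
        Per-fraction target median concentration (mg/dL) per group
        (columns M, W, YM, OM, YW, OW); rows are fraction names.
    within_class_corr, between_class_corr
        Latent correlation between fractions of the same / different
        lipoprotein density class.
    noise_sd
        Coefficient of variation on the square-root concentration scale,
        relative to the square root of the men's median; held constant
        across groups so the square-root transform is exactly
        variance-stabilizing.
    seed
        Default random seed for :func:`generate_cohort`.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"M": 661, "W": 183}
    )
    strata_sizes: dict[str, int] = field(
        default_factory=lambda: {"YM": 216, "OM": 213, "YW": 56, "OW": 60}
    )
    age_medians: dict[str, float] = field(
        default_factory=lambda: {"YM": 29, "OM": 52, "YW": 27, "OW": 55}
    )
    strata_boundaries: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"M": (35.0, 45.0), "W": (37.0, 48.0)}
    )
    age_range: tuple[float, float] = (18.0, 60.0)
    group_medians: pd.DataFrame = field(default_factory=lambda: GROUP_MEDIANS.copy())
    within_class_corr: float = 0.6
    between_class_corr: float = 0.2
    noise_sd: float = 0.12
    seed: int = 0

    @property
    def total(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def base_medians(self) -> pd.Series:
        """Reference (men's) per-fraction medians, mg/dL."""
        return self.group_medians["M"]

    @property
    def effect_table(self) -> pd.DataFrame:
        """Multiplicative median shift of each group relative to the men's
        reference column; encodes the sex/age effect directions."""
        return self.group_medians.div(self.base_medians, axis=0)

    def latent_correlation(self) -> np.ndarray:
        """Class-block latent correlation matrix over the fractions."""
        names = list(self.group_medians.index)
        classes = [fraction_class(n) for n in names]
        m = len(names)
        corr = np.full((m, m), self.between_class_corr)
        for i in range(m):
            for j in range(m):
                if classes[i] == classes[j]:
                    corr[i, j] = self.within_class_corr
        np.fill_diagonal(corr, 1.0)
        if not (-1 < self.between_class_corr < 1 and -1 < self.within_class_corr < 1):
            raise ValueError("correlation levels must lie in (-1, 1)")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("block correlation matrix is not positive definite")
        return corr


def default_study_design() -> SyntheticCohortSpec:
    """The default cohort design: 844 donors, 661 men / 183 women, with
    age strata YM=216, OM=213, YW=56, OW=60 and the default median table."""
    return SyntheticCohortSpec()


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _triangular_mode(lo: float, hi: float, median: float) -> float:
    """Mode of a triangular(lo, mode, hi) with the requested median."""
    if not lo < median < hi:
        raise ValueError("median must lie strictly inside the age interval")
    mid = 0.5 * (lo + hi)
    if median >= mid:
        # median = lo + sqrt((hi-lo)(mode-lo)/2)
        mode = lo + 2 * (median - lo) ** 2 / (hi - lo)
    else:
        # median = hi - sqrt((hi-lo)(hi-mode)/2)
        mode = hi - 2 * (hi - median) ** 2 / (hi - lo)
    return float(np.clip(mode, lo, hi))


def _draw_ages(rng, n: int, lo: float, hi: float, median: float | None) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    if median is None:
        return rng.uniform(lo, hi, size=n)
    return rng.triangular(lo, _triangular_mode(lo, hi, median), hi, size=n)


def generate_cohort(
    spec: SyntheticCohortSpec | None = None, seed: int | None = None
) -> LipidProfileTable:
    """Draw a cohort table from the design in ``spec``.

    Each subject belongs to a planted stratum (young / middle / old within
    sex).  On the square-root concentration scale the fractions are jointly
    Gaussian: mean ``sqrt(median of the subject's group)``, standard
    deviation ``noise_sd * sqrt(men's reference median)`` (identical across
    groups), and correlation given by the class-block matrix.  Squaring
    returns strictly positive, right-skewed concentrations whose group
    medians follow the design's effect table.
    """
    spec = spec or default_study_design()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    corr = spec.latent_correlation()
    chol = np.linalg.cholesky(corr)
    names = list(spec.group_medians.index)
    m = len(names)
    sd = spec.noise_sd * np.sqrt(spec.base_medians.to_numpy())

    rows, sexes, ages = [], [], []
    for sex in ("M", "W"):
        n_sex = spec.group_sizes[sex]
        young_lbl, old_lbl = ("YM", "OM") if sex == "M" else ("YW", "OW")
        n_young = spec.strata_sizes[young_lbl]
        n_old = spec.strata_sizes[old_lbl]
        n_mid = n_sex - n_young - n_old
        if n_mid < 0:
            raise ValueError(f"strata sizes exceed the {sex} group size")
        lo_bound, hi_bound = spec.strata_boundaries[sex]
        age_lo, age_hi = spec.age_range
        plan = [
            (n_young, young_lbl, age_lo, lo_bound, spec.age_medians[young_lbl]),
            (n_mid, sex, lo_bound, hi_bound, None),
            (n_old, old_lbl, hi_bound, age_hi, spec.age_medians[old_lbl]),
        ]
        for n_grp, med_col, a_lo, a_hi, a_med in plan:
            if n_grp == 0:
                continue
            mu = np.sqrt(spec.group_medians[med_col].to_numpy())
            z = rng.standard_normal((n_grp, m)) @ chol.T
            sqrt_conc = mu + sd * z
            rows.append(sqrt_conc**2)
            sexes.extend([sex] * n_grp)
            ages.append(_draw_ages(rng, n_grp, a_lo, a_hi, a_med))

    conc = np.vstack(rows)
    ids = [f"S{i + 1:04d}" for i in range(conc.shape[0])]
    table = pd.DataFrame(conc, index=ids, columns=names)
    return LipidProfileTable(
        table,
        pd.Series(sexes, index=ids),
        pd.Series(np.concatenate(ages), index=ids),
    )


# --------------------------------------------------------------------------
# planted partial-correlation networks
# --------------------------------------------------------------------------

@dataclass
class PlantedNetwork:
    """Ground-truth partial-correlation network for recovery tests.

    ``partial_corr`` is the m x m matrix of planted partial correlations
    (zero diagonal); ``adjacency`` marks which pairs are true edges.  The
    generating precision matrix has unit diagonal and off-diagonal entries
    ``-r_ij``, so the partial correlations of the sampled distribution equal
    the planted values exactly.
    """

    partial_corr: np.ndarray
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.partial_corr, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("partial_corr must be square")
        if not np.allclose(r, r.T):
            raise ValueError("partial_corr must be symmetric")
        if np.abs(np.diag(r)).max() > 0:
            raise ValueError("partial_corr diagonal must be zero")
        self.partial_corr = r
        self.adjacency = (np.abs(r) > 0).astype(int)
        if np.linalg.eigvalsh(self.precision()).min() <= 0:
            raise ValueError("generating precision matrix is not positive definite")

    @property
    def m(self) -> int:
        return self.partial_corr.shape[0]

    def precision(self) -> np.ndarray:
        omega = -self.partial_corr.copy()
        np.fill_diagonal(omega, 1.0)
        return omega

    @classmethod
    def from_edges(
        cls, m: int, edges: list[tuple[int, int, float]]
    ) -> "PlantedNetwork":
        """Build from ``(i, j, partial_correlation)`` triples."""
        r = np.zeros((m, m))
        for i, j, rij in edges:
            r[i, j] = r[j, i] = rij
        return cls(r, (np.abs(r) > 0).astype(int))

    @classmethod
    def disjoint_pairs(
        cls, m: int, n_edges: int, r: float = 0.5
    ) -> "PlantedNetwork":
        """``n_edges`` vertex-disjoint edges of strength ``r`` — always
        positive definite for \\|r\\| < 1."""
        if 2 * n_edges > m:
            raise ValueError("too many disjoint edges for m nodes")
        return cls.from_edges(m, [(2 * k, 2 * k + 1, r) for k in range(n_edges)])


def generate_from_planted_network(
    planted: PlantedNetwork, n: int, seed: int | None = None
) -> np.ndarray:
    """Sample ``n`` observations from the Gaussian with the planted
    partial-correlation structure (unit-diagonal precision convention)."""
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(planted.precision())
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n, planted.m)) @ chol.T


# --------------------------------------------------------------------------
# COVSCA ground truth
# --------------------------------------------------------------------------

def generate_covsca_instances(
    K: int,
    L: int,
    ranks: list[int],
    m: int,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> tuple[list[np.ndarray], np.ndarray, list[np.ndarray]]:
    """Matrices built exactly from the prototype model S_k = sum_l c_kl Z_l Z_l'.

    Returns ``(matrices, coefficients, prototypes)`` with ``coefficients``
    of shape (K, L) drawn positive and prototypes ``Z_l`` of shape
    (m, ranks[l]) normalized so each ``Z_l Z_l'`` has unit Frobenius norm.
    With ``noise_sd > 0`` symmetric Gaussian noise is added to each matrix.
    """
    if len(ranks) != L:
        raise ValueError("ranks must have length L")
    if m < max(ranks):
        raise ValueError("m must be at least the largest prototype rank")
    rng = np.random.default_rng(seed)
    prototypes = []
    for r in ranks:
        z = rng.standard_normal((m, r))
        z /= np.linalg.norm(z @ z.T, "fro") ** 0.5
        prototypes.append(z)
    coeff = rng.uniform(0.5, 2.0, size=(K, L))
    mats = []
    for k in range(K):
        s = sum(coeff[k, l] * prototypes[l] @ prototypes[l].T for l in range(L))
        if noise_sd > 0:
            e = rng.standard_normal((m, m)) * noise_sd
            s = s + (e + e.T) / 2
        mats.append(s)
    return mats, coeff, prototypes
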