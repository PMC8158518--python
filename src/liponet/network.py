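"""Association-network inference: shrinkage partial correlations gated by
PCLRC edge-stability probabilities.

The edge weights are partial correlations from a Gaussian graphical model
estimated with analytic shrinkage of the correlation matrix toward the
identity (Schafer-Strimmer intensity).  Which edges are trusted is decided
by PCLRC (Probabilistic Context Likelihood of Relatedness on Correlations):
the association matrix is recomputed on many row subsamples, CLR-transformed
against each node's background, the top fraction of pairs is marked per
iteration, and the per-pair marking frequency becomes a selection
probability.  A pair enters the final network iff its probability reaches
the threshold (default 0.95), in which case its weight is the full-sample
shrinkage partial correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fractions import fraction_class
from .preprocess import GROUP_LABELS, StratifiedGroups, preprocess_matrix
from .profile import LipidProfileTable


@dataclass
class PclrcParams:
    """PCLRC configuration (defaults follow the algorithm's standard use)."""

    niter: int = 1000
    frac: float = 0.75
    rank_thr: float = 0.3
    prob_threshold: float = 0.95
    estimator: str = "partial"  # "partial" or "pearson" inside the subsamples

    def __post_init__(self) -> None:
        if not 0 < self.frac <= 1:
            raise ValueError("frac must lie in (0, 1]")
        if not 0 < self.rank_thr <= 1:
            raise ValueError("rank_thr must lie in (0, 1]")
        if not 0 <= self.prob_threshold <= 1:
            raise ValueError("prob_threshold must lie in [0, 1]")
        if self.niter < 1:
            raise ValueError("niter must be positive")
        if self.estimator not in ("partial", "pearson"):
            raise ValueError("estimator must be 'partial' or 'pearson'")


@dataclass
class AssociationNetwork:
    """One group-specific network over the fraction panel.

    ``partial_corr`` (R) is the full shrinkage partial-correlation matrix
    (unit diagonal); ``probability`` (P) the PCLRC selection probabilities;
    ``weights`` (W) the masked edge weights: ``W_ij = R_ij`` where
    ``P_ij >= prob_threshold`` and exactly zero elsewhere (zero diagonal).
    """

    nodes: list[str]
    partial_corr: np.ndarray
    probability: np.ndarray
    weights: np.ndarray
    prob_threshold: float = 0.95
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = len(self.nodes)
        for name in ("partial_corr", "probability", "weights"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (m, m):
                raise ValueError(f"{name} must be {m}x{m}")
            if not np.allclose(a, a.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            setattr(self, name, a)

    @property
    def m(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, k=1)))

    def edge_list(self) -> pd.DataFrame:
        """All unordered pairs with partial correlation, probability and
        masked weight (full fidelity: non-edges included with weight 0)."""
        rows = []
        for i in range(self.m):
            for j in range(i + 1, self.m):
                rows.append(
                    {
                        "node_i": self.nodes[i],
                        "node_j": self.nodes[j],
                        "partial_correlation": self.partial_corr[i, j],
                        "probability": self.probability[i, j],
                        "weight": self.weights[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_graph(self):
        """networkx Graph of the masked edges, with signed ``weight`` edge
        attribute and a lipoprotein ``lipid_class`` node attribute."""
        import networkx as nx

        g = nx.Graph(**{k: str(v) for k, v in self.metadata.items()})
        for name in self.nodes:
            g.add_node(name, lipid_class=fraction_class(name))
        for i in range(self.m):
            for j in range(i + 1, self.m):
                if self.weights[i, j] != 0:
                    g.add_edge(
                        self.nodes[i],
                        self.nodes[j],
                        weight=float(self.weights[i, j]),
                        probability=float(self.probability[i, j]),
                    )
        return g


# --------------------------------------------------------------------------
# shrinkage partial correlation
# --------------------------------------------------------------------------

def shrinkage_intensity(X: np.ndarray) -> float:
    """Analytic shrinkage intensity lambda* toward the identity target.

    lambda* = sum_{i != j} Var-hat(r_ij) / sum_{i != j} r_ij^2, clipped to
    [0, 1]; with all off-diagonal correlations zero the intensity is 1.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    r = xs.T @ xs / (n - 1)
    off = ~np.eye(m, dtype=bool)
    denom = np.sum(r[off] ** 2)
    if denom <= 1e-24:  # exact orthogonality up to rounding noise
        warnings.warn("all correlations zero: shrinkage intensity set to 1",
                      stacklevel=2)
        return 1.0
    w_bar = (n - 1) / n * r
    # Var-hat(r_ij) = n/(n-1)^3 * sum_k (x_ki x_kj - mean_k)^2
    sq = (xs**2).T @ (xs**2)          # sum_k x_ki^2 x_kj^2
    var_w = sq / n - w_bar**2          # E[w^2] - E[w]^2 over k
    var_r = n / (n - 1) ** 3 * n * var_w
    lam = np.sum(var_r[off]) / denom
    return float(np.clip(lam, 0.0, 1.0))


def shrinkage_partial_correlation(
    X, lam: float | None = None
) -> np.ndarray:
    """Partial correlations from the shrunken correlation matrix.

    The sample correlation R is replaced by (1 - lambda) R + lambda I with
    the analytic intensity (or an explicit ``lam``), inverted, and scaled:
    ptcor_ij = -omega_ij / sqrt(omega_ii * omega_jj), unit diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need an n x m matrix with n >= 4")
    n, m = X.shape
    xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    r = xs.T @ xs / (n - 1)
    np.fill_diagonal(r, 1.0)
    if lam is None:
        lam = shrinkage_intensity(X)
    r_shrunk = (1.0 - lam) * r + lam * np.eye(m)
    omega = np.linalg.pinv(r_shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return (pcor + pcor.T) / 2


def _pearson_abs(X: np.ndarray) -> np.ndarray:
    c = np.corrcoef(X, rowvar=False)
    return np.abs(c)


# --------------------------------------------------------------------------
# PCLRC
# --------------------------------------------------------------------------

def _clr_scores(A: np.ndarray) -> np.ndarray:
    """CLR transform of an association matrix: per-row z-scores against the
    row background (off-diagonal mean/sd), negatives clipped, combined
    symmetrically as sqrt(z_ij^2 + z_ji^2)."""
    m = A.shape[0]
    off = ~np.eye(m, dtype=bool)
    vals = np.where(off, A, np.nan)
    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    z = np.clip((A - mu) / sd, 0.0, None)
    s = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(s, 0.0)
    return s


def pclrc_probabilities(
    X,
    niter: int = 1000,
    frac: float = 0.75,
    rank_thr: float = 0.3,
    seed: int | None = None,
    estimator: str = "partial",
) -> np.ndarray:
    """Per-pair selection probabilities by subsampled CLR ranking.

    Each iteration subsamples ``floor(frac * n)`` rows without replacement,
    computes the absolute association matrix (shrinkage partial correlations
    by default, Pearson correlations as the alternative reading), applies
    the CLR transform, and marks the top ``rank_thr`` fraction of the
    *predicted* interactions — the unordered pairs with a strictly positive
    CLR score, i.e. above their nodes' background (ties at the cutoff all
    kept).  The returned matrix holds the fraction of iterations in which
    each pair was marked.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    n_sub = int(np.floor(frac * n))
    if n_sub < 4:
        raise ValueError(f"subsample of {n_sub} rows is too small (need >= 4)")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(m, k=1)
    counts = np.zeros(iu[0].size)
    assoc = _pearson_abs if estimator == "pearson" else (
        lambda sub: np.abs(shrinkage_partial_correlation(sub))
    )
    for _ in range(niter):
        rows = rng.choice(n, size=n_sub, replace=False)
        s = _clr_scores(assoc(X[rows]))[iu]
        positive = s[s > 0]
        if positive.size == 0:
            continue
        cutoff = np.quantile(positive, 1.0 - rank_thr)
        counts += s >= cutoff
    P = np.zeros((m, m))
    P[iu] = counts / niter
    return P + P.T


def mask_network(
    R,
    P,
    prob_threshold: float = 0.95,
    nodes: list[str] | None = None,
    metadata: dict | None = None,
) -> AssociationNetwork:
    """Assemble the network: keep R_ij where P_ij >= threshold, zero else."""
    R = np.asarray(R, dtype=float)
    P = np.asarray(P, dtype=float)
    if R.shape != P.shape:
        raise ValueError("R and P must have the same shape")
    W = np.where(P >= prob_threshold, R, 0.0)
    np.fill_diagonal(W, 0.0)
    m = R.shape[0]
    return AssociationNetwork(
        nodes=list(nodes) if nodes is not None else [f"v{i}" for i in range(m)],
        partial_corr=R,
        probability=P,
        weights=W,
        prob_threshold=prob_threshold,
        metadata=metadata or {},
    )


def infer_network(
    table: LipidProfileTable,
    params: PclrcParams | None = None,
    seed: int | None = None,
    metadata: dict | None = None,
) -> AssociationNetwork:
    """Infer one network from a (sub)cohort: preprocess (sqrt + autoscale),
    run PCLRC for the probabilities, and take the final edge weights from
    the full-group shrinkage partial correlation."""
    params = params or PclrcParams()
    # canonical row order so inference is invariant to sample shuffling
    table = table.subset(table.concentrations.index.sort_values())
    X = preprocess_matrix(table).to_numpy()
    if X.shape[0] < X.shape[1] + 2:
        warnings.warn(
            f"group of n={X.shape[0]} is small for m={X.shape[1]} variables; "
            "network attempted anyway",
            stacklevel=2,
        )
    P = pclrc_probabilities(
        X, niter=params.niter, frac=params.frac, rank_thr=params.rank_thr,
        seed=seed, estimator=params.estimator,
    )
    R = shrinkage_partial_correlation(X)
    meta = dict(metadata or {})
    meta.setdefault("n", table.n_samples)
    return mask_network(R, P, params.prob_threshold, table.fraction_names, meta)


def infer_group_networks(
    table: LipidProfileTable,
    groups: StratifiedGroups,
    params: PclrcParams | None = None,
    seed: int | None = None,
    group_labels: tuple[str, ...] = GROUP_LABELS,
) -> dict[str, AssociationNetwork]:
    """One association network per study group (default: W, M, YM, OM, YW, OW)."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(group_labels))
    nets = {}
    for label, child in zip(group_labels, children):
        sub = table.subset(groups.labels[label])
        nets[label] = infer_network(
            sub, params,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            metadata={"group": label},
        )
    return nets
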