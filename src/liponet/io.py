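"""Reading and writing of tables, networks, and run configuration.

Canonical formats: CSV for concentration tables (one sex column, one age
column, remaining numeric columns are fractions), GraphML plus a flat
edge-list CSV for networks, YAML for run configuration.  The edge-list CSV
stores every unordered pair with its partial correlation, PCLRC probability
and masked weight, so a network round-trips losslessly; the GraphML carries
only the significant edges (signed weight) plus the lipoprotein class as a
node attribute.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .classify import RfSettings
from .covsca import CovscaParams
from .network import AssociationNetwork, PclrcParams, mask_network
from .profile import LipidProfileTable, ValidationError


# --------------------------------------------------------------------------
# profile tables
# --------------------------------------------------------------------------

def read_profile_table(
    path,
    sex_column: str = "sex",
    age_column: str = "age",
    sex_mapping: dict[str, str] | None = None,
) -> LipidProfileTable:
    """Read a samples x fractions CSV with sex/age metadata columns.

    The first column is used as the sample identifier.  ``sex_mapping``
    translates other sex codings (e.g. ``{"F": "W"}``) onto the canonical
    ``{"M", "W"}`` codes.  Validation failures name the offending cell.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    for col in (sex_column, age_column):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    sex = df[sex_column].astype(str)
    if sex_mapping:
        sex = sex.replace(sex_mapping)
    age = pd.to_numeric(df[age_column], errors="coerce")
    conc = df.drop(columns=[sex_column, age_column])
    conc = conc.apply(pd.to_numeric, errors="coerce")
    return LipidProfileTable(conc, sex, age)


def write_profile_table(
    table: LipidProfileTable, path, sex_column: str = "sex", age_column: str = "age"
) -> None:
    out = table.concentrations.copy()
    out.insert(0, age_column, table.age)
    out.insert(0, sex_column, table.sex)
    out.to_csv(path, index_label="sample_id")


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

def write_network(
    net: AssociationNetwork, graphml_path, edgelist_path=None
) -> None:
    """Write GraphML (masked edges) and the full-fidelity edge-list CSV.

    ``edgelist_path`` defaults to the GraphML path with a ``.edges.csv``
    suffix.
    """
    graphml_path = Path(graphml_path)
    edgelist_path = (
        Path(edgelist_path)
        if edgelist_path is not None
        else graphml_path.with_suffix(".edges.csv")
    )
    nx.write_graphml(net.to_graph(), graphml_path)
    edges = net.edge_list()
    edges.insert(0, "prob_threshold", net.prob_threshold)
    edges.to_csv(edgelist_path, index=False)


def read_network(edgelist_path) -> AssociationNetwork:
    """Rebuild a network from its full-fidelity edge-list CSV."""
    df = pd.read_csv(edgelist_path)
    nodes: list[str] = []
    for col in ("node_i", "node_j"):
        for name in df[col]:
            if name not in nodes:
                nodes.append(name)
    pos = {name: i for i, name in enumerate(nodes)}
    m = len(nodes)
    R = np.eye(m)
    P = np.zeros((m, m))
    for row in df.itertuples():
        i, j = pos[row.node_i], pos[row.node_j]
        R[i, j] = R[j, i] = row.partial_correlation
        P[i, j] = P[j, i] = row.probability
    thr = float(df["prob_threshold"].iloc[0])
    return mask_network(R, P, thr, nodes)


def read_network_graphml(path) -> tuple[list[str], np.ndarray]:
    """Node names and masked-weight adjacency from a GraphML file."""
    g = nx.read_graphml(path)
    nodes = list(g.nodes)
    w = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    return nodes, w


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class Alphas:
    univariate: float = 0.05
    tracy_widom: float = 0.001


@dataclass
class RunConfig:
    """Everything a pipeline run needs; YAML-serializable field for field."""

    input_path: str | None = None
    sex_column: str = "sex"
    age_column: str = "age"
    comparison: str = "all"  # "sex", "age_within_sex", or "all"
    pclrc: PclrcParams = field(default_factory=PclrcParams)
    covsca: CovscaParams = field(default_factory=CovscaParams)
    rf: RfSettings = field(default_factory=RfSettings)
    alphas: Alphas = field(default_factory=Alphas)
    roc_bootstrap: int = 2000
    seed: int = 0
    out_dir: str = "liponet_out"

    def __post_init__(self) -> None:
        if self.comparison not in ("sex", "age_within_sex", "all"):
            raise ValueError("comparison must be 'sex', 'age_within_sex' or 'all'")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    nested = {
        "pclrc": PclrcParams,
        "covsca": CovscaParams,
        "rf": RfSettings,
        "alphas": Alphas,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**(value or {}))
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
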