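"""Piecewise path models with d-separation tests.

Each endogenous node of a directed acyclic graph is regressed by ordinary
least squares on its parents; reported coefficients are standardised
(raw slope x sd(x)/sd(y)).  Global fit of a non-saturated model is tested
with Fisher's C over the union basis set of missing edges: for each
non-adjacent ordered pair (i, j), the partial slope of i in the
regression of j on parents(j) + parents(i) + i gives an independence
p-value, and C = -2 sum ln p_i ~ chi2(2k) under the causal model.
Saturated models (no missing edges) carry no test.  A model p-value above
0.05 is read as good agreement between data and graph, the standard
convention for d-separation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class PathModelSpec:
    """A DAG of standardised linear relations.

    ``edges`` are (parent, child) pairs; every node mentioned in an edge
    must appear in ``nodes``.  Edges absent from the DAG are treated as
    asserted-zero paths and generate independence claims.
    """

    nodes: tuple
    edges: tuple

    def __post_init__(self):
        self.nodes = tuple(self.nodes)
        self.edges = tuple((str(a), str(b)) for a, b in self.edges)
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model must be a DAG")
        unknown = {v for e in self.edges for v in e} - set(self.nodes)
        if unknown:
            raise ValueError(f"edge variables not in nodes: {sorted(unknown)}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def missing_pairs(self):
        """Non-adjacent ordered pairs (earlier, later) in topological order."""
        g = self.graph()
        order = list(nx.topological_sort(g))
        pairs = []
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                if not (g.has_edge(a, b) or g.has_edge(b, a)):
                    pairs.append((a, b))
        return pairs

    @property
    def saturated(self) -> bool:
        return len(self.missing_pairs()) == 0


TROPHIC_CASCADE = PathModelSpec(
    nodes=("dose", "scraper_biomass", "chla"),
    edges=(("dose", "scraper_biomass"), ("scraper_biomass", "chla")),
)

PREDATOR_PREY = PathModelSpec(
    nodes=("dose", "predator_biomass", "prey_biomass"),
    edges=(("dose", "predator_biomass"), ("dose", "prey_biomass"),
           ("predator_biomass", "prey_biomass")),
)


@dataclass
class PathFit:
    coefficients: pd.DataFrame  # (from, to, coefficient, std_coefficient, p_value)
    fisher_c: float | None
    df: int | None
    model_p: float | None
    saturated: bool
    n: int


def _check_collinear(X: np.ndarray, threshold: float = 1e8):
    if X.shape[1] > 1:
        cond = np.linalg.cond(X)
        if cond > threshold:
            raise ValueError(f"collinear parents (condition number {cond:.2g})")


def fit_path_model(spec: PathModelSpec, data: pd.DataFrame) -> PathFit:
    """OLS component regressions with standardised coefficients.

    Includes Fisher's C, its degrees of freedom and the model p-value when
    the spec is non-saturated.
    """
    missing_cols = set(spec.nodes) - set(data.columns)
    if missing_cols:
        raise ValueError(f"data lacks variable(s) {sorted(missing_cols)}")
    n = len(data)
    g = spec.graph()
    n_params = sum(g.in_degree(v) + 1 for v in spec.nodes if g.in_degree(v) > 0)
    if n <= n_params:
        raise ValueError("need more observations than parameters")

    rows = []
    for node in nx.topological_sort(g):
        parents = sorted(g.predecessors(node))
        if not parents:
            continue
        X = data[parents].to_numpy(dtype=float)
        _check_collinear(X)
        y = data[node].to_numpy(dtype=float)
        model = sm.OLS(y, sm.add_constant(X)).fit()
        sd_y = y.std(ddof=1)
        for j, parent in enumerate(parents):
            slope = model.params[j + 1]
            sd_x = X[:, j].std(ddof=1)
            rows.append({
                "from": parent, "to": node,
                "coefficient": float(slope),
                "std_coefficient": float(slope * sd_x / sd_y),
                "p_value": float(model.pvalues[j + 1]),
            })
    coefficients = pd.DataFrame(rows)

    if spec.saturated:
        return PathFit(coefficients, None, None, None, True, n)
    c, df, model_p = dsep_fisher_c(spec, data)
    return PathFit(coefficients, c, df, model_p, False, n)


def dsep_fisher_c(spec: PathModelSpec, data: pd.DataFrame):
    """Fisher's C over the basis set of missing edges.

    Returns (C, df, model_p) with df = 2 x number of independence claims.
    Raises on a saturated spec.
    """
    pairs = spec.missing_pairs()
    if not pairs:
        raise ValueError("saturated model: no independence claims to test")
    g = spec.graph()
    pvals = []
    for a, b in pairs:
        conditioning = sorted((set(g.predecessors(b)) | set(g.predecessors(a))) - {a, b})
        cols = conditioning + [a]
        X = data[cols].to_numpy(dtype=float)
        _check_collinear(X)
        model = sm.OLS(data[b].to_numpy(dtype=float), sm.add_constant(X)).fit()
        pvals.append(float(model.pvalues[len(cols)]))
    return fisher_c_from_pvalues(pvals)


def fisher_c_from_pvalues(pvals):
    """Combine independence-claim p-values: C = -2 sum ln p ~ chi2(2k)."""
    pvals = np.clip(np.asarray(pvals, dtype=float), 1e-300, 1.0)
    if pvals.size == 0:
        raise ValueError("need at least one independence claim")
    c = float(-2.0 * np.sum(np.log(pvals)))
    df = 2 * len(pvals)
    model_p = float(stats.chi2.sf(c, df))
    return c, df, model_p


def total_effect(fit: PathFit, path) -> float:
    """Product of standardised coefficients along a node sequence."""
    path = list(path)
    if len(path) < 2:
        raise ValueError("path needs at least two nodes")
    coef = {(r["from"], r["to"]): r["std_coefficient"]
            for _, r in fit.coefficients.iterrows()}
    product = 1.0
    for a, b in zip(path[:-1], path[1:]):
        if (a, b) not in coef:
            raise ValueError(f"no edge {a!r} -> {b!r} in the fitted model")
        product *= coef[(a, b)]
    return float(product)


def read_edge_list(path) -> PathModelSpec:
    """Parse a simple edge-list spec file: one ``from -> to`` per line,
    ``#`` comments allowed; isolated nodes may be listed alone."""
    nodes, edges = [], []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "->" in line:
                a, b = (part.strip() for part in line.split("->", 1))
                edges.append((a, b))
                for v in (a, b):
                    if v not in nodes:
                        nodes.append(v)
            else:
                if line not in nodes:
                    nodes.append(line)
    return PathModelSpec(tuple(nodes), tuple(edges))
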