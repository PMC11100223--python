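"""Piecewise path model of hydraulic conductivity.

The model is a DAG of directed trait-to-trait effects, estimated the
piecewise way: one ordinary least-squares regression per endogenous node on
its parents, run on z-scored data so the slopes are standardized path
coefficients.  Goodness of fit uses the d-separation basis set and Fisher's
C: each conditional-independence claim implied by the DAG is tested by the
partial-regression t-test of the omitted edge, C = -2*sum(ln p_i) is
referred to chi-square with 2*(number of claims) df, and the structure is
accepted when the resulting p exceeds 0.05.

The default structure encodes the hydraulic cascade: double wall thickness
(DWT) and radial tracheid diameter (D_r) set the thickness-to-span ratio
(TSR); TSR and D_r set the hydraulic diameter (D_h); D_h sets K_s.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_EDGES: list[tuple[str, str]] = [
    ("DWT", "TSR"),
    ("D_r", "TSR"),
    ("D_r", "D_h"),
    ("TSR", "D_h"),
    ("D_h", "K_s"),
]

_CONDITION_NUMBER_WARN = 1e8


@dataclass
class PathModel:
    nodes: list[str]
    edges: list[tuple[str, str]]

    def __post_init__(self):
        for u, v in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise ValueError("path model must be acyclic")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(u for u, v in self.edges if v == node)

    def endogenous(self) -> list[str]:
        return sorted({v for _, v in self.edges})

    @classmethod
    def default(cls) -> "PathModel":
        nodes = sorted({n for e in DEFAULT_EDGES for n in e})
        return cls(nodes, list(DEFAULT_EDGES))

    @classmethod
    def from_json(cls, path) -> "PathModel":
        with open(path) as fh:
            spec = json.load(fh)
        return cls(list(spec["nodes"]), [tuple(e) for e in spec["edges"]])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"nodes": self.nodes, "edges": [list(e) for e in self.edges]},
                      fh, indent=1, sort_keys=True)


@dataclass
class Effects:
    direct: float
    indirect: float

    @property
    def total(self) -> float:
        return self.direct + self.indirect


@dataclass
class PathFit:
    model: PathModel
    coefficients: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    r_squared: dict[str, float]
    dsep_C: float
    dsep_df: int
    dsep_p: float
    n: int
    effects_on: dict[str, dict[str, Effects]] = field(default_factory=dict)


def _zscore(data: pd.DataFrame, cols) -> pd.DataFrame:
    sub = data[list(cols)].astype(float)
    sd = sub.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"zero-variance model variables: {list(sd.index[sd == 0])}")
    return (sub - sub.mean()) / sd


def fit_path_model(model: PathModel, data: pd.DataFrame,
                   standardize: bool = True) -> PathFit:
    """Fit every local regression of the path model and the d-sep test.

    ``data`` is individuals x traits; with ``standardize=True`` (default)
    columns are z-scored first so coefficients are standardized paths.
    """
    missing = [n for n in model.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"data lacks model variables: {missing}")
    z = _zscore(data, model.nodes) if standardize else data[model.nodes].astype(float)
    z = z.dropna(axis=0)
    n = len(z)

    coeffs: dict[tuple[str, str], float] = {}
    pvals: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    for node in model.endogenous():
        parents = model.parents(node)
        if n <= len(parents) + 1:
            raise ValueError(f"too few rows ({n}) to fit {node} ~ {parents}")
        X = z[parents].to_numpy()
        if len(parents) > 1 and np.linalg.cond(X.T @ X) > _CONDITION_NUMBER_WARN:
            warnings.warn(
                f"collinear parents of {node}: coefficient variances inflated")
        res = sm.OLS(z[node].to_numpy(), sm.add_constant(X)).fit()
        for k, par in enumerate(parents):
            coeffs[(par, node)] = float(res.params[k + 1])
            pvals[(par, node)] = float(res.pvalues[k + 1])
        r2[node] = float(res.rsquared)

    C, df, p = dsep_test(model, z, standardize=False)
    fit = PathFit(model, coeffs, pvals, r2, C, df, p, n)
    for target in model.endogenous():
        fit.effects_on[target] = total_effects(fit, target)
    return fit


def total_effects(fit: PathFit, target: str) -> dict[str, Effects]:
    """Direct, indirect and total standardized effect of every other node on
    ``target``.

    Computed from the coefficient matrix B (B[i, j] = path i -> j) via the
    finite power series sum_{k>=1} B^k, which a DAG's nilpotency truncates;
    the k=1 term is the direct effect, the remainder the indirect, and
    total = direct + indirect by construction.
    """
    model = fit.model
    if target not in model.nodes:
        raise ValueError(f"target {target!r} not in model")
    nodes = model.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    B = np.zeros((k, k))
    for (u, v), b in fit.coefficients.items():
        B[idx[u], idx[v]] = b
    total = np.zeros((k, k))
    term = B.copy()
    for _ in range(k):
        total += term
        term = term @ B
    if not np.allclose(term, 0):
        raise ValueError("cyclic model: effect series does not terminate")
    out = {}
    for node in nodes:
        if node == target:
            continue
        direct = B[idx[node], idx[target]]
        out[node] = Effects(direct=float(direct),
                            indirect=float(total[idx[node], idx[target]] - direct))
    return out


def basis_set(model: PathModel) -> list[tuple[str, str, tuple[str, ...]]]:
    """Conditional-independence claims implied by the DAG.

    One claim per non-adjacent node pair (x, y): x independent of y given
    the union of both nodes' parents, with y the later node in topological
    order (ties alphabetical), so each claim is tested as the partial slope
    of x in the regression of y on x plus the conditioning set.
    """
    g = model.graph()
    topo = list(nx.lexicographical_topological_sort(g))
    pos = {n: i for i, n in enumerate(topo)}
    claims = []
    for i in range(len(topo)):
        for j in range(i + 1, len(topo)):
            x, y = topo[i], topo[j]
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            cond = sorted((set(model.parents(x)) | set(model.parents(y)))
                          - {x, y})
            claims.append((x, y, tuple(cond)))
    claims.sort()
    return claims


def dsep_test(model: PathModel, data: pd.DataFrame,
              standardize: bool = True) -> tuple[float, int, float]:
    """Fisher's C over the d-separation basis set.

    Returns (C, df, p); an empty basis set (saturated model) gives
    (0, 0, 1).  Model acceptance convention: p > 0.05.
    """
    z = _zscore(data, model.nodes) if standardize else data[model.nodes]
    z = z.dropna(axis=0)
    claims = basis_set(model)
    if not claims:
        return 0.0, 0, 1.0
    log_ps = []
    for x, y, cond in claims:
        X = sm.add_constant(z[[x, *cond]].to_numpy())
        res = sm.OLS(z[y].to_numpy(), X).fit()
        p = float(res.pvalues[1])
        log_ps.append(np.log(max(p, 1e-300)))
    C = -2.0 * float(np.sum(log_ps))
    df = 2 * len(claims)
    return C, df, float(stats.chi2.sf(C, df))


def edge_table(fit: PathFit) -> pd.DataFrame:
    rows = [{"source": u, "target": v,
             "coefficient": fit.coefficients[(u, v)],
             "p_value": fit.p_values[(u, v)]}
            for u, v in sorted(fit.coefficients)]
    return pd.DataFrame(rows)


def effects_table(fit: PathFit, target: str = "K_s") -> pd.DataFrame:
    eff = fit.effects_on.get(target) or total_effects(fit, target)
    rows = [{"node": n, "direct": e.direct, "indirect": e.indirect,
             "total": e.total} for n, e in sorted(eff.items())]
    return pd.DataFrame(rows)
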