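"""Phylogenetic signal of species-mean traits.

Brownian-motion (BM) machinery: the tree's variance-covariance matrix V has
V[i, j] equal to the shared root-to-MRCA path length of tips i and j and
V[i, i] the root-to-tip distance.  On top of it:

* Blomberg's K — the ratio of observed to BM-expected (MSE0/MSE); K = 1 is
  the BM expectation, K < 1 less resemblance among relatives than BM.
  Significance by permuting trait values across tips.
* Pagel's lambda — multiplies V's off-diagonals by lambda in [0, lambda_max]
  and maximizes the GLS (multivariate-normal) likelihood profiled over the
  phylogenetic mean and the BM rate; tested against lambda = 0 by a 1-df
  likelihood-ratio test.

Traits enter as one value per tip (species means); within-species variance
is ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)

def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path into a rooted dendropy tree.

    Requires unique tip labels and non-negative branch lengths.
    """
    txt = source
    if "(" not in source:  # looks like a path, not newick
        with open(source) as fh:
            txt = fh.read()
    try:
        tree = dendropy.Tree.get(data=txt, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length: {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def prune_to_species(tree: dendropy.Tree, keep: list[str]) -> dendropy.Tree:
    """Retain only tips with trait data; dropped tips are logged, not errors."""
    tree = tree.clone(depth=1)
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    drop = sorted(present - set(keep))
    if drop:
        logger.warning("pruning %d tips without trait data: %s", len(drop), drop)
        tree.retain_taxa_with_labels([l for l in keep if l in present])
    return tree


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = [lf.distance_from_root() for lf in tree.leaf_node_iter()]
    span = max(depths) - min(depths)
    return span <= rel_tol * max(depths)


# ---------------------------------------------------------------------------
# BM covariance

def tree_vcv(tree: dendropy.Tree, order: list[str] | None = None
             ) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix of the tips.

    V[i, j] = depth of MRCA(i, j); V[i, i] = root-to-tip distance.  Tips are
    returned in ``order`` if given, else alphabetically.
    """
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if order is None:
        order = sorted(labels)
    idx = {lab: i for i, lab in enumerate(order)}
    missing = [l for l in order if l not in set(labels)]
    if missing:
        raise ValueError(f"tips absent from tree: {missing}")
    n = len(order)
    v = np.zeros((n, n))

    depth: dict[int, float] = {}
    tipsets: dict[int, list[str]] = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(id(node.parent_node), 0.0)
        depth[id(node)] = parent_depth + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[id(node)] = [node.taxon.label]
            lab = node.taxon.label
            if lab in idx:
                v[idx[lab], idx[lab]] = depth[id(node)]
            continue
        kids = [tipsets[id(c)] for c in node.child_nodes()]
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for la in kids[a]:
                    for lb in kids[b]:
                        if la in idx and lb in idx:
                            v[idx[la], idx[lb]] = depth[id(node)]
                            v[idx[lb], idx[la]] = depth[id(node)]
        tipsets[id(node)] = [l for k in kids for l in k]
    return v, list(order)


# ---------------------------------------------------------------------------
# Blomberg's K

def _gls_mean(y: np.ndarray, vinv_fac) -> float:
    one = np.ones_like(y)
    vi1 = cho_solve(vinv_fac, one)
    return float(one @ cho_solve(vinv_fac, y)) / float(one @ vi1)


def blomberg_k(y: np.ndarray, V: np.ndarray) -> float:
    """Blomberg's K.

    With the phylogenetic GLS mean a = (1'V^-1 y)/(1'V^-1 1):
    MSE0 = (y-a)'(y-a)/(n-1), MSE = (y-a)'V^-1(y-a)/(n-1), and K is the
    ratio MSE0/MSE divided by its BM expectation
    (tr(V) - n/(1'V^-1 1)) / (n - 1).
    """
    y = np.asarray(y, float)
    n = y.size
    if n < 4 or V.shape != (n, n):
        raise ValueError("blomberg_k: need >= 4 tips and matching V")
    try:
        fac = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular phylogenetic covariance; consider jittering zero-length "
            "branches") from exc
    one = np.ones(n)
    a = _gls_mean(y, fac)
    r = y - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(fac, r)) / (n - 1)
    expected = (np.trace(V) - n / float(one @ cho_solve(fac, one))) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_permutation_p(y: np.ndarray, V: np.ndarray,
                           n_perm: int = 999, seed: int | None = None) -> float:
    """Permutation p-value for Blomberg's K.

    Trait values are shuffled across tips; the observed phylogenetic MSE is
    compared with the permutation distribution (signal => small MSE), and
    p = (1 + #{MSE_perm <= MSE_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a stable p-value")
    y = np.asarray(y, float)
    n = y.size
    rng = np.random.default_rng(seed)
    fac = cho_factor(V)
    vinv = cho_solve(fac, np.eye(n))
    one = np.ones(n)
    vi1 = vinv @ one
    denom = float(one @ vi1)

    def mse_of(cols: np.ndarray) -> np.ndarray:
        a = (vi1 @ cols) / denom            # GLS mean per column
        r = cols - a[None, :]
        return np.einsum("ij,ik,kj->j", r, vinv, r) / (n - 1)

    obs = mse_of(y[:, None])[0]
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(y)
    perm_mse = mse_of(perms)
    return float((1 + np.sum(perm_mse <= obs)) / (n_perm + 1))


# ---------------------------------------------------------------------------
# Pagel's lambda

def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale V's off-diagonal entries by lambda, keeping the diagonal."""
    W = lam * V
    np.fill_diagonal(W, np.diag(V))
    return W


def lambda_max(V: np.ndarray, cap: float = 1.5) -> float:
    """Largest admissible lambda: min over tip pairs of V_ii*V_jj/V_ij^2,
    capped (never above ``cap``), then backed off until V(lambda) is
    positive definite."""
    n = V.shape[0]
    lo = cap
    for i in range(n):
        for j in range(i + 1, n):
            if V[i, j] > 0:
                lo = min(lo, V[i, i] * V[j, j] / V[i, j] ** 2)
    lam = lo
    for _ in range(60):
        try:
            cho_factor(lambda_transform(V, lam))
            return lam
        except np.linalg.LinAlgError:
            lam *= 0.99
    raise ValueError("could not find positive-definite lambda bound")


def gls_loglik(y: np.ndarray, W: np.ndarray) -> float:
    """Multivariate-normal log-likelihood profiled over the mean and rate.

    For y ~ N(a*1, s2*W): a is the GLS mean, s2 its ML estimate
    (y-a)'W^-1(y-a)/n, giving
    logL = -0.5 * (n*log(2*pi*s2) + log|W| + n).
    """
    y = np.asarray(y, float)
    n = y.size
    fac = cho_factor(W)
    a = _gls_mean(y, fac)
    r = y - a
    s2 = float(r @ cho_solve(fac, r)) / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(fac[0]))))
    return -0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)


@dataclass
class LambdaResult:
    lam: float
    loglik: float
    loglik0: float
    lrt_p: float
    lam_max: float


def pagel_lambda_ml(y: np.ndarray, V: np.ndarray) -> LambdaResult:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs 0.

    lambda is optimized on [0, lambda_max] by bounded 1-D search; the
    endpoints are also evaluated so boundary optima are exact.  The LRT
    compares 2*(logL(lambda_hat) - logL(0)) with chi-square(1).
    """
    y = np.asarray(y, float)
    n = y.size
    if n < 4 or V.shape != (n, n):
        raise ValueError("pagel_lambda_ml: need >= 4 tips and matching V")
    lmax = lambda_max(V)

    def nll(lam: float) -> float:
        return -gls_loglik(y, lambda_transform(V, lam))

    res = optimize.minimize_scalar(nll, bounds=(0.0, lmax), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"lambda optimizer failed on [0, {lmax}]: {res.message}")
    candidates = [(0.0, -nll(0.0)), (float(res.x), -float(res.fun)),
                  (lmax, -nll(lmax))]
    lam, ll = max(candidates, key=lambda t: t[1])
    ll0 = -nll(0.0)
    lrt = max(0.0, 2.0 * (ll - ll0))
    p = float(stats.chi2.sf(lrt, 1))
    return LambdaResult(lam=lam, loglik=ll, loglik0=ll0, lrt_p=p, lam_max=lmax)


# ---------------------------------------------------------------------------
# Per-trait table

def signal_table(tree: dendropy.Tree, species_means: pd.DataFrame,
                 traits: list[str] | None = None,
                 n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Blomberg's K (with permutation p) and Pagel's lambda (with LRT p)
    for every trait column, species means matched to tree tips by label.

    Tips without data are pruned with a log message; each trait uses its own
    derived seed so results do not depend on trait order.
    """
    if traits is None:
        traits = [c for c in species_means.columns
                  if pd.api.types.is_numeric_dtype(species_means[c])]
    species = [s for s in species_means.index.astype(str)]
    tree = prune_to_species(tree, species)
    tips = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    V, order = tree_vcv(tree, order=tips)
    rows = []
    for k, trait in enumerate(traits):
        yv = species_means.loc[[s for s in order], trait].to_numpy(float)
        K = blomberg_k(yv, V)
        kp = blomberg_permutation_p(yv, V, n_perm=n_perm,
                                    seed=(seed * 10007 + k) % (2**31 - 1))
        lr = pagel_lambda_ml(yv, V)
        rows.append({"trait": trait, "n_tips": len(order), "K": K,
                     "K_p": kp, "lambda": lr.lam, "lambda_p": lr.lrt_p})
    return pd.DataFrame(rows).set_index("trait")
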