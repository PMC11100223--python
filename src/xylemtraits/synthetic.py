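"""Synthetic data emulating a 17-species conifer common-garden study.

Every pipeline stage can be exercised without real measurements:

* a pure-birth (Yule) species tree, ultrametric, depth scaled to 1;
* species-mean traits evolved by Brownian motion (BM) on that tree with a
  tunable Pagel's lambda, on the log scale so traits stay positive, at
  magnitudes matching published conifer wood anatomy (torus diameter ~6 um,
  pit membrane ~12 um, radial tracheid ~20 um, tracheid density
  ~1600 mm^-2);
* per-individual replicates around the species means (default 10
  individuals, 50 measured tracheid diameters each), with the measurement
  invariants (lumen < diameter, aperture < torus < membrane) enforced by
  rejection sampling;
* standardized linear path data with known coefficients for recovery tests
  of the piecewise path model;
* climate-of-origin covariates with specified correlations to chosen traits
  via a direct mixing construction.

All generators are seeded and reproducible; per-stage seeds are derived
from the run seed so stages stay deterministic under reordering.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .pathmodel import PathModel
from .phylosignal import lambda_transform, tree_vcv

# (grand mean, interspecific CV fraction, within-species CV fraction)
TRAIT_SCALES: dict[str, tuple[float, float, float]] = {
    "DPM": (12.0, 0.06, 0.05),
    "D_r": (20.5, 0.10, 0.06),
    "DWT": (4.55, 0.05, 0.06),
    "FL": (1290.0, 0.08, 0.06),
    "RH": (17.5, 0.05, 0.07),
    "NR": (6.2, 0.10, 0.09),
}

#: log-scale coupling of tracheid density to radial diameter (denser wood
#: has narrower tracheids), plus density's own log-SD
TD_MEAN, TD_COUPLING, TD_NOISE_SD = 1600.0, -1.5, 0.10

#: default standardized path coefficients for recovery simulations
DEFAULT_PATH_COEFFS: dict[tuple[str, str], float] = {
    ("DWT", "TSR"): -0.4,
    ("D_r", "TSR"): -0.5,
    ("TSR", "D_h"): -0.5,
    ("D_r", "D_h"): 0.5,
    ("D_h", "K_s"): 0.8,
}

CLIMATE_SCALES: dict[str, tuple[float, float]] = {
    "Ele": (2500.0, 800.0), "Lat": (35.0, 8.0), "Lon": (100.0, 15.0),
    "AMT": (5.0, 4.0), "MTWQ": (15.0, 3.0), "MTDQ": (-5.0, 5.0),
    "APRE": (600.0, 250.0), "PREWQ": (300.0, 120.0), "PREDQ": (30.0, 20.0),
    "AI": (0.6, 0.25),
}

#: default climate-trait coupling targets: pit aperture tracks longitude and
#: dry-quarter temperature, lumen size tracks precipitation, fiber length
#: tracks aridity
DEFAULT_CLIMATE_TARGETS: dict[str, tuple[str, float]] = {
    "Lon": ("DPA", 0.8),
    "MTDQ": ("DPA", -0.56),
    "APRE": ("LD_r", 0.46),
    "AI": ("FL", 0.48),
}


@dataclass
class SimulationConfig:
    seed: int
    n_species: int = 17
    n_individuals: int = 10
    n_tracheids: int = 50
    birth_rate: float = 1.0
    bm_sigma2: float = 1.0
    lambda_true: float = 1.0
    within_individual_cv: float = 0.15  # tracheid-to-tracheid spread
    path_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFS))
    climate_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_TARGETS))

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")


def _subseed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Tree and BM traits

def simulate_tree(n_species: int, birth_rate: float = 1.0,
                  seed: int = 0) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_species`` extant tips, relabelled
    sp01.. in leaf order and rescaled to unit root-to-tip depth."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=rng)
    # the simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry; extend all tips by the waiting time to the next
    # event so the covariance matrix is non-singular
    extra = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def simulate_bm_traits(tree: dendropy.Tree, sigma2: float = 1.0,
                       lambda_true: float = 1.0, seed: int = 0,
                       mean: float = 0.0) -> pd.Series:
    """One multivariate-normal draw of tip values with covariance
    sigma2 * V(lambda); lambda interpolates between star-like independence
    (0) and pure BM (1)."""
    V, order = tree_vcv(tree)
    W = lambda_transform(V, lambda_true)
    evals = np.linalg.eigvalsh(W)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise ValueError("lambda-transformed covariance is not PSD")
    rng = np.random.default_rng(seed)
    if sigma2 == 0:
        y = np.full(len(order), mean)
    else:
        L = np.linalg.cholesky(W + 1e-12 * np.eye(len(order)))
        y = mean + np.sqrt(sigma2) * (L @ rng.standard_normal(len(order)))
    return pd.Series(y, index=order)


# ---------------------------------------------------------------------------
# Species means on measurement scales

def simulate_species_means(tree: dendropy.Tree, lambda_true: float = 1.0,
                           seed: int = 0) -> pd.DataFrame:
    """Species x raw-trait means: log-scale BM deviations around published
    magnitudes, with structural couplings (lumen = diameter minus wall,
    torus/aperture nested inside the membrane, density trading off against
    diameter) so derived traits come out at realistic values."""
    V, order = tree_vcv(tree)
    n = len(order)
    W = lambda_transform(V, lambda_true) + 1e-12 * np.eye(n)
    L = np.linalg.cholesky(W)

    def bm(sd: float, k: int) -> np.ndarray:
        rng = np.random.default_rng(_subseed(seed, k))
        return sd * (L @ rng.standard_normal(n))

    cols: dict[str, np.ndarray] = {}
    z: dict[str, np.ndarray] = {}
    for k, (trait, (mu, cv, _)) in enumerate(sorted(TRAIT_SCALES.items())):
        z[trait] = bm(cv, k)
        cols[trait] = mu * np.exp(z[trait] - 0.5 * cv**2)

    cols["DT"] = 0.52 * cols["DPM"] * np.exp(bm(0.04, 101))
    cols["DPA"] = 0.55 * cols["DT"] * np.exp(bm(0.07, 102))
    cols["D_c"] = 0.92 * cols["D_r"] * np.exp(bm(0.04, 103))
    wall_r = cols["DWT"] * np.exp(bm(0.05, 104))
    wall_c = cols["DWT"] * np.exp(bm(0.05, 105))
    cols["LD_r"] = np.clip(cols["D_r"] - wall_r, 0.3 * cols["D_r"],
                           0.97 * cols["D_r"])
    cols["LD_c"] = np.clip(cols["D_c"] - wall_c, 0.3 * cols["D_c"],
                           0.97 * cols["D_c"])
    td_rng = np.random.default_rng(_subseed(seed, 106))
    cols["TD"] = TD_MEAN * np.exp(TD_COUPLING * z["D_r"]
                                  + TD_NOISE_SD * td_rng.standard_normal(n))
    return pd.DataFrame(cols, index=order).sort_index(axis=1)


_WITHIN_CV_DEFAULT = {t: s[2] for t, s in TRAIT_SCALES.items()}
_WITHIN_CV_DEFAULT.update({"DT": 0.06, "DPA": 0.08, "DPM": 0.05,
                           "D_c": 0.06, "LD_r": 0.07, "LD_c": 0.07,
                           "TD": 0.08})


def add_individual_noise(species_means: pd.DataFrame, n_individuals: int = 10,
                         within_cv: dict[str, float] | float | None = None,
                         n_tracheids: int = 50, seed: int = 0,
                         within_individual_cv: float = 0.15,
                         max_tries: int = 1000) -> pd.DataFrame:
    """Per-individual anatomy table around the species means.

    Each individual's scalar traits are Gaussian multiplicative replicates
    of the species mean; measurement invariants (positive values,
    lumen < diameter, DPA < DT < DPM) are enforced by redrawing the whole
    row, erroring after ``max_tries`` attempts.  Each individual also gets
    ``n_tracheids`` measured radial diameters around its own D_r.
    """
    if isinstance(within_cv, (int, float)):
        cv = {t: float(within_cv) for t in _WITHIN_CV_DEFAULT}
    else:
        cv = dict(_WITHIN_CV_DEFAULT)
        if within_cv:
            cv.update(within_cv)
    if any(v < 0 for v in cv.values()):
        raise ValueError("within-species CVs must be >= 0")
    rng = np.random.default_rng(_subseed(seed, 7))
    scalar_traits = ["D_r", "LD_r", "D_c", "LD_c", "TD", "DWT", "FL", "RH",
                     "NR", "DPM", "DT", "DPA"]
    rows = []
    for species, means in species_means.iterrows():
        if (means[scalar_traits] <= 0).any():
            raise ValueError(f"non-positive species mean for {species}")
        if not (means["DPA"] < means["DT"] < means["DPM"]):
            raise ValueError(
                f"species means for {species} violate DPA < DT < DPM; "
                "invariants infeasible at any noise level")
        for ind in range(1, n_individuals + 1):
            for attempt in range(max_tries):
                row = {t: float(means[t]) * (1.0 + cv[t] * rng.standard_normal())
                       for t in scalar_traits}
                ok = (all(v > 0 for v in row.values())
                      and row["LD_r"] < row["D_r"]
                      and row["LD_c"] < row["D_c"]
                      and row["DPA"] < row["DT"] < row["DPM"])
                if ok:
                    break
            else:
                raise ValueError(
                    f"could not satisfy anatomy invariants for {species} "
                    f"after {max_tries} draws")
            diams = row["D_r"] * (1.0 + within_individual_cv
                                  * rng.standard_normal(n_tracheids))
            diams = np.clip(diams, 0.2 * row["D_r"], None)
            rows.append({"species": species, "individual": f"{species}_i{ind:02d}",
                         **row, "tracheid_diams": [round(d, 4) for d in diams]})
    out = pd.DataFrame(rows)
    return out[["species", "individual", "D_r", "LD_r", "D_c", "LD_c", "TD",
                "DWT", "FL", "RH", "NR", "DPM", "DT", "DPA", "tracheid_diams"]]


# ---------------------------------------------------------------------------
# Path-structured data

def simulate_path_data(coefficients: dict[tuple[str, str], float] | None = None,
                       n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Standardized linear SEM draw with known path coefficients.

    Exogenous variables are iid standard normal; each endogenous variable is
    the linear combination of its parents plus a Gaussian residual scaled so
    every variable has unit population variance.  A coefficient set whose
    parent contribution reaches variance >= 1 is rejected with the feasible
    range reported.
    """
    if n < 50:
        raise ValueError("n must be >= 50")
    coeffs = dict(DEFAULT_PATH_COEFFS if coefficients is None else coefficients)
    nodes = sorted({x for e in coeffs for x in e})
    model = PathModel(nodes, sorted(coeffs))
    import networkx as nx
    topo = list(nx.lexicographical_topological_sort(model.graph()))
    rng = np.random.default_rng(seed)
    cov = pd.DataFrame(np.eye(len(topo)), index=topo, columns=topo)
    data: dict[str, np.ndarray] = {}
    for node in topo:
        parents = model.parents(node)
        if not parents:
            data[node] = rng.standard_normal(n)
            continue
        beta = np.array([coeffs[(p, node)] for p in parents])
        spp = cov.loc[parents, parents].to_numpy()
        explained = float(beta @ spp @ beta)
        if explained >= 1.0:
            raise ValueError(
                f"path coefficients into {node!r} imply variance "
                f"{explained:.3f} >= 1; scale them by < "
                f"{1.0 / np.sqrt(explained):.3f}")
        vals = sum(b * data[p] for b, p in zip(beta, parents))
        data[node] = vals + np.sqrt(1.0 - explained) * rng.standard_normal(n)
        for other in topo:
            if other == node:
                continue
            c = float(beta @ cov.loc[parents, other].to_numpy())
            cov.loc[node, other] = cov.loc[other, node] = c
    return pd.DataFrame({k: data[k] for k in topo})


# ---------------------------------------------------------------------------
# Climate covariates

def simulate_climate(species_means: pd.DataFrame,
                     targets: dict[str, tuple[str, float]] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Climate-of-origin table with chosen trait correlations.

    Each targeted covariate is built as r * z(trait) + sqrt(1-r^2) * noise
    (so r = +/-1 is an exact linear copy); untargeted covariates are
    independent Gaussians.  All columns are then shifted/scaled to realistic
    montane-conifer magnitudes.
    """
    targets = dict(DEFAULT_CLIMATE_TARGETS if targets is None else targets)
    for var, (trait, r) in targets.items():
        if abs(r) > 1:
            raise ValueError(f"target correlation |r| > 1 for {var}: {r}")
        if trait not in species_means.columns:
            raise ValueError(f"target trait {trait!r} missing from species means")
    rng = np.random.default_rng(_subseed(seed, 11))
    n = len(species_means)
    cols = {}
    for var, (mu, sd) in CLIMATE_SCALES.items():
        if var in targets:
            trait, r = targets[var]
            t = species_means[trait].to_numpy(float)
            zt = (t - t.mean()) / t.std(ddof=1)
            c = r * zt + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
        else:
            c = rng.standard_normal(n)
        cols[var] = mu + sd * c
    return pd.DataFrame(cols, index=species_means.index)


# ---------------------------------------------------------------------------
# Clade labels and the full bundle

def assign_clades(tree: dendropy.Tree, n_groups: int = 3) -> pd.Series:
    """Deterministic split of the tree into ``n_groups`` monophyletic-ish
    groups by repeatedly dividing the largest group at its root split."""
    groups = [sorted(lf.taxon.label for lf in tree.leaf_node_iter())]
    node_of = {}
    for node in tree.preorder_node_iter():
        key = tuple(sorted(lf.taxon.label for lf in node.leaf_iter()))
        node_of[key] = node
    while len(groups) < n_groups:
        groups.sort(key=lambda g: (-len(g), g))
        big = groups.pop(0)
        node = node_of[tuple(big)]
        kids = [c for c in node.child_nodes()]
        if len(kids) < 2 or len(big) < 2:
            groups.append(big)
            break
        parts = [sorted(lf.taxon.label for lf in c.leaf_iter()) for c in kids]
        groups.extend(parts)
    groups.sort(key=lambda g: g)
    out = {}
    for i, g in enumerate(groups, start=1):
        for tip in g:
            out[tip] = f"clade{i}"
    return pd.Series(out).sort_index()


@dataclass
class SyntheticDataset:
    tree: dendropy.Tree
    newick: str
    species_means: pd.DataFrame
    anatomy: pd.DataFrame
    climate: pd.DataFrame
    clades: pd.Series
    config: SimulationConfig


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate every input the pipeline consumes, from one seed."""
    tree = simulate_tree(config.n_species, config.birth_rate,
                         seed=_subseed(config.seed, 1))
    means = simulate_species_means(tree, lambda_true=config.lambda_true,
                                   seed=_subseed(config.seed, 2))
    anatomy = add_individual_noise(
        means, n_individuals=config.n_individuals,
        n_tracheids=config.n_tracheids, seed=_subseed(config.seed, 3),
        within_individual_cv=config.within_individual_cv)
    climate = simulate_climate(means, targets=config.climate_targets,
                               seed=_subseed(config.seed, 4))
    clades = assign_clades(tree)
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return SyntheticDataset(tree, newick, means, anatomy, climate, clades,
                            config)
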