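"""End-to-end orchestration: derive -> variation -> ordination -> path model
-> phylogenetic signal -> climate screen, with all intermediates written as
CSV so any stage can be re-run from saved files."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import ordination, pathmodel, phylosignal, traits, varstats
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "xylemtraits_out"
    anatomy_csv: str | None = None
    tree_file: str | None = None
    climate_csv: str | None = None
    clades_csv: str | None = None
    model_json: str | None = None
    synthetic: bool = False
    n_perm: int = 999
    log_before_analysis: bool = True
    tsr_formula: str = "double_wall_over_span"
    cwr_formula: str = "area_fraction"
    constants: PhysicalConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is required")
        if not self.synthetic:
            for name in ("anatomy_csv", "tree_file", "climate_csv"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise ValueError(
                        f"{name} missing or not found ({path}); pass the file "
                        "or use synthetic mode")


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, index=index)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order, writing intermediates plus a
    machine-readable ``summary.json``; returns the summary dict.

    On a stage failure the exception is re-raised annotated with the stage
    name; outputs of completed stages remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}
    stage = "inputs"
    try:
        if config.synthetic:
            ds = simulate_dataset(SimulationConfig(seed=config.seed))
            anatomy = ds.anatomy
            tree = ds.tree
            climate_df = ds.climate
            clades = ds.clades
            traits.write_anatomy_csv(anatomy, out / "anatomy.csv")
            (out / "tree.nwk").write_text(ds.newick + "\n")
            climate_df.rename_axis("species").to_csv(out / "climate.csv")
            clades.rename("clade").rename_axis("species").to_csv(
                out / "clades.csv")
        else:
            anatomy = traits.read_anatomy_csv(config.anatomy_csv)
            tree = phylosignal.read_newick(config.tree_file)
            climate_df = climate_mod.read_climate_csv(config.climate_csv)
            clades = None
            if config.clades_csv:
                clades = pd.read_csv(config.clades_csv).set_index(
                    "species")["clade"]
        summary["stages"].append(stage)

        stage = "derive"
        derived = traits.derive_all(anatomy, constants=config.constants,
                                    tsr_formula=config.tsr_formula,
                                    cwr_formula=config.cwr_formula)
        means, sds, counts = traits.species_summary(derived)
        traits.write_derived_csv(derived, out / "derived.csv")
        _write_csv(means.rename_axis("species"), out / "species_means.csv")
        _write_csv(sds.rename_axis("species"), out / "species_sds.csv")
        summary["n_individuals"] = int(len(derived))
        summary["n_species"] = int(len(means))
        summary["stages"].append(stage)

        stage = "varstats"
        trait_cols = [t for t in traits.ALL_TRAITS if t in derived.columns]
        analysed = derived[["species"] + trait_cols]
        if config.log_before_analysis:
            analysed = pd.concat(
                [derived[["species"]], varstats.log_transform(derived[trait_cols])],
                axis=1)
        cv = varstats.interspecific_cv(means)
        cv.rename("interspecific_cv_pct").rename_axis("trait").to_csv(
            out / "cv.csv")
        within = varstats.within_species_cv(derived, traits=trait_cols)
        _write_csv(within.rename_axis("species"), out / "within_species_cv.csv")
        anova_rows, letters_rows = [], []
        for trait in trait_cols:
            res = varstats.anova_tukey(analysed, trait)
            anova_rows.append({"trait": trait, "F": res.F, "p": res.p})
            for sp, let in res.letters.items():
                letters_rows.append({"trait": trait, "species": sp,
                                     "letters": let})
        anova_df = pd.DataFrame(anova_rows).set_index("trait")
        _write_csv(anova_df, out / "anova.csv")
        _write_csv(pd.DataFrame(letters_rows), out / "tukey_letters.csv",
                   index=False)
        r, p = varstats.pearson_matrix(means)
        _write_csv(r, out / "corr_r.csv")
        _write_csv(p, out / "corr_p.csv")
        clust = varstats.cluster_traits(r)
        pd.Series(clust.leaf_order, name="trait").to_csv(
            out / "cluster_order.csv", index=False)
        summary["cv_range_pct"] = [float(cv.min()), float(cv.max())]
        summary["widest_cv_trait"] = str(cv.idxmax())
        summary["stages"].append(stage)

        stage = "ordination"
        z = ordination.standardize(means)
        pca = ordination.pca_fit(z)
        _write_csv(pca.loadings.rename_axis("trait"), out / "pca_loadings.csv")
        _write_csv(pca.scores.rename_axis("species"), out / "pca_scores.csv")
        pd.DataFrame({"component": pca.loadings.columns,
                      "explained_fraction": pca.explained_fraction}).to_csv(
            out / "pca_explained.csv", index=False)
        summary["pca_first_two_pct"] = float(
            100 * pca.explained_fraction[:2].sum())
        summary["stages"].append(stage)

        stage = "pathmodel"
        model = (pathmodel.PathModel.from_json(config.model_json)
                 if config.model_json else pathmodel.PathModel.default())
        fit = pathmodel.fit_path_model(model, derived)
        _write_csv(pathmodel.edge_table(fit), out / "sem_edges.csv",
                   index=False)
        target = "K_s" if "K_s" in model.nodes else model.endogenous()[-1]
        _write_csv(pathmodel.effects_table(fit, target),
                   out / "sem_effects.csv", index=False)
        summary["sem"] = {
            "dsep_C": fit.dsep_C, "dsep_df": fit.dsep_df, "dsep_p": fit.dsep_p,
            "accepted": bool(fit.dsep_p > 0.05),
            "total_effects_on_" + target: {
                n: e.total for n, e in fit.effects_on[target].items()},
        }
        summary["stages"].append(stage)

        stage = "phylosignal"
        sig_means = means
        if config.log_before_analysis:
            sig_means = varstats.log_transform(means)
        signal = phylosignal.signal_table(tree, sig_means,
                                          n_perm=config.n_perm,
                                          seed=config.seed)
        _write_csv(signal, out / "signal.csv")
        summary["signal"] = {
            t: {"K": float(row["K"]), "K_p": float(row["K_p"]),
                "lambda": float(row["lambda"]),
                "lambda_p": float(row["lambda_p"])}
            for t, row in signal.iterrows()}
        if clades is not None:
            clades.rename("clade").rename_axis("species").to_csv(
                out / "clades_used.csv")
        summary["stages"].append(stage)

        stage = "climate"
        scores2 = pca.scores[["PC1", "PC2"]]
        trait_block = pd.concat([means, scores2], axis=1)
        r_c, p_c, star = climate_mod.climate_correlation_table(
            trait_block, climate_df)
        _write_csv(r_c, out / "climate_r.csv")
        _write_csv(p_c, out / "climate_p.csv")
        _write_csv(star, out / "climate_stars.csv")
        summary["stages"].append(stage)
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1, sort_keys=True)
    return summary
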