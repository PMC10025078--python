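"""End-to-end orchestration: load a survey bundle, run every analysis stage.

The stage sequence mirrors a standard heterogeneity-community workflow:
collinearity screen, integrated densities and offsets, evenness profiles,
compositional clustering, multivariate NB GLMs with sum-of-LR bootstrap
tests (local and landscape predictor subsets separately), beta regression of
evenness, and penalized SDM / fourth-corner models. Every stage writes CSV
or JSON artifacts plus a machine-readable manifest with all seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .betareg import beta_lr_test, fit_beta_logit, stepwise_aic_beta
from .diversity import evenness_table
from .exploration import cluster_tables, pearson_screen, silhouette_validate, ward_cluster
from .fourthcorner import build_fourth_corner_design, cv_select_lambda, standardized_coefficients
from .nbglm import backward_stepwise_aic, dunn_smyth_residuals, fit_many_nb, sum_of_lr_test
from .simulate import LANDSCAPE_PREDICTORS, LOCAL_PREDICTORS
from .survey import (
    SpeciesCatalog,
    SurveyError,
    pool_site_matrix,
    read_plots,
    read_recording_groups,
    read_species_catalog,
    write_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    offset_mode: str = "by_group"
    n_boot: int = 999
    cv_folds: int = 5
    lambda_points: int = 50
    seed: int = 0
    local_predictors: list[str] = field(default_factory=lambda: list(LOCAL_PREDICTORS))
    landscape_predictors: list[str] = field(default_factory=lambda: list(LANDSCAPE_PREDICTORS))
    trait_columns: list[str] | None = None
    log1p_cluster: bool = False

    def __post_init__(self) -> None:
        if self.n_boot < 99:
            raise ValueError("n_boot must be at least 99")


@dataclass
class Bundle:
    """Validated in-memory survey dataset."""

    plots: list
    catalog: SpeciesCatalog
    env: pd.DataFrame
    traits: pd.DataFrame | None
    report: dict


def load_bundle(
    plots_path, groups_path, catalog_path, env_path, traits_path=None
) -> Bundle:
    """Load and cross-validate a CSV input bundle.

    Referential integrity: every species appearing in plot counts must have
    a recording-group assignment, and (when traits are supplied) a trait
    row. Violations raise with the offending species named.
    """
    groups = read_recording_groups(groups_path)
    catalog = read_species_catalog(catalog_path, groups)
    plots = read_plots(plots_path)
    env = pd.read_csv(env_path, index_col=0)
    traits = pd.read_csv(traits_path, index_col=0) if traits_path else None

    observed = sorted({sp for p in plots for sp in p.counts})
    missing = [sp for sp in observed if sp not in catalog.assignment]
    if missing:
        raise SurveyError(f"species missing from catalog: {missing}")
    if traits is not None:
        missing_t = [sp for sp in observed if sp not in traits.index]
        if missing_t:
            raise SurveyError(f"species missing from traits table: {missing_t}")
    plot_sites = sorted({p.site_id for p in plots})
    missing_env = [s for s in plot_sites if s not in env.index.astype(str)]
    if missing_env:
        raise SurveyError(f"sites missing from env table: {missing_env}")
    report = {"n_plots": len(plots), "n_sites": len(plot_sites), "n_species": len(observed)}
    return Bundle(plots=plots, catalog=catalog, env=env, traits=traits, report=report)


def run_all(bundle: Bundle, config: RunConfig, outdir) -> dict:
    """Execute every stage and write artifacts under `outdir`.

    Returns the manifest dict (also written as manifest.json). A stage
    failure propagates after earlier artifacts are on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    seeds = {name: int(config.seed * 31 + k) % (2**31 - 1)
             for k, name in enumerate(
                 ["mvglm_local", "mvglm_landscape", "residuals", "sdm", "fourth_corner"])}
    manifest["stage_seeds"] = seeds

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **counts}

        return done

    # 1. collinearity screen
    done = stage("collinearity")
    flagged = pearson_screen(bundle.env)
    flagged.to_csv(out / "collinearity.csv", index=False)
    done(n_flagged=len(flagged))
    if len(flagged):
        logger.warning("collinear predictor pairs flagged (|r| >= 0.7):\n%s", flagged)

    # 2. densities + offsets
    done = stage("density")
    matrix = pool_site_matrix(bundle.plots, bundle.catalog, offset_mode=config.offset_mode)
    write_matrix(matrix, out / "densities.csv", out / "offsets.csv")
    done(n_sites=len(matrix.sites), n_species=len(matrix.species),
         empty_sites=len(matrix.empty_sites))

    # 3. evenness
    done = stage("evenness")
    even = evenness_table(matrix.density)
    even.to_csv(out / "evenness.csv")
    done(n_sites=len(even))

    # 4. clustering
    done = stage("cluster")
    cl = ward_cluster(matrix.density, log1p=config.log1p_cluster)
    cl = silhouette_validate(matrix.density, cl, log1p=config.log1p_cluster)
    labels, sil = cluster_tables(cl)
    labels.to_csv(out / "clusters.csv")
    sil.to_csv(out / "silhouette.csv", index=False)
    done(best_k=cl.best_k)

    # 5. multivariate NB GLMs per predictor subset
    model = matrix.modeling_view()
    env_model = bundle.env.loc[[s for s in model.sites]]
    mv_summary = {}
    for subset, terms, seed_key in (
        ("local", config.local_predictors, "mvglm_local"),
        ("landscape", config.landscape_predictors, "mvglm_landscape"),
    ):
        done = stage(f"mvglm_{subset}")
        full = fit_many_nb(model.raw_counts, env_model[terms], model.offset)
        selected, path = backward_stepwise_aic(full)
        intercept_only = fit_many_nb(
            model.raw_counts, env_model[terms], model.offset,
            design=selected.design.subset([]),
        )
        overall = sum_of_lr_test(selected, intercept_only, n_boot=config.n_boot,
                                 seed=seeds[seed_key])
        per_term = {}
        for k, t in enumerate(selected.design.term_names):
            reduced = fit_many_nb(
                model.raw_counts, env_model[terms], model.offset,
                design=selected.design.subset(
                    [x for x in selected.design.term_names if x != t]),
            )
            res = sum_of_lr_test(selected, reduced, n_boot=config.n_boot,
                                 seed=seeds[seed_key] + 1 + k)
            per_term[t] = {"LR": res.statistic, "p": res.p_value}
        mv_summary[subset] = {
            "selected_terms": selected.design.term_names,
            "selection_path": path,
            "overall": {"LR": overall.statistic, "p": overall.p_value},
            "per_term": per_term,
            "dropped_species": selected.dropped_species,
        }
        selected.coef_frame().to_csv(out / f"coefficients_{subset}.csv")
        dunn_smyth_residuals(selected, seed=seeds["residuals"]).to_csv(
            out / f"residuals_{subset}.csv")
        done(n_terms_selected=len(selected.design.term_names))
    (out / "mvglm_summary.json").write_text(json.dumps(mv_summary, indent=2))

    # 6. beta regression of evenness
    ok = even["RLE02"].notna()
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("excluding %d sites without defined RLE from evenness models", n_excluded)
    beta_summary = {}
    for subset, terms in (("local", config.local_predictors),
                          ("landscape", config.landscape_predictors)):
        done = stage(f"betareg_{subset}")
        env_b = bundle.env.loc[even.index[ok], terms]
        y = even.loc[ok, "RLE02"]
        full = fit_beta_logit(y, env_b)
        selected, path = stepwise_aic_beta(full)
        null = fit_beta_logit(y, env_b, design=full.design.subset([]))
        stat, df, p = beta_lr_test(selected, null)
        per_term = {}
        for t in selected.design.term_names:
            red = fit_beta_logit(y, env_b, design=selected.design.subset(
                [x for x in selected.design.term_names if x != t]))
            s_t, df_t, p_t = beta_lr_test(selected, red)
            per_term[t] = {"logLR": s_t, "df": df_t, "p": p_t}
        beta_summary[subset] = {
            "selected_terms": selected.design.term_names,
            "selection_path": path,
            "phi": selected.phi,
            "coefficients": selected.coef.to_dict(),
            "overall": {"logLR": stat, "df": df, "p": p},
            "per_term": per_term,
            "n_sites_excluded": n_excluded,
        }
        pd.DataFrame({"site": even.index[ok], "RLE02": y.to_numpy(),
                      "fitted": selected.fitted}).to_csv(
            out / f"evenness_effects_{subset}.csv", index=False)
        done(n_terms_selected=len(selected.design.term_names))
    (out / "betareg_summary.json").write_text(json.dumps(beta_summary, indent=2))

    # 7. SDM + fourth-corner (needs traits)
    if bundle.traits is not None:
        done = stage("sdm")
        env_all = env_model[config.local_predictors + config.landscape_predictors]
        traits = bundle.traits.loc[model.species]
        if config.trait_columns:
            traits = traits[config.trait_columns]
        sdm_design = build_fourth_corner_design(env_all, traits, model.offset, mode="sdm")
        sdm = cv_select_lambda(sdm_design, model.raw_counts, k_folds=config.cv_folds,
                               n_lambda=config.lambda_points, seed=seeds["sdm"])
        standardized_coefficients(sdm).to_csv(out / "msdm_coefficients.csv")
        done(lam=sdm.lam, nonzero=sdm.n_nonzero, pseudo_r2=sdm.pseudo_r2)

        done = stage("fourth_corner")
        fc_design = build_fourth_corner_design(env_all, traits, model.offset,
                                               mode="fourth_corner")
        fc = cv_select_lambda(fc_design, model.raw_counts, k_folds=config.cv_folds,
                              n_lambda=config.lambda_points, seed=seeds["fourth_corner"])
        standardized_coefficients(fc).to_csv(out / "fourth_corner_coefficients.csv")
        fc.cv_path.to_csv(out / "cv_path.csv", index=False)
        done(lam=fc.lam, nonzero=fc.n_nonzero, pseudo_r2=fc.pseudo_r2)

    manifest["inputs"] = bundle.report
    manifest["config"] = {
        "offset_mode": config.offset_mode, "n_boot": config.n_boot,
        "cv_folds": config.cv_folds, "local_predictors": config.local_predictors,
        "landscape_predictors": config.landscape_predictors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
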