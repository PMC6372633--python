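"""End-to-end pipeline: simulate -> validate -> QC -> allometry ->
multivariate -> differential -> coherence -> predict, driven by a single
serializable config with explicit per-stage seeds and a machine-readable
run report.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import allometry as am
from . import coherence as ch
from . import differential as dm
from . import multivariate as mv
from . import predictive as pr
from . import qc
from . import synthetic as syn
from .errors import ConfigError
from .seeds import spawn_seed
from .tables import (
    BiomassTable,
    FeatureTable,
    read_blanks,
    validate_biomass_csv,
    validate_feature_csv,
    write_blanks,
)

STAGES = (
    "simulate",
    "validate",
    "qc",
    "allometry",
    "multivariate",
    "differential",
    "coherence",
    "predict",
)


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    # simulate
    n_genotypes: int = 30
    n_replicates: int = 5
    n_features: int = 2897
    missing_rate: float = 0.03
    outlier_rate: float = 0.002
    effect_tissue: float = 3.0
    effect_genotype: float = 2.0
    effect_regime: float = 0.6
    effect_biomass: float = 0.8
    biomass_noise_sd: float = 0.15
    # qc
    blank_ratio_threshold: float = 0.5
    min_present: int = 3
    fence_mult: float = 3.0
    # allometry
    mcmc_chains: int = 4
    mcmc_warmup: int = 1000
    mcmc_draws: int = 1000
    # multivariate
    n_perm_permanova: int = 10000
    n_perm_gamma: int = 1000
    impute_rank: int = 5
    # differential
    alpha: float = 0.01
    # predict
    n_folds: int = 5
    rf_trees: int = 500
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")


def validate_inputs(paths: dict) -> dict:
    """Schema-check the referenced CSVs; returns pass/fail + diagnostics."""
    problems: list[str] = []
    if "features" in paths:
        problems += validate_feature_csv(paths["features"])
    if "biomass" in paths:
        problems += validate_biomass_csv(paths["biomass"])
    return {"passed": not problems, "problems": problems}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in canonical order; return the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
        "stages": {},
    }
    enabled = [s for s in STAGES if s in config.stages]
    report["enabled_stages"] = enabled
    state: dict = {}

    for stage in enabled:
        try:
            _run_stage(stage, config, outdir, state, report)
        except Exception as exc:
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_report(report, outdir)
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)


def _run_stage(stage, config, outdir, state, report) -> None:
    entry: dict = {"status": "ok"}
    if stage == "simulate":
        spec = syn.DesignSpec(
            n_genotypes=config.n_genotypes,
            n_replicates=config.n_replicates,
            n_features=config.n_features,
            seed=spawn_seed(config.seed, "simulate"),
        )
        effects = syn.EffectSizes(
            tissue=config.effect_tissue,
            genotype=config.effect_genotype,
            regime=config.effect_regime,
            biomass=config.effect_biomass,
        )
        bundle = syn.generate_study(
            spec,
            effects=effects,
            missing_rate=config.missing_rate,
            outlier_rate=config.outlier_rate,
            biomass_noise_sd=config.biomass_noise_sd,
        )
        bundle.table.to_csv(outdir / "features.csv")
        write_blanks(bundle.blanks, outdir / "blanks.csv")
        bundle.biomass.to_csv(outdir / "biomass.csv")
        bundle.truth.to_json(outdir / "ground_truth.json")
        state["bundle"] = bundle
        entry.update(
            n_samples=bundle.table.n_samples,
            n_features=bundle.table.n_features,
            n_plants=len(bundle.biomass.data),
        )
    elif stage == "validate":
        res = validate_inputs(
            {"features": outdir / "features.csv", "biomass": outdir / "biomass.csv"}
        )
        entry.update(res)
        if not res["passed"]:
            raise ConfigError("input validation failed: " + "; ".join(res["problems"]))
    elif stage == "qc":
        bundle = state["bundle"]
        filtered = qc.run_qc(
            bundle.table,
            bundle.blanks,
            ratio_threshold=config.blank_ratio_threshold,
            min_present=config.min_present,
            rule=qc.OutlierRule(config.fence_mult, config.fence_mult),
        )
        log2 = qc.log2_transform(filtered)
        testability = qc.anova_presence_filter(log2)
        filtered.to_csv(outdir / "features_filtered.csv")
        with open(outdir / "filter_report.json", "w") as fh:
            json.dump(qc.filter_report(filtered), fh, indent=1, sort_keys=True)
        state["filtered"] = filtered
        state["log2"] = log2
        state["testability"] = testability
        entry.update(
            n_features_surviving=filtered.n_features,
            filter_counts={e["step"]: e.get("n_removed", e.get("n_nulled", 0))
                           for e in filtered.log if e["step"] != "simulate"},
            anova_filter_removed=testability.n_removed,
        )
    elif stage == "allometry":
        bundle = state["bundle"]
        fits = {}
        for regime in ("control", "drought"):
            post = am.fit_allometry_bhm(
                bundle.biomass,
                mcmc=am.MCMCConfig(
                    n_chains=config.mcmc_chains,
                    n_warmup=config.mcmc_warmup,
                    n_draws=config.mcmc_draws,
                ),
                seed=spawn_seed(config.seed, f"allometry_{regime}"),
                regime=regime,
            )
            post.summary.to_csv(outdir / f"allometry_{regime}.csv", index=False)
            fits[regime] = post
        rmf = am.compute_rmf(bundle.biomass)
        rmf.to_csv(outdir / "rmf.csv", index=False)
        drought = am.test_drought_biomass(bundle.biomass)
        drought.results.to_csv(outdir / "drought_biomass_tests.csv", index=False)
        state["allometry"] = fits
        entry.update(
            converged={r: bool(f.converged) for r, f in fits.items()},
            k_range={
                r: [float(f.summary["k_mean"].min()), float(f.summary["k_mean"].max())]
                for r, f in fits.items()
            },
        )
    elif stage == "multivariate":
        log2 = state["log2"]
        completed, info = mv.impute_pca(log2.values, n_components=config.impute_rank)
        dist = mv.euclidean_distances(completed)
        perm_res = mv.permanova(
            dist,
            log2.meta,
            n_perm=config.n_perm_permanova,
            seed=spawn_seed(config.seed, "permanova"),
        )
        perm_res.table.to_csv(outdir / "permanova.csv", index=False)
        # genotype-averaged control dendrograms per tissue + Baker's gamma
        trees = {}
        for tissue in sorted(log2.meta["tissue"].unique()):
            rows = (
                (log2.meta["tissue"] == tissue) & (log2.meta["regime"] == "control")
            ).to_numpy()
            d = mv.euclidean_distances(
                completed.loc[rows], log2.meta.loc[rows], average_by_genotype=True
            )
            tree = mv.hcluster_ward_squared(d)
            trees[tissue] = tree
            with open(outdir / f"dendrogram_{tissue}.nwk", "w") as fh:
                fh.write(tree.to_newick() + "\n")
        gamma = mv.gamma_permutation_test(
            trees[sorted(trees)[0]],
            trees[sorted(trees)[1]],
            n_perm=config.n_perm_gamma,
            seed=spawn_seed(config.seed, "gamma"),
        )
        pca_res = mv.pca(completed, scale=True)
        pca_res.scores.iloc[:, :10].to_csv(outdir / "pca_scores.csv")
        state["completed"] = completed
        state["impute_info"] = info
        entry.update(
            impute_converged=bool(info.converged),
            permanova_degenerate=bool(perm_res.degenerate),
            pseudo_f={
                r.term: float(r.pseudo_f) for r in perm_res.table.itertuples()
            },
            bakers_gamma=float(gamma.gamma),
            gamma_p=float(gamma.p_value),
        )
    elif stage == "differential":
        log2 = state["log2"]
        testability = state["testability"]
        counts = {}
        for tissue in sorted(log2.meta["tissue"].unique()):
            diff = dm.test_metabolites(
                log2, tissue, testability=testability, alpha=config.alpha
            )
            diff.results.to_csv(outdir / f"differential_{tissue}.csv", index=False)
            z, sig, flagged = dm.logfold_heatmap_matrix(diff)
            z.to_csv(outdir / f"heatmap_{tissue}.csv")
            sig.to_csv(outdir / f"heatmap_mask_{tissue}.csv")
            c = dm.count_significant(diff)
            counts[tissue] = {
                str(r.genotype): int(r.n_significant) for r in c.itertuples()
            }
        entry.update(n_significant=counts)
    elif stage == "coherence":
        completed = state["completed"]
        log2 = state["log2"]
        summary = {}
        for regime in sorted(log2.meta["regime"].unique()):
            wide = _per_plant_concat(completed, log2.meta, regime)
            dist = mv.euclidean_distances(wide)
            tree = mv.hcluster_ward_squared(dist)
            k = min(config.n_genotypes, tree.n_leaves)
            labels = mv.cut_tree(tree, k)
            genos = [p.rsplit("_", 2)[0] for p in wide.index]
            tab = ch.build_coherence_table(labels, genos)
            frac, coherent = ch.coherence_fraction(tab)
            tab.tidy().to_csv(outdir / f"coherence_{regime}.csv", index=False)
            summary[regime] = {
                "fraction": frac,
                "coherent_genotypes": sorted(map(str, coherent)),
            }
        with open(outdir / "coherence_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        entry.update(summary)
    elif stage == "predict":
        bundle = state["bundle"]
        completed = state["completed"]
        meta = state["log2"].meta
        results = {}
        for regime in ("control",):
            wide = _per_plant_concat(completed, meta, regime)
            bio = bundle.biomass.data.set_index("plant_id")
            target = bio.loc[wide.index, "shoot_dw_g"].to_numpy()
            genos = bio.loc[wide.index, "genotype"].to_numpy()
            res = pr.fit_biomass_predictor(
                wide,
                genos,
                target,
                n_folds=config.n_folds,
                seed=spawn_seed(config.seed, f"predict_{regime}"),
                config=pr.PredictorConfig(n_estimators=config.rf_trees),
            )
            res.importances.sort_values(ascending=False).to_csv(
                outdir / f"importance_{regime}.csv", header=["importance"]
            )
            mask = np.array([c.endswith("_belowground") for c in wide.columns])
            if mask.any() and not mask.all():
                abl = pr.ablation_rmse_delta(
                    wide, genos, mask, target,
                    n_folds=config.n_folds,
                    seed=spawn_seed(config.seed, f"predict_{regime}"),
                    config=pr.PredictorConfig(n_estimators=config.rf_trees),
                    group="belowground",
                )
                results[regime] = {
                    "cv_rmse": res.cv_rmse,
                    "ablated_rmse": abl.ablated_rmse,
                    "pct_increase": abl.pct_increase,
                }
            else:
                results[regime] = {"cv_rmse": res.cv_rmse}
        with open(outdir / "prediction_report.json", "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
        entry.update(results)
    report["stages"][stage] = entry


def _per_plant_concat(
    values: pd.DataFrame, meta: pd.DataFrame, regime: str
) -> pd.DataFrame:
    """Per-plant feature vectors: aboveground and belowground concatenated."""
    rows = (meta["regime"] == regime).to_numpy()
    vals = values.loc[rows]
    sub = meta.loc[rows]
    parts = []
    for tissue in sorted(sub["tissue"].unique()):
        t_rows = (sub["tissue"] == tissue).to_numpy()
        part = vals.loc[t_rows].copy()
        part.index = sub.loc[t_rows, "plant_id"]
        part.columns = [f"{c}_{tissue}" for c in part.columns]
        parts.append(part.sort_index())
    wide = pd.concat(parts, axis=1)
    if wide.isna().any().any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wide = wide.dropna()
    return wide
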