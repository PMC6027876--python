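"""End-to-end pipeline orchestration and tabular reports.

``run_pipeline`` wires the stages together — synthetic data (or user files)
→ genotype QC → F1 projection → mixed-model BLUPs → genomic prediction —
and writes the summary tables: per-marker statistics with the
average/median roll-up used for platform comparisons, variance partitions
per population, heterosis medians, the long-format scheme-accuracy table,
pairwise scheme contrasts, exhaustive-hybrid GEBVs and the
yield-vs-flowering frontier. A manifest records the seed, a config hash,
package versions, per-stage timings and record counts so reruns are exactly
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CrossPlan, GenotypeMatrix
from .errors import MilletGSError, ParameterError
from .genotyping import filter_markers, impute_naive, maf_filter, marker_stats
from .genomic_prediction import (
    CVResult,
    SchemeConfig,
    compare_schemes,
    pareto_frontier,
    predict_all_hybrids,
    rrblup_fit,
    run_scheme,
)
from .hybrid_projection import project_all
from .io import write_csv, write_matrix
from .mixed_models import (
    HeritabilityInput,
    fit_random_model,
    heritability,
    heterosis_median,
    midparent_heterosis,
)
from .synthetic_data import (
    TraitArchitecture,
    add_missingness,
    combine_pools,
    simulate_field_book,
    simulate_founders,
    simulate_trait,
)


@dataclass
class TraitSpec:
    """Generator settings for one synthetic trait."""

    name: str
    n_qtl: int = 100
    dominance_ratio: float = 0.0
    baseline: float = 50.0
    loc_sd: float = 1.0
    gxe_sd: float = 1.0
    rep_sd: float = 0.5
    block_sd: float = 0.5
    resid_sd: float = 2.0
    target_h2: float = 0.8


@dataclass
class RunConfig:
    """Declarative configuration of a full synthetic run.

    Defaults mirror the emulated study design: two founder pools crossed in
    a sparse factorial, phenotyped at 4 locations × 2 replicates in 15-plot
    blocks with 2 repeated controls, four CV schemes with 20 repetitions of
    five-fold cross-validation.
    """

    seed: int = 0
    out_dir: str = "milletgs_run"
    # founders / markers
    n_b: int = 40
    n_r: int = 40
    n_markers: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    pool_divergence: float = 0.0
    missing_rate: float = 0.1
    # phenotyped populations and field design
    n_pheno_hybrids: int = 286
    n_pheno_inbreds: int = 39
    n_locations: int = 4
    n_reps: int = 2
    block_size: int = 15
    n_controls: int = 2
    nesting: str = "nested"
    # traits
    traits: list = field(
        default_factory=lambda: [
            TraitSpec("flowering_like", dominance_ratio=0.1, resid_sd=1.5, target_h2=0.88),
            TraitSpec("yield_like", dominance_ratio=1.0, resid_sd=3.0, target_h2=0.6),
        ]
    )
    # genomic prediction
    schemes: tuple = ("M1", "M2", "M3A", "M3B")
    n_repetitions: int = 20
    marker_counts: tuple = (64, 256, 1024, "all")
    frontier_max_trait: str = "yield_like"
    frontier_min_trait: str = "flowering_like"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        traits = [TraitSpec(**t) for t in raw.pop("traits", [])]
        cfg = cls(**raw)
        if traits:
            cfg.traits = traits
        return cfg

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class _Stage:
    """Context manager logging per-stage wall time into the manifest."""

    def __init__(self, manifest: dict, name: str):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.manifest["stages"][self.name] = round(time.perf_counter() - self.t0, 3)
        if exc is not None and not isinstance(exc, MilletGSError):
            raise MilletGSError(f"stage {self.name!r} failed: {exc}") from exc
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline and write the report bundle.

    Returns a dict of the in-memory results keyed by stage, with all tables
    also written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "versions": {
            "milletgs": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "counts": {},
    }
    rng = np.random.default_rng(config.seed)
    results: dict = {}

    with _Stage(manifest, "simulate"):
        pool_b, pool_r = simulate_founders(
            config.n_b, config.n_r, config.n_markers,
            config.maf_low, config.maf_high, seed=config.seed,
            pool_divergence=config.pool_divergence,
        )
        parents_true = combine_pools(pool_b, pool_r)
        full_plan = CrossPlan.full_factorial(pool_b.line_ids, pool_r.line_ids)
        n_pheno = config.n_pheno_hybrids + config.n_controls
        if n_pheno > len(full_plan):
            raise ParameterError("more phenotyped hybrids requested than crosses exist")
        pick = rng.choice(len(full_plan), size=n_pheno, replace=False)
        pheno_plan = CrossPlan(full_plan.table.iloc[np.sort(pick)])
        hybrids_true = project_all(pheno_plan, parents_true)
        # phenotyped inbreds are parents of the phenotyped hybrids, as in a
        # breeding programme where parental lines are trialled alongside
        parent_pool = pd.unique(
            pheno_plan.table[["female_id", "male_id"]].to_numpy().ravel()
        )
        inbred_ids = list(
            rng.choice(parent_pool,
                       size=min(config.n_pheno_inbreds, len(parent_pool)),
                       replace=False)
        )
        controls = list(pheno_plan.hybrid_ids[: config.n_controls])
        experimental_hybrids = list(pheno_plan.hybrid_ids[config.n_controls:])

        everything = GenotypeMatrix.concat_entries(parents_true, hybrids_true)
        pheno_entries = experimental_hybrids + inbred_ids + controls
        archs, true_vals = {}, {}
        for i, spec in enumerate(config.traits):
            arch = TraitArchitecture.random(
                config.n_markers, spec.n_qtl, seed=config.seed + 1000 + i,
                dominance_ratio=spec.dominance_ratio, baseline=spec.baseline,
                loc_sd=spec.loc_sd, gxe_sd=spec.gxe_sd, rep_sd=spec.rep_sd,
                block_sd=spec.block_sd, resid_sd=spec.resid_sd,
                target_h2=spec.target_h2,
            )
            archs[spec.name] = arch
            true_vals[spec.name] = simulate_trait(arch, everything)
        truth = pd.DataFrame(true_vals).loc[pheno_entries]
        entry_types = everything.entries["entry_type"].reindex(pheno_entries)
        book = simulate_field_book(
            truth, config.n_locations, config.n_reps, config.block_size,
            archs, controls, seed=config.seed + 7, entry_types=entry_types,
        )
        write_csv(book, out / "field_book.csv", seed=config.seed)
        pheno_plan.to_csv(out / "cross_plan.csv", seed=config.seed)
        manifest["counts"]["plots"] = len(book)
        manifest["counts"]["phenotyped_hybrids"] = len(pheno_plan)
        manifest["counts"]["phenotyped_inbreds"] = len(inbred_ids)
        results["plan"], results["book"], results["archs"] = pheno_plan, book, archs

    with _Stage(manifest, "genotyping"):
        observed = add_missingness(parents_true, config.missing_rate, seed=config.seed + 11)
        filtered, tally = filter_markers(observed)
        informative = maf_filter(filtered, 0.05)
        imputed = impute_naive(informative, seed=config.seed + 13)
        stats = marker_stats(informative)
        roll = stats[["missing_rate", "het_rate", "maf"]].agg(["mean", "median"])
        write_csv(stats, out / "marker_stats.csv", seed=config.seed, index=True)
        write_csv(roll, out / "marker_stats_summary.csv", seed=config.seed, index=True)
        write_csv(tally.to_frame().T, out / "filter_tally.csv", seed=config.seed)
        manifest["counts"]["markers_total"] = config.n_markers
        manifest["counts"]["markers_informative"] = informative.n_markers
        results["parents_imputed"], results["filter_tally"] = imputed, tally
        results["marker_stats"] = stats

    with _Stage(manifest, "projection"):
        hybrids_obs = project_all(pheno_plan, imputed)
        write_matrix(hybrids_obs, out / "hybrid_dosages.tsv", seed=config.seed)
        manifest["counts"]["projected_hybrids"] = hybrids_obs.n_entries
        results["hybrids_obs"] = hybrids_obs

    with _Stage(manifest, "mixed_models"):
        design = HeritabilityInput(config.n_locations, config.n_reps)
        vc_rows, h2_rows, het_rows, blups = [], [], [], {}
        part_rows = []
        for spec in config.traits:
            subsets = {
                "joint": book,
                "hybrid": book[book["entry_type"].isin(["hybrid", "control"])],
                "inbred": book[book["entry_type"].str.startswith("inbred")],
            }
            for popname, sub in subsets.items():
                vc, bl, _ = fit_random_model(sub, spec.name, nesting=config.nesting)
                vc_rows.append({"trait": spec.name, "population": popname, **{
                    k: getattr(vc, k) for k in
                    ("v_g", "v_l", "v_gxl", "v_rep", "v_block", "v_resid")}})
                h2_rows.append({
                    "trait": spec.name, "population": popname,
                    "H2": heritability(vc, design),
                })
                part = vc.partition()
                part_rows.append({"trait": spec.name, "population": popname,
                                  **part.to_dict()})
                if popname == "joint":
                    blups[spec.name] = bl
            # heterosis only where both parents carry a fitted value
            fitted = set(blups[spec.name].values.index)
            sub = pheno_plan.table[
                pheno_plan.table["female_id"].isin(fitted)
                & pheno_plan.table["male_id"].isin(fitted)
            ]
            if len(sub):
                het = midparent_heterosis(blups[spec.name], CrossPlan(sub))
                het_rows.append({
                    "trait": spec.name,
                    "median_heterosis": heterosis_median(het),
                    "n_valid": int(het["valid"].sum()),
                    "n_flagged": int((~het["valid"]).sum()),
                })
            else:
                het_rows.append({"trait": spec.name, "median_heterosis": float("nan"),
                                 "n_valid": 0, "n_flagged": 0})
        write_csv(pd.DataFrame(vc_rows), out / "variance_components.csv", seed=config.seed)
        write_csv(pd.DataFrame(part_rows), out / "variance_partition.csv", seed=config.seed)
        write_csv(pd.DataFrame(h2_rows), out / "heritability.csv", seed=config.seed)
        write_csv(pd.DataFrame(het_rows), out / "heterosis_medians.csv", seed=config.seed)
        blup_tables = pd.concat(
            [b.table().assign(trait=t) for t, b in blups.items()]
        )
        write_csv(blup_tables, out / "blups.csv", seed=config.seed, index=True)
        results["blups"] = blups
        results["heritability"] = pd.DataFrame(h2_rows)
        results["heterosis"] = pd.DataFrame(het_rows)
        results["variance_components"] = pd.DataFrame(vc_rows)

    with _Stage(manifest, "genomic_prediction"):
        inbred_geno = imputed.subset_entries(inbred_ids)
        marker_counts = [
            c for c in config.marker_counts
            if c == "all" or int(c) <= hybrids_obs.n_markers
        ]
        cv_parts = []
        for spec in config.traits:
            cfg = SchemeConfig(
                schemes=config.schemes,
                n_repetitions=config.n_repetitions,
                marker_counts=marker_counts,
                seed=config.seed + 17,
            )
            cv_parts.append(
                run_scheme(cfg, inbred_geno, hybrids_obs, blups[spec.name],
                           blups[spec.name], trait=spec.name)
            )
        cv = CVResult.concat(cv_parts)
        comparison = compare_schemes(cv)
        write_csv(cv.table, out / "cv_accuracy_long.csv", seed=config.seed)
        write_csv(cv.summary(), out / "cv_accuracy_summary.csv", seed=config.seed)
        write_csv(comparison, out / "scheme_comparison.csv", seed=config.seed)
        results["cv"], results["comparison"] = cv, comparison

    with _Stage(manifest, "exhaustive_prediction"):
        models = {}
        for spec in config.traits:
            y = blups[spec.name].mean_restored().reindex(hybrids_obs.entry_ids)
            models[spec.name] = rrblup_fit(hybrids_obs, y)
        gebv = predict_all_hybrids(models, full_plan, imputed)
        frontier = pareto_frontier(
            gebv, config.frontier_max_trait, config.frontier_min_trait
        )
        write_csv(gebv, out / "gebv_all_hybrids.csv", seed=config.seed, index=True)
        write_csv(frontier, out / "frontier.csv", seed=config.seed, index=True)
        manifest["counts"]["gebv_rows"] = len(gebv)
        manifest["counts"]["frontier_size"] = len(frontier)
        results["gebv"], results["frontier"] = gebv, frontier

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    return results
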