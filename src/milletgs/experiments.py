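"""Canned simulation experiments built from the synthetic-data generator.

These wire the generator to the prediction machinery for the recurring
validation designs: a genotyped two-pool founder set with a sampled set of
phenotyped hybrids ("prediction study"), line-mean phenotypes at a target
entry-mean heritability, and the matched hold-out-parent versus standard
cross-validation comparison. Both the test suite and the acceptance script
drive these rather than re-assembling the pieces ad hoc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CrossPlan, GenotypeMatrix
from .genomic_prediction import SchemeConfig, holdout_parent_cv, run_scheme
from .hybrid_projection import project_all
from .synthetic_data import (
    TraitArchitecture,
    combine_pools,
    simulate_founders,
    simulate_trait,
)


@dataclass
class PredictionStudy:
    """Genotypes, cross plan and phenotypes for one simulated study."""

    parents: GenotypeMatrix        # both founder pools, fully genotyped
    plan: CrossPlan                # the phenotyped subset of crosses
    full_plan: CrossPlan           # every possible B x R cross
    hybrids: GenotypeMatrix        # projected genotypes of the phenotyped hybrids
    architecture: TraitArchitecture
    true_values: pd.Series         # per entry (parents + phenotyped hybrids)
    inbred_values: pd.Series       # observed line means, parents
    hybrid_values: pd.Series       # observed line means, hybrids


def simulate_line_values(
    true_values: pd.Series, h2: float, seed: int, reference: pd.Index | None = None
) -> pd.Series:
    """Add line-mean noise so the entry-mean heritability equals ``h2``.

    The noise SD derives from the genetic variance of ``reference`` entries
    (defaults to all of them): v_e = v_g (1 - h2) / h2.
    """
    rng = np.random.default_rng(seed)
    ref = true_values if reference is None else true_values.loc[reference]
    v_g = float(ref.var())
    noise_sd = np.sqrt(v_g * (1.0 - h2) / h2) if h2 < 1 else 0.0
    return true_values + rng.normal(0.0, noise_sd, len(true_values))


def simulate_prediction_study(
    n_b: int = 40,
    n_r: int = 40,
    n_markers: int = 600,
    n_hybrids: int = 250,
    n_qtl: int = 100,
    dominance_ratio: float = 0.0,
    pool_divergence: float = 0.0,
    h2: float = 0.7,
    baseline: float = 50.0,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed: int = 0,
) -> PredictionStudy:
    """Simulate a complete two-pool prediction study.

    Founders are crossed in a full factorial; ``n_hybrids`` of the crosses
    are "phenotyped". Observed values are true genotypic values plus
    line-mean noise at entry-mean heritability ``h2`` (computed on the
    hybrid genetic variance). With ``dominance_ratio > 0`` the hybrids sit
    above the inbreds (mid-parent heterosis); with ``pool_divergence > 0``
    the pools carry opposite common alleles at a fraction of markers.
    """
    pool_b, pool_r = simulate_founders(
        n_b, n_r, n_markers, maf_low, maf_high, seed=seed,
        pool_divergence=pool_divergence,
    )
    parents = combine_pools(pool_b, pool_r)
    full_plan = CrossPlan.full_factorial(pool_b.line_ids, pool_r.line_ids)
    rng = np.random.default_rng(seed + 1)
    pick = np.sort(rng.choice(len(full_plan), size=n_hybrids, replace=False))
    plan = CrossPlan(full_plan.table.iloc[pick])
    hybrids = project_all(plan, parents)
    arch = TraitArchitecture.random(
        n_markers, n_qtl, seed=seed + 2, dominance_ratio=dominance_ratio,
        baseline=baseline, target_h2=h2,
    )
    everything = GenotypeMatrix.concat_entries(parents, hybrids)
    true_values = simulate_trait(arch, everything)
    observed = simulate_line_values(
        true_values, h2, seed=seed + 3, reference=hybrids.entry_ids
    )
    return PredictionStudy(
        parents=parents,
        plan=plan,
        full_plan=full_plan,
        hybrids=hybrids,
        architecture=arch,
        true_values=true_values,
        inbred_values=observed.loc[parents.entry_ids],
        hybrid_values=observed.loc[hybrids.entry_ids],
    )


def scheme_accuracies(
    study: PredictionStudy,
    schemes=("M1", "M2", "M3A", "M3B"),
    n_repetitions: int = 20,
    marker_counts=("all",),
    seed: int = 0,
) -> pd.DataFrame:
    """Repetition × scheme accuracy table for a simulated study."""
    cfg = SchemeConfig(
        schemes=schemes, n_repetitions=n_repetitions,
        marker_counts=marker_counts, seed=seed,
    )
    cv = run_scheme(
        cfg, study.parents, study.hybrids, study.inbred_values, study.hybrid_values
    )
    return cv.accuracies().pivot_table(
        index="repetition", columns="scheme", values="accuracy", aggfunc="mean"
    )


def heritability_recovery(
    n_seeds: int = 20,
    n_entries: int = 299,
    n_locations: int = 4,
    n_reps: int = 2,
    block_size: int = 15,
    v_g: float = 1.0,
    v_l: float = 0.5,
    v_gxl: float = 0.24,
    v_rep: float = 0.1,
    v_block: float = 0.1,
    v_resid: float = 0.611,
    seed: int = 0,
) -> pd.Series:
    """Entry-mean heritability estimates over repeated simulated trials.

    Each replicate simulates a trial with the given true variance components
    (the defaults put the entry-mean heritability at
    v_g / (v_g + v_gxl/4 + v_resid/8) = 0.88 for 4 locations x 2 reps),
    fits the all-random model by REML and evaluates the heritability
    formula. Returns one estimate per seed.
    """
    from .mixed_models import (
        HeritabilityInput,
        fit_random_model,
        heritability,
    )
    from .synthetic_data import simulate_field_book

    out = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 10_000 + s)
        entries = [f"E{i:03d}" for i in range(n_entries)] + ["C1", "C2"]
        true_g = pd.Series(
            rng.normal(50.0, np.sqrt(v_g), len(entries)), index=entries, name="y"
        )
        arch = TraitArchitecture(
            qtl_indices=[0], additive_effects=[0.0], dominance_effects=[0.0],
            loc_sd=np.sqrt(v_l), gxe_sd=np.sqrt(v_gxl), rep_sd=np.sqrt(v_rep),
            block_sd=np.sqrt(v_block), resid_sd=np.sqrt(v_resid),
        )
        book = simulate_field_book(
            true_g, n_locations, n_reps, block_size, arch,
            controls=["C1", "C2"], seed=seed + 20_000 + s,
        )
        vc, _, _ = fit_random_model(book, "y")
        out.append(heritability(vc, HeritabilityInput(n_locations, n_reps)))
    return pd.Series(out, name="H2")


def permuted_null_accuracies(
    study: PredictionStudy,
    schemes=("M1", "M2", "M3A", "M3B"),
    n_repetitions: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Null distribution of scheme accuracies under a permuted trait.

    Each repetition permutes the trait values afresh (breaking any
    genotype-phenotype association, including the chance alignment a single
    fixed permutation would retain with the family structure) and runs one
    round of five-fold cross-validation per scheme.
    """
    rows = []
    for rep in range(n_repetitions):
        rng = np.random.default_rng(seed + 500 + rep)
        hy = pd.Series(
            rng.permutation(study.hybrid_values.to_numpy()),
            index=study.hybrid_values.index,
        )
        iy = pd.Series(
            rng.permutation(study.inbred_values.to_numpy()),
            index=study.inbred_values.index,
        )
        cfg = SchemeConfig(
            schemes=schemes, n_repetitions=1, marker_counts=("all",),
            seed=seed + 900 + rep,
        )
        cv = run_scheme(cfg, study.parents, study.hybrids, iy, hy)
        acc = cv.accuracies().set_index("scheme")["accuracy"]
        rows.append(acc.rename(rep))
    return pd.DataFrame(rows)


def holdout_vs_standard(
    study: PredictionStudy,
    n_pairs: int = 12,
    n_repetitions: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Matched comparison of hold-out-parent CV against standard M2 CV.

    For each of ``n_pairs`` randomly drawn (B-line, R-line) pairs, runs the
    hold-out-parent validation and a standard M2 run with the same seed;
    returns one row per pair with both mean accuracies.
    """
    rng = np.random.default_rng(seed)
    b_parents = sorted(set(study.plan.table["female_id"]))
    r_parents = sorted(set(study.plan.table["male_id"]))
    rows = []
    for i in range(n_pairs):
        b = b_parents[rng.integers(len(b_parents))]
        r = r_parents[rng.integers(len(r_parents))]
        cfg = SchemeConfig(
            schemes=("M2",), n_repetitions=n_repetitions,
            marker_counts=("all",), seed=seed + 100 + i,
        )
        ho = holdout_parent_cv(
            cfg, study.hybrids, study.hybrid_values, study.plan, b, r
        )
        m2 = run_scheme(cfg, None, study.hybrids, None, study.hybrid_values)
        rows.append(
            {
                "b_line": b,
                "r_line": r,
                "holdout": float(ho.accuracies()["accuracy"].mean()),
                "m2": float(m2.accuracies()["accuracy"].mean()),
            }
        )
    return pd.DataFrame(rows)
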