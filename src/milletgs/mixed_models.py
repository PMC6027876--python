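"""Phenotype analysis: all-random mixed model, heritability and heterosis.

Plot-level trait records are fit with genotype (G), location (L), their
interaction (G×L), replicate (R) and block (B) all treated as random
effects. REML variance components feed the broad-sense heritability on an
entry-mean basis,

    H2 = VG / (VG + VGxL / NL + Ve / (NR * NL)),

with NL locations and NR replicates; location, replicate and block variance
do not enter the formula. Genotype BLUPs (plus the fitted grand mean) feed
mid-parent heterosis, (Y_hybrid - MP) / MP with MP = (Y_female + Y_male)/2,
and the population-centred values used by the M3B prediction scheme.

Replicates and blocks are coded nested within location by default
(replicate:location, block:replicate:location); a flat coding is available
since the factor list could equally be read unnested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CrossPlan, population_of
from .errors import ModelError
from .reml import RandomTerm, REMLResult, reml_fit


@dataclass
class HeritabilityInput:
    """Trial dimensions entering the heritability denominator."""

    n_locations: int
    n_reps: int

    def __post_init__(self) -> None:
        if self.n_locations < 1 or self.n_reps < 1:
            raise ModelError("n_locations and n_reps must be >= 1")


@dataclass
class VarianceComponents:
    """REML variance estimates for one trait (all nonnegative)."""

    v_g: float
    v_l: float
    v_gxl: float
    v_rep: float
    v_block: float
    v_resid: float
    trait: str = ""

    def residual_bucket(self) -> float:
        """Residual including replicate and block variance, the bucket used
        in variance-partition reporting."""
        return self.v_resid + self.v_rep + self.v_block

    def partition(self) -> pd.Series:
        """Proportions of total variance: G, L, G×L, residual-incl-rep/block."""
        total = self.v_g + self.v_l + self.v_gxl + self.residual_bucket()
        return pd.Series(
            {
                "genotype": self.v_g / total,
                "location": self.v_l / total,
                "gxl": self.v_gxl / total,
                "residual": self.residual_bucket() / total,
            },
            name=self.trait,
        )


@dataclass
class TraitBLUPs:
    """Per-entry genotype BLUPs for one trait.

    ``values`` are the zero-centred random-effect solutions; add
    ``grand_mean`` to put them back on the observed trait scale
    (``mean_restored``). ``population`` labels each entry inbred / hybrid
    (controls keep their own label).
    """

    trait: str
    values: pd.Series
    population: pd.Series
    grand_mean: float

    def mean_restored(self) -> pd.Series:
        return self.values + self.grand_mean

    def population_means(self, restored: bool = True) -> pd.Series:
        vals = self.mean_restored() if restored else self.values
        return vals.groupby(self.population).mean()

    def entries(self, population: str) -> pd.Index:
        return self.values.index[self.population == population]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population": self.population,
                "blup": self.values,
                "mean_restored_value": self.mean_restored(),
            }
        ).rename_axis("entry_id")


def _term_labels(book: pd.DataFrame, nesting: str):
    loc = book["location"].astype(str)
    rep = book["replicate"].astype(str)
    blk = book["block"].astype(str)
    if nesting == "nested":
        rep_lab = loc + ":" + rep
        blk_lab = loc + ":" + rep + ":" + blk
    elif nesting == "flat":
        rep_lab, blk_lab = rep, blk
    else:
        raise ModelError(f"unknown nesting mode: {nesting!r}")
    ent = book["entry_id"].astype(str)
    return {
        "genotype": ent,
        "location": loc,
        "gxl": ent + "@" + loc,
        "rep": rep_lab,
        "block": blk_lab,
    }


def fit_random_model(
    book: pd.DataFrame,
    trait: str,
    nesting: str = "nested",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[VarianceComponents, TraitBLUPs, REMLResult]:
    """REML fit of the all-random plot model for one trait.

    Rows with a missing trait value are dropped. Requires at least two
    locations and a replicated set of entries; degenerate designs raise
    :class:`ModelError` with a diagnostic.
    """
    if trait not in book.columns:
        raise ModelError(f"trait {trait!r} not in field book")
    data = book.loc[book[trait].notna()].reset_index(drop=True)
    if data["location"].nunique() < 2:
        raise ModelError("need >= 2 locations for the G, L, GxL decomposition")
    if data["entry_id"].nunique() < 2:
        raise ModelError("need >= 2 entries")
    if len(data) <= data["entry_id"].nunique():
        raise ModelError("entries are unreplicated; variance components unidentifiable")

    labels = _term_labels(data, nesting)
    terms = [RandomTerm.from_labels(name, lab) for name, lab in labels.items()]
    res = reml_fit(data[trait].to_numpy(), terms, tol=tol, max_iter=max_iter)

    vc = VarianceComponents(
        v_g=res.sigma2["genotype"],
        v_l=res.sigma2["location"],
        v_gxl=res.sigma2["gxl"],
        v_rep=res.sigma2["rep"],
        v_block=res.sigma2["block"],
        v_resid=res.sigma2["residual"],
        trait=trait,
    )
    gterm = next(t for t in res.terms if t.name == "genotype")
    values = pd.Series(res.u["genotype"], index=pd.Index(gterm.levels, name="entry_id"),
                       name=trait)
    etype = (
        data.drop_duplicates("entry_id").set_index("entry_id")["entry_type"].astype(str)
    )
    population = etype.reindex(values.index).map(population_of)
    blups = TraitBLUPs(trait, values, population, grand_mean=res.mu)
    return vc, blups, res


def heritability(vc: VarianceComponents, design: HeritabilityInput) -> float:
    """Broad-sense heritability on an entry-mean basis; NaN when all three
    entering components are zero."""
    denom = vc.v_g + vc.v_gxl / design.n_locations + vc.v_resid / (
        design.n_reps * design.n_locations
    )
    if denom <= 0:
        return float("nan")
    return vc.v_g / denom


def midparent_heterosis(
    blups: TraitBLUPs, plan: CrossPlan, mode: str = "mean_restored"
) -> pd.DataFrame:
    """Per-hybrid mid-parent heterosis from fitted trait values.

    ``mode='mean_restored'`` (default) evaluates the ratio on grand-mean-
    restored values, since a ratio of zero-centred BLUPs is ill-defined;
    ``mode='blup'`` uses the raw BLUPs for sign/robustness checks. Hybrids
    whose mid-parent value is <= 0 on the evaluated scale are flagged
    (``valid=False``) and should be excluded from summary medians.
    """
    if mode == "mean_restored":
        vals = blups.mean_restored()
    elif mode == "blup":
        vals = blups.values
    else:
        raise ModelError(f"unknown heterosis mode: {mode!r}")
    missing = [
        h for cols in ("hybrid_id", "female_id", "male_id")
        for h in plan.table[cols] if h not in vals.index
    ]
    if missing:
        raise ModelError(f"no fitted value for: {sorted(set(missing))[:5]}")
    hyb = vals.loc[plan.table["hybrid_id"]].to_numpy()
    mid = (
        vals.loc[plan.table["female_id"]].to_numpy()
        + vals.loc[plan.table["male_id"]].to_numpy()
    ) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        het = (hyb - mid) / mid
    return pd.DataFrame(
        {"heterosis": het, "mid_parent": mid, "valid": mid > 0},
        index=pd.Index(plan.table["hybrid_id"], name="hybrid_id"),
    )


def heterosis_median(het: pd.DataFrame) -> float:
    """Median heterosis over hybrids with a valid (positive) mid-parent."""
    valid = het.loc[het["valid"], "heterosis"]
    return float(valid.median()) if len(valid) else float("nan")


def center_by_population(blups: TraitBLUPs) -> TraitBLUPs:
    """Express each entry's value as a deviation from its own population mean
    (the M3B normalisation). Both population means are 0 afterwards."""
    pops = blups.population
    if pops.nunique() < 1 or pops.isna().any():
        raise ModelError("every entry needs a population label")
    restored = blups.mean_restored()
    centred = restored - restored.groupby(pops).transform("mean")
    return TraitBLUPs(blups.trait, centred, pops.copy(), grand_mean=0.0)
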