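"""Synthetic genotypes, crosses, trait architectures and field books.

This module generates data with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable without external
downloads. It emulates a CMS-based hybrid breeding study: two pools of fully
inbred parents (B-lines used as females, R-lines as pollinators), a factorial
cross plan, traits with additive + dominance architecture (dominance is the
knob that produces mid-parent heterosis), and multi-location replicated
alpha-lattice field trials with repeated control entries in every incomplete
block.

Field-trial structure emulated: 4 locations × 2 replicates, 15-plot blocks
each holding 2 common controls and 13 experimental entries; plot values are
the entry's true genotypic value plus location, G×L, replicate, block and
residual effects, each drawn from a zero-mean normal with its configured SD.
The incomplete blocking is a random assignment of entries to blocks within a
replicate — the downstream model consumes only the factor labels, not the
generating design. Replicates and blocks are nested within location by
default (a ``nested`` switch gives flat coding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CrossPlan, GenotypeMatrix
from .errors import DataError, LayoutError, ParameterError

#: number of chromosomes used for synthetic marker coordinates (pearl millet has 7)
N_CHROMOSOMES = 7


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass
class FounderPool:
    """A pool of fully inbred lines (dosages in {0, 2}) with its sampled
    per-marker alternate-allele frequencies."""

    pool_label: str  # "B" or "R"
    genotypes: GenotypeMatrix
    allele_freqs: np.ndarray

    @property
    def n_lines(self) -> int:
        return self.genotypes.n_entries

    @property
    def line_ids(self) -> pd.Index:
        return self.genotypes.entry_ids


def _marker_metadata(n_markers: int) -> pd.DataFrame:
    chrom = (np.arange(n_markers) % N_CHROMOSOMES) + 1
    pos = (np.arange(n_markers) // N_CHROMOSOMES + 1) * 1000
    mid = [f"S{c}_{p}" for c, p in zip(chrom, pos)]
    return pd.DataFrame(
        {"chrom": chrom.astype(str), "pos": pos, "ref": "A", "alt": "T",
         "n_alleles": 2},
        index=pd.Index(mid, name="marker_id"),
    )


def simulate_founders(
    n_b: int,
    n_r: int,
    n_markers: int,
    maf_low: float,
    maf_high: float,
    seed: int,
    pool_divergence: float = 0.0,
) -> tuple[FounderPool, FounderPool]:
    """Simulate two pools of fully inbred founder lines.

    Each pool draws its own per-marker alternate-allele frequency uniformly in
    [maf_low, maf_high]; each line then receives a homozygous dosage (0 or 2)
    by a single Bernoulli draw per marker. ``pool_divergence`` is the fraction
    of markers at which the common allele is flipped between the pools
    (frequency p in the B pool vs 1−p in the R pool), modelling strongly
    differentiated heterotic pools; 0 leaves the pools exchangeable.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ParameterError("require 0 < maf_low <= maf_high <= 0.5")
    if min(n_b, n_r, n_markers) <= 0:
        raise ParameterError("counts must be positive")
    if not (0 <= pool_divergence <= 1):
        raise ParameterError("pool_divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    markers = _marker_metadata(n_markers)

    freq_b = rng.uniform(maf_low, maf_high, size=n_markers)
    freq_r = rng.uniform(maf_low, maf_high, size=n_markers)
    flipped = rng.random(n_markers) < pool_divergence
    freq_r = np.where(flipped, 1.0 - freq_r, freq_r)

    pools = []
    for label, n, freq in (("B", n_b, freq_b), ("R", n_r, freq_r)):
        draws = rng.random((n, n_markers)) < freq
        dosages = pd.DataFrame(
            np.where(draws, 2.0, 0.0),
            index=pd.Index([f"{label}{i + 1:03d}" for i in range(n)], name="entry_id"),
            columns=markers.index,
        )
        entries = pd.DataFrame({"entry_type": f"inbred_{label}"}, index=dosages.index)
        pools.append(FounderPool(label, GenotypeMatrix(dosages, markers.copy(), entries), freq))
    return pools[0], pools[1]


def combine_pools(pool_b: FounderPool, pool_r: FounderPool) -> GenotypeMatrix:
    """Stack both founder pools into a single parent genotype matrix."""
    return GenotypeMatrix.concat_entries(pool_b.genotypes, pool_r.genotypes)


def add_missingness(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Mask a random fraction of calls as missing (emulates GBS sparsity)."""
    if not (0 <= rate < 1):
        raise ParameterError("missing rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    vals = gm.values().copy()
    vals[rng.random(vals.shape) < rate] = np.nan
    return GenotypeMatrix(
        pd.DataFrame(vals, index=gm.entry_ids, columns=gm.marker_ids),
        gm.markers.copy(),
        gm.entries.copy(),
    )


# ---------------------------------------------------------------------------
# trait architecture and true genotypic values
# ---------------------------------------------------------------------------

@dataclass
class TraitArchitecture:
    """Additive + dominance QTL architecture plus field-trial noise SDs.

    The genotypic value of an entry is
    ``baseline + Σ_j a_j (x_j − 1) + d_j · 1[x_j == 1]`` over the QTL;
    fully inbred lines (dosages 0/2) receive no dominance contribution, so a
    positive ``dominance_effects`` vector is what creates mid-parent
    heterosis in the simulated hybrids. The SD fields parameterise the field
    book: location, G×L, replicate, block and residual effects. Units are
    abstract (no attempt to mimic kg/ha magnitudes).
    """

    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    target_h2: float = 0.8
    baseline: float = 0.0
    loc_sd: float = 0.0
    gxe_sd: float = 0.0
    rep_sd: float = 0.0
    block_sd: float = 0.0
    resid_sd: float = 0.0

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.additive_effects = np.asarray(self.additive_effects, dtype=float)
        self.dominance_effects = np.asarray(self.dominance_effects, dtype=float)
        if len(np.unique(self.qtl_indices)) != len(self.qtl_indices):
            raise ParameterError("qtl_indices must be distinct")
        n = len(self.qtl_indices)
        if len(self.additive_effects) != n or len(self.dominance_effects) != n:
            raise ParameterError("effect vectors must match qtl_indices length")
        if not (0 < self.target_h2 <= 1):
            raise ParameterError("target_h2 must be in (0, 1]")
        for name in ("loc_sd", "gxe_sd", "rep_sd", "block_sd", "resid_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_indices)

    @classmethod
    def random(
        cls,
        n_markers: int,
        n_qtl: int,
        seed: int,
        dominance_ratio: float = 0.0,
        **kwargs,
    ) -> "TraitArchitecture":
        """Sample an architecture: additive effects ~ N(0,1), dominance effects
        directional, ``d_j = dominance_ratio · |a_j|`` (1.0 = complete
        dominance at every QTL)."""
        rng = np.random.default_rng(seed)
        if n_qtl > n_markers:
            raise ParameterError("n_qtl exceeds n_markers")
        idx = rng.choice(n_markers, size=n_qtl, replace=False)
        a = rng.normal(0.0, 1.0, size=n_qtl)
        d = dominance_ratio * np.abs(a)
        return cls(idx, a, d, **kwargs)


def simulate_trait(architecture: TraitArchitecture, genotypes: GenotypeMatrix) -> pd.Series:
    """True genotypic value per entry under the architecture (deterministic).

    value = baseline + Σ a·(x−1) + d·1[x == 1]; dosage-1 heterozygotes are
    the only carriers of dominance deviations.
    """
    if architecture.qtl_indices.max(initial=-1) >= genotypes.n_markers:
        raise ParameterError("qtl_indices outside marker range")
    X = genotypes.values()[:, architecture.qtl_indices]
    if np.isnan(X).any():
        raise DataError("missing genotype calls at QTL markers")
    additive = (X - 1.0) @ architecture.additive_effects
    dominance = (X == 1.0) @ architecture.dominance_effects
    return pd.Series(
        architecture.baseline + additive + dominance,
        index=genotypes.entry_ids,
        name="true_value",
    )


def midparent_heterosis_true(
    values: pd.Series, plan: CrossPlan
) -> pd.Series:
    """Mid-parent heterosis fraction on true values, (H − MP)/MP per hybrid.

    Convenience for generator-level checks; the estimation-side version
    operating on fitted BLUPs lives in :mod:`milletgs.mixed_models`.
    """
    fem = values.loc[plan.table["female_id"]].to_numpy()
    mal = values.loc[plan.table["male_id"]].to_numpy()
    hyb = values.loc[plan.table["hybrid_id"]].to_numpy()
    mid = (fem + mal) / 2.0
    return pd.Series((hyb - mid) / mid, index=plan.hybrid_ids, name="heterosis")


# ---------------------------------------------------------------------------
# field book
# ---------------------------------------------------------------------------

def simulate_field_book(
    true_values: pd.Series | pd.DataFrame,
    n_locations: int,
    n_reps: int,
    block_size: int,
    architecture: TraitArchitecture | dict,
    controls: Sequence[str],
    seed: int,
    entry_types: pd.Series | None = None,
    segregate_populations: bool = False,
) -> pd.DataFrame:
    """Simulate plot-level records for a replicated multi-location trial.

    Every block holds every control plus ``block_size − len(controls)``
    experimental entries; every non-control entry appears exactly once per
    replicate per location. ``true_values`` may be a Series (one trait) or a
    DataFrame (one column per trait), in which case ``architecture`` is a
    dict mapping trait name → TraitArchitecture and all traits share the
    same field layout with independent noise draws.

    With ``segregate_populations`` hybrids are assigned to the leading blocks
    of each replicate and inbreds to the trailing blocks, mimicking trials
    where the two populations are not interleaved.
    """
    if isinstance(true_values, pd.Series):
        name = true_values.name if true_values.name not in (None, "true_value") else "trait"
        true_values = true_values.to_frame(name)
        architecture = {name: architecture}
    if not isinstance(architecture, dict):
        raise ParameterError("architecture must be a dict when multiple traits are given")

    controls = list(controls)
    missing_controls = [c for c in controls if c not in true_values.index]
    if missing_controls:
        raise DataError(f"controls lack true values: {missing_controls}")
    n_exp_per_block = block_size - len(controls)
    if n_exp_per_block < 1:
        raise LayoutError("block_size leaves no room for experimental entries")
    experimental = [e for e in true_values.index if e not in controls]
    if len(experimental) % n_exp_per_block != 0:
        raise LayoutError(
            f"{len(experimental)} experimental entries cannot be divided into "
            f"blocks of {n_exp_per_block} (block_size {block_size} minus "
            f"{len(controls)} controls); adjust entry count or block size"
        )
    n_blocks = len(experimental) // n_exp_per_block

    if entry_types is None:
        entry_types = pd.Series("hybrid", index=true_values.index)
    entry_types = entry_types.reindex(true_values.index).fillna("hybrid")

    rng = np.random.default_rng(seed)
    traits = list(true_values.columns)
    locations = [f"loc{i + 1}" for i in range(n_locations)]
    entry_pos = {e: i for i, e in enumerate(true_values.index)}

    # random effects shared across plots, drawn once per trait
    eff = {}
    for t in traits:
        arch = architecture[t]
        eff[t] = {
            "loc": rng.normal(0, arch.loc_sd, size=n_locations),
            "gxe": rng.normal(0, arch.gxe_sd, size=(len(true_values), n_locations)),
            "rep": rng.normal(0, arch.rep_sd, size=(n_locations, n_reps)),
            "block": rng.normal(0, arch.block_sd, size=(n_locations, n_reps, n_blocks)),
        }

    if segregate_populations:
        hybrids = [e for e in experimental if entry_types[e] == "hybrid"]
        inbreds = [e for e in experimental if entry_types[e] != "hybrid"]
    rows = []
    for li, loc in enumerate(locations):
        for rep in range(n_reps):
            if segregate_populations:
                order = list(rng.permutation(hybrids)) + list(rng.permutation(inbreds))
            else:
                order = list(rng.permutation(experimental))
            plot = 0
            for b in range(n_blocks):
                members = controls + order[b * n_exp_per_block:(b + 1) * n_exp_per_block]
                for entry in members:
                    plot += 1
                    row = {
                        "location": loc,
                        "replicate": f"rep{rep + 1}",
                        "block": f"block{b + 1}",
                        "plot": plot,
                        "entry_id": entry,
                        "entry_type": entry_types[entry],
                    }
                    for t in traits:
                        arch = architecture[t]
                        e = eff[t]
                        row[t] = (
                            true_values.loc[entry, t]
                            + e["loc"][li]
                            + e["gxe"][entry_pos[entry], li]
                            + e["rep"][li, rep]
                            + e["block"][li, rep, b]
                            + rng.normal(0, arch.resid_sd)
                        )
                    rows.append(row)
    return pd.DataFrame(rows)
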