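"""Genotype calling from allele depths, per-marker QC statistics and filters.

Calling thresholds (applied to per-sample read counts at a site):

* homozygous — site covered by >= 5 reads and the top allele has frequency
  strictly > 0.9;
* heterozygous — site covered by >= 5 reads, the two most frequent alleles
  jointly account for >= 90% of reads, each of the two has >= 2 reads, and
  each has frequency strictly > 0.2;
* anything else is missing (missing is a value, not an error).

Marker filters retain sites that are biallelic, polymorphic (>= 2 observed
genotype classes), have a heterozygote proportion among called samples
<= 0.10, a minor allele observed (het or hom-minor) in >= 5 samples, and a
call rate >= 0.20. Boundary semantics are literal readings of each rule and
are unit-tested. MAF is computed over non-missing calls only:
(2 × hom-minor + het) / (2 × called).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import CoordinateError, DataError

MIN_DEPTH = 5
HOM_FREQ = 0.9          # top-allele frequency must exceed this (strict)
HET_TOP2_FRAC = 0.9     # top-two alleles must jointly reach this (>=)
HET_MIN_READS = 2       # each of the top-two alleles needs this many reads (>=)
HET_MIN_FREQ = 0.2      # each of the top-two alleles must exceed this (strict)

MAX_HET_RATE = 0.10     # filter: exclude only when strictly above
MIN_MINOR_SAMPLES = 5   # filter: minor allele carriers required (>=)
MIN_CALL_RATE = 0.20    # filter: exclude strictly below


@dataclass(frozen=True)
class GenotypeCall:
    """A genotype call: ``kind`` is 'hom' or 'het'; ``alleles`` the allele
    pair (identical for homozygotes), sorted for order independence."""

    kind: str
    alleles: tuple[str, str]


def call_genotype(allele_counts: Mapping[str, int], min_depth: int = MIN_DEPTH):
    """Call one sample at one site from its per-allele read counts.

    Returns a :class:`GenotypeCall` or ``None`` for missing. The call is
    invariant to the ordering of alleles in the mapping; ties in read counts
    are broken by allele name for determinism (the thresholds make the call
    itself order-independent).
    """
    counts = {a: int(c) for a, c in allele_counts.items() if c > 0}
    if any(c < 0 for c in allele_counts.values()):
        raise DataError("negative read count")
    total = sum(counts.values())
    if total < min_depth:
        return None
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_allele, top_count = ranked[0]
    if top_count / total > HOM_FREQ:
        return GenotypeCall("hom", (top_allele, top_allele))
    if len(ranked) >= 2:
        (a1, c1), (a2, c2) = ranked[0], ranked[1]
        if (
            (c1 + c2) / total >= HET_TOP2_FRAC
            and c1 >= HET_MIN_READS
            and c2 >= HET_MIN_READS
            and c1 / total > HET_MIN_FREQ
            and c2 / total > HET_MIN_FREQ
        ):
            return GenotypeCall("het", tuple(sorted((a1, a2))))
    return None


def call_genotypes(
    depths: pd.DataFrame, min_depth: int = MIN_DEPTH, entry_type: str = "hybrid"
) -> GenotypeMatrix:
    """Call every (sample, site) cell of a long allele-depth table.

    ``depths`` columns: sample, chrom, pos, allele, count. The site's
    reference allele is the overall most-read allele, the alternate the
    second; calls involving any further allele are recorded as missing and
    the site's ``n_alleles`` metadata counts every allele seen in a call, so
    the multi-allelic filter rule can act on it.
    """
    required = {"sample", "chrom", "pos", "allele", "count"}
    if missing := required.difference(depths.columns):
        raise DataError(f"allele-depth table missing columns: {sorted(missing)}")
    samples = pd.Index(sorted(depths["sample"].unique()), name="entry_id")
    cols, meta = {}, []
    for (chrom, pos), site in depths.groupby(["chrom", "pos"], sort=True):
        calls = {}
        for sample, rows in site.groupby("sample"):
            calls[sample] = call_genotype(
                dict(zip(rows["allele"], rows["count"])), min_depth=min_depth
            )
        called_alleles = sorted(
            {a for c in calls.values() if c is not None for a in c.alleles}
        )
        site_totals = site.groupby("allele")["count"].sum().sort_values(ascending=False)
        ref = site_totals.index[0]
        alts = [a for a in site_totals.index if a != ref]
        alt = alts[0] if alts else "."
        dosage_of = {
            ("hom", (ref, ref)): 0.0,
            ("het", tuple(sorted((ref, alt)))): 1.0,
            ("hom", (alt, alt)): 2.0,
        }
        col = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            c = calls.get(s)
            if c is not None:
                col[i] = dosage_of.get((c.kind, c.alleles), np.nan)
        mid = f"S{chrom}_{pos}"
        meta.append((mid, str(chrom), int(pos), ref, alt, max(len(called_alleles), 2)))
        cols[mid] = col
    markers = pd.DataFrame(
        meta, columns=["marker_id", "chrom", "pos", "ref", "alt", "n_alleles"]
    ).set_index("marker_id")
    dosages = pd.DataFrame(cols, index=samples)
    entries = pd.DataFrame({"entry_type": entry_type}, index=samples)
    return GenotypeMatrix(dosages, markers, entries)


# ---------------------------------------------------------------------------
# per-marker statistics
# ---------------------------------------------------------------------------

def marker_stats(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """missing_rate, het_rate and MAF per marker.

    missing_rate = missing samples / total samples;
    het_rate = het calls / called samples;
    maf = (2·hom-minor + het) / (2·called). All-missing markers report NaN.
    Requires integer dosages (pre-projection matrices).
    """
    vals = genotypes.values()
    with np.errstate(invalid="ignore"):
        if not np.all(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))):
            raise DataError("marker_stats requires integer dosage calls")
    n = vals.shape[0]
    n_missing = np.isnan(vals).sum(axis=0)
    n_called = n - n_missing
    n_het = np.nansum(vals == 1.0, axis=0)
    n_alt_hom = np.nansum(vals == 2.0, axis=0)
    n_ref_hom = n_called - n_het - n_alt_hom
    alt_copies = 2 * n_alt_hom + n_het
    ref_copies = 2 * n_ref_hom + n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        missing_rate = n_missing / n
        het_rate = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
        maf = np.where(
            n_called > 0,
            np.minimum(alt_copies, ref_copies) / np.maximum(2 * n_called, 1),
            np.nan,
        )
    return pd.DataFrame(
        {
            "missing_rate": missing_rate,
            "het_rate": het_rate,
            "maf": maf,
            "n_called": n_called,
            "n_het": n_het,
            "n_hom_ref": n_ref_hom,
            "n_hom_alt": n_alt_hom,
        },
        index=genotypes.marker_ids,
    )


def _minor_allele_samples(stats: pd.DataFrame) -> np.ndarray:
    """Samples carrying the minor allele (hom-minor or het) per marker.

    The minor allele is the one with fewer copies; on a copy tie the allele
    with fewer carrier samples is taken (conservative for the >= 5 rule), and
    on a full tie the alternate allele.
    """
    alt_copies = 2 * stats["n_hom_alt"] + stats["n_het"]
    ref_copies = 2 * stats["n_hom_ref"] + stats["n_het"]
    alt_carriers = stats["n_hom_alt"] + stats["n_het"]
    ref_carriers = stats["n_hom_ref"] + stats["n_het"]
    alt_minor = (alt_copies < ref_copies) | (
        (alt_copies == ref_copies) & (alt_carriers <= ref_carriers)
    )
    return np.where(alt_minor, alt_carriers, ref_carriers)


FILTER_RULES = (
    "multi_allelic",
    "monomorphic",
    "excess_heterozygosity",
    "rare_minor_allele",
    "low_call_rate",
)


def filter_markers(
    genotypes: GenotypeMatrix,
    max_het_rate: float = MAX_HET_RATE,
    min_minor_samples: int = MIN_MINOR_SAMPLES,
    min_call_rate: float = MIN_CALL_RATE,
) -> tuple[GenotypeMatrix, pd.Series]:
    """Apply the marker QC rules; returns (filtered matrix, exclusion tally).

    The tally counts, per rule, how many markers fail it (rules are assessed
    independently, so one marker may be counted under several) plus the total
    number excluded.
    """
    stats = marker_stats(genotypes)
    if "n_alleles" in genotypes.markers.columns:
        biallelic = genotypes.markers["n_alleles"].to_numpy() <= 2
    else:
        biallelic = np.ones(genotypes.n_markers, dtype=bool)
    classes = (
        (stats[["n_hom_ref", "n_het", "n_hom_alt"]] > 0).sum(axis=1).to_numpy()
    )
    polymorphic = classes >= 2
    # integer counts avoid floating-point trouble at the exact boundaries
    het_ok = ~(
        stats["n_het"].to_numpy()
        > max_het_rate * stats["n_called"].to_numpy() + 1e-9
    )
    minor_ok = _minor_allele_samples(stats) >= min_minor_samples
    call_ok = stats["n_called"].to_numpy() + 1e-9 >= min_call_rate * genotypes.n_entries
    keep = biallelic & polymorphic & het_ok & minor_ok & call_ok
    tally = pd.Series(
        {
            "multi_allelic": int((~biallelic).sum()),
            "monomorphic": int((~polymorphic).sum()),
            "excess_heterozygosity": int((~het_ok).sum()),
            "rare_minor_allele": int((~minor_ok).sum()),
            "low_call_rate": int((~call_ok).sum()),
            "total_excluded": int((~keep).sum()),
            "retained": int(keep.sum()),
        },
        name="n_markers",
    )
    return genotypes.subset_markers(genotypes.marker_ids[keep]), tally


def maf_filter(genotypes: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain markers with MAF strictly larger than ``threshold``."""
    maf = marker_stats(genotypes)["maf"].to_numpy()
    keep = maf > threshold  # NaN compares False: all-missing markers drop
    return genotypes.subset_markers(genotypes.marker_ids[keep])


# ---------------------------------------------------------------------------
# imputation stand-in
# ---------------------------------------------------------------------------

def impute_naive(
    genotypes: GenotypeMatrix, seed: int, method: str = "sample"
) -> GenotypeMatrix:
    """Fill missing calls marker-by-marker — a deliberately naive stand-in
    for haplotype-based imputation (Beagle-class tools are out of scope).

    ``method='sample'`` draws each missing call from the marker's observed
    genotype-class frequencies (seeded); ``method='mode'`` uses the most
    frequent class (ties to the lower dosage). Never introduces a genotype
    class absent from the observed calls.
    """
    if method not in ("sample", "mode"):
        raise DataError(f"unknown imputation method: {method}")
    rng = np.random.default_rng(seed)
    vals = genotypes.values().copy()
    for j in range(vals.shape[1]):
        col = vals[:, j]
        miss = np.isnan(col)
        if not miss.any():
            continue
        observed = col[~miss]
        if observed.size == 0:
            raise DataError(
                f"marker {genotypes.marker_ids[j]} is entirely missing; "
                "filter before imputing"
            )
        classes, counts = np.unique(observed, return_counts=True)
        if method == "sample":
            col[miss] = rng.choice(classes, size=miss.sum(), p=counts / counts.sum())
        else:
            col[miss] = classes[np.argmax(counts)]
    return GenotypeMatrix(
        pd.DataFrame(vals, index=genotypes.entry_ids, columns=genotypes.marker_ids),
        genotypes.markers.copy(),
        genotypes.entries.copy(),
    )


# ---------------------------------------------------------------------------
# cross-platform overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Markers shared between two genotyping platforms and their call
    concordance on shared samples."""

    n_overlap: int
    shared_positions: pd.DataFrame  # chrom, pos, marker_id_a, marker_id_b
    n_shared_samples: int
    concordance: float  # fraction of doubly-called shared cells that agree

def platform_overlap(set_a: GenotypeMatrix, set_b: GenotypeMatrix) -> OverlapReport:
    """Match two marker sets on (chromosome, position) and compare calls.

    Raises :class:`CoordinateError` when the chromosome naming conventions
    are incompatible (e.g. 'chr1' vs '1'), which would silently yield an
    empty overlap.
    """
    chroms_a = set(set_a.markers["chrom"].astype(str))
    chroms_b = set(set_b.markers["chrom"].astype(str))

    def _norm(c: str) -> str:
        return c.lower().removeprefix("chr")

    if chroms_a and chroms_b and not (chroms_a & chroms_b):
        if {_norm(c) for c in chroms_a} & {_norm(c) for c in chroms_b}:
            raise CoordinateError(
                "chromosome names differ only by naming convention "
                "(e.g. 'chr1' vs '1'); harmonise before comparing"
            )
    key_a = set_a.markers.reset_index().set_index(["chrom", "pos"])["marker_id"]
    key_b = set_b.markers.reset_index().set_index(["chrom", "pos"])["marker_id"]
    shared = key_a.index.intersection(key_b.index)
    table = pd.DataFrame(
        {
            "chrom": [c for c, _ in shared],
            "pos": [p for _, p in shared],
            "marker_id_a": key_a.loc[shared].to_numpy(),
            "marker_id_b": key_b.loc[shared].to_numpy(),
        }
    )
    samples = set_a.entry_ids.intersection(set_b.entry_ids)
    concordance = float("nan")
    if len(shared) and len(samples):
        va = set_a.dosages.loc[samples, table["marker_id_a"]].to_numpy()
        vb = set_b.dosages.loc[samples, table["marker_id_b"]].to_numpy()
        both = ~np.isnan(va) & ~np.isnan(vb)
        if both.any():
            concordance = float((va[both] == vb[both]).mean())
    return OverlapReport(len(shared), table, len(samples), concordance)
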