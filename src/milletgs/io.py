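"""Readers and writers for the standard on-disk formats.

Genotypes move as VCF (via pysam) or as a tab-delimited dosage matrix;
field books and cross plans as CSV. Integer dosages are encoded in VCF GT
fields; projected hybrids with real-valued dosages use a DS (dosage) FORMAT
field, since GT cannot represent a dosage of 0.5. All writers stamp the
generating seed in a header comment when one is supplied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .containers import GenotypeMatrix
from .errors import DataError

_GT_BY_DOSAGE = {0.0: (0, 0), 1.0: (0, 1), 2.0: (1, 1)}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(gm: GenotypeMatrix, seed=None, ds: bool = False) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in pd.unique(gm.markers["chrom"].astype(str)):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    if ds:
        header.formats.add("DS", 1, "Float", "Dosage of the alternate allele (0-2)")
    if seed is not None:
        header.add_meta("milletgs_seed", str(seed))
    for entry in gm.entry_ids:
        header.add_sample(str(entry))
    return header


def write_vcf(gm: GenotypeMatrix, path, seed=None, ds: bool = False) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF.

    With ``ds=False`` every dosage must be integer (0/1/2) or missing.
    With ``ds=True`` a DS field carries real dosages and GT is set only
    where the dosage is integer.
    """
    vals = gm.values()
    integral = np.isclose(vals, np.round(vals), atol=1e-9)
    if not ds and not np.all(integral | np.isnan(vals)):
        raise DataError("non-integer dosages require ds=True (DS-field VCF)")
    header = _vcf_header(gm, seed=seed, ds=ds)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, (mid, meta) in enumerate(gm.markers.iterrows()):
            rec = out.new_record(
                contig=str(meta["chrom"]),
                start=int(meta["pos"]) - 1,
                stop=int(meta["pos"]),
                alleles=(str(meta["ref"]), str(meta["alt"])),
                id=str(mid),
            )
            col = vals[:, j]
            for i, sample in enumerate(gm.entry_ids):
                v = col[i]
                if np.isnan(v):
                    rec.samples[str(sample)]["GT"] = (None, None)
                elif integral[i, j]:
                    rec.samples[str(sample)]["GT"] = _GT_BY_DOSAGE[round(v)]
                else:
                    rec.samples[str(sample)]["GT"] = (None, None)
                if ds:
                    rec.samples[str(sample)]["DS"] = None if np.isnan(v) else float(v)
            out.write(rec)


def read_vcf(path, entry_type: str = "hybrid") -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (GT → dosage 0/1/2; DS wins if present).

    Multi-allelic records are kept with ``n_alleles`` metadata so the
    marker filter can tally them; their calls involving alleles beyond the
    first alternate are recorded as missing.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        has_ds = "DS" in vcf.header.formats
        rows, meta = [], []
        for rec in vcf:
            n_alleles = len(rec.alleles)
            alt = rec.alts[0] if rec.alts else "."
            mid = rec.id or f"{rec.contig}:{rec.pos}"
            meta.append((mid, str(rec.contig), int(rec.pos), rec.ref, alt, n_alleles))
            col = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                sample = rec.samples[s]
                if has_ds and sample.get("DS") is not None:
                    col[i] = float(sample["DS"])
                    continue
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                if any(a > 1 for a in gt):  # third allele: not representable
                    continue
                col[i] = float(sum(gt))
            rows.append(col)
    markers = pd.DataFrame(
        meta, columns=["marker_id", "chrom", "pos", "ref", "alt", "n_alleles"]
    ).set_index("marker_id")
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="entry_id"),
        columns=markers.index,
    )
    entries = pd.DataFrame({"entry_type": entry_type}, index=dosages.index)
    return GenotypeMatrix(dosages, markers, entries)


def read_vcf_allele_depths(path) -> pd.DataFrame:
    """Extract per-sample AD fields from a VCF as a long allele-depth table.

    Returns a DataFrame with columns sample, chrom, pos, allele, count —
    the input format of the genotype caller.
    """
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        if "AD" not in vcf.header.formats:
            raise DataError("VCF has no AD FORMAT field")
        for rec in vcf:
            for s in vcf.header.samples:
                ad = rec.samples[s].get("AD")
                if ad is None:
                    continue
                for allele, count in zip(rec.alleles, ad):
                    if count is not None and count > 0:
                        records.append((s, str(rec.contig), int(rec.pos), allele, int(count)))
    return pd.DataFrame(records, columns=["sample", "chrom", "pos", "allele", "count"])


# ---------------------------------------------------------------------------
# dosage matrix (TSV)
# ---------------------------------------------------------------------------

def write_matrix(gm: GenotypeMatrix, path, seed=None) -> None:
    """Tab-delimited dosage matrix: marker metadata columns then one column
    per entry. Canonical format for projected hybrids (real dosages)."""
    table = gm.markers[["chrom", "pos", "ref", "alt"]].copy()
    table = pd.concat([table, gm.dosages.T], axis=1)
    with open(path, "w") as fh:
        fh.write("# milletgs dosage matrix\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        table.to_csv(fh, sep="\t", index_label="marker_id")


def read_matrix(path, entry_type: str = "hybrid") -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", comment="#", index_col="marker_id")
    markers = table[["chrom", "pos", "ref", "alt"]]
    dosages = table.drop(columns=["chrom", "pos", "ref", "alt"]).T.astype(float)
    dosages.index.name = "entry_id"
    entries = pd.DataFrame({"entry_type": entry_type}, index=dosages.index)
    return GenotypeMatrix(dosages, markers.copy(), entries)


# ---------------------------------------------------------------------------
# field book / generic seed-stamped CSV
# ---------------------------------------------------------------------------

def write_csv(frame: pd.DataFrame, path, seed=None, index: bool = False) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=index)


def read_field_book(path) -> pd.DataFrame:
    book = pd.read_csv(path, comment="#")
    required = {"location", "replicate", "block", "entry_id", "entry_type"}
    missing = required.difference(book.columns)
    if missing:
        raise DataError(f"field book missing columns: {sorted(missing)}")
    return book
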