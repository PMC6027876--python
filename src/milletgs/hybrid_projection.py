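"""Projection of F1 hybrid genotypes from their inbred parents' genotypes.

Dosages are on the 0–2 scale (0 = homozygous reference, 2 = homozygous
alternate). The three projection rules — same homozygote → same call,
opposite homozygotes → heterozygote, any heterozygous parent → mean of the
two parental dosages — are jointly equivalent to the midpoint rule
``(p1 + p2) / 2`` for every non-missing dosage pair, which is how the
vectorised implementation computes them. A missing parent call yields a
missing hybrid call. Projected dosages may be non-integer (0.5, 1.5) and are
stored as reals; downstream ridge regression consumes them directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CrossPlan, GenotypeMatrix
from .errors import AlignmentError, DataError


def project_hybrid(parent1_dosage: float, parent2_dosage: float) -> float:
    """Project a single-marker hybrid dosage from two parental dosages.

    Symmetric in its arguments; returns NaN when either parent is missing.
    """
    p1, p2 = float(parent1_dosage), float(parent2_dosage)
    if np.isnan(p1) or np.isnan(p2):
        return float("nan")
    for p in (p1, p2):
        if not 0.0 <= p <= 2.0:
            raise DataError(f"parental dosage {p} outside [0, 2]")
    return (p1 + p2) / 2.0


def project_all(plan: CrossPlan, parents: GenotypeMatrix) -> GenotypeMatrix:
    """Project every hybrid in the cross plan from the parent matrix.

    The hybrid matrix shares the parental marker set; entry_type is
    ``hybrid``. Unknown parent ids raise an error naming the id.
    """
    vals = parents.values()
    row_of = {e: i for i, e in enumerate(parents.entry_ids)}
    for col in ("female_id", "male_id"):
        unknown = [p for p in plan.table[col].unique() if p not in row_of]
        if unknown:
            raise AlignmentError(f"unknown parent id(s) in plan: {unknown[:5]}")
    fem = np.fromiter((row_of[p] for p in plan.table["female_id"]), dtype=int)
    mal = np.fromiter((row_of[p] for p in plan.table["male_id"]), dtype=int)
    hybrid = (vals[fem, :] + vals[mal, :]) / 2.0
    dosages = pd.DataFrame(
        hybrid,
        index=pd.Index(plan.table["hybrid_id"], name="entry_id"),
        columns=parents.marker_ids,
    )
    entries = pd.DataFrame({"entry_type": "hybrid"}, index=dosages.index)
    return GenotypeMatrix(dosages, parents.markers.copy(), entries)
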