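"""Phenotype assignment from binary marker calls.

Lineage markers are CD20 (B cells), CD4 (helper T cells) and CD21
(follicular dendritic cells, fDC). CD4 T cells subdivide by the
transcription factors FOXP3, Tbet and BCL6:

========================  =======================
FOXP3+ (only)             Treg
Tbet+ (only)              Th1
BCL6+ (only)              Tfh
FOXP3+ BCL6+ (Tbet-)      Tfr
none of the three         CD4-other
any Tbet+ double/triple   CD4-multi
========================  =======================

CD20 B cells split into BCL6+ germinal-center B cells (GC-B) and B-other.
CK+ cells without a lineage marker are tumor cells; everything else is
"other". Cells positive for two lineages (CD4 together with CD20 or CD21)
are handled by the ambiguity policy: the default ``"exclude"`` labels them
``ambiguous`` and keeps them out of every lineage count; ``"priority"``
resolves CD20 > CD4 > CD21. CD21 on a CD20+ cell never creates ambiguity:
the B-cell lineage wins (follicular B cells carry CD21).

Every combination of the seven flags maps to exactly one label, so under the
default policy the exclusive labels partition the cells of a field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import MARKERS, Field, Region

__all__ = [
    "CD4_SUBSETS",
    "B_SUBSETS",
    "EXCLUSIVE_LABELS",
    "ROLLUP_LABELS",
    "LYMPHOCYTE_LABELS",
    "PhenotypeRuleSet",
    "assign_phenotype",
    "assign_phenotypes",
    "expand_label",
    "phenotype_counts",
]

CD4_SUBSETS: tuple[str, ...] = ("Treg", "Th1", "Tfh", "Tfr", "CD4-other", "CD4-multi")
B_SUBSETS: tuple[str, ...] = ("GC-B", "B-other")

#: Mutually exclusive labels; under the "exclude" policy they partition cells.
EXCLUSIVE_LABELS: tuple[str, ...] = (
    *CD4_SUBSETS, *B_SUBSETS, "fDC", "tumor", "other", "ambiguous",
)

#: Roll-up labels resolve to sets of exclusive labels.
ROLLUP_LABELS: dict[str, tuple[str, ...]] = {
    "CD4 T cell": CD4_SUBSETS,
    "CD20 B cell": B_SUBSETS,
    "lymphocyte": (*CD4_SUBSETS, *B_SUBSETS),
}

#: Labels counting as lymphocytes for TLS detection (CD4 T + CD20 B cells).
LYMPHOCYTE_LABELS: tuple[str, ...] = ROLLUP_LABELS["lymphocyte"]


@dataclass
class PhenotypeRuleSet:
    """Marker-combination rules; covers all 2**7 flag combinations."""

    ambiguity_policy: str = "exclude"
    lineage_priority: tuple[str, ...] = ("CD20", "CD4", "CD21")

    def __post_init__(self) -> None:
        if self.ambiguity_policy not in ("exclude", "priority"):
            raise ValueError("ambiguity_policy must be 'exclude' or 'priority'")
        if tuple(sorted(self.lineage_priority)) != ("CD20", "CD21", "CD4"):
            raise ValueError("lineage_priority must permute ('CD20', 'CD4', 'CD21')")

    def to_dict(self) -> dict[str, object]:
        return {
            "ambiguity_policy": self.ambiguity_policy,
            "lineage_priority": list(self.lineage_priority),
        }


def expand_label(label: str) -> tuple[str, ...]:
    """Resolve a (possibly roll-up) label to its exclusive labels."""
    if label in ROLLUP_LABELS:
        return ROLLUP_LABELS[label]
    if label in EXCLUSIVE_LABELS:
        return (label,)
    raise ValueError(f"unknown phenotype label {label!r}")


def assign_phenotypes(cells: pd.DataFrame,
                      rules: PhenotypeRuleSet | None = None) -> pd.Series:
    """Vectorized phenotype assignment for a cell table.

    Returns the label series and writes it into ``cells['phenotype']``.
    """
    rules = rules or PhenotypeRuleSet()
    n = len(cells)
    if n == 0:
        cells["phenotype"] = pd.Series(dtype=object)
        return cells["phenotype"]

    flag = {m: cells[m].to_numpy().astype(bool) for m in MARKERS}
    cd4, cd20, cd21 = flag["CD4"], flag["CD20"], flag["CD21"]
    fox, tbet, bcl6, ck = flag["FOXP3"], flag["TBET"], flag["BCL6"], flag["CK"]

    if rules.ambiguity_policy == "exclude":
        # CD4 with any other lineage marker is ambiguous; CD20+CD21+ is a B cell.
        ambiguous = cd4 & (cd20 | cd21)
        is_b = cd20 & ~cd4
        is_cd4 = cd4 & ~cd20 & ~cd21
        is_fdc = cd21 & ~cd20 & ~cd4
    else:
        order = rules.lineage_priority
        taken = np.zeros(n, bool)
        lineage = {}
        for m in order:
            base = {"CD20": cd20, "CD4": cd4, "CD21": cd21}[m]
            lineage[m] = base & ~taken
            taken |= base
        is_b, is_cd4, is_fdc = lineage["CD20"], lineage["CD4"], lineage["CD21"]
        ambiguous = np.zeros(n, bool)
        # CD20+CD21+ resolves to B regardless of priority order.
        is_b = is_b | (cd20 & cd21 & is_fdc)
        is_fdc = is_fdc & ~cd20

    labels = np.full(n, "other", dtype=object)
    labels[ck & ~(is_b | is_cd4 | is_fdc | ambiguous)] = "tumor"
    labels[is_fdc] = "fDC"
    labels[is_b & bcl6] = "GC-B"
    labels[is_b & ~bcl6] = "B-other"
    labels[is_cd4 & ~fox & ~tbet & ~bcl6] = "CD4-other"
    labels[is_cd4 & fox & ~tbet & ~bcl6] = "Treg"
    labels[is_cd4 & tbet & ~fox & ~bcl6] = "Th1"
    labels[is_cd4 & bcl6 & ~fox & ~tbet] = "Tfh"
    labels[is_cd4 & fox & bcl6 & ~tbet] = "Tfr"
    labels[is_cd4 & tbet & (fox | bcl6)] = "CD4-multi"
    labels[ambiguous] = "ambiguous"

    cells["phenotype"] = labels
    return cells["phenotype"]


def assign_phenotype(markers: Mapping[str, bool | int],
                     rules: PhenotypeRuleSet | None = None) -> str:
    """Label a single cell from its marker flags."""
    missing = [m for m in MARKERS if m not in markers]
    if missing:
        raise ValueError(f"missing marker calls: {missing}")
    row = pd.DataFrame({m: [int(bool(markers[m]))] for m in MARKERS})
    return str(assign_phenotypes(row, rules).iloc[0])


def assign_cohort(patients: Iterable, rules: PhenotypeRuleSet | None = None) -> None:
    """Assign phenotypes in place across all fields of the given patients."""
    for patient in patients:
        for fld in patient.fields:
            assign_phenotypes(fld.cells, rules)


def phenotype_counts(field: Field, region: Region, label: str) -> int:
    """Count cells with ``label`` (or roll-up) in the given region of a field.

    Returns 0 when the field's class does not match the region's.
    """
    targets = expand_label(label)
    if field.field_class != region.field_class:
        return 0
    cells = field.cells
    if not len(cells):
        return 0
    mask = cells["phenotype"].isin(targets) & (cells["compartment"] == region.compartment)
    return int(mask.sum())
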