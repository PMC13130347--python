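"""Medicinal-part severity and 2x2 chi-square association tests.

Species recorded for several part categories are assigned the most severe
one (I > II > III): any use of a fatal part (whole plant, roots, heartwood)
classifies the species as a fatal-part user, however many gentler parts are
also used. Associations (threat status x severity, threat status x endemism)
are tested with the chi-square test of independence on 2x2 tables, with the
Yates continuity correction optional per test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import PartCategory, Species

__all__ = [
    "Severity",
    "classify_severity",
    "ContingencyTable2x2",
    "contingency",
    "ChiSquareResult",
    "chi_square",
]


class Severity(str, Enum):
    FATAL = "FATAL"
    NON_FATAL = "NON_FATAL"


def classify_severity(species: Species) -> Severity:
    """FATAL iff category I is among the species' medicinal parts."""
    if not species.part_categories:
        raise ValueError(f"{species.species_id}: empty medicinal-part set")
    return Severity.FATAL if PartCategory.I in species.part_categories else Severity.NON_FATAL


@dataclass(frozen=True)
class ContingencyTable2x2:
    counts: Tuple[Tuple[int, int], Tuple[int, int]]  # rows x cols
    row_labels: Tuple[str, str]
    col_labels: Tuple[str, str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def contingency(
    species: Sequence[Species],
    row: Callable[[Species], bool],
    col: Callable[[Species], bool],
    row_labels: Tuple[str, str] = ("row+", "row-"),
    col_labels: Tuple[str, str] = ("col+", "col-"),
) -> ContingencyTable2x2:
    """Cross-tabulate two boolean predicates over a species list.

    Cell [0][0] counts species where both predicates hold; row 0 is the
    row-predicate-true margin, column 0 the col-predicate-true margin.
    """
    a = b = c = d = 0
    for s in species:
        r, k = bool(row(s)), bool(col(s))
        if r and k:
            a += 1
        elif r:
            b += 1
        elif k:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(((a, b), (c, d)), row_labels, col_labels)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    corrected: bool


def chi_square(table: ContingencyTable2x2, yates: bool = True) -> ChiSquareResult:
    """Chi-square test of independence on a 2x2 table.

    ``yates`` applies the continuity correction (|O-E| reduced by 0.5 before
    squaring). Expected counts are the usual row x column products over the
    grand total; a zero margin makes expectations degenerate and is a hard
    error.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin: expected counts undefined")
    stat, p, dof, _expected = stats.chi2_contingency(arr, correction=yates)
    return ChiSquareResult(float(stat), int(dof), float(p), bool(yates))
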