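"""Dataset-level comparisons: coverage overlap and assignment concordance.

Used to relate one fractionation study to another: which proteins were
detected in both (set overlap on normalized locus tags) and, for shared
proteins, how the two studies' compartment assignments cross-tabulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import PipelineError
from .markers import normalize_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapReport:
    n_only_a: int
    n_only_b: int
    n_both: int
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]
    both: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_only_A": self.n_only_a,
            "n_only_B": self.n_only_b,
            "n_both": self.n_both,
        }


@dataclass(frozen=True)
class ConcordanceReport:
    table: pd.DataFrame  # rows: labels in A; columns: labels in B
    n_shared: int

    def to_dict(self) -> dict:
        return {
            "n_shared": self.n_shared,
            "contingency": {r: dict(row) for r, row in self.table.iterrows()},
            "row_marginals": self.table.sum(axis=1).to_dict(),
            "col_marginals": self.table.sum(axis=0).to_dict(),
        }


def overlap(list_a: Iterable[str], list_b: Iterable[str]) -> OverlapReport:
    """Exact set arithmetic on normalized protein IDs."""
    a = {normalize_id(p) for p in list_a}
    b = {normalize_id(p) for p in list_b}
    both = a & b
    return OverlapReport(
        n_only_a=len(a - b),
        n_only_b=len(b - a),
        n_both=len(both),
        only_a=tuple(sorted(a - b)),
        only_b=tuple(sorted(b - a)),
        both=tuple(sorted(both)),
    )


def concordance(
    assignments_a: pd.DataFrame,
    assignments_b: pd.DataFrame,
    label_map: Mapping[str, str] | None = None,
) -> ConcordanceReport:
    """Contingency table of two assignment tables over their shared proteins.

    Both tables need columns protein_id and final_label. ``label_map``
    translates table B's vocabulary into table A's; an unmappable label is
    an error naming it. Swapping A and B transposes the table.
    """
    a = assignments_a.assign(protein_id=assignments_a["protein_id"].map(normalize_id))
    b = assignments_b.assign(protein_id=assignments_b["protein_id"].map(normalize_id))
    a = a.set_index("protein_id")["final_label"]
    b = b.set_index("protein_id")["final_label"]
    if label_map is not None:
        unmappable = set(b.unique()) - set(label_map)
        if unmappable:
            raise PipelineError(f"unmappable label(s) in table B: {sorted(unmappable)}")
        b = b.map(label_map)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        logger.warning("no shared proteins between the two assignment tables")
        return ConcordanceReport(pd.DataFrame(dtype=int), 0)
    table = pd.crosstab(a.loc[shared], b.loc[shared])
    table.index.name = "label_A"
    table.columns.name = "label_B"
    return ConcordanceReport(table, int(len(shared)))
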