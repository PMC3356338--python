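"""Shared data containers.

Two containers are threaded through the whole package: a labeled two-group
expression matrix (:class:`GroupedExpression`) and a collection of named,
possibly overlapping gene sets (:class:`PathwayCollection`).  A single ordered
gene universe -- the row order of the expression matrix, which equals the node
order of any underlying network -- keeps matrices, networks and pathways
aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

CONTROL = "control"
TREATMENT = "treatment"


@dataclass
class GroupedExpression:
    """A genes x samples real matrix with a two-group sample labeling.

    Parameters
    ----------
    values : ndarray, shape (p, n1 + n2)
        Expression values, one row per gene.
    gene_ids : sequence of str
        Unique identifiers, one per row; order is authoritative.
    group_labels : sequence of str
        One label per column; exactly two distinct values.  The label of the
        first column is taken as the control group.
    """

    values: np.ndarray
    gene_ids: list[str]
    group_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.group_labels = np.asarray(self.group_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d genes x samples matrix")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {self.values.shape[0]} rows"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids must be unique")
        if self.group_labels.shape[0] != self.values.shape[1]:
            raise ValueError(
                f"{self.group_labels.shape[0]} labels for "
                f"{self.values.shape[1]} columns"
            )
        distinct = list(dict.fromkeys(self.group_labels.tolist()))
        if len(distinct) != 2:
            raise ValueError(
                f"expected exactly 2 distinct group labels, got {distinct!r}"
            )
        self._control_label, self._treatment_label = distinct
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- group structure ---------------------------------------------------
    @property
    def control_label(self) -> str:
        return self._control_label

    @property
    def treatment_label(self) -> str:
        return self._treatment_label

    @property
    def treatment_mask(self) -> np.ndarray:
        """Boolean mask over columns; True marks the treatment group."""
        return np.asarray(self.group_labels == self._treatment_label)

    @property
    def n1(self) -> int:
        return int(self.values.shape[1] - self.treatment_mask.sum())

    @property
    def n2(self) -> int:
        return int(self.treatment_mask.sum())

    @property
    def n_genes(self) -> int:
        return int(self.values.shape[0])

    # -- gene lookup -------------------------------------------------------
    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of ``genes``; raises KeyError naming missing genes."""
        missing = [g for g in genes if g not in self._index]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
        return np.asarray([self._index[g] for g in genes], dtype=int)

    def subset_samples(self, columns: np.ndarray) -> "GroupedExpression":
        return GroupedExpression(
            self.values[:, columns], self.gene_ids, self.group_labels[columns]
        )


@dataclass
class Pathway:
    """A named gene set with its ground-truth bookkeeping.

    ``truly_de`` marks the pathway as differentially expressed by
    construction; ``realized_detection_call`` records the exact fraction
    ceil(DC * size) / size of member genes that received a mean shift.
    """

    name: str
    genes: list[str] = field(default_factory=list)
    truly_de: bool = False
    realized_detection_call: float = 0.0

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"pathway {self.name!r} has duplicate genes")

    @property
    def size(self) -> int:
        return len(self.genes)


class PathwayCollection:
    """Ordered mapping of pathway name -> :class:`Pathway` (sizes >= 2)."""

    def __init__(self, pathways: Iterable[Pathway]):
        self._pathways: dict[str, Pathway] = {}
        for pw in pathways:
            if pw.name in self._pathways:
                raise ValueError(f"duplicate pathway name {pw.name!r}")
            if pw.size < 2:
                raise ValueError(f"pathway {pw.name!r} has size {pw.size} < 2")
            self._pathways[pw.name] = pw

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self._pathways.values())

    def __contains__(self, name: str) -> bool:
        return name in self._pathways

    def __getitem__(self, name: str) -> Pathway:
        return self._pathways[name]

    @property
    def names(self) -> list[str]:
        return list(self._pathways)

    def gene_universe(self) -> list[str]:
        seen: dict[str, None] = {}
        for pw in self:
            for g in pw.genes:
                seen.setdefault(g)
        return list(seen)

    def validate_against(self, gene_ids: Sequence[str]) -> None:
        universe = set(gene_ids)
        for pw in self:
            missing = [g for g in pw.genes if g not in universe]
            if missing:
                raise KeyError(
                    f"pathway {pw.name!r} members absent from data: {missing[:5]}"
                )

    def copy(self) -> "PathwayCollection":
        return PathwayCollection(replace(pw, genes=list(pw.genes)) for pw in self)
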