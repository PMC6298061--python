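"""Core domain types shared across the pipeline.

The atomic input is an :class:`ExpressionDataset` — one cohort's genes x
samples log-expression matrix tagged with a tissue label.  Gene pairs
("links") are always stored canonically with ``gene_a < gene_b``
(lexicographic), so a single orientation represents the unordered pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "ExpressionDataset",
    "AnnotationMap",
    "canonical_pair",
    "canonical_pairs",
    "pair_index",
    "n_pairs",
]


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Return the unordered pair in its canonical (lexicographic) orientation."""
    if gene_a == gene_b:
        raise ValueError(f"self-pair not allowed: {gene_a!r}")
    return (gene_a, gene_b) if gene_a < gene_b else (gene_b, gene_a)


def canonical_pairs(pairs: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    return [canonical_pair(a, b) for a, b in pairs]


def n_pairs(n_genes: int) -> int:
    return n_genes * (n_genes - 1) // 2


def pair_index(i: int, j: int, n: int) -> int:
    """Condensed (upper-triangular, row-major) index of pair positions i<j among n genes.

    Matches the ordering of ``itertools.combinations(range(n), 2)`` and of the
    off-diagonal upper triangle of an n x n matrix read row by row.
    """
    if i > j:
        i, j = j, i
    if i == j:
        raise ValueError("diagonal excluded")
    return n * i - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class ExpressionDataset:
    """One dataset: log2 expression, genes as rows.

    Parameters
    ----------
    dataset_id
        Unique identifier of the cohort.
    tissue
        Tissue (or condition) label the dataset was collected from.
    gene_ids
        Row labels; must be unique.
    matrix
        ``(len(gene_ids), n_samples)`` array of log-scale expression values.
        At least 3 samples are required (fewer leaves the Pearson correlation
        without degrees of freedom).
    """

    dataset_id: str
    tissue: str
    gene_ids: list[str]
    matrix: np.ndarray
    _mean: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"dataset {self.dataset_id!r}: matrix must be 2-D")
        if len(self.gene_ids) != self.matrix.shape[0]:
            raise ValueError(
                f"dataset {self.dataset_id!r}: {len(self.gene_ids)} gene ids "
                f"for {self.matrix.shape[0]} rows"
            )
        seen: set[str] = set()
        for g in self.gene_ids:
            if g in seen:
                raise ValueError(
                    f"dataset {self.dataset_id!r}: duplicate gene ID {g!r}"
                )
            seen.add(g)
        if self.n_samples < 3:
            raise ValueError(
                f"dataset {self.dataset_id!r} has {self.n_samples} samples; "
                "at least 3 are required"
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def mean_expression(self) -> np.ndarray:
        """Per-gene mean of the log expression (e_ik for this dataset k)."""
        if self._mean is None:
            self._mean = self.matrix.mean(axis=1)
        return self._mean

    def restrict(self, genes: list[str]) -> "ExpressionDataset":
        """Return a copy reindexed to `genes` (which must all be present)."""
        pos = {g: r for r, g in enumerate(self.gene_ids)}
        rows = [pos[g] for g in genes]
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            tissue=self.tissue,
            gene_ids=list(genes),
            matrix=self.matrix[rows],
        )


class AnnotationMap:
    """Gene -> term annotations with the inverse term -> gene index.

    Term identity is opaque to the pipeline: any flat gene/term pairing
    (GO slices, pathway sets, synthetic blocks) works.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        gene2terms: dict[str, set[str]] = {}
        term2genes: dict[str, set[str]] = {}
        for gene, term in pairs:
            gene2terms.setdefault(gene, set()).add(term)
            term2genes.setdefault(term, set()).add(gene)
        self.gene2terms = gene2terms
        self.term2genes = term2genes

    def terms_of(self, gene: str) -> set[str]:
        return self.gene2terms.get(gene, set())

    def genes_of(self, term: str) -> set[str]:
        return self.term2genes.get(term, set())

    @property
    def genes(self) -> set[str]:
        return set(self.gene2terms)

    @property
    def terms(self) -> set[str]:
        return set(self.term2genes)

    def items(self) -> Iterable[tuple[str, str]]:
        for gene in sorted(self.gene2terms):
            for term in sorted(self.gene2terms[gene]):
                yield gene, term

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self.gene2terms == other.gene2terms

    def __len__(self) -> int:
        return sum(len(t) for t in self.gene2terms.values())

    def check_inverse(self) -> None:
        """Assert the two indexes are mutual inverses (internal invariant)."""
        for g, terms in self.gene2terms.items():
            for t in terms:
                assert g in self.term2genes[t]
        for t, genes in self.term2genes.items():
            for g in genes:
                assert t in self.gene2terms[g]
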