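"""Per-dataset correlation networks and tissue-aggregated networks (TANs).

Pipeline stage: for each dataset, Pearson-correlate every pair of genes
expressed in its tissue; binarize at the top ``1 - tan_percentile`` of
correlations (strict ``>``); and, per tissue, keep the links present in at
least ``n`` of the tissue's binary networks, where ``n`` is the smallest
support level whose false discovery rate under a binomial null (a link
independently enters each binary network with probability
``1 - tan_percentile``) is at or below the configured target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .core import ExpressionDataset, canonical_pair, n_pairs, pair_index

__all__ = [
    "DatasetCorrelations",
    "BinaryNetwork",
    "TAN",
    "harmonize_genes",
    "mark_expressed",
    "correlation_network",
    "binarize",
    "aggregation_threshold",
    "build_tan",
    "build_tissue_tan",
]


def harmonize_genes(
    datasets: list[ExpressionDataset],
) -> tuple[list[str], list[ExpressionDataset]]:
    """Restrict every dataset to the shared gene universe (sorted intersection)."""
    if len(datasets) < 2:
        raise ValueError("harmonization needs at least 2 datasets")
    universe: set[str] = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        universe &= set(ds.gene_ids)
    if not universe:
        raise ValueError("empty gene intersection across datasets")
    genes = sorted(universe)
    return genes, [ds.restrict(genes) for ds in datasets]


def mark_expressed(
    datasets: list[ExpressionDataset],
    method: str = "gmm2",
    threshold: float | None = None,
    random_state: int = 0,
) -> tuple[set[str], dict]:
    """Expressed genes of one tissue from tissue-wide mean log-expression.

    ``gmm2`` fits a 2-component 1-D Gaussian mixture to the per-gene mean
    (averaged over the tissue's datasets) and marks genes whose posterior for
    the higher-mean component is >= 0.5.  If the two components land closer
    than 0.1 pooled SD the fit is treated as degenerate and the method falls
    back to a fixed cut at the distribution median, with a warning.

    Returns the expressed set and an info dict (method actually used,
    threshold/split point).
    """
    if not datasets:
        raise ValueError("mark_expressed needs at least one dataset")
    tissues = {ds.tissue for ds in datasets}
    if len(tissues) > 1:
        raise ValueError(f"datasets span multiple tissues: {sorted(tissues)}")
    genes = datasets[0].gene_ids
    for ds in datasets[1:]:
        if ds.gene_ids != genes:
            raise ValueError("datasets must share an identical gene index")
    means = np.mean([ds.mean_expression for ds in datasets], axis=0)

    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        mask = means > threshold
        return {g for g, m in zip(genes, mask) if m}, {"method": "fixed", "threshold": threshold}
    if method != "gmm2":
        raise ValueError(f"unknown expressed-gene method {method!r}")

    gmm = GaussianMixture(n_components=2, n_init=3, random_state=random_state)
    x = means.reshape(-1, 1)
    gmm.fit(x)
    mu = gmm.means_.ravel()
    sd = np.sqrt(gmm.covariances_.ravel())
    # degenerate when the components nearly coincide (closer than 0.1 data SD)
    # or fail Ashman's bimodality criterion D >= 2 (unimodal input)
    ashman_d = abs(mu[0] - mu[1]) / np.sqrt((sd[0] ** 2 + sd[1] ** 2) / 2)
    if abs(mu[0] - mu[1]) < 0.1 * float(np.std(means)) or ashman_d < 2.0:
        fallback = float(np.median(means))
        warnings.warn(
            "degenerate 2-component mixture; falling back to median threshold "
            f"{fallback:.3f}",
            RuntimeWarning,
            stacklevel=2,
        )
        mask = means > fallback
        return {g for g, m in zip(genes, mask) if m}, {"method": "fixed", "threshold": fallback}
    hi = int(np.argmax(mu))
    post = gmm.predict_proba(x)[:, hi]
    mask = post >= 0.5
    # split point: midpoint of the posterior crossover, for diagnostics
    on_means = means[mask]
    off_means = means[~mask]
    split = float((off_means.max() + on_means.min()) / 2) if mask.any() and (~mask).any() else float("nan")
    return {g for g, m in zip(genes, mask) if m}, {"method": "gmm2", "split": split}


@dataclass
class DatasetCorrelations:
    """All-pairs Pearson correlations of one dataset's expressed genes.

    ``values`` is the condensed upper triangle in the row-major order of
    ``itertools.combinations(range(n_genes), 2)``; ``zero_variance`` flags
    pairs involving a constant gene (their correlation is set to 0).
    """

    dataset_id: str
    tissue: str
    gene_ids: list[str]
    values: np.ndarray
    zero_variance: np.ndarray
    _index: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]
    _sorted: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sorted = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.values)

    @property
    def sorted_values(self) -> np.ndarray:
        if self._sorted is None:
            self._sorted = np.sort(self.values)
        return self._sorted

    def has_gene(self, gene: str) -> bool:
        return gene in self._index

    def corr(self, gene_a: str, gene_b: str) -> float:
        """Symmetric access: corr(a, b) == corr(b, a); the diagonal is excluded."""
        i, j = self._index[gene_a], self._index[gene_b]
        return float(self.values[pair_index(i, j, self.n_genes)])

    def pair_indices(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        n = self.n_genes
        idx = self._index
        return np.array([pair_index(idx[a], idx[b], n) for a, b in pairs], dtype=np.int64)


def correlation_network(dataset: ExpressionDataset, expressed: set[str]) -> DatasetCorrelations:
    """Pearson correlations between all pairs of the tissue's expressed genes.

    Pairs involving a zero-variance gene get correlation 0 with a flag rather
    than propagating NaN.
    """
    genes = [g for g in dataset.gene_ids if g in expressed]
    if len(genes) < 2:
        raise ValueError(f"dataset {dataset.dataset_id!r}: fewer than 2 expressed genes")
    sub = dataset.restrict(genes)
    sd = sub.matrix.std(axis=1)
    constant = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.matrix)
    iu = np.triu_indices(len(genes), k=1)
    values = corr[iu]
    flags = constant[iu[0]] | constant[iu[1]]
    values = np.where(flags, 0.0, values)
    values = np.clip(values, -1.0, 1.0)  # guard fp drift
    return DatasetCorrelations(
        dataset_id=dataset.dataset_id,
        tissue=dataset.tissue,
        gene_ids=genes,
        values=values,
        zero_variance=flags,
    )


@dataclass
class BinaryNetwork:
    """Top-percentile links of one dataset (condensed indices into its pair order)."""

    dataset_id: str
    cutoff_value: float
    link_indices: np.ndarray
    n_pairs: int

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_pairs, dtype=bool)
        m[self.link_indices] = True
        return m


def binarize(store: DatasetCorrelations, percentile: float) -> BinaryNetwork:
    """Links = pairs strictly above the empirical percentile of all pair correlations.

    Ties at the cutoff are excluded (strict ``>``), so with heavy ties the
    network can be smaller than the nominal ``1 - percentile`` fraction.
    """
    cutoff = float(np.quantile(store.values, percentile))
    idx = np.flatnonzero(store.values > cutoff)
    return BinaryNetwork(
        dataset_id=store.dataset_id,
        cutoff_value=cutoff,
        link_indices=idx,
        n_pairs=store.n_pairs,
    )


def aggregation_threshold(
    n_datasets: int,
    keep_fraction: float,
    n_pairs_total: int,
    fdr: float,
    support_counts: np.ndarray | None = None,
    mode: str = "planning",
) -> int:
    """Smallest cross-dataset support ``n`` meeting the binomial-null FDR.

    The null: a pair enters each of the ``n_datasets`` binary networks
    independently with probability ``keep_fraction``, so its support is
    Binomial(n_datasets, keep_fraction).

    planning mode (no observed counts needed): smallest ``n`` with
    ``P(X >= n) <= fdr``.

    empirical mode: smallest ``n`` with
    ``n_pairs_total * P(X >= n) / max(#{pairs with support >= n}, 1) <= fdr``;
    requires ``support_counts`` (per-pair support).
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if not 0.0 < keep_fraction < 1.0:
        raise ValueError("keep_fraction must be in (0, 1)")
    if mode == "empirical" and support_counts is None:
        raise ValueError("empirical mode needs support_counts")
    tail = stats.binom.sf(np.arange(n_datasets + 1) - 1, n_datasets, keep_fraction)
    for n in range(1, n_datasets + 1):
        expected_false = n_pairs_total * tail[n]
        if mode == "planning" or support_counts is None:
            ok = tail[n] <= fdr
        else:
            observed = max(int(np.count_nonzero(support_counts >= n)), 1)
            ok = expected_false / observed <= fdr
        if ok:
            return n
    raise ValueError(
        f"no support level n <= {n_datasets} meets FDR {fdr:g} "
        f"(P(X >= {n_datasets}) = {tail[n_datasets]:.3g}); consider a looser fdr"
    )


@dataclass
class TAN:
    """Tissue-aggregated network: links supported by >= min_support binary networks."""

    tissue: str
    gene_ids: list[str]
    n_datasets: int
    min_support: int
    support: np.ndarray  # per condensed pair
    link_indices: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.support)

    @property
    def n_links(self) -> int:
        return len(self.link_indices)

    @property
    def density(self) -> float:
        return self.n_links / self.n_pairs if self.n_pairs else 0.0

    def links_as_pairs(self) -> set[tuple[str, str]]:
        genes = self.gene_ids
        n = len(genes)
        out = set()
        i_idx, j_idx = _condensed_to_ij(self.link_indices, n)
        for i, j in zip(i_idx, j_idx):
            out.add(canonical_pair(genes[i], genes[j]))
        return out

    def neighborhoods(self) -> dict[str, set[str]]:
        """Adjacency of the TAN as gene -> neighbor set."""
        nbrs: dict[str, set[str]] = {}
        for a, b in self.links_as_pairs():
            nbrs.setdefault(a, set()).add(b)
            nbrs.setdefault(b, set()).add(a)
        return nbrs


def _condensed_to_ij(indices: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Invert the condensed row-major pair index (vectorized)."""
    indices = np.asarray(indices, dtype=np.int64)
    # row i satisfies offset(i) <= idx < offset(i+1), offset(i) = i*n - i*(i+1)/2
    rows = np.arange(n, dtype=np.int64)
    offsets = rows * n - rows * (rows + 1) // 2
    i = np.searchsorted(offsets, indices, side="right") - 1
    j = indices - offsets[i] + i + 1
    return i, j


def build_tan(binary_networks: list[BinaryNetwork], n: int, tissue: str, gene_ids: list[str]) -> TAN:
    """Aggregate a tissue's binary networks: exact support counts, keep support >= n."""
    if not binary_networks:
        raise ValueError("no binary networks to aggregate")
    n_pairs_total = binary_networks[0].n_pairs
    support = np.zeros(n_pairs_total, dtype=np.int32)
    for bn in binary_networks:
        if bn.n_pairs != n_pairs_total:
            raise ValueError("binary networks do not share a gene universe")
        support[bn.link_indices] += 1
    links = np.flatnonzero(support >= n)
    return TAN(
        tissue=tissue,
        gene_ids=gene_ids,
        n_datasets=len(binary_networks),
        min_support=n,
        support=support,
        link_indices=links,
    )


def build_tissue_tan(
    stores: list[DatasetCorrelations],
    percentile: float,
    fdr: float,
    mode: str = "planning",
) -> TAN:
    """Binarize each dataset of one tissue and aggregate with the binomial FDR rule."""
    tissues = {s.tissue for s in stores}
    if len(tissues) != 1:
        raise ValueError(f"stores span multiple tissues: {sorted(tissues)}")
    gene_ids = stores[0].gene_ids
    for s in stores[1:]:
        if s.gene_ids != gene_ids:
            raise ValueError("stores do not share a gene universe")
    nets = [binarize(s, percentile) for s in stores]
    support = np.zeros(stores[0].n_pairs, dtype=np.int32)
    for bn in nets:
        support[bn.link_indices] += 1
    n = aggregation_threshold(
        n_datasets=len(nets),
        keep_fraction=1.0 - percentile,
        n_pairs_total=stores[0].n_pairs,
        fdr=fdr,
        support_counts=support,
        mode=mode,
    )
    return build_tan(nets, n, tissue=stores[0].tissue, gene_ids=gene_ids)
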