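"""Reproducibility of link groups in an external expression collection.

An external cohort (one dataset per tissue, e.g. an RNA-seq atlas) is
binarized at the correlation cutoff that reproduces the reference TAN's
density on the shared gene universe, so overlap statistics compare
networks of equal sparsity.  A link group's reproducibility is summarized
by (i) the distribution of its links' external correlations against the
all-pairs null, (ii) the ratio of observed to chance overlap with the
external binary network, and (iii) the fraction of its links present
there.  Neighborhood topological overlap provides an orthogonal,
within-collection check that a link's two genes share network context in
the target tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import canonical_pair
from .networks import TAN, DatasetCorrelations

__all__ = [
    "ExternalNetwork",
    "match_density_binarize",
    "overlap_likelihood_ratio",
    "group_correlation_distributions",
    "reproduced_fraction",
    "topological_overlap",
]

QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class ExternalNetwork:
    """Density-matched binary network of one external dataset."""

    tissue: str
    shared_genes: list[str]
    links: set[tuple[str, str]]
    cutoff: float
    density: float
    n_shared_pairs: int


def _shared_pairs_values(
    store: DatasetCorrelations, shared: list[str]
) -> tuple[list[tuple[str, str]], np.ndarray]:
    pairs = [
        canonical_pair(shared[i], shared[j])
        for i in range(len(shared))
        for j in range(i + 1, len(shared))
    ]
    vals = store.values[store.pair_indices(pairs)]
    return pairs, vals


def match_density_binarize(
    external: DatasetCorrelations, reference_tan: TAN, min_overlap: int = 100
) -> ExternalNetwork:
    """Binarize the external dataset at the reference TAN's density.

    Density is computed on the shared gene universe; the external cutoff is
    the correlation quantile giving the same link count there (exact up to
    integer rounding / ties).
    """
    shared = sorted(set(external.gene_ids) & set(reference_tan.gene_ids))
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} genes shared with the TAN universe "
            f"(need >= {min_overlap})"
        )
    pairs, vals = _shared_pairs_values(external, shared)
    n_shared = len(pairs)
    tan_links = reference_tan.links_as_pairs()
    shared_set = set(pairs)
    n_target = len(tan_links & shared_set)
    if n_target == 0:
        return ExternalNetwork(external.tissue, shared, set(), float("inf"), 0.0, n_shared)
    order = np.argsort(vals)[::-1]
    keep = order[:n_target]
    cutoff = float(vals[keep[-1]])
    links = {pairs[i] for i in keep}
    return ExternalNetwork(
        tissue=external.tissue,
        shared_genes=shared,
        links=links,
        cutoff=cutoff,
        density=len(links) / n_shared,
        n_shared_pairs=n_shared,
    )


def overlap_likelihood_ratio(
    link_group: set[tuple[str, str]], external: ExternalNetwork
) -> float | None:
    """Observed / expected overlap with the external binary network.

    Expected = (testable group links) x (external density); a group with no
    testable links on the shared universe has no defined ratio (None).
    """
    genes = set(external.shared_genes)
    testable = {canonical_pair(a, b) for a, b in link_group if a in genes and b in genes}
    if not testable or external.density == 0.0:
        return None
    observed = len(testable & external.links)
    expected = len(testable) * external.density
    return observed / expected


def reproduced_fraction(
    link_group: set[tuple[str, str]], external: ExternalNetwork
) -> float | None:
    """Fraction of the group's testable links present in the external network."""
    genes = set(external.shared_genes)
    testable = {canonical_pair(a, b) for a, b in link_group if a in genes and b in genes}
    if not testable:
        return None
    return len(testable & external.links) / len(testable)


def group_correlation_distributions(
    link_groups: dict[str, set[tuple[str, str]]],
    external: DatasetCorrelations,
    tan_universe: list[str] | None = None,
) -> dict[str, dict]:
    """External-correlation quantiles per link group, against the all-pairs null.

    For each group: the 5/25/50/75/95% quantiles of the external correlations
    of its (testable) links, plus a one-sided rank-sum p for group > null.
    The null entry ("__null__") holds the all-shared-pairs quantiles.
    """
    genes = set(external.gene_ids)
    if tan_universe is not None:
        genes &= set(tan_universe)
    shared = sorted(genes)
    _, null_vals = _shared_pairs_values(external, shared)
    out: dict[str, dict] = {
        "__null__": {
            "quantiles": dict(zip(QUANTILES, np.quantile(null_vals, QUANTILES))),
            "n": len(null_vals),
        }
    }
    for name, group in link_groups.items():
        testable = [
            canonical_pair(a, b) for a, b in group if a in genes and b in genes
        ]
        if not testable:
            out[name] = {"quantiles": {}, "n": 0, "p_greater_null": None}
            continue
        vals = external.values[external.pair_indices(testable)]
        p = float(
            stats.mannwhitneyu(vals, null_vals, alternative="greater").pvalue
        )
        out[name] = {
            "quantiles": dict(zip(QUANTILES, np.quantile(vals, QUANTILES))),
            "n": len(vals),
            "p_greater_null": p,
        }
    return out


def topological_overlap(
    link: tuple[str, str], tans: dict[str, TAN]
) -> dict[str, float | None]:
    """Per-tissue neighborhood overlap of the link's genes.

    TO = |N(a) & N(b)| / min(|N(a)|, |N(b)|) over each tissue's TAN
    neighborhoods, with a and b excluded from each other's neighborhood;
    0 when either neighborhood is empty, None when a gene is outside the
    TAN's universe.
    """
    a, b = canonical_pair(*link)
    out: dict[str, float | None] = {}
    for tissue, tan in tans.items():
        universe = set(tan.gene_ids)
        if a not in universe or b not in universe:
            out[tissue] = None
            continue
        nbrs = tan.neighborhoods()
        na = nbrs.get(a, set()) - {a, b}
        nb = nbrs.get(b, set()) - {a, b}
        if not na or not nb:
            out[tissue] = 0.0
        else:
            out[tissue] = len(na & nb) / min(len(na), len(nb))
    return out
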