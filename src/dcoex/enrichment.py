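"""Link-based functional statistics.

Coexpression links tend to connect functionally related genes.  Three
statistics quantify this on a network plus a flat gene -> term map:

* shared-annotation likelihood ratio — how much more likely two connected
  genes are to share at least one term than two unconnected genes;
* per-term link enrichment — whether the genes of a term are joined by more
  links than size-matched random gene sets (empirical p, BH across terms);
* drop-out analysis — how many enriched terms lose enrichment when a
  designated link set (e.g. the pure links) is removed, compared to
  removing equally many random or expression-induced links.

The enrichment null samples gene sets, not rewired edges, by default; a
degree-preserving edge-rewiring null is available as an alternative for
networks whose hubs could bias the gene-sampling null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import AnnotationMap, canonical_pair

__all__ = [
    "shared_annotation_lr",
    "TermEnrichmentResult",
    "term_enrichment",
    "EnrichmentEngine",
    "enrich_terms",
    "DropoutResult",
    "dropout_analysis",
    "exclusive_enrichment",
    "rewire_null_counts",
]


def shared_annotation_lr(
    network_links: set[tuple[str, str]],
    annotations: AnnotationMap,
    gene_universe: set[str],
) -> float:
    """P(share >= 1 term | connected) / P(share >= 1 term | not connected).

    Pairs are enumerated over the annotated genes of the universe.  If no
    unconnected pair shares a term the ratio is infinite (reported as
    ``math.inf``); if every pair shares a term both probabilities are 1 and
    the ratio is 1.
    """
    genes = sorted(g for g in gene_universe if annotations.terms_of(g))
    if len(genes) < 2:
        raise ValueError("need at least 2 annotated genes")
    links = {canonical_pair(a, b) for a, b in network_links}
    n_conn = n_conn_share = n_unc = n_unc_share = 0
    terms = {g: annotations.terms_of(g) for g in genes}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            share = not terms[a].isdisjoint(terms[b])
            if (a, b) in links:
                n_conn += 1
                n_conn_share += share
            else:
                n_unc += 1
                n_unc_share += share
    if n_conn == 0:
        raise ValueError("no links among annotated universe genes")
    p_conn = n_conn_share / n_conn
    p_unc = n_unc_share / n_unc if n_unc else 0.0
    if p_unc == 0.0:
        return math.inf if p_conn > 0 else 1.0
    return p_conn / p_unc


def _links_within(links: set[tuple[str, str]], genes: set[str]) -> int:
    return sum(1 for a, b in links if a in genes and b in genes)


@dataclass
class TermEnrichmentResult:
    term: str
    observed: int
    null_mean: float
    null_sd: float
    p_emp: float
    fdr_pass: bool = False


def term_enrichment(
    network_links: set[tuple[str, str]],
    term_genes: set[str],
    gene_universe: list[str],
    n_null: int,
    rng: np.random.Generator,
    term: str = "",
) -> TermEnrichmentResult:
    """Within-term link count against size-matched random gene sets.

    observed = links with both endpoints annotated with the term; the null
    draws ``n_null`` gene sets of the same size uniformly from the network's
    gene universe and recounts.  p = (1 + #{null >= observed}) / (1 + n_null).
    """
    members = set(term_genes) & set(gene_universe)
    if len(members) < 2:
        raise ValueError(f"term {term!r}: fewer than 2 genes in the universe")
    links = {canonical_pair(a, b) for a, b in network_links}
    observed = _links_within(links, members)
    size = len(members)
    null = np.empty(n_null, dtype=int)
    universe = list(gene_universe)
    for s in range(n_null):
        draw = set(rng.choice(universe, size=size, replace=False))
        null[s] = _links_within(links, draw)
    p = (1.0 + int(np.count_nonzero(null >= observed))) / (1.0 + n_null)
    return TermEnrichmentResult(
        term=term,
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_emp=p,
    )


class EnrichmentEngine:
    """Batched per-term enrichment over many link subsets of one network.

    The random gene sets of the null are drawn once per term; for every term
    a boolean (draw x link) incidence table records which network links fall
    inside each draw.  Enrichment of any link subset is then a column sum,
    which makes drop-out analysis (hundreds of removal conditions on the
    same network) tractable at large ``n_null``.
    """

    def __init__(
        self,
        network_links: set[tuple[str, str]],
        annotations: AnnotationMap,
        gene_universe: list[str],
        n_null: int,
        rng: np.random.Generator,
        fdr: float = 0.01,
    ):
        self.links = sorted(canonical_pair(a, b) for a, b in network_links)
        self.link_pos = {l: i for i, l in enumerate(self.links)}
        self.fdr = fdr
        self.n_null = n_null
        gene_idx = {g: i for i, g in enumerate(gene_universe)}
        n_genes = len(gene_universe)
        la = np.array([gene_idx[a] for a, _ in self.links], dtype=np.int64)
        lb = np.array([gene_idx[b] for _, b in self.links], dtype=np.int64)

        self.terms: list[str] = []
        self.term_observed_mask: list[np.ndarray] = []  # per-term bool over links
        self.term_null_table: list[np.ndarray] = []  # per-term (n_null, n_links) bool
        uni_set = set(gene_universe)
        for term in sorted(annotations.terms):
            members = annotations.genes_of(term) & uni_set
            if len(members) < 2:
                continue  # skipped, not reported as p = 1
            midx = np.array([gene_idx[g] for g in members], dtype=np.int64)
            in_term = np.zeros(n_genes, dtype=bool)
            in_term[midx] = True
            obs_mask = in_term[la] & in_term[lb]
            # size-matched random gene sets, drawn once and reused
            keys = rng.random((n_null, n_genes))
            draws = np.argpartition(keys, len(members), axis=1)[:, : len(members)]
            member = np.zeros((n_null, n_genes), dtype=bool)
            member[np.arange(n_null)[:, None], draws] = True
            self.terms.append(term)
            self.term_observed_mask.append(obs_mask)
            self.term_null_table.append(member[:, la] & member[:, lb])

    def results(self, link_subset: set[tuple[str, str]] | None = None) -> list[TermEnrichmentResult]:
        """Enrichment of a link subset (default: the whole network), BH across terms."""
        if link_subset is None:
            present = np.ones(len(self.links), dtype=bool)
        else:
            present = np.zeros(len(self.links), dtype=bool)
            for l in link_subset:
                i = self.link_pos.get(canonical_pair(*l))
                if i is not None:
                    present[i] = True
        out = []
        for term, obs_mask, table in zip(
            self.terms, self.term_observed_mask, self.term_null_table
        ):
            observed = int(np.count_nonzero(obs_mask & present))
            null = (table & present).sum(axis=1)
            p = (1.0 + int(np.count_nonzero(null >= observed))) / (1.0 + self.n_null)
            out.append(
                TermEnrichmentResult(
                    term=term,
                    observed=observed,
                    null_mean=float(null.mean()),
                    null_sd=float(null.std()),
                    p_emp=p,
                )
            )
        if out:
            reject, *_ = multipletests([r.p_emp for r in out], alpha=self.fdr, method="fdr_bh")
            for r, rej in zip(out, reject):
                r.fdr_pass = bool(rej)
        return out

    def enriched(self, link_subset: set[tuple[str, str]] | None = None) -> set[str]:
        return {r.term for r in self.results(link_subset) if r.fdr_pass}


def enrich_terms(
    network_links: set[tuple[str, str]],
    annotations: AnnotationMap,
    gene_universe: list[str],
    n_null: int,
    rng: np.random.Generator,
    fdr: float = 0.01,
) -> list[TermEnrichmentResult]:
    """Enrichment over all terms with >= 2 universe genes, BH across terms.

    Terms with fewer than 2 genes in the universe are skipped (not reported
    as p = 1) to avoid diluting the FDR correction.
    """
    engine = EnrichmentEngine(network_links, annotations, gene_universe, n_null, rng, fdr=fdr)
    return engine.results()


def rewire_null_counts(
    network_links: set[tuple[str, str]],
    term_genes: set[str],
    n_null: int,
    rng: np.random.Generator,
    n_swaps_per_link: int = 10,
) -> np.ndarray:
    """Degree-preserving alternative null: within-term link counts of rewired networks.

    Each draw double-edge-swaps the network (~``n_swaps_per_link`` accepted
    swaps per link) and recounts the links inside ``term_genes``.
    """
    links = [canonical_pair(a, b) for a, b in network_links]
    members = set(term_genes)
    out = np.empty(n_null, dtype=int)
    for s in range(n_null):
        edges = list(links)
        edge_set = set(edges)
        target = n_swaps_per_link * len(edges)
        accepted = tries = 0
        while accepted < target and tries < 20 * target:
            tries += 1
            i, j = rng.integers(0, len(edges), size=2)
            if i == j:
                continue
            (a, b), (c, d) = edges[i], edges[j]
            if len({a, b, c, d}) < 4:
                continue
            e1, e2 = canonical_pair(a, d), canonical_pair(c, b)
            if e1 in edge_set or e2 in edge_set:
                continue
            edge_set -= {edges[i], edges[j]}
            edge_set |= {e1, e2}
            edges[i], edges[j] = e1, e2
            accepted += 1
        out[s] = _links_within(edge_set, members)
    return out


@dataclass
class DropoutResult:
    enriched_before: set[str]
    enriched_after_removal: set[str]
    dropout_count: int
    random_dropout_counts: list[int] = field(default_factory=list)
    induced_dropout_counts: list[int] = field(default_factory=list)
    p_vs_random: float | None = None
    p_vs_induced: float | None = None
    dropped_terms: set[str] = field(default_factory=set)
    sensitive_only_to_removal: set[str] = field(default_factory=set)


def dropout_analysis(
    network_links: set[tuple[str, str]],
    removal_set: set[tuple[str, str]],
    annotations: AnnotationMap,
    gene_universe: list[str],
    n_random: int,
    rng: np.random.Generator,
    induced_set: set[tuple[str, str]] | None = None,
    random_pool: set[tuple[str, str]] | None = None,
    n_null: int = 9999,
    fdr: float = 0.01,
) -> DropoutResult:
    """Which enriched terms depend on a particular link set.

    Enrichment is computed on the full network, then after removing the
    designated set, then after each of ``n_random`` removals of (a) a
    uniformly random link set of equal size (drawn from ``random_pool``,
    default all network links) and (b, if given) a random subset of the
    expression-induced links of equal size.  The same null draws are reused
    across conditions so comparisons differ only through the removed links.
    The empirical p values test whether the designated removal causes FEWER
    drop-outs than the competing removals (one-sided).  Terms enriched
    before but dropped only by the designated removal (never by a random
    one) are flagged ``sensitive_only_to_removal``.
    """
    links = {canonical_pair(a, b) for a, b in network_links}
    removal = {canonical_pair(a, b) for a, b in removal_set}
    if not removal <= links:
        raise ValueError("removal set is not a subset of the network links")
    engine = EnrichmentEngine(links, annotations, gene_universe, n_null, rng, fdr=fdr)

    before = engine.enriched()
    after = engine.enriched(links - removal)
    dropped = before - after
    size = len(removal)

    pool = sorted(links if random_pool is None else {canonical_pair(a, b) for a, b in random_pool} & links)
    random_counts: list[int] = []
    random_dropped_union: set[str] = set()
    for _ in range(n_random):
        idx = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        after_r = engine.enriched(links - {pool[i] for i in idx})
        dr = before - after_r
        random_counts.append(len(dr))
        random_dropped_union |= dr

    induced_counts: list[int] = []
    if induced_set is not None:
        induced = sorted({canonical_pair(a, b) for a, b in induced_set} & links)
        k = min(size, len(induced))
        if k > 0:
            for _ in range(n_random):
                idx = rng.choice(len(induced), size=k, replace=False)
                after_i = engine.enriched(links - {induced[i] for i in idx})
                induced_counts.append(len(before - after_i))

    def one_sided_p(counts: list[int]) -> float | None:
        if not counts:
            return None
        return (1.0 + sum(c <= len(dropped) for c in counts)) / (1.0 + len(counts))

    return DropoutResult(
        enriched_before=before,
        enriched_after_removal=after,
        dropout_count=len(dropped),
        random_dropout_counts=random_counts,
        induced_dropout_counts=induced_counts,
        p_vs_random=one_sided_p(random_counts),
        p_vs_induced=one_sided_p(induced_counts),
        dropped_terms=dropped,
        sensitive_only_to_removal=dropped - random_dropped_union,
    )


def exclusive_enrichment(enriched_by_tissue: dict[str, set[str]]) -> dict[str, set[str]]:
    """Terms enriched in exactly one tissue's network."""
    out: dict[str, set[str]] = {}
    for tissue, terms in enriched_by_tissue.items():
        others: set[str] = set()
        for other, oterms in enriched_by_tissue.items():
            if other != tissue:
                others |= oterms
        out[tissue] = terms - others
    return out
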