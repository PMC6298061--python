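"""Synthetic multi-tissue expression collections with planted link classes.

The generator emulates the structure of a multi-cohort compendium: several
tissues, several independent datasets per tissue, log-scale expression with
a bimodal expressed/not-expressed mixture, correlation structure that
differs by tissue, and variance that shrinks with expression level.

Three classes of gene pairs are planted, matching the extreme cases of how
mean expression can relate to differential coexpression:

* ``pure`` — both genes expressed everywhere; the pair is correlated
  (``rho_target``) only in datasets of its target tissue.
* ``induced1`` — one gene is expressed only in the target tissue; the pair
  is correlated there and decorrelated elsewhere because the off gene is
  pure noise.
* ``induced2`` — both genes are expressed only in the target tissue.

Samples are drawn from a Gaussian copula on the log scale: each planted
pair is its own 2x2 correlation block (trivially positive definite), all
other genes are independent, so the generative correlation/mean structure
is exactly controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import child_rng
from .core import AnnotationMap, ExpressionDataset, canonical_pair

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "PlantedLink",
    "simulate_collection",
    "expected_link_class",
    "make_annotations",
]

LINK_CLASSES = ("pure", "induced1", "induced2")


@dataclass(frozen=True)
class PlantedLink:
    gene_a: str
    gene_b: str
    target_tissue: str
    link_class: str


@dataclass
class GroundTruth:
    """Planted links with class labels, keyed by canonical pair."""

    links: list[PlantedLink]
    _by_pair: dict[tuple[str, str], PlantedLink] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        by_pair = {}
        for pl in self.links:
            key = canonical_pair(pl.gene_a, pl.gene_b)
            if key in by_pair:
                raise ValueError(f"pair {key} planted twice")
            by_pair[key] = pl
        self._by_pair = by_pair

    def lookup(self, gene_a: str, gene_b: str) -> PlantedLink | None:
        return self._by_pair.get(canonical_pair(gene_a, gene_b))

    def pairs_of(self, link_class: str | None = None, tissue: str | None = None) -> set[tuple[str, str]]:
        return {
            canonical_pair(pl.gene_a, pl.gene_b)
            for pl in self.links
            if (link_class is None or pl.link_class == link_class)
            and (tissue is None or pl.target_tissue == tissue)
        }


def expected_link_class(truth: GroundTruth, gene_a: str, gene_b: str) -> str:
    """Class of a pair under the ground truth; unplanted pairs are 'background'."""
    pl = truth.lookup(gene_a, gene_b)
    return pl.link_class if pl is not None else "background"


@dataclass
class SimulationDesign:
    """Parameters of the synthetic collection.

    Defaults mirror a realistic compendium: 5 tissues with 7-15 datasets
    each, 20-120 samples per dataset, log2 means of ~4 for silent and ~9 for
    expressed genes, unit-SD noise, and planted correlation 0.7.
    """

    n_tissues: int = 5
    datasets_per_tissue: tuple[int, int] | list[int] = (7, 15)
    samples_per_dataset: tuple[int, int] = (20, 120)
    n_genes: int = 600
    n_planted_pure: int = 20
    n_planted_induced1: int = 20
    n_planted_induced2: int = 20
    module_size: int = 10  # gene-block size for synthetic annotation terms
    rho_target: float = 0.7
    rho_background: float = 0.0
    off_mean: float = 4.0
    on_mean: float = 9.0
    noise_sd: float = 1.0
    mean_variance_coupling: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_target < 1.0:
            raise ValueError("rho_target must be in (0, 1)")
        if not -1.0 < self.rho_background < 1.0:
            raise ValueError("rho_background must be in (-1, 1)")
        n_planted_genes = 2 * (self.n_planted_pure + self.n_planted_induced1 + self.n_planted_induced2)
        if n_planted_genes > self.n_genes:
            raise ValueError("not enough genes for the planted links")
        if self.noise_sd < 0 or self.mean_variance_coupling < 0:
            raise ValueError("noise_sd and mean_variance_coupling must be nonnegative")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


def _dataset_counts(design: SimulationDesign, rng: np.random.Generator) -> list[int]:
    d = design.datasets_per_tissue
    if isinstance(d, (tuple,)) and len(d) == 2:
        lo, hi = d
        return [int(rng.integers(lo, hi + 1)) for _ in range(design.n_tissues)]
    counts = list(d)
    if len(counts) != design.n_tissues:
        raise ValueError("datasets_per_tissue list length must equal n_tissues")
    return [int(c) for c in counts]


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _plant(design: SimulationDesign) -> tuple[GroundTruth, list[str]]:
    """Allocate disjoint gene pairs to planted classes, round-robin over tissues."""
    genes = _gene_names(design.n_genes)
    tissues = design.tissues
    links: list[PlantedLink] = []
    cursor = 0
    tissue_cursor = 0
    for link_class, count in (
        ("pure", design.n_planted_pure),
        ("induced1", design.n_planted_induced1),
        ("induced2", design.n_planted_induced2),
    ):
        for _ in range(count):
            a, b = genes[cursor], genes[cursor + 1]
            cursor += 2
            links.append(PlantedLink(a, b, tissues[tissue_cursor % len(tissues)], link_class))
            tissue_cursor += 1
    return GroundTruth(links), genes


def _gene_means(
    design: SimulationDesign, truth: GroundTruth, genes: list[str], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-tissue vector of population means for every gene.

    Planted genes sit exactly at on/off means so the expressed/silent split is
    unambiguous; background genes get a gene-level mean drawn uniformly in
    [off_mean, on_mean + 2], identical across tissues (no planted confound).
    """
    tissues = design.tissues
    gi = {g: k for k, g in enumerate(genes)}
    means = np.empty((len(tissues), len(genes)))
    background = rng.uniform(design.off_mean, design.on_mean + 2.0, size=len(genes))
    means[:] = background[None, :]
    for pl in truth.links:
        t = tissues.index(pl.target_tissue)
        a, b = gi[pl.gene_a], gi[pl.gene_b]
        if pl.link_class == "pure":
            means[:, a] = design.on_mean
            means[:, b] = design.on_mean
        elif pl.link_class == "induced1":
            means[:, a] = design.off_mean
            means[t, a] = design.on_mean
            means[:, b] = design.on_mean
        else:  # induced2
            means[:, [a, b]] = design.off_mean
            means[t, a] = design.on_mean
            means[t, b] = design.on_mean
    return {t: means[i] for i, t in enumerate(tissues)}


def _sd_for_mean(design: SimulationDesign, mu: np.ndarray) -> np.ndarray:
    """Mean-variance coupling: silent genes keep only floor noise.

    SD interpolates from ``noise_sd * sqrt(coupling)`` at ``off_mean`` up to
    ``noise_sd`` at ``on_mean`` (clipped outside), so off-state variance is
    reduced by the coupling factor and sample correlations there are noise.
    """
    c = design.mean_variance_coupling
    frac = np.clip((mu - design.off_mean) / (design.on_mean - design.off_mean), 0.0, 1.0)
    return design.noise_sd * np.sqrt(c + (1.0 - c) * frac)


def simulate_collection(design: SimulationDesign) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Draw the full collection.

    Returns one :class:`ExpressionDataset` per (tissue, replicate) plus the
    planted ground truth.  Each planted pair forms its own 2x2 correlation
    block; the block is checked to be positive definite before sampling.
    """
    rho = design.rho_target
    for name, r in (("rho_target", rho), ("rho_background", design.rho_background)):
        if abs(r) >= 1.0:
            raise ValueError(f"correlation block for {name}={r} is not positive definite")

    truth, genes = _plant(design)
    gi = {g: k for k, g in enumerate(genes)}
    rng_struct = child_rng(design.rng_seed, "design")
    rng_data = child_rng(design.rng_seed, "samples")
    counts = _dataset_counts(design, rng_struct)
    tissue_means = _gene_means(design, truth, genes, rng_struct)

    lo_s, hi_s = design.samples_per_dataset
    datasets: list[ExpressionDataset] = []
    for t_idx, tissue in enumerate(design.tissues):
        mu = tissue_means[tissue]
        sd = _sd_for_mean(design, mu)
        for rep in range(counts[t_idx]):
            n = int(rng_data.integers(lo_s, hi_s + 1))
            z = rng_data.standard_normal((len(genes), n))
            # correlate planted pairs: mix the partner's latent noise in
            for pl in truth.links:
                r = rho if pl.target_tissue == tissue else design.rho_background
                if pl.link_class in ("induced1", "induced2") and pl.target_tissue != tissue:
                    r = 0.0  # off-state gene carries no shared signal
                if r != 0.0:
                    a, b = gi[pl.gene_a], gi[pl.gene_b]
                    z[b] = r * z[a] + math.sqrt(1.0 - r * r) * z[b]
            matrix = mu[:, None] + sd[:, None] * z
            datasets.append(
                ExpressionDataset(
                    dataset_id=f"{tissue}_d{rep + 1}",
                    tissue=tissue,
                    gene_ids=list(genes),
                    matrix=matrix,
                )
            )
    return datasets, truth


def make_annotations(
    design: SimulationDesign,
    truth: GroundTruth,
    rng: np.random.Generator,
    n_background_terms: int = 30,
    aligned: bool = True,
) -> AnnotationMap:
    """Synthetic gene -> term map for enrichment tests.

    With ``aligned=True``, one term per (target tissue, link class) collects
    exactly the genes of those planted links, so term link structure mirrors
    the planted links; background terms are random gene blocks of
    ``module_size`` genes and carry no link structure.
    """
    genes = _gene_names(design.n_genes)
    pairs: list[tuple[str, str]] = []
    if aligned:
        groups: dict[tuple[str, str], set[str]] = {}
        for pl in truth.links:
            groups.setdefault((pl.target_tissue, pl.link_class), set()).update(
                (pl.gene_a, pl.gene_b)
            )
        for (tissue, link_class), members in sorted(groups.items()):
            term = f"term_{tissue}_{link_class}"
            pairs.extend((g, term) for g in sorted(members))
    for i in range(n_background_terms):
        block = rng.choice(genes, size=min(design.module_size, len(genes)), replace=False)
        pairs.extend((g, f"term_rand{i + 1}") for g in block)
    return AnnotationMap(pairs)
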