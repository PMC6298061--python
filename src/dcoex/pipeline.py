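"""End-to-end orchestration of the differential-coexpression pipeline.

Stages: harmonize genes -> mark expressed genes per tissue -> per-dataset
correlation networks -> tissue-aggregated networks (TAN) -> binned rank
transform and tissue-specificity scores with pseudo-tissue FDR -> tissue-
specific networks (TSN) -> per-link expression model and pure/induced
classification.  Every stage is importable on its own; this module wires
them together for the analysis scripts, the tests and the acceptance run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import ExpressionDataset
from .expression_model import LinkModelFit, classify_links, fit_link_model, null_r2
from .networks import (
    TAN,
    DatasetCorrelations,
    build_tissue_tan,
    correlation_network,
    harmonize_genes,
    mark_expressed,
)
from .specificity import (
    TsnSelection,
    make_pseudo_tissues,
    sb_matrix,
    select_tsn,
    tss_from_sb,
    tss_fdr_curve,
    tss_wilcoxon,
)

__all__ = ["PipelineResult", "run_network_stage", "run_tss_stage", "run_model_stage", "run_pipeline"]


@dataclass
class PipelineResult:
    config: RunConfig
    gene_universe: list[str]
    datasets: list[ExpressionDataset]
    tissues: list[str]
    expressed: dict[str, set[str]]
    stores: list[DatasetCorrelations]
    tans: dict[str, TAN]
    links: list[tuple[str, str]]
    sb: np.ndarray
    tss_by_tissue: dict[str, np.ndarray]
    tan_membership: dict[str, np.ndarray]
    curves: dict
    tsn: TsnSelection
    fits: list[LinkModelFit] = field(default_factory=list)
    classes: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def dataset_tissues(self) -> list[str]:
        return [ds.tissue for ds in self.datasets]

    def tsn_tissue_of(self, link: tuple[str, str]) -> list[str]:
        return [t for t, links in self.tsn.selected.items() if link in links]

    def tss_table(self, wilcoxon: bool = False) -> pd.DataFrame:
        """Long-format TSS table (one row per TAN link x tissue)."""
        rows = []
        tissue_list = self.dataset_tissues
        for t in self.tissues:
            member = self.tan_membership[t]
            for i in np.flatnonzero(member):
                a, b = self.links[i]
                row = {"gene_a": a, "gene_b": b, "tissue": t,
                       "tss": float(self.tss_by_tissue[t][i])}
                if wilcoxon:
                    row["wilcoxon_p"] = tss_wilcoxon(self.sb[i], tissue_list, t)[0]
                rows.append(row)
        return pd.DataFrame(rows)

    def linkset_table(self) -> pd.DataFrame:
        """Final link table in the link-TSV dialect (one row per TSN link x tissue)."""
        fit_by_link = {f.link: f for f in self.fits}
        rows = []
        link_pos = {l: i for i, l in enumerate(self.links)}
        for t in self.tissues:
            for link in sorted(self.tsn.selected[t]):
                f = fit_by_link.get(link)
                rows.append(
                    {
                        "gene_a": link[0],
                        "gene_b": link[1],
                        "tissue": t,
                        "tss": float(self.tss_by_tissue[t][link_pos[link]]),
                        "tss_fdr_pass": True,
                        "r2": f.r2 if f is not None else np.nan,
                        "link_class": self.classes.get(link, pd.NA),
                    }
                )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "tissue", "tss",
                                           "tss_fdr_pass", "r2", "link_class"])


def run_network_stage(datasets: list[ExpressionDataset], config: RunConfig):
    """Harmonize, mark expressed genes per tissue, correlate, and build TANs."""
    universe, datasets = harmonize_genes(datasets)
    tissues = sorted({ds.tissue for ds in datasets})
    expressed: dict[str, set[str]] = {}
    for t in tissues:
        tissue_ds = [ds for ds in datasets if ds.tissue == t]
        expressed[t], _ = mark_expressed(
            tissue_ds,
            method=config.expressed_threshold_method,
            threshold=config.expressed_fixed_threshold
            if config.expressed_threshold_method == "fixed"
            else None,
            random_state=config.rng_seed & 0x7FFFFFFF,
        )
    stores = [correlation_network(ds, expressed[ds.tissue]) for ds in datasets]
    tans = {}
    for t in tissues:
        tissue_stores = [s for s in stores if s.tissue == t]
        tans[t] = build_tissue_tan(
            tissue_stores,
            percentile=config.tan_percentile,
            fdr=config.tan_fdr,
            mode=config.tan_fdr_mode,
        )
    return universe, datasets, tissues, expressed, stores, tans


def run_tss_stage(
    datasets: list[ExpressionDataset],
    stores: list[DatasetCorrelations],
    tans: dict[str, TAN],
    tissues: list[str],
    config: RunConfig,
):
    """Score every TAN link in every tissue and select tissue-specific links."""
    links = sorted(set().union(*(tan.links_as_pairs() for tan in tans.values())) or set())
    if not links:
        raise ValueError("all TANs are empty; nothing to score")
    sb = sb_matrix(links, stores, n_bins=config.n_bins)
    dataset_tissues = [ds.tissue for ds in datasets]
    ds_tissue_map = {ds.dataset_id: ds.tissue for ds in datasets}
    dataset_ids = [ds.dataset_id for ds in datasets]

    tss_by_tissue = {}
    tan_membership = {}
    curves = {}
    for t in tissues:
        mask = np.array([tt == t for tt in dataset_tissues])
        tss_by_tissue[t] = tss_from_sb(sb, mask)
        tan_links = tans[t].links_as_pairs()
        tan_membership[t] = np.array([l in tan_links for l in links])

    for t in tissues:
        member = tan_membership[t]
        if not member.any():
            # an empty TAN yields no real scores; give a degenerate curve
            curves[t] = tss_fdr_curve(np.array([0.0]), [np.array([1.0])])
            continue
        rng = config.rng(f"pseudo:{t}")
        pseudo = make_pseudo_tissues(ds_tissue_map, t, config.n_pseudo, rng)
        sb_member = sb[member]
        pseudo_tss = []
        for pt in pseudo:
            pmask = np.array([d in pt.dataset_ids for d in dataset_ids])
            pseudo_tss.append(tss_from_sb(sb_member, pmask))
        curves[t] = tss_fdr_curve(tss_by_tissue[t][member], pseudo_tss)

    tsn = select_tsn(
        links, tss_by_tissue, tan_membership, curves,
        fdr_target=config.tss_fdr, other_max=config.tss_other_max,
    )
    return links, sb, tss_by_tissue, tan_membership, curves, tsn


def run_model_stage(
    datasets: list[ExpressionDataset],
    stores: list[DatasetCorrelations],
    links: list[tuple[str, str]],
    sb: np.ndarray,
    tsn: TsnSelection,
    expressed: dict[str, set[str]],
    config: RunConfig,
):
    """Fit the expression model on every TSN link and classify pure vs induced."""
    link_pos = {l: i for i, l in enumerate(links)}
    gene_row = {g: r for r, g in enumerate(datasets[0].gene_ids)}
    e_matrix = np.column_stack([ds.mean_expression for ds in datasets])  # genes x K
    rng = config.rng("shuffles")

    tsn_links = sorted(tsn.all_links())
    fits: list[LinkModelFit] = []
    for link in tsn_links:
        a, b = link
        i = link_pos[link]
        if config.model_response == "binned":
            y = sb[i]
        else:
            y = np.array(
                [
                    s.corr(a, b) if (s.has_gene(a) and s.has_gene(b)) else 0.0
                    for s in stores
                ]
            )
        e_i = e_matrix[gene_row[a]]
        e_j = e_matrix[gene_row[b]]
        evaluable = np.array([s.has_gene(a) and s.has_gene(b) for s in stores])
        fit = fit_link_model(link, y, e_i, e_j, evaluable=evaluable)
        if fit.valid:
            fit.null_r2s = null_r2(y, e_i, e_j, config.n_shuffles, rng)
        fits.append(fit)
    classes = classify_links(fits, expressed, config.r2_fdr)
    return fits, classes


def run_pipeline(datasets: list[ExpressionDataset], config: RunConfig) -> PipelineResult:
    universe, datasets, tissues, expressed, stores, tans = run_network_stage(datasets, config)
    links, sb, tss_by_tissue, membership, curves, tsn = run_tss_stage(
        datasets, stores, tans, tissues, config
    )
    fits, classes = run_model_stage(datasets, stores, links, sb, tsn, expressed, config)
    return PipelineResult(
        config=config,
        gene_universe=universe,
        datasets=datasets,
        tissues=tissues,
        expressed=expressed,
        stores=stores,
        tans=tans,
        links=links,
        sb=sb,
        tss_by_tissue=tss_by_tissue,
        tan_membership=membership,
        curves=curves,
        tsn=tsn,
        fits=fits,
        classes=classes,
    )
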