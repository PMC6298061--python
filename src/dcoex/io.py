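"""On-disk formats.

* Expression TSV: first column ``gene_id``, remaining columns samples.
* Metadata TSV: columns ``dataset_id``, ``tissue``, ``filename``.
* Annotation TSV: two columns ``gene_id``, ``term_id``, one pair per line.
* Link TSV: ``gene_a, gene_b, tissue, tss, tss_fdr_pass, r2, link_class``
  with ``gene_a < gene_b``.

All writers round-trip losslessly through the matching reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AnnotationMap, ExpressionDataset, canonical_pair

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_expression_collection",
    "write_expression_collection",
    "read_annotations",
    "write_annotations",
    "LINK_COLUMNS",
    "write_linkset",
    "read_linkset",
    "write_ground_truth",
    "read_ground_truth",
]

LINK_COLUMNS = ["gene_a", "gene_b", "tissue", "tss", "tss_fdr_pass", "r2", "link_class"]


def read_expression_tsv(path: str | Path, dataset_id: str, tissue: str) -> ExpressionDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    genes = df["gene_id"].tolist()
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate gene ID {dup.iloc[0]!r}")
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    return ExpressionDataset(dataset_id=dataset_id, tissue=tissue, gene_ids=genes, matrix=matrix)


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> None:
    cols = [f"s{i + 1}" for i in range(dataset.n_samples)]
    df = pd.DataFrame(dataset.matrix, columns=cols)
    df.insert(0, "gene_id", dataset.gene_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_expression_collection(metadata_path: str | Path, data_dir: str | Path) -> list[ExpressionDataset]:
    """Read a whole collection: metadata row per dataset, one TSV each.

    Genes are kept per-dataset here; harmonization to a common universe is a
    separate, explicit step in the network-construction stage.
    """
    metadata_path = Path(metadata_path)
    data_dir = Path(data_dir)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"dataset_id", "tissue", "filename"}
    if not required.issubset(meta.columns):
        raise ValueError(f"{metadata_path}: metadata needs columns {sorted(required)}")
    datasets = []
    for row in meta.itertuples(index=False):
        datasets.append(
            read_expression_tsv(data_dir / row.filename, dataset_id=row.dataset_id, tissue=row.tissue)
        )
    return datasets


def write_expression_collection(datasets: Sequence[ExpressionDataset], out_dir: str | Path) -> Path:
    """Write every dataset plus the metadata table; returns the metadata path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ds in datasets:
        fname = f"{ds.dataset_id}.tsv"
        write_expression_tsv(ds, out_dir / fname)
        rows.append({"dataset_id": ds.dataset_id, "tissue": ds.tissue, "filename": fname,
                     "n_samples": ds.n_samples})
    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(rows).to_csv(meta_path, sep="\t", index=False)
    return meta_path


def read_annotations(path: str | Path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        raise ValueError(f"{path}: annotation columns must be gene_id, term_id")
    return AnnotationMap(zip(df["gene_id"], df["term_id"]))


def write_annotations(annotations: AnnotationMap, path: str | Path) -> None:
    pd.DataFrame(list(annotations.items()), columns=["gene_id", "term_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_ground_truth(truth, path: str | Path) -> None:
    """Planted-link table: gene_a, gene_b, target_tissue, link_class."""
    rows = [
        {
            "gene_a": min(pl.gene_a, pl.gene_b),
            "gene_b": max(pl.gene_a, pl.gene_b),
            "target_tissue": pl.target_tissue,
            "link_class": pl.link_class,
        }
        for pl in truth.links
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "target_tissue", "link_class"]).to_csv(
        path, sep="\t", index=False
    )


def read_ground_truth(path: str | Path):
    from .simulate import GroundTruth, PlantedLink

    df = pd.read_csv(path, sep="\t", dtype=str)
    return GroundTruth(
        [PlantedLink(r.gene_a, r.gene_b, r.target_tissue, r.link_class) for r in df.itertuples()]
    )


def write_linkset(links: pd.DataFrame, path: str | Path) -> None:
    """Write a link table in the canonical dialect.

    Pairs are re-canonicalized (gene_a < gene_b) on the way out; missing
    attribute columns are filled with NA so the header is stable.
    """
    df = links.copy()
    for col in LINK_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    if len(df):
        pairs = [canonical_pair(a, b) for a, b in zip(df["gene_a"], df["gene_b"])]
        df["gene_a"] = [p[0] for p in pairs]
        df["gene_b"] = [p[1] for p in pairs]
        df = df.sort_values(["tissue", "gene_a", "gene_b"], kind="mergesort")
    df[LINK_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_linkset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene_a": str, "gene_b": str, "tissue": str, "link_class": str},
    )
    if list(df.columns) != LINK_COLUMNS:
        raise ValueError(f"{path}: unexpected link columns {list(df.columns)}")
    if "tss_fdr_pass" in df and df["tss_fdr_pass"].notna().any():
        df["tss_fdr_pass"] = df["tss_fdr_pass"].astype(bool)
    return df
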