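"""Per-link linear model of coexpression on mean expression.

For a link (g_i, g_j) the binned correlation across the K datasets is
modeled as

    bincorr(i, j, k) = beta0 + beta1 * (e_ik + e_jk) + beta2 * |e_ik - e_jk|

where e_ik is gene i's mean log expression in dataset k.  beta1 captures
the predictive value of the genes' total expression, beta2 of their
difference; the absolute value keeps the model symmetric in the two genes.
R^2 measures how much of the link's cross-dataset coexpression profile is
explained by expression level alone.  Significance is judged against a
null built by shuffling each gene's expression vector across datasets
(independently per gene) and refitting, with Benjamini-Hochberg control
across links.

Tissue-specific links whose R^2 is NOT significantly above the null and
whose genes are expressed in every tissue are "pure" differential
coexpression; links with a gene silent in some tissue are
expression-induced; the remainder are expression-associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LinkModelFit",
    "ols_expression_model",
    "fit_link_model",
    "null_r2",
    "classify_links",
]


def _design(e_i: np.ndarray, e_j: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(e_i), e_i + e_j, np.abs(e_i - e_j)])


def ols_expression_model(y: np.ndarray, e_i: np.ndarray, e_j: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of the response on (1, e_i + e_j, |e_i - e_j|); returns (betas, R^2).

    A constant response (zero total sum of squares) is defined to have
    R^2 = 0 — expression then explains nothing that needed explaining.
    """
    y = np.asarray(y, dtype=float)
    X = _design(np.asarray(e_i, float), np.asarray(e_j, float))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0.0:
        return beta, 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return beta, float(np.clip(r2, 0.0, 1.0))


@dataclass
class LinkModelFit:
    link: tuple[str, str]
    beta0: float
    beta1: float
    beta2: float
    r2: float
    n_obs: int
    valid: bool = True
    null_r2s: np.ndarray = field(default_factory=lambda: np.array([]))
    p_emp: float = float("nan")
    r2_fdr_pass: bool = False


def fit_link_model(
    link: tuple[str, str],
    y: np.ndarray,
    e_i: np.ndarray,
    e_j: np.ndarray,
    evaluable: np.ndarray | None = None,
) -> LinkModelFit:
    """Fit the expression model for one link across all K datasets (tissues pooled).

    ``evaluable`` marks datasets where the link's correlation is actually
    measured (both genes in the expressed pool); datasets where it is not
    enter the fit with the SB floor, but at least 4 evaluable datasets are
    required (3 parameters + 1 df) for the fit to be considered valid.
    Invalid fits are excluded from classification downstream.
    """
    y = np.asarray(y, dtype=float)
    n_eval = int(np.count_nonzero(evaluable)) if evaluable is not None else len(y)
    beta, r2 = ols_expression_model(y, e_i, e_j)
    return LinkModelFit(
        link=link,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        r2=r2,
        n_obs=len(y),
        valid=n_eval >= 4,
    )


def null_r2(
    y: np.ndarray,
    e_i: np.ndarray,
    e_j: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shuffle null for R^2.

    Each draw permutes the two genes' dataset-indexed mean-expression
    vectors independently (breaking any expression-correlation coupling
    while preserving each gene's expression distribution) and refits.
    """
    y = np.asarray(y, dtype=float)
    e_i = np.asarray(e_i, dtype=float)
    e_j = np.asarray(e_j, dtype=float)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        pi = rng.permutation(len(e_i))
        pj = rng.permutation(len(e_j))
        _, out[s] = ols_expression_model(y, e_i[pi], e_j[pj])
    return out


def empirical_p(real: float, null: np.ndarray) -> float:
    """Permutation p with the +1 correction: (1 + #{null >= real}) / (1 + N)."""
    null = np.asarray(null, dtype=float)
    return (1.0 + int(np.count_nonzero(null >= real))) / (1.0 + null.size)


def classify_links(
    fits: list[LinkModelFit],
    expressed_by_tissue: dict[str, set[str]],
    r2_fdr: float,
) -> dict[tuple[str, str], str]:
    """Assign pure / induced_offgene / expression_associated to fitted links.

    * ``induced_offgene``: at least one gene is not expressed in at least one
      tissue (coexpression loss is attributable to absent expression).
    * ``pure``: both genes expressed in all tissues AND R^2 not significantly
      above the shuffle null (BH at ``r2_fdr``).
    * ``expression_associated``: the rest.

    Links with invalid fits are never called pure (conservative) and come
    out expression_associated unless an off gene makes them induced.
    """
    for f in fits:
        if f.valid and np.isnan(f.p_emp):
            f.p_emp = empirical_p(f.r2, f.null_r2s)
    testable = [f for f in fits if f.valid and not np.isnan(f.p_emp)]
    if testable:
        reject, *_ = multipletests([f.p_emp for f in testable], alpha=r2_fdr, method="fdr_bh")
        for f, rej in zip(testable, reject):
            f.r2_fdr_pass = bool(rej)

    classes: dict[tuple[str, str], str] = {}
    for f in fits:
        a, b = f.link
        expressed_everywhere = all(
            a in expressed and b in expressed for expressed in expressed_by_tissue.values()
        )
        if not expressed_everywhere:
            classes[f.link] = "induced_offgene"
        elif f.valid and not f.r2_fdr_pass:
            classes[f.link] = "pure"
        else:
            classes[f.link] = "expression_associated"
    return classes
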