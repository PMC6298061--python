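"""Tissue-specificity scoring of coexpression links.

Raw Pearson correlations are not comparable across datasets, so each
dataset's correlations are first mapped to their quantile bin among all of
that dataset's expressed-pair correlations ("binned rank transform", SB).
With ``n_bins = 1000`` the bins are per-milles; SB is expressed on the
(0, 1] scale.  Negative correlations carry no signal for presence of
coexpression and would act as outliers, so they are floored to SB = 0.5
(approximately zero correlation), as is any positive correlation ranking
below the median.

The tissue-specificity score (TSS) of a link for a target tissue is the
mean positive difference between its SB values in the target tissue's
datasets and its SB values in all other datasets:

    TSS = sum_{p in target} sum_{q in others} max(SB_p - SB_q, 0) / (|target| * |others|)

TSS lives in [0, 0.5].  Its null distribution is estimated from
"pseudo-tissues": random, tissue-balanced subsets of datasets of the same
size as the real tissue.  The FDR at a score cut is the pseudo-tissue mean
exceedance count over the real exceedance count (capped at 1 and made
monotone by a running minimum from high scores downward).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import canonical_pair
from .networks import DatasetCorrelations

__all__ = [
    "sb_values",
    "sb_all",
    "sb_matrix",
    "tss_from_sb",
    "tss",
    "tss_wilcoxon",
    "PseudoTissue",
    "make_pseudo_tissues",
    "TssFdrCurve",
    "tss_fdr_curve",
    "TsnSelection",
    "select_tsn",
]


def _bin_of_quantile(q: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize quantiles in (0, 1] into n_bins equal steps: ceil(q * n_bins) / n_bins."""
    b = np.ceil(q * n_bins) / n_bins
    return np.clip(b, 1.0 / n_bins, 1.0)


def sb_values(store: DatasetCorrelations, corrs: np.ndarray, n_bins: int = 1000) -> np.ndarray:
    """SB of given correlation values within a dataset's all-pairs distribution.

    The quantile of ``r`` is the fraction of the dataset's pair correlations
    that are <= r.  Negative correlations are hard-assigned SB = 0.5; all
    others are floored at 0.5.
    """
    corrs = np.asarray(corrs, dtype=float)
    counts = np.searchsorted(store.sorted_values, corrs, side="right")
    q = counts / store.n_pairs
    sb = np.maximum(_bin_of_quantile(q, n_bins), 0.5)
    return np.where(corrs < 0.0, 0.5, sb)


def sb_all(store: DatasetCorrelations, n_bins: int = 1000) -> np.ndarray:
    """SB for every pair of the dataset (condensed order)."""
    return sb_values(store, store.values, n_bins)


def sb_matrix(
    links: list[tuple[str, str]],
    stores: list[DatasetCorrelations],
    n_bins: int = 1000,
) -> np.ndarray:
    """links x datasets SB matrix.

    A link is evaluable in a dataset only when both genes are in that
    dataset's expressed-pair pool; otherwise it takes the no-coexpression
    floor SB = 0.5.
    """
    L, K = len(links), len(stores)
    out = np.full((L, K), 0.5)
    for k, store in enumerate(stores):
        rows = [
            (r, a, b)
            for r, (a, b) in enumerate(links)
            if store.has_gene(a) and store.has_gene(b)
        ]
        if not rows:
            continue
        idx = store.pair_indices([(a, b) for _, a, b in rows])
        vals = store.values[idx]
        out[[r for r, _, _ in rows], k] = sb_values(store, vals, n_bins)
    return out


def tss_from_sb(sb: np.ndarray, target_mask: np.ndarray) -> np.ndarray:
    """TSS for every link row of an SB matrix given a target-dataset mask.

    Vectorized double sum of positive SB differences (target vs rest).
    """
    sb = np.atleast_2d(sb)
    target_mask = np.asarray(target_mask, dtype=bool)
    if target_mask.sum() == 0:
        raise ValueError("target tissue has no datasets")
    if (~target_mask).sum() == 0:
        raise ValueError("no datasets outside the target tissue")
    t = sb[:, target_mask]
    o = sb[:, ~target_mask]
    diff = t[:, :, None] - o[:, None, :]
    return np.maximum(diff, 0.0).mean(axis=(1, 2))


def tss(sb_row: np.ndarray, dataset_tissues: list[str], target_tissue: str) -> float:
    """TSS of a single link from its per-dataset SB values."""
    mask = np.array([t == target_tissue for t in dataset_tissues])
    return float(tss_from_sb(sb_row[None, :], mask)[0])


def tss_wilcoxon(
    sb_row: np.ndarray, dataset_tissues: list[str], target_tissue: str
) -> tuple[float, bool]:
    """One-sided Wilcoxon rank-sum p (target SB > others).

    Exact distribution when the combined sample is <= 20 and tie-free, the
    tie-corrected normal approximation otherwise.  Returns ``(p, ok)``;
    with fewer than 2 datasets on either side there is no meaningful test
    and ``(1.0, False)`` is returned.
    """
    mask = np.array([t == target_tissue for t in dataset_tissues])
    x = np.asarray(sb_row, dtype=float)[mask]
    y = np.asarray(sb_row, dtype=float)[~mask]
    if len(x) < 2 or len(y) < 2:
        return 1.0, False
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return 1.0, True  # fully tied: no evidence either way
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.pvalue), True


@dataclass(frozen=True)
class PseudoTissue:
    """A tissue-sized, tissue-balanced random subset of dataset IDs (a TSS null)."""

    id: str
    dataset_ids: frozenset[str]


def make_pseudo_tissues(
    dataset_tissues: dict[str, str],
    mirror_tissue: str,
    n_pseudo: int,
    rng: np.random.Generator,
) -> list[PseudoTissue]:
    """Draw ``n_pseudo`` pseudo-tissues mirroring one tissue's dataset count.

    Each draw samples datasets without replacement, stratified so that every
    real tissue contributes floor or ceil of size/T datasets (the remainder
    tissues chosen uniformly at random).  If a tissue cannot fill its quota
    the deficit is redistributed to tissues with spare datasets, with a
    warning.
    """
    tissues = sorted(set(dataset_tissues.values()))
    by_tissue = {t: sorted(d for d, tt in dataset_tissues.items() if tt == t) for t in tissues}
    if mirror_tissue not in by_tissue:
        raise ValueError(f"unknown tissue {mirror_tissue!r}")
    size = len(by_tissue[mirror_tissue])
    if size > len(dataset_tissues):
        raise ValueError("mirrored tissue larger than the whole collection")
    T = len(tissues)
    out = []
    for p in range(n_pseudo):
        base, rem = divmod(size, T)
        quotas = {t: base for t in tissues}
        for t in rng.choice(tissues, size=rem, replace=False):
            quotas[t] += 1
        deficit = 0
        for t in tissues:
            avail = len(by_tissue[t])
            if quotas[t] > avail:
                deficit += quotas[t] - avail
                quotas[t] = avail
        if deficit:
            warnings.warn(
                "pseudo-tissue stratification relaxed: redistributing "
                f"{deficit} dataset(s) to tissues with spare capacity",
                RuntimeWarning,
                stacklevel=2,
            )
            while deficit > 0:
                spare = [t for t in tissues if quotas[t] < len(by_tissue[t])]
                if not spare:
                    raise ValueError("not enough datasets to fill the pseudo-tissue")
                quotas[str(rng.choice(spare))] += 1
                deficit -= 1
        chosen: list[str] = []
        for t in tissues:
            chosen.extend(rng.choice(by_tissue[t], size=quotas[t], replace=False))
        out.append(PseudoTissue(id=f"{mirror_tissue}_pseudo{p + 1}", dataset_ids=frozenset(chosen)))
    return out


@dataclass
class TssFdrCurve:
    """Empirical FDR as a function of the TSS cut.

    ``grid`` holds candidate cuts in increasing order with the raw and
    monotone-smoothed (running minimum from high cuts downward) FDR at each.
    Grid points with no real score strictly above them carry no information
    about discoveries (the estimator's denominator is empty); their FDR is
    defined as 0 for queries but they neither seed the smoothing nor qualify
    as thresholds.  Above the largest real score the FDR is likewise 0.
    """

    grid: np.ndarray
    raw_fdr: np.ndarray
    fdr: np.ndarray
    defined: np.ndarray  # real exceedance count > 0 at this cut

    def fdr_at(self, cut: float) -> float:
        """Smoothed FDR of selecting links with tss >= cut."""
        i = int(np.searchsorted(self.grid, cut, side="left"))
        if i >= len(self.grid):
            return 0.0
        return float(self.fdr[i])

    def threshold(self, fdr_target: float) -> float | None:
        """Smallest cut whose smoothed FDR is <= target, or None.

        Only cuts where the FDR estimator is defined (nonzero real
        exceedance) are candidates; if none qualifies there is no
        threshold and the selection is empty.
        """
        ok = np.flatnonzero(self.defined & (self.fdr <= fdr_target))
        if len(ok) == 0:
            return None
        return float(self.grid[ok[0]])


def tss_fdr_curve(real_tss: np.ndarray, pseudo_tss: list[np.ndarray]) -> TssFdrCurve:
    """FDR(tss) = mean pseudo-tissue exceedance count / real exceedance count.

    Exceedance is strict (> tss).  The curve is evaluated at each observed
    real score, capped at 1, and monotone-smoothed (running minimum from
    high cuts downward) so thresholding is well-defined; cuts with an empty
    real exceedance set get FDR 0 but are excluded from the smoothing.
    """
    real = np.sort(np.asarray(real_tss, dtype=float))
    if real.size == 0:
        raise ValueError("no real TSS values")
    pseudo_sorted = [np.sort(np.asarray(p, dtype=float)) for p in pseudo_tss]
    if not pseudo_sorted:
        raise ValueError("no pseudo-tissue TSS values")
    grid = np.unique(real)
    n_real_gt = real.size - np.searchsorted(real, grid, side="right")
    mean_pseudo_gt = np.mean(
        [p.size - np.searchsorted(p, grid, side="right") for p in pseudo_sorted], axis=0
    )
    defined = n_real_gt > 0
    raw = np.where(defined, mean_pseudo_gt / np.maximum(n_real_gt, 1), 0.0)
    raw = np.minimum(raw, 1.0)
    smoothed = raw.copy()
    running = np.inf
    for i in range(len(grid) - 1, -1, -1):
        if defined[i]:
            running = min(running, raw[i])
            smoothed[i] = running
    return TssFdrCurve(grid=grid, raw_fdr=raw, fdr=smoothed, defined=defined)


@dataclass
class TsnSelection:
    """Per-tissue TSS threshold and the links surviving both filters."""

    thresholds: dict[str, float | None]
    selected: dict[str, set[tuple[str, str]]]

    def all_links(self) -> set[tuple[str, str]]:
        out: set[tuple[str, str]] = set()
        for s in self.selected.values():
            out |= s
        return out


def select_tsn(
    links: list[tuple[str, str]],
    tss_by_tissue: dict[str, np.ndarray],
    tan_membership: dict[str, np.ndarray],
    curves: dict[str, TssFdrCurve],
    fdr_target: float,
    other_max: float,
) -> TsnSelection:
    """Tissue-specific links: TAN links at the TSS-FDR cut, specific to one tissue.

    Per tissue: threshold = smallest score with smoothed FDR <= ``fdr_target``
    (estimated on that tissue's TAN links); selected links are the tissue's
    TAN links with tss >= threshold AND tss < ``other_max`` in every other
    tissue.  If no score achieves the target the tissue's TSN is empty (with
    a warning), not an error.
    """
    links = [canonical_pair(a, b) for a, b in links]
    tissues = sorted(tss_by_tissue)
    thresholds: dict[str, float | None] = {}
    selected: dict[str, set[tuple[str, str]]] = {}
    for t in tissues:
        thr = curves[t].threshold(fdr_target)
        thresholds[t] = thr
        if thr is None:
            warnings.warn(
                f"tissue {t!r}: no TSS cut achieves FDR {fdr_target:g}; empty TSN",
                RuntimeWarning,
                stacklevel=2,
            )
            selected[t] = set()
            continue
        score = tss_by_tissue[t]
        keep = tan_membership[t] & (score >= thr)
        for other in tissues:
            if other != t:
                keep &= tss_by_tissue[other] < other_max
        selected[t] = {links[i] for i in np.flatnonzero(keep)}
    return TsnSelection(thresholds=thresholds, selected=selected)
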