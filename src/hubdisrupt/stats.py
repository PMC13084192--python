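"""Two-group comparisons with normality routing, and abnormal-region ranking.

Each scalar quantity (a global network metric or a hub-disruption index) is
compared between the control and patient groups.  Both samples are first
screened with a Shapiro-Wilk normality test at alpha = 0.05; if both pass,
an independent-samples t-test (Welch by default) is used, otherwise a
two-sided Mann-Whitney U.  Which route was taken, and the normality
p-values that drove it, are recorded in the result.  Significance is
flagged at p < 0.05 and p < 0.01; no multiple-testing correction is applied
by default (a Benjamini-Hochberg option is available).

Abnormal regions are ranked by the signed difference of group-level mean
nodal metrics (patient minus control): the most elevated and the most
reduced regions per metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

from .containers import NodalMetrics
from .hdi import _check_same_labels

ALPHA_NORMALITY = 0.05


@dataclass
class NormalityResult:
    is_normal: bool
    p_value: float
    diagnostic: str = ""


@dataclass
class ComparisonResult:
    """One two-group comparison of a scalar quantity."""

    quantity_name: str
    sparsity: float | None
    test_used: str                    # "t_test" or "mann_whitney_u"
    statistic: float
    p_value: float
    group_means: tuple[float, float]  # (NC, EMCI)
    group_sds: tuple[float, float]
    n: tuple[int, int]
    significant_05: bool
    significant_01: bool
    normality_p: tuple[float, float] = (float("nan"), float("nan"))


@dataclass
class RegionDifference:
    """Group-mean difference of one nodal metric in one region."""

    region_label: str
    metric_name: str
    nc_mean: float
    emci_mean: float
    difference: float          # emci_mean - nc_mean
    rank_elevated: int         # 1 = most elevated
    rank_reduced: int          # 1 = most reduced
    top_elevated: bool = False
    top_reduced: bool = False


def normality_check(values: np.ndarray) -> NormalityResult:
    """Shapiro-Wilk at alpha = 0.05; constant samples fail with a diagnostic."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 observations for a normality check")
    if np.ptp(values) == 0:
        return NormalityResult(False, 0.0, "degenerate: constant sample")
    stat, p = sps.shapiro(values)
    return NormalityResult(bool(p >= ALPHA_NORMALITY), float(p))


def compare_groups(
    nc_values: np.ndarray,
    emci_values: np.ndarray,
    quantity_name: str = "",
    sparsity: float | None = None,
    pooled_t: bool = False,
) -> ComparisonResult:
    """Normality-routed two-sided comparison of two independent samples.

    Both samples normal by Shapiro-Wilk -> independent t-test (Welch unless
    ``pooled_t``); otherwise Mann-Whitney U (exact for small untied
    samples, normal approximation with tie correction otherwise).
    """
    nc = np.asarray(nc_values, dtype=float)
    em = np.asarray(emci_values, dtype=float)
    if nc.size < 3 or em.size < 3:
        raise ValueError("each group needs at least 3 observations")
    norm_nc = normality_check(nc)
    norm_em = normality_check(em)
    for tag, res in (("NC", norm_nc), ("EMCI", norm_em)):
        if res.diagnostic:
            log.warning("%s %s sample: %s; using Mann-Whitney U",
                        quantity_name, tag, res.diagnostic)
    if norm_nc.is_normal and norm_em.is_normal:
        stat, p = sps.ttest_ind(nc, em, equal_var=pooled_t)
        test_used = "t_test"
    else:
        method = "exact" if (min(nc.size, em.size) < 20
                             and np.unique(np.r_[nc, em]).size == nc.size + em.size) \
            else "asymptotic"
        stat, p = sps.mannwhitneyu(nc, em, alternative="two-sided", method=method)
        test_used = "mann_whitney_u"
    p = float(p)
    return ComparisonResult(
        quantity_name=quantity_name,
        sparsity=sparsity,
        test_used=test_used,
        statistic=float(stat),
        p_value=p,
        group_means=(float(nc.mean()), float(em.mean())),
        group_sds=(float(nc.std(ddof=1)), float(em.std(ddof=1))),
        n=(int(nc.size), int(em.size)),
        significant_05=bool(p < 0.05),
        significant_01=bool(p < 0.01),
        normality_p=(norm_nc.p_value, norm_em.p_value),
    )


def abnormal_regions(
    nc_metrics: list[NodalMetrics],
    emci_metrics: list[NodalMetrics],
    metric_name: str,
    top_k: int = 4,
) -> list[RegionDifference]:
    """Rank regions by the patient-minus-control group-mean difference.

    Returns the full per-region table with elevation and reduction ranks;
    the ``top_k`` most elevated and most reduced regions are flagged.  Ties
    are broken by region order for determinism.  If all differences are
    zero, the ranking is non-informative and no region is flagged.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    labels = nc_metrics[0].region_labels
    for m in list(nc_metrics[1:]) + list(emci_metrics):
        _check_same_labels(labels, m.region_labels)
    nc_mean = np.vstack([m.get(metric_name) for m in nc_metrics]).mean(axis=0)
    em_mean = np.vstack([m.get(metric_name) for m in emci_metrics]).mean(axis=0)
    diff = em_mean - nc_mean
    order_elev = np.lexsort((np.arange(diff.size), -diff))
    order_red = np.lexsort((np.arange(diff.size), diff))
    rank_elev = np.empty(diff.size, dtype=int)
    rank_red = np.empty(diff.size, dtype=int)
    rank_elev[order_elev] = np.arange(1, diff.size + 1)
    rank_red[order_red] = np.arange(1, diff.size + 1)
    informative = bool(np.ptp(diff) > 0)
    return [
        RegionDifference(
            region_label=labels[i],
            metric_name=metric_name,
            nc_mean=float(nc_mean[i]),
            emci_mean=float(em_mean[i]),
            difference=float(diff[i]),
            rank_elevated=int(rank_elev[i]),
            rank_reduced=int(rank_red[i]),
            top_elevated=informative and rank_elev[i] <= top_k,
            top_reduced=informative and rank_red[i] <= top_k,
        )
        for i in range(diff.size)
    ]


def region_table(diffs: list[RegionDifference]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in diffs])


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "quantity": r.quantity_name, "sparsity": r.sparsity,
            "test": r.test_used, "statistic": r.statistic, "p_value": r.p_value,
            "nc_mean": r.group_means[0], "emci_mean": r.group_means[1],
            "nc_sd": r.group_sds[0], "emci_sd": r.group_sds[1],
            "n_nc": r.n[0], "n_emci": r.n[1],
            "normality_p_nc": r.normality_p[0], "normality_p_emci": r.normality_p[1],
            "significant_05": r.significant_05, "significant_01": r.significant_01,
        })
    return pd.DataFrame(rows)


def benjamini_hochberg(table: pd.DataFrame) -> pd.DataFrame:
    """Append BH-adjusted p-values to a comparison table (optional)."""
    from statsmodels.stats.multitest import multipletests

    out = table.copy()
    _, q, _, _ = multipletests(out["p_value"].to_numpy(), method="fdr_bh")
    out["p_fdr_bh"] = q
    return out


def run_full_comparison(
    global_by_sparsity: dict[float, tuple[list, list]],
    hdi_by_sparsity: dict[float, tuple[dict, dict]],
    nodal_at_primary: tuple[list[NodalMetrics], list[NodalMetrics]] | None = None,
    top_k: int = 4,
    pooled_t: bool = False,
    fdr: bool = False,
) -> dict:
    """Assemble the full group-level report.

    ``global_by_sparsity``: sparsity -> (NC GlobalMetrics list, EMCI list).
    ``hdi_by_sparsity``: sparsity -> ({metric: NC k-values}, {metric: EMCI
    k-values}).  With three sparsities this yields 3 global + 4 HDI
    comparisons each, 21 rows.  ``nodal_at_primary`` adds the per-metric
    abnormal-region tables at the primary sparsity.
    """
    comparisons: list[ComparisonResult] = []
    for s, (nc_glob, em_glob) in sorted(global_by_sparsity.items()):
        for attr, name in (("L", "L"), ("E_glob", "E_glob"), ("C", "C")):
            comparisons.append(compare_groups(
                np.array([getattr(g, attr) for g in nc_glob]),
                np.array([getattr(g, attr) for g in em_glob]),
                quantity_name=name, sparsity=s, pooled_t=pooled_t,
            ))
    for s, (nc_k, em_k) in sorted(hdi_by_sparsity.items()):
        for metric, kname in (("degree", "k_D"), ("clustering", "k_C"),
                              ("betweenness", "k_B"), ("local_efficiency", "k_loc")):
            comparisons.append(compare_groups(
                np.asarray(nc_k[metric]), np.asarray(em_k[metric]),
                quantity_name=kname, sparsity=s, pooled_t=pooled_t,
            ))
    table = comparison_table(comparisons)
    if fdr:
        table = benjamini_hochberg(table)
    report = {"comparisons": comparisons, "comparison_table": table}
    if nodal_at_primary is not None:
        nc_nodal, em_nodal = nodal_at_primary
        report["abnormal_regions"] = {
            metric: abnormal_regions(nc_nodal, em_nodal, metric, top_k=top_k)
            for metric in ("degree", "clustering", "betweenness", "local_efficiency")
        }
    return report


def plot_group_violin(values: dict[float, tuple[np.ndarray, np.ndarray]],
                      quantity_name: str, ax=None):
    """Violin plots of one quantity per sparsity x group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data, positions, labels = [], [], []
    pos = 0
    for s, (nc, em) in sorted(values.items()):
        data += [np.asarray(nc, dtype=float), np.asarray(em, dtype=float)]
        positions += [pos, pos + 0.8]
        labels += [f"NC\ns={s}", f"EMCI\ns={s}"]
        pos += 2.5
    parts = ax.violinplot(data, positions=positions, showmeans=True)
    for body, color in zip(parts["bodies"], ["tab:blue", "tab:orange"] * len(values)):
        body.set_facecolor(color)
    ax.set_xticks(positions, labels, fontsize=8)
    ax.set_ylabel(quantity_name)
    return ax
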