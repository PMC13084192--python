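"""Hub disruption index: per-subject slope of nodal-metric differences.

For a nodal metric (degree, clustering, betweenness or local efficiency),
a subject's hub disruption index k is the ordinary-least-squares slope of

    y = (subject's per-region metric) - (control-group mean per region)

regressed on

    x = control-group mean per region,

fitted across all regions.  A negative k means regions that are strong in
the control profile (hubs) have lost metric value in the subject while weak
regions have gained — the signature of hub reorganisation — independent of
any global shift, which the intercept absorbs.

The fit includes an intercept by default: forcing the line through the
origin would conflate a uniform metric offset with hub reorganisation.
When control subjects are scored against their own group profile, the
group-mean k is exactly 0 (the slope is linear in y and the per-region
differences average to zero across the group); that identity holds for the
default full-group profile, not for the leave-one-out variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import NODAL_METRIC_NAMES, NodalMetrics


@dataclass
class GroupNodalProfile:
    """Per-region group mean of one nodal metric."""

    metric_name: str
    mean_values: np.ndarray
    group_tag: str
    sparsity: float | None = None
    n_subjects: int = 0
    region_labels: list[str] | None = None


@dataclass
class HDIResult:
    """One subject's fitted hub-disruption slope for one nodal metric."""

    k: float
    intercept: float
    metric_name: str
    sparsity: float | None
    subject_id: str
    r_squared: float
    n_regions_used: int


def _check_same_labels(a: list[str] | None, b: list[str] | None) -> None:
    if a is None or b is None:
        return
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            raise ValueError(f"region label mismatch at position {i}: {x!r} != {y!r}")
    if len(a) != len(b):
        raise ValueError(f"label lists differ in length: {len(a)} vs {len(b)}")


def group_nodal_profile(
    subject_metrics: list[NodalMetrics],
    metric_name: str,
    group_tag: str,
    sparsity: float | None = None,
) -> GroupNodalProfile:
    """Per-region arithmetic mean of one metric across >= 2 subjects."""
    if len(subject_metrics) < 2:
        raise ValueError("need at least 2 subjects for a group profile")
    labels = subject_metrics[0].region_labels
    for m in subject_metrics[1:]:
        _check_same_labels(labels, m.region_labels)
    stacked = np.vstack([m.get(metric_name) for m in subject_metrics])
    return GroupNodalProfile(
        metric_name=metric_name,
        mean_values=stacked.mean(axis=0),
        group_tag=group_tag,
        sparsity=sparsity,
        n_subjects=len(subject_metrics),
        region_labels=labels,
    )


def hdi_slope(
    nc_profile: GroupNodalProfile,
    subject: NodalMetrics,
    subject_id: str = "",
    include_intercept: bool = True,
) -> HDIResult:
    """OLS fit of (subject - control mean) on the control mean across regions."""
    _check_same_labels(nc_profile.region_labels, subject.region_labels)
    x = np.asarray(nc_profile.mean_values, dtype=float)
    y = subject.get(nc_profile.metric_name) - x
    if np.ptp(x) == 0:
        raise ValueError("degenerate abscissa: control profile is constant")
    if include_intercept:
        xm, ym = x.mean(), y.mean()
        sxx = float(np.dot(x - xm, x - xm))
        k = float(np.dot(x - xm, y - ym)) / sxx
        intercept = ym - k * xm
    else:
        k = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    resid = y - (k * x + intercept)
    ss_tot = float(np.dot(y - y.mean(), y - y.mean()))
    ss_res = float(np.dot(resid, resid))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return HDIResult(
        k=k,
        intercept=intercept,
        metric_name=nc_profile.metric_name,
        sparsity=nc_profile.sparsity,
        subject_id=subject_id,
        r_squared=r2,
        n_regions_used=x.size,
    )


def cohort_hdi(
    nc_subjects: list[NodalMetrics],
    target_subjects: list[NodalMetrics],
    metric_name: str,
    sparsity: float | None = None,
    subject_ids: list[str] | None = None,
    include_intercept: bool = True,
    leave_one_out: bool = False,
) -> list[HDIResult]:
    """One HDI per target subject, all against the control-group profile.

    With ``leave_one_out`` and targets that *are* the control subjects
    (matched by object identity), each control subject is scored against
    the mean of the other controls; the default scores everyone against the
    full-group mean, for which the controls' mean k is exactly zero.
    """
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(len(target_subjects))]
    profile = group_nodal_profile(nc_subjects, metric_name, "NC", sparsity)
    results = []
    for sid, subj in zip(subject_ids, target_subjects):
        if leave_one_out and any(subj is s for s in nc_subjects):
            others = [s for s in nc_subjects if s is not subj]
            prof = group_nodal_profile(others, metric_name, "NC", sparsity)
        else:
            prof = profile
        results.append(hdi_slope(prof, subj, subject_id=sid,
                                 include_intercept=include_intercept))
    return results


def hdi_table(results: list[HDIResult], group: str) -> pd.DataFrame:
    """Long-format table: one row per subject x metric x sparsity."""
    return pd.DataFrame(
        [
            {"subject_id": r.subject_id, "group": group, "metric": r.metric_name,
             "sparsity": r.sparsity, "k": r.k, "intercept": r.intercept,
             "r_squared": r.r_squared}
            for r in results
        ]
    )


def plot_hdi_scatter(nc_profile: GroupNodalProfile, subject: NodalMetrics,
                     result: HDIResult | None = None, ax=None):
    """Scatter of per-region differences vs the control profile with the fit line.

    x: control-group mean of the metric per region; y: subject minus that
    mean; the fitted line's slope is the subject's hub disruption index.
    """
    import matplotlib.pyplot as plt

    if result is None:
        result = hdi_slope(nc_profile, subject)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x = np.asarray(nc_profile.mean_values, dtype=float)
    y = subject.get(nc_profile.metric_name) - x
    ax.scatter(x, y, s=12, alpha=0.7)
    xs = np.linspace(x.min(), x.max(), 2)
    ax.plot(xs, result.k * xs + result.intercept, color="crimson",
            label=f"k = {result.k:.3f}")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel(f"NC group mean {nc_profile.metric_name}")
    ax.set_ylabel(f"subject - NC mean {nc_profile.metric_name}")
    ax.legend()
    return ax
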