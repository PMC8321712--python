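"""Group comparison of TAC metrics and qualitative dynamics labels.

The healthy and GAD groups are compared per ROI x metric with the pooled
two-sample (Student) t-test computed from group summaries (mean, SD, n):

    t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)),
    s_p^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2),  df = n1 + n2 - 2,

with a two-sided p-value; magnitudes are reported to 2 decimals (the table
convention) and the signed t is retained in machine output.  A Welch option
exists but pooled variance is the published variant.  No multiple-testing
correction is applied by default; Bonferroni/Benjamini-Hochberg are opt-in.

Each ROI's three comparisons (peak, pre-peak uptake rate, post-peak
metabolic rate) are condensed into a qualitative dynamics label: e.g. a
significantly lower pre-peak rate in GAD reads "slow-in", a significantly
higher post-peak rate "fast-out", a significantly lower peak "total
decreased".  An ROI is called *altered* overall when a majority (>= 2 of 3)
of its metrics differ significantly — the rule used for the pattern
summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .phantom import LOOP_ROIS, METRICS, SIDES

ALPHA = 0.05
METRIC_LABELS = {
    "peak": "SUVmax peak",
    "pre_rate": "pre-peak uptake rate",
    "post_rate": "post-peak metabolic rate",
}


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one group for one ROI x metric."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("SD must be non-negative")
        if self.n < 2:
            raise ValueError("group size must be >= 2")


@dataclass(frozen=True)
class DynamicsLabel:
    """Verbal uptake/washout pattern of one ROI (GAD relative to healthy)."""

    roi: str
    side: str
    in_label: str  # slow-in / fast-in / none
    out_label: str  # slow-out / fast-out / none
    total_label: str  # decreased / increased / none


def two_sample_t(
    g1: GroupSummary, g2: GroupSummary, *, welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test from summaries; returns (signed t, df, p).

    Pooled-variance Student's t by default; ``welch=True`` uses the
    Welch-Satterthwaite statistic instead.  With zero variance in both
    groups, equal means give t = 0 and unequal means signal an infinite t
    (p = 0).
    """
    diff = g1.mean - g2.mean
    if welch:
        se1, se2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        se = np.sqrt(se1 + se2)
        if se == 0:
            return _degenerate_t(diff, float(g1.n + g2.n - 2))
        df = (se1 + se2) ** 2 / (
            se1**2 / (g1.n - 1) + se2**2 / (g2.n - 1)
        )
    else:
        df = float(g1.n + g2.n - 2)
        pooled = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
        se = np.sqrt(pooled) * np.sqrt(1 / g1.n + 1 / g2.n)
        if se == 0:
            return _degenerate_t(diff, df)
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def _degenerate_t(diff: float, df: float) -> tuple[float, float, float]:
    if diff == 0:
        return 0.0, df, 1.0
    return float(np.copysign(np.inf, diff)), df, 0.0


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Collapse tidy per-subject metrics to (roi, side, metric) summaries.

    Expects columns subject, roi, side, metric, value (the cohort layout);
    returns mean, sd (ddof=1) and n per cell.
    """
    grouped = metrics.groupby(["roi", "side", "metric"])["value"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    return out.reset_index()


def compare_groups(
    healthy: pd.DataFrame,
    gad: pd.DataFrame,
    *,
    welch: bool = False,
    correction: str | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Compare two cohorts per ROI x metric; one row per table cell.

    Inputs are tidy per-subject metric tables (subject, roi, side, metric,
    value).  The output has 24 rows (8 ROIs x 3 metrics) with the group
    summaries, signed t, |t| rounded to 2 decimals, df, p and the
    significance flag at ``alpha``.  ``correction`` may be ``"bonferroni"``
    or ``"bh"`` (Benjamini-Hochberg); default is none, matching the source
    analysis.
    """
    h_sum = summarize_metrics(healthy).set_index(["roi", "side", "metric"])
    g_sum = summarize_metrics(gad).set_index(["roi", "side", "metric"])
    rows = []
    for roi in LOOP_ROIS:
        for side in SIDES:
            for metric in METRICS:
                key = (roi, side, metric)
                if key not in h_sum.index or key not in g_sum.index:
                    raise ValueError(f"missing cell {key} in a cohort")
                h = GroupSummary(*h_sum.loc[key][["mean", "sd", "n"]])
                g = GroupSummary(*g_sum.loc[key][["mean", "sd", "n"]])
                t, df, p = two_sample_t(h, g, welch=welch)
                rows.append(
                    dict(
                        roi=roi, side=side, metric=metric,
                        healthy_mean=h.mean, healthy_sd=h.sd, healthy_n=h.n,
                        gad_mean=g.mean, gad_sd=g.sd, gad_n=g.n,
                        t=t, t_abs=round(abs(t), 2), df=df, p=p,
                    )
                )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _adjust(table["p"].to_numpy(), correction)
    table["significant"] = table["p_adjusted"] < alpha
    return table


def compare_from_summaries(
    targets: pd.DataFrame, *, alpha: float = ALPHA
) -> pd.DataFrame:
    """Pooled t per row of a printed-summary table.

    ``targets`` rows carry roi, side, metric, healthy_mean, healthy_sd,
    gad_mean, gad_sd, n_per_group — the layout of :func:`load_group_targets`.
    """
    rows = []
    for r in targets.itertuples():
        n = int(r.n_per_group)
        t, df, p = two_sample_t(
            GroupSummary(r.healthy_mean, r.healthy_sd, n),
            GroupSummary(r.gad_mean, r.gad_sd, n),
        )
        rows.append(
            dict(
                roi=r.roi, side=r.side, metric=r.metric,
                healthy_mean=r.healthy_mean, healthy_sd=r.healthy_sd,
                healthy_n=n, gad_mean=r.gad_mean, gad_sd=r.gad_sd, gad_n=n,
                t=t, t_abs=round(abs(t), 2), df=df, p=p, p_adjusted=p,
                significant=p < alpha,
            )
        )
    return pd.DataFrame(rows)


def _adjust(p: np.ndarray, method: str | None) -> np.ndarray:
    if method is None:
        return p
    from statsmodels.stats.multitest import multipletests

    name = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[method]
    return multipletests(p, method=name)[1]


def classify_dynamics(rows: pd.DataFrame) -> DynamicsLabel:
    """Condense one ROI's three comparison rows into a dynamics label.

    ``rows`` must hold exactly the peak, pre_rate and post_rate rows of one
    ROI from :func:`compare_groups`.  Direction is GAD relative to healthy;
    non-significant cells map to "none".
    """
    if set(rows["metric"]) != set(METRICS) or len(rows) != 3:
        raise ValueError("need exactly the peak, pre_rate, post_rate rows")
    if rows["roi"].nunique() != 1 or rows["side"].nunique() != 1:
        raise ValueError("rows must belong to a single ROI")
    by_metric = rows.set_index("metric")

    def direction(metric: str, low: str, high: str) -> str:
        cell = by_metric.loc[metric]
        if not cell["significant"]:
            return "none"
        return low if cell["gad_mean"] < cell["healthy_mean"] else high

    return DynamicsLabel(
        roi=str(by_metric["roi"].iloc[0]),
        side=str(by_metric["side"].iloc[0]),
        in_label=direction("pre_rate", "slow-in", "fast-in"),
        out_label=direction("post_rate", "slow-out", "fast-out"),
        total_label=direction("peak", "decreased", "increased"),
    )


def dynamics_table(comparison: pd.DataFrame) -> pd.DataFrame:
    """Dynamics labels for every ROI in a comparison table."""
    rows = []
    for (roi, side), group in comparison.groupby(["roi", "side"], sort=False):
        label = classify_dynamics(group)
        rows.append(
            dict(
                roi=roi, side=side, in_label=label.in_label,
                out_label=label.out_label, total_label=label.total_label,
            )
        )
    return pd.DataFrame(rows)


def roi_alteration_pattern(comparison: pd.DataFrame) -> pd.DataFrame:
    """Majority-rule ROI pattern: altered iff >= 2 of 3 metrics significant."""
    out = (
        comparison.groupby(["roi", "side"], sort=False)["significant"]
        .agg(n_significant="sum")
        .reset_index()
    )
    out["altered"] = out["n_significant"] >= 2
    return out


def load_group_targets() -> pd.DataFrame:
    """Published group summaries (mean, SD, n) for all 24 ROI x metric cells.

    Shipped as package data; also carries the printed |t| and significance
    call of each cell for cross-checking.
    """
    with resources.files("petloop.data").joinpath("group_targets.csv").open() as f:
        return pd.read_csv(f)


def targets_to_cohort_targets(
    targets: pd.DataFrame, group: str
) -> pd.DataFrame:
    """Extract one group's (roi, side, metric, mean, sd) block for simulation."""
    if group not in ("healthy", "gad"):
        raise ValueError("group must be 'healthy' or 'gad'")
    out = targets[["roi", "side", "metric"]].copy()
    out["mean"] = targets[f"{group}_mean"]
    out["sd"] = targets[f"{group}_sd"]
    return out


def plot_tac(
    healthy_curves: pd.DataFrame,
    gad_curves: pd.DataFrame,
    path,
    *,
    rois: list | None = None,
) -> pd.DataFrame:
    """Plot mean +/- SD time-activity curves per ROI, one panel each.

    Curve tables are tidy: subject, roi, side, time, value.  Returns the
    per-group, per-timepoint means/SDs actually plotted and writes the figure
    to ``path``.
    """
    keys = rois or sorted(
        set(zip(healthy_curves["roi"], healthy_curves["side"]))
    )
    if not keys:
        raise ValueError("no ROI curves to plot")
    ncols = min(4, len(keys))
    nrows = -(-len(keys) // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    plotted = []
    for ax, (roi, side) in zip(axes.ravel(), keys):
        for name, curves, color in (
            ("healthy", healthy_curves, "tab:blue"),
            ("GAD", gad_curves, "tab:red"),
        ):
            sel = curves[(curves["roi"] == roi) & (curves["side"] == side)]
            if sel.empty:
                raise ValueError(f"no {name} curves for {roi} {side}")
            agg = sel.groupby("time")["value"].agg(["mean", "std"])
            ax.plot(agg.index, agg["mean"], color=color, label=name)
            ax.fill_between(
                agg.index,
                agg["mean"] - agg["std"].fillna(0),
                agg["mean"] + agg["std"].fillna(0),
                color=color, alpha=0.2,
            )
            for time, row in agg.iterrows():
                plotted.append(
                    dict(roi=roi, side=side, group=name, time=time,
                         mean=row["mean"], sd=row["std"])
                )
        ax.set_title(f"{side} {roi}", fontsize=9)
        ax.set_xlabel("min")
        ax.set_ylabel("SUVmax (norm.)")
    for ax in axes.ravel()[len(keys):]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return pd.DataFrame(plotted)
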