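"""Binarizer parameter sweeps and two-group comparisons.

Each (estimator, binarizer, metric) cell is swept over the binarizer's
parameter grid; at every grid point the two groups are compared with
Wilcoxon's rank-sum test, two-sided, alpha = 0.05, with no multiple-testing
correction across grid points by default (a Benjamini-Hochberg option is
available).  Subjects whose network fails at a grid point (disconnected graph
for MST/MCC, undefined assortativity) are recorded as missing with a reason,
never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from fconnet.binarize import DisconnectedGraphError, binarize
from fconnet.connectivity import ConnectivityMatrix
from fconnet.metrics import compute_metric
from fconnet.preproc import ValidationError

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))
DEFAULT_DENSITY_GRID = tuple(np.round(np.arange(0.05, 0.55, 0.05), 2))


def default_grid(binarizer: str) -> tuple:
    """Default sweep grid per binarizer (singleton [None] for mst/mcc)."""
    if binarizer == "threshold":
        return DEFAULT_THRESHOLD_GRID
    if binarizer == "density":
        return DEFAULT_DENSITY_GRID
    return (None,)


def clipped_threshold_grid(matrices, grid=DEFAULT_THRESHOLD_GRID) -> tuple:
    """Threshold grid restricted to the observed off-diagonal weight range
    across subjects, so that every grid point yields a non-trivial network
    for at least one subject."""
    lo, hi = np.inf, -np.inf
    for cm in matrices:
        w = cm.weights[np.triu_indices(cm.n_channels, 1)]
        w = w[w > 0]
        if w.size:
            lo, hi = min(lo, w.min()), max(hi, w.max())
    clipped = tuple(t for t in grid if lo <= t < hi)
    return clipped if clipped else (float(np.round((lo + hi) / 2, 3)),)


@dataclass
class MetricSweepResult:
    """Per-subject metric values over one binarizer parameter grid.

    ``table`` is a long-format DataFrame with columns
    (subject, group, parameter, value, missing_reason); ``parameter`` is NaN
    for mst/mcc.
    """

    estimator: str
    binarizer: str
    metric: str
    parameter_grid: tuple
    table: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def values_at(self, parameter) -> pd.DataFrame:
        if parameter is None:
            return self.table[self.table["parameter"].isna()]
        return self.table[self.table["parameter"] == parameter]


@dataclass
class GroupComparison:
    """Rank-sum p-values and the significance mask over the grid."""

    estimator: str
    binarizer: str
    metric: str
    parameter_grid: tuple
    p_values: list
    significant: list
    alpha: float = 0.05
    group_labels: tuple = ("A", "B")
    flags: list = field(default_factory=list)


def ranksum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration when the combined sample size is <= 12 and there
    are no ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("ranksum: both samples need >= 2 values")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def sweep(
    matrices: list[ConnectivityMatrix],
    binarizer: str,
    metric: str,
    grid: tuple | None = None,
) -> MetricSweepResult:
    """Binarize every subject at every grid point and compute one metric."""
    if grid is None:
        grid = default_grid(binarizer)
    grid = tuple(grid)
    if len(grid) == 0:
        raise ValidationError("grid: must be nonempty")
    if binarizer in ("mst", "mcc") and grid != (None,):
        raise ValidationError(f"{binarizer} takes no parameter; use grid=(None,)")
    estimators = {m.estimator for m in matrices}
    if len(estimators) != 1:
        raise ValidationError("sweep: all matrices must share one estimator")
    rows = []
    for cm in matrices:
        for p in grid:
            value, reason = None, None
            try:
                net = binarize(cm, binarizer, p)
                mv = compute_metric(net, metric)
                if mv.is_defined:
                    value = mv.value
                else:
                    reason = mv.undefined_reason
            except (DisconnectedGraphError, ValidationError) as exc:
                reason = str(exc)
            rows.append(
                {
                    "subject": cm.subject_id,
                    "group": cm.group,
                    "parameter": np.nan if p is None else float(p),
                    "value": np.nan if value is None else value,
                    "missing_reason": reason,
                }
            )
    table = pd.DataFrame(rows)
    return MetricSweepResult(
        estimator=estimators.pop(),
        binarizer=binarizer,
        metric=metric,
        parameter_grid=grid,
        table=table,
    )


def compare_groups(
    sw: MetricSweepResult, alpha: float = 0.05, fdr: bool = False
) -> GroupComparison:
    """Rank-sum test at each grid point; significance mask at ``alpha``.

    No correction across grid points by default; ``fdr=True`` applies
    Benjamini-Hochberg over the grid.
    """
    groups = sorted(g for g in sw.table["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly 2 groups, found {groups}")
    p_values, flags = [], []
    for p in sw.parameter_grid:
        sub = sw.values_at(p).dropna(subset=["value"])
        a = sub[sub["group"] == groups[0]]["value"].to_numpy()
        b = sub[sub["group"] == groups[1]]["value"].to_numpy()
        if a.size < 2 or b.size < 2:
            p_values.append(np.nan)
            flags.append(f"group missing at parameter {p}")
            continue
        p_values.append(ranksum(a, b))
        flags.append(None)
    pv = np.asarray(p_values, dtype=float)
    if fdr:
        ok = ~np.isnan(pv)
        adj = np.full_like(pv, np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(pv[ok], method="bh")
        sig = [bool(q < alpha) if np.isfinite(q) else False for q in adj]
    else:
        sig = [bool(q < alpha) if np.isfinite(q) else False for q in pv]
    return GroupComparison(
        estimator=sw.estimator,
        binarizer=sw.binarizer,
        metric=sw.metric,
        parameter_grid=sw.parameter_grid,
        p_values=[None if np.isnan(q) else float(q) for q in pv],
        significant=sig,
        alpha=alpha,
        group_labels=tuple(groups),
        flags=flags,
    )


def assemble_report(
    sweeps: list[MetricSweepResult],
    comparisons: list[GroupComparison] | None = None,
    alpha: float = 0.05,
    meta: dict | None = None,
) -> dict:
    """Figure-style machine-readable summary.

    For each (estimator, binarizer, metric) cell: group means and standard
    errors per grid point, rank-sum p-values and significance markers.
    """
    if not sweeps:
        raise ValidationError("assemble_report: needs >= 1 completed sweep")
    if comparisons is None:
        comparisons = [compare_groups(sw, alpha=alpha) for sw in sweeps]
    cells = []
    for sw, gc in zip(sweeps, comparisons):
        groups = gc.group_labels
        per_group = {}
        for g in groups:
            means, sems, ns = [], [], []
            for p in sw.parameter_grid:
                sub = sw.values_at(p)
                vals = sub[sub["group"] == g]["value"].dropna().to_numpy()
                ns.append(int(vals.size))
                means.append(float(vals.mean()) if vals.size else None)
                sems.append(
                    float(vals.std(ddof=1) / np.sqrt(vals.size))
                    if vals.size > 1
                    else None
                )
            per_group[g] = {"mean": means, "sem": sems, "n": ns}
        missing = sw.table.dropna(subset=["missing_reason"])
        cells.append(
            {
                "estimator": sw.estimator,
                "binarizer": sw.binarizer,
                "metric": sw.metric,
                "parameter_grid": [
                    None if p is None else float(p) for p in sw.parameter_grid
                ],
                "groups": per_group,
                "p_values": gc.p_values,
                "significant": gc.significant,
                "n_missing": int(len(missing)),
                "missing_reasons": sorted(
                    missing["missing_reason"].unique().tolist()
                ),
            }
        )
    report = {
        "alpha": alpha,
        "cells": cells,
        "n_subjects": int(
            pd.concat([sw.table for sw in sweeps])["subject"].nunique()
        ),
    }
    if meta:
        report["meta"] = meta
    return report


def plot_report(report: dict, outdir=None):
    """Render each report cell: metric vs parameter with group mean +- SEM and
    significance asterisks, or a two-bar comparison for mst/mcc."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figures = {}
    for cell in report["cells"]:
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        grid = cell["parameter_grid"]
        groups = cell["groups"]
        if grid == [None]:
            for k, (g, d) in enumerate(sorted(groups.items())):
                ax.bar(
                    k,
                    d["mean"][0] if d["mean"][0] is not None else 0.0,
                    yerr=d["sem"][0] or 0.0,
                    label=g,
                )
            ax.set_xticks(range(len(groups)))
            ax.set_xticklabels(sorted(groups))
            if cell["significant"][0]:
                ax.set_title("*", fontsize=14)
        else:
            x = np.asarray(grid, dtype=float)
            for g, d in sorted(groups.items()):
                mean = np.array(
                    [np.nan if m is None else m for m in d["mean"]], dtype=float
                )
                sem = np.array(
                    [0.0 if s is None else s for s in d["sem"]], dtype=float
                )
                ax.errorbar(x, mean, yerr=sem, label=g, capsize=2)
            ymax = ax.get_ylim()[1]
            for xi, sig in zip(x, cell["significant"]):
                if sig:
                    ax.annotate("*", (xi, ymax), ha="center")
            ax.set_xlabel(
                "threshold" if cell["binarizer"] == "threshold" else "density"
            )
        ax.set_ylabel(cell["metric"].replace("_", " "))
        ax.legend(fontsize=8)
        fig.tight_layout()
        name = f"{cell['estimator']}_{cell['binarizer']}_{cell['metric']}"
        figures[name] = fig
        if outdir is not None:
            fig.savefig(f"{outdir}/{name}.png", dpi=120)
            plt.close(fig)
    return figures
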