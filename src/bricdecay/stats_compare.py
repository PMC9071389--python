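"""Group-comparison machinery: equal-count binning, means with 95% CI,
rank statistics, differential-stability curves, and the differential
stability-versus-expression analysis.

The central comparative analysis bins genes by differential transcript level
(equal gene counts per bin) and plots the mean differential half-life per bin
and group; the strength of the stability-expression coupling is quantified by
a gene-level (not bin-level) Spearman correlation.  A negative coupling means
RNA stability buffers transcriptional changes; a positive coupling means it
reinforces adapted differential expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "equal_count_bins",
    "group_mean_ci",
    "compare_groups",
    "stability_vs_expression",
    "differential_curve",
    "halflife_ratio_density",
    "plot_differential_curve",
    "plot_bin_profile",
]


def equal_count_bins(values, k: int) -> np.ndarray:
    """Assign values to ``k`` rank-based bins of (near-)equal size.

    Bins are ordered by increasing value; with remainder r = n mod k, the
    first r bins receive one extra element.  Ties are broken by stable input
    order.  Returns 1-based bin indices aligned with the input.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} values into {k} bins")
    order = np.argsort(v, kind="stable")
    base, rem = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:rem] += 1
    bins = np.empty(n, dtype=int)
    bins[order] = np.repeat(np.arange(1, k + 1), sizes)
    return bins


def group_mean_ci(values, level: float = 0.95) -> tuple[float, float, float]:
    """Mean with a t-based confidence interval of the mean.

    Returns (mean, lo, hi).  Zero-variance input gives a degenerate interval;
    a single value gives (value, nan, nan).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = len(v)
    if n == 0:
        return np.nan, np.nan, np.nan
    m = float(v.mean())
    if n == 1:
        return m, np.nan, np.nan
    sem = v.std(ddof=1) / np.sqrt(n)
    if sem == 0:
        return m, m, m
    half = float(stats.t.ppf(0.5 + level / 2.0, df=n - 1) * sem)
    return m, m - half, m + half


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (Wilcoxon rank-sum).

    Exact for small samples without ties; the normal approximation with
    continuity correction otherwise.  Returns (U statistic of the first
    group, two-sided p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def stability_vs_expression(
    diff_table: pd.DataFrame,
    k: int = 10,
    split_by: str | None = None,
    expr_col: str = "delta_log2_expression",
    hl_col: str = "delta_log2_halflife",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential stability across bins of differential transcript level.

    Genes are split into ``k`` bins of equal counts by increasing
    differential expression (bins are global, computed on all genes); within
    each bin (and optional ``split_by`` group) the mean differential
    half-life and its 95% CI are reported.  The coupling statistic is the
    gene-level Spearman correlation between the two differentials, computed
    per group on all genes, not on bin means.  The bin whose expression range
    contains zero is flagged ``contains_zero``.

    Returns (bin summary, per-group Spearman table).
    """
    df = diff_table.dropna(subset=[expr_col, hl_col]).copy()
    if df.empty:
        raise ValueError("no genes with both differential quantities")
    df["bin"] = equal_count_bins(df[expr_col].to_numpy(), k)

    bin_lo = df.groupby("bin")[expr_col].min()
    bin_hi = df.groupby("bin")[expr_col].max()
    zero_bin = [b for b in bin_lo.index if bin_lo[b] <= 0.0 <= bin_hi[b]]

    group_keys = ["bin"] + ([split_by] if split_by else [])
    rows = []
    for keys, sub in df.groupby(group_keys):
        keys = keys if isinstance(keys, tuple) else (keys,)
        m, lo, hi = group_mean_ci(sub[hl_col])
        rec = {
            "bin": keys[0],
            "n": len(sub),
            "mean_delta_halflife": m,
            "ci_lo": lo,
            "ci_hi": hi,
            "mean_delta_expression": float(sub[expr_col].mean()),
            "contains_zero": keys[0] in zero_bin,
        }
        if split_by:
            rec["group"] = keys[1]
        rows.append(rec)
    summary = pd.DataFrame(rows).sort_values(group_keys).reset_index(drop=True)

    stat_rows = []
    for name, sub in (df.groupby(split_by) if split_by else [("all", df)]):
        rho, p = stats.spearmanr(sub[expr_col], sub[hl_col])
        stat_rows.append(
            {"group": name, "spearman_rho": float(rho), "p_value": float(p),
             "n": len(sub)}
        )
    return summary, pd.DataFrame(stat_rows)


def differential_curve(
    differences, threshold_h: float = 5.0
) -> dict:
    """Sorted gene-wise half-life differences and tail counts.

    Returns the ascending differences, their median, and how many genes
    differ by more than +threshold or less than -threshold hours.
    """
    d = np.asarray(differences, dtype=float)
    d = d[np.isfinite(d)]
    d.sort()
    return {
        "sorted_differences": d,
        "median": float(np.median(d)) if d.size else np.nan,
        "n_above": int((d > threshold_h).sum()),
        "n_below": int((d < -threshold_h).sum()),
    }


def halflife_ratio_density(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    cap_h: float = 16.0,
    value_col: str = "half_life_h",
) -> pd.DataFrame:
    """Per-gene log2 half-life ratios between two conditions.

    Joins on gene_id and returns log2(A/B) together with flags marking genes
    capped at the stability ceiling in either condition: both-capped genes
    have ratio 0 by construction and pile up as an artifact at the cap, so
    downstream density plots can identify them.
    """
    a = table_a.set_index("gene_id")[value_col]
    b = table_b.set_index("gene_id")[value_col]
    genes = a.index.intersection(b.index)
    a, b = a.loc[genes], b.loc[genes]
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "log2_ratio": np.log2(a.to_numpy() / b.to_numpy()),
            "capped_a": (a >= cap_h).to_numpy(),
            "capped_b": (b >= cap_h).to_numpy(),
        }
    )
    out["both_capped"] = out["capped_a"] & out["capped_b"]
    return out


# ---------------------------------------------------------------------------
# plotting (thin matplotlib wrappers)
# ---------------------------------------------------------------------------

def plot_differential_curve(curve: dict, path, ylabel="difference (h)") -> None:
    """Sorted differential half-life curve with the median marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = curve["sorted_differences"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.arange(1, len(d) + 1), d, lw=1.2)
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(np.searchsorted(d, curve["median"]) + 1, color="k", ls="--", lw=0.8)
    ax.set_xlabel("genes (increasing order)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bin_profile(summary: pd.DataFrame, path, split_by_group=True) -> None:
    """Per-bin mean with CI error bars, one line per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = (
        summary.groupby("group") if split_by_group and "group" in summary
        else [("all", summary)]
    )
    for name, sub in groups:
        sub = sub.sort_values("bin")
        yerr = np.vstack(
            [
                sub["mean_delta_halflife"] - sub["ci_lo"],
                sub["ci_hi"] - sub["mean_delta_halflife"],
            ]
        )
        ax.errorbar(
            sub["bin"], sub["mean_delta_halflife"], yerr=yerr,
            marker="o", capsize=3, label=str(name),
        )
    zero_bins = summary.loc[summary["contains_zero"], "bin"].unique()
    for zb in zero_bins:
        ax.axvspan(zb - 0.5, zb + 0.5, color="grey", alpha=0.2)
    ax.set_xlabel("differential transcript-level bin")
    ax.set_ylabel("mean differential half-life (log2)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
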