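"""The BRIC-seq half-life pipeline.

Stages, in order: gene-level filtering (total raw counts and early-time-point
cpm), per-gene time-point masking (low-cpm suffix and composition-rebound
rules), estimation of per-time-point normalization factors from complete-data
genes (fit each gene to a*exp(-b*t), collect correction coefficients
predicted/observed, average per time point, iterate), exponential decay
fitting of the factor-corrected counts (t_half = ln 2 / b, capped at 16 h),
and replicate merging.

Counts are fit on the raw (factor-corrected) scale; cpm enters only through
the filtering and masking thresholds.  All fits minimize the sum of squared
residuals of a*exp(-b*t); for fixed b the optimal amplitude is available in
closed form, so the optimizer is a profiled 1-D search over b (coarse grid
plus golden-section refinement), which is deterministic and fast enough to
refit thousands of genes per normalization iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HalfLifeConfig",
    "DecayFit",
    "NormFactors",
    "filter_genes",
    "mask_timepoints",
    "estimate_norm_factors",
    "fit_decay",
    "merge_replicates",
    "compute_half_lives",
    "counts_matrix",
    "parse_time_columns",
    "write_halflife_tsv",
    "read_halflife_tsv",
]

STATUS_FITTED = "fitted"
STATUS_CAPPED = "capped16"
STATUS_FAILED = "failed"


@dataclass(frozen=True)
class HalfLifeConfig:
    """Thresholds and numerical settings of the half-life pipeline."""

    raw_sum_min: float = 10.0        # genes with total raw counts below -> dropped
    cpm_early_min: float = 2.0       # cpm floor at each early time point
    early_timepoints: tuple[float, ...] = (0.0, 1.0, 2.0)
    cpm_point_min: float = 0.5       # per-time-point cpm floor (suffix masking)
    rebound_ratio: float = 3.0       # ">200% increase" read as ratio > 3
    cap_h: float = 16.0              # stability cap in hours
    min_points: int = 3              # minimum valid time points for a fit
    norm_mode: str = "iterative"     # "iterative" | "single" | "off"
    norm_min_genes: int = 50         # floor on complete-data genes
    norm_max_iter: int = 10
    norm_tol: float = 1e-3
    norm_average: str = "weighted"   # "weighted" | "arithmetic" | "geometric"
    b_lo: float = -2.0               # decay-rate search range (per hour)
    b_hi: float = 8.0
    grid_points: int = 201

    def __post_init__(self) -> None:
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        if self.rebound_ratio <= 1:
            raise ValueError("rebound_ratio must exceed 1")
        if self.norm_mode not in ("iterative", "single", "off"):
            raise ValueError("norm_mode must be iterative, single or off")
        if self.norm_average not in ("weighted", "arithmetic", "geometric"):
            raise ValueError("norm_average must be weighted, arithmetic or geometric")
        for name in ("raw_sum_min", "cpm_early_min", "cpm_point_min", "cap_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class NormFactors:
    """Per-time-point multiplicative correction factors."""

    factors: np.ndarray
    n_genes_used: int
    n_iterations: int


@dataclass
class DecayFit:
    """Exponential fit of one gene: amplitude a, rate b (1/h), half-life."""

    a: float
    b: float
    half_life_h: float
    status: str
    n_points_used: int
    rss: float


# ---------------------------------------------------------------------------
# tidy-table helpers
# ---------------------------------------------------------------------------

def parse_time_columns(df: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Time-point columns ('t0', 't1', ...) and their hours, in order."""
    cols = [c for c in df.columns if c.startswith("t") and c[1:].replace(".", "", 1).isdigit()]
    times = np.array([float(c[1:]) for c in cols])
    order = np.argsort(times)
    return [cols[i] for i in order], times[order]


def counts_matrix(
    counts: pd.DataFrame, condition: str, replicate: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene x time-point matrix of one replicate of one condition."""
    cols, times = parse_time_columns(counts)
    sel = counts[
        (counts["condition"] == condition) & (counts["replicate"] == replicate)
    ]
    mat = sel.set_index("gene_id")[cols]
    return mat, times


def _cpm(mat: pd.DataFrame) -> pd.DataFrame:
    lib = mat.sum(axis=0)
    return mat.div(lib.replace(0, np.nan), axis=1).mul(1e6).fillna(0.0)


# ---------------------------------------------------------------------------
# filtering and masking
# ---------------------------------------------------------------------------

def filter_genes(
    mat: pd.DataFrame, times: np.ndarray, config: HalfLifeConfig = HalfLifeConfig()
) -> pd.DataFrame:
    """Gene-level filter on raw totals and early-time-point cpm.

    A gene is dropped iff its total raw count is below ``raw_sum_min`` or its
    cpm is below ``cpm_early_min`` at any of the early time points (0, 1 and
    2 h).  cpm is computed on the full pre-filter library sizes.

    Returns a DataFrame indexed by gene with columns ``kept`` and ``reason``
    ('' | 'low_total' | 'low_early_cpm').
    """
    early_idx = [
        i for i, t in enumerate(times) if t in set(config.early_timepoints)
    ]
    if len(early_idx) < len(config.early_timepoints):
        raise ValueError(
            f"early time points {config.early_timepoints} not all present in {times}"
        )
    total = mat.sum(axis=1)
    cpm_early = _cpm(mat).iloc[:, early_idx]
    low_total = total < config.raw_sum_min
    low_early = (cpm_early < config.cpm_early_min).any(axis=1)
    reason = np.where(low_total, "low_total", np.where(low_early, "low_early_cpm", ""))
    return pd.DataFrame(
        {"kept": ~(low_total | low_early), "reason": reason}, index=mat.index
    )


def mask_timepoints(
    cpm_mat: pd.DataFrame, config: HalfLifeConfig = HalfLifeConfig()
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene time-point validity under the suffix and rebound rules.

    First, the earliest time point with cpm below ``cpm_point_min`` is
    masked together with every later time point (low-count tails of rapidly
    decaying genes are mostly noise).  Then, scanning the remaining valid
    points in order, a cpm increase from one point to the next exceeding the
    rebound threshold (ratio > ``rebound_ratio``, i.e. an increase > 200%
    with the default 3.0) masks the later point and all subsequent ones;
    such late rebounds reflect library composition becoming biased toward
    stable genes.

    Returns (valid-flags DataFrame, reason Series with
    '' | 'low_cpm_tail' | 'rebound_tail' | 'too_few_points').
    """
    vals = cpm_mat.to_numpy(dtype=float)
    n, k = vals.shape
    valid = np.ones((n, k), dtype=bool)
    reason = np.array([""] * n, dtype=object)

    low = vals < config.cpm_point_min
    first_low = np.where(low.any(axis=1), low.argmax(axis=1), k)
    col_idx = np.arange(k)
    valid &= col_idx[None, :] < first_low[:, None]
    reason[first_low < k] = "low_cpm_tail"

    # rebound scan on the surviving prefix
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratio = vals[:, 1:] / vals[:, :-1]
    rebound = np.zeros(n, dtype=int)
    rebound[:] = k
    for j in range(1, k):
        fires = (
            (col_idx[j] < first_low)
            & (ratio[:, j - 1] > config.rebound_ratio)
            & (rebound == k)
        )
        rebound[fires] = j
    valid &= col_idx[None, :] < rebound[:, None]
    hit = rebound < np.minimum(first_low, k)
    reason[hit] = "rebound_tail"

    too_few = valid.sum(axis=1) < config.min_points
    reason[too_few] = "too_few_points"

    return (
        pd.DataFrame(valid, index=cpm_mat.index, columns=cpm_mat.columns),
        pd.Series(reason, index=cpm_mat.index, name="reason"),
    )


# ---------------------------------------------------------------------------
# exponential fitting (profiled least squares over the decay rate)
# ---------------------------------------------------------------------------

def _profile_objective(b: np.ndarray, t: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """-(sum y*w)^2 / sum w^2 with w = exp(-b t); equals SSE minus sum y^2
    at the profiled optimal amplitude, so minimizing it minimizes the SSE."""
    W = np.exp(-b[:, None] * t[None, :])
    num = (Y * W).sum(axis=1)
    den = (W * W).sum(axis=1)
    return -(num * num) / den


def _fit_exp_batch(
    t: np.ndarray, Y: np.ndarray, config: HalfLifeConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares a*exp(-b*t) fits of many series sharing time points.

    Returns (a, b, rss) arrays.  Rows with no positive value get a = b = nan.
    """
    G, k = Y.shape
    grid = np.linspace(config.b_lo, config.b_hi, config.grid_points)
    W = np.exp(-np.outer(grid, t))
    num = Y @ W.T
    den = (W * W).sum(axis=1)
    obj = -(num * num) / den
    idx = obj.argmin(axis=1)
    lo = grid[np.maximum(idx - 1, 0)]
    hi = grid[np.minimum(idx + 1, len(grid) - 1)]

    gr = (np.sqrt(5.0) - 1.0) / 2.0
    c = hi - gr * (hi - lo)
    d = lo + gr * (hi - lo)
    fc = _profile_objective(c, t, Y)
    fd = _profile_objective(d, t, Y)
    for _ in range(90):
        left = fc < fd
        lo = np.where(left, lo, c)
        hi = np.where(left, d, hi)
        c = hi - gr * (hi - lo)
        d = lo + gr * (hi - lo)
        fc = _profile_objective(c, t, Y)
        fd = _profile_objective(d, t, Y)
    b = 0.5 * (lo + hi)
    Wb = np.exp(-b[:, None] * t[None, :])
    den_b = (Wb * Wb).sum(axis=1)
    a = (Y * Wb).sum(axis=1) / den_b
    rss = (Y * Y).sum(axis=1) - a * a * den_b
    rss = np.maximum(rss, 0.0)

    dead = ~(Y > 0).any(axis=1)
    a[dead] = np.nan
    b[dead] = np.nan
    rss[dead] = np.nan
    return a, b, rss


def fit_decay(
    values, times, config: HalfLifeConfig = HalfLifeConfig()
) -> DecayFit:
    """Fit a*exp(-b*t) to one gene's valid time points.

    The half-life is ln(2)/b.  A non-positive rate or a half-life above the
    16 h cap marks the transcript as very stable: status ``capped16`` with
    half_life_h = 16.  Fewer than ``min_points`` valid points, an all-zero
    series, or a non-finite optimum give status ``failed``.
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have equal length")
    n = len(y)
    if n < config.min_points:
        return DecayFit(np.nan, np.nan, np.nan, STATUS_FAILED, n, np.nan)
    a, b, rss = _fit_exp_batch(t, y[None, :], config)
    a, b, rss = float(a[0]), float(b[0]), float(rss[0])
    if not np.isfinite(a) or not np.isfinite(b):
        return DecayFit(np.nan, np.nan, np.nan, STATUS_FAILED, n, np.nan)
    if b <= 0 or np.log(2.0) / b > config.cap_h:
        return DecayFit(a, b, config.cap_h, STATUS_CAPPED, n, rss)
    return DecayFit(a, b, np.log(2.0) / b, STATUS_FITTED, n, rss)


# ---------------------------------------------------------------------------
# normalization factors from complete-data genes
# ---------------------------------------------------------------------------

def estimate_norm_factors(
    mat: pd.DataFrame,
    mask: pd.DataFrame,
    times: np.ndarray,
    config: HalfLifeConfig = HalfLifeConfig(),
) -> NormFactors:
    """Per-time-point correction factors from complete-data genes.

    Genes with valid data at every time point are fitted to a*exp(-b*t); the
    correction coefficient of gene g at time t is predicted/observed — the
    factor that turns the gene's observed curve into its fitted perfect
    exponential.  Coefficients are averaged per time point across genes to
    form the factors, the factors are applied, and the procedure is repeated
    on the corrected data until the per-iteration factors are within
    ``norm_tol`` of 1 (at most ``norm_max_iter`` rounds); the accumulated
    product is returned.  Purely exponential distortions are invisible to
    this procedure (they are absorbed into the fitted rates), so factors are
    identified only up to a factor c*exp(k*t); see docs/methods.md.
    """
    complete = mask.all(axis=1)
    Y0 = mat.loc[complete[complete].index].to_numpy(dtype=float)
    Y0 = Y0[(Y0 > 0).all(axis=1)]
    n_used = Y0.shape[0]
    if n_used < config.norm_min_genes:
        raise ValueError(
            f"only {n_used} genes have data for all time points; "
            f">= {config.norm_min_genes} are required to estimate "
            "normalization factors - provide a larger input or set "
            "norm_mode='off'"
        )
    k = len(times)
    f_acc = np.ones(k)
    max_iter = 1 if config.norm_mode == "single" else config.norm_max_iter
    Y = Y0.copy()
    n_iter = 0
    prev_dev = np.inf
    for n_iter in range(1, max_iter + 1):
        a, b, _ = _fit_exp_batch(times, Y, config)
        ok = np.isfinite(a) & np.isfinite(b)
        pred = a[ok, None] * np.exp(-np.outer(b[ok], times))
        coeff = pred / Y[ok]
        if config.norm_average == "weighted":
            # observed-count-weighted mean of the coefficients = ratio of
            # sums; unlike the plain mean of ratios it is not Jensen-biased
            # upward by sampling noise in the denominator.
            f_it = pred.sum(axis=0) / Y[ok].sum(axis=0)
        elif config.norm_average == "arithmetic":
            f_it = coeff.mean(axis=0)
        else:
            f_it = np.exp(np.log(coeff).mean(axis=0))
        dev = np.abs(f_it - 1.0).max()
        if n_iter > 1 and dev >= prev_dev:
            # stalled at the sampling-noise floor of the correction
            # estimates; applying further rounds only accumulates drift
            break
        f_acc *= f_it
        Y *= f_it
        if dev < config.norm_tol:
            break
        prev_dev = dev
    logger.info(
        "normalization factors from %d complete genes in %d iteration(s): %s",
        n_used, n_iter, np.array2string(f_acc, precision=4),
    )
    return NormFactors(factors=f_acc, n_genes_used=n_used, n_iterations=n_iter)


# ---------------------------------------------------------------------------
# replicate merging and the full pipeline
# ---------------------------------------------------------------------------

def merge_replicates(fits: list[DecayFit | None], cap_h: float = 16.0):
    """Pool per-replicate half-lives into one value.

    Replicate values in (0, cap] are averaged arithmetically; capped values
    participate (inclusive reading of "between 0 and 16 h").  If exactly one
    replicate is usable its value is taken, flagged ``single_replicate``;
    with no usable replicate the gene is absent (returns (nan, None)).
    """
    usable = [
        f.half_life_h
        for f in fits
        if f is not None
        and f.status in (STATUS_FITTED, STATUS_CAPPED)
        and 0.0 < f.half_life_h <= cap_h
    ]
    if not usable:
        return np.nan, None
    if len(usable) == 1 and len(fits) > 1:
        return usable[0], "single_replicate"
    return float(np.mean(usable)), "merged"


def _fit_replicate(
    mat: pd.DataFrame, times: np.ndarray, config: HalfLifeConfig
) -> tuple[pd.DataFrame, NormFactors | None, dict]:
    """Filter, mask, normalize and fit one replicate's count matrix."""
    flt = filter_genes(mat, times, config)
    kept = mat.loc[flt["kept"]]
    cpm_kept = _cpm(mat).loc[flt["kept"]]
    mask, mask_reason = mask_timepoints(cpm_kept, config)

    if config.norm_mode == "off":
        nf = None
        corrected = kept
    else:
        nf = estimate_norm_factors(kept, mask, times, config)
        corrected = kept * nf.factors

    n_valid = mask.sum(axis=1)
    results = pd.DataFrame(
        index=kept.index,
        columns=["a", "b", "half_life_h", "status", "n_points", "rss"],
    )
    results["status"] = STATUS_FAILED
    results["n_points"] = n_valid
    too_few = n_valid < config.min_points

    for npts in sorted(n_valid[~too_few].unique()):
        sel = (n_valid == npts) & ~too_few
        idx = results.index[sel]
        # masks are prefixes, so genes with equal n share the same time points
        tt = times[:npts]
        Y = corrected.loc[idx].to_numpy(dtype=float)[:, :npts]
        a, b, rss = _fit_exp_batch(tt, Y, config)
        hl = np.full(len(idx), np.nan)
        status = np.full(len(idx), STATUS_FAILED, dtype=object)
        ok = np.isfinite(a) & np.isfinite(b)
        with np.errstate(divide="ignore"):
            raw_hl = np.log(2.0) / b
        capped = ok & ((b <= 0) | (raw_hl > config.cap_h))
        fitted = ok & ~capped
        hl[capped] = config.cap_h
        hl[fitted] = raw_hl[fitted]
        status[capped] = STATUS_CAPPED
        status[fitted] = STATUS_FITTED
        results.loc[idx, "a"] = a
        results.loc[idx, "b"] = b
        results.loc[idx, "half_life_h"] = hl
        results.loc[idx, "status"] = status
        results.loc[idx, "rss"] = rss

    stage = {
        "genes_in": int(len(mat)),
        "kept_after_filter": int(flt["kept"].sum()),
        "dropped_low_total": int((flt["reason"] == "low_total").sum()),
        "dropped_low_early_cpm": int((flt["reason"] == "low_early_cpm").sum()),
        "too_few_points": int(too_few.sum()),
        "fitted": int((results["status"] == STATUS_FITTED).sum()),
        "capped16": int((results["status"] == STATUS_CAPPED).sum()),
        "failed": int((results["status"] == STATUS_FAILED).sum()),
    }
    return results, nf, stage


def compute_half_lives(
    counts: pd.DataFrame,
    config: HalfLifeConfig = HalfLifeConfig(),
) -> tuple[pd.DataFrame, dict]:
    """Run the full pipeline on a tidy count table (all replicates).

    ``counts`` columns: gene_id, condition, replicate, t<hours>...  Returns
    (half-life table, run report).  The table has one row per gene and
    condition with a merged half-life, plus per-replicate values and
    statuses; genes with no usable replicate are omitted.
    """
    if counts.empty:
        return (
            pd.DataFrame(
                columns=["gene_id", "condition", "half_life_h", "status"]
            ),
            {"conditions": {}},
        )
    report: dict = {"conditions": {}}
    tables = []
    for condition in counts["condition"].unique():
        reps = sorted(counts.loc[counts["condition"] == condition, "replicate"].unique())
        per_rep: dict[int, pd.DataFrame] = {}
        rep_report = {}
        for rep in reps:
            mat, times = counts_matrix(counts, condition, rep)
            results, nf, stage = _fit_replicate(mat, times, config)
            per_rep[rep] = results
            if nf is not None:
                stage["norm_factors"] = nf.factors.tolist()
                stage["norm_iterations"] = nf.n_iterations
                stage["norm_genes_used"] = nf.n_genes_used
            rep_report[str(rep)] = stage

        genes = pd.Index(
            sorted(set().union(*[set(r.index) for r in per_rep.values()]))
        )
        cond_table = pd.DataFrame({"gene_id": genes, "condition": condition})
        hl_cols, usable_cols = [], []
        for rep in reps:
            r = per_rep[rep].reindex(genes)
            hl = r["half_life_h"].to_numpy(dtype=float)
            status = r["status"].fillna("filtered").to_numpy(dtype=object)
            npts = r["n_points"].fillna(0).to_numpy(dtype=int)
            usable = (
                np.isin(status, [STATUS_FITTED, STATUS_CAPPED])
                & np.isfinite(hl)
                & (hl > 0)
                & (hl <= config.cap_h)
            )
            cond_table[f"half_life_rep{rep}"] = hl
            cond_table[f"status_rep{rep}"] = status
            cond_table[f"n_points_rep{rep}"] = npts
            hl_cols.append(np.where(usable, hl, np.nan))
            usable_cols.append(usable)
        hl_mat = np.column_stack(hl_cols)
        n_usable = np.column_stack(usable_cols).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            merged = np.nansum(hl_mat, axis=1) / n_usable
        cond_table["half_life_h"] = merged
        cond_table["status"] = np.where(
            (n_usable == 1) & (len(reps) > 1), "single_replicate", "merged"
        )
        cond_table = cond_table[n_usable > 0].reset_index(drop=True)
        tables.append(cond_table)
        rep_report["merged_genes"] = int(len(cond_table))
        n_expressed = max(
            (s["kept_after_filter"] for k, s in rep_report.items()
             if isinstance(s, dict)),
            default=0,
        )
        rep_report["fraction_determined"] = (
            float(len(cond_table)) / n_expressed if n_expressed else 0.0
        )
        report["conditions"][condition] = rep_report

    tables = [t for t in tables if not t.empty]
    if not tables:
        return (
            pd.DataFrame(columns=["gene_id", "condition", "half_life_h", "status"]),
            report,
        )
    table = pd.concat(tables, ignore_index=True)
    front = ["gene_id", "condition", "half_life_h", "status"]
    table = table[front + [c for c in table.columns if c not in front]]
    return table, report


def write_halflife_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_halflife_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
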