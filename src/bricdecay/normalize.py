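"""Library normalization: cpm, TPM, TMM factors, GeTMM, expressed-gene
threshold, and a median-of-ratios log2 fold-change.

TMM (trimmed mean of M-values) computes per-sample scaling factors from
doubly trimmed, precision-weighted log2 ratios against a reference sample;
GeTMM applies the TMM procedure to TPM values so that gene length enters the
between-sample normalization.  The log2 fold-change helper uses
median-of-ratios size factors over a geometric-mean pseudo-reference; it is a
deliberately simple substitute for a full differential-expression model (no
dispersion shrinkage, no significance testing).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "cpm",
    "tpm",
    "tmm_factors",
    "getmm",
    "expressed_mask",
    "log2fc_median_of_ratios",
    "write_expression_tsv",
    "read_expression_tsv",
]


def _as_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts with gene_id index; accepts a gene_id column or an index."""
    if "gene_id" in counts.columns:
        counts = counts.set_index("gene_id")
    return counts.astype(float)


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: count / column sum * 1e6, per sample."""
    m = _as_matrix(counts)
    lib = m.sum(axis=0)
    zero = lib == 0
    if zero.any():
        logger.warning("all-zero library column(s): %s", list(lib.index[zero]))
        lib = lib.replace(0, np.nan)
    out = m.div(lib, axis=1).mul(1e6).fillna(0.0)
    out.attrs["unit"] = "cpm"
    return out


def tpm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Transcripts per million given per-gene lengths in bp.

    rate_g = count_g / length_g; TPM_g = rate_g / sum(rate) * 1e6.
    """
    m = _as_matrix(counts)
    lengths = pd.Series(lengths_bp).reindex(m.index)
    if lengths.isna().any():
        missing = list(m.index[lengths.isna()])[:5]
        raise ValueError(f"missing lengths for genes, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = m.div(lengths, axis=0)
    out = rate.div(rate.sum(axis=0), axis=1).mul(1e6).fillna(0.0)
    out.attrs["unit"] = "TPM"
    return out


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Log2 TMM factor of one sample against the reference sample."""
    pos = (obs > 0) & (ref > 0)
    o, r = obs[pos], ref[pos]
    if o.size == 0:
        logger.warning("no genes shared with reference sample; factor set to 1")
        return 0.0
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # delta-method variance of M under binomial sampling
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = M.size
    lo_m = int(np.floor(n * logratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * sum_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank(method="average").to_numpy()
    rank_a = pd.Series(A).rank(method="average").to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        logger.warning("no genes survive TMM trimming; factor set to 1")
        return 0.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    matrix: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    ref_column: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples (unless ``ref_column`` is given).
    Genes with a zero in either compared sample are excluded pairwise.
    """
    m = _as_matrix(matrix)
    if m.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = m.sum(axis=0).to_numpy()
    frac = m.to_numpy() / lib
    if ref_column is None:
        q75 = np.quantile(frac, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = list(m.columns).index(ref_column)
    ref = m.iloc[:, ref_idx].to_numpy()
    log2f = np.zeros(m.shape[1])
    for j in range(m.shape[1]):
        if j == ref_idx:
            continue
        log2f[j] = _tmm_pair(
            m.iloc[:, j].to_numpy(), ref, lib[j], lib[ref_idx],
            logratio_trim, sum_trim,
        )
    factors = 2.0 ** log2f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.columns, name="tmm_factor")


def getmm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Gene-length-corrected TMM: TPM values rescaled by TMM factors
    estimated on the TPM table (GeTMM)."""
    t = tpm(counts, lengths_bp)
    factors = tmm_factors(t)
    out = t.div(factors, axis=1)
    out.attrs["unit"] = "GeTMM"
    return out


def expressed_mask(
    expression: pd.DataFrame, threshold: float = 0.2, samples=None
) -> pd.Series:
    """Genes expressed strictly above ``threshold`` in all given samples
    (default: all columns).  The conventional cutoff is 0.2 GeTMM in both
    compared samples."""
    cols = list(expression.columns) if samples is None else list(samples)
    return (expression[cols] > threshold).all(axis=1)


def log2fc_median_of_ratios(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    min_total: int = 10,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-gene log2 fold change of condition B over condition A.

    Size factors per sample are medians of ratios to the geometric-mean
    pseudo-reference (genes with a zero anywhere drop out of the reference);
    the fold change is the ratio of normalized condition means with a
    pseudocount.  Genes whose raw-count total across all samples is below
    ``min_total`` are excluded from the result.
    """
    a = _as_matrix(counts_a)
    b = _as_matrix(counts_b)
    genes = a.index.intersection(b.index)
    a, b = a.loc[genes], b.loc[genes]
    all_counts = pd.concat([a, b], axis=1)
    if (all_counts.sum(axis=0) == 0).any():
        raise ValueError("a sample has zero counts for all genes")

    keep = all_counts.sum(axis=1) >= min_total
    m = all_counts.to_numpy()
    log_gm = np.mean(np.log(np.where(m > 0, m, np.nan)), axis=1)
    ref_ok = np.isfinite(log_gm) & (m > 0).all(axis=1)
    if not ref_ok.any():
        raise ValueError("no genes usable for size-factor estimation")
    sf = np.exp(
        np.median(np.log(m[ref_ok]) - log_gm[ref_ok, None], axis=0)
    )
    norm = m / sf
    na, nb = a.shape[1], b.shape[1]
    mean_a = norm[:, :na].mean(axis=1)
    mean_b = norm[:, na : na + nb].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    out = pd.Series(lfc, index=genes, name="log2fc")[keep]
    return out


def write_expression_tsv(table: pd.DataFrame, path) -> None:
    """Write an expression table with its unit recorded as a header comment."""
    unit = table.attrs.get("unit", "raw")
    with open(path, "w") as fh:
        fh.write(f"# unit={unit}\n")
        table.to_csv(fh, sep="\t", index=True, index_label="gene_id")


def read_expression_tsv(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        unit = "raw"
        if first.startswith("# unit="):
            unit = first.strip().split("=", 1)[1]
            table = pd.read_csv(fh, sep="\t", index_col="gene_id")
        else:
            fh.seek(0)
            table = pd.read_csv(fh, sep="\t", index_col="gene_id")
    table.attrs["unit"] = unit
    return table
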