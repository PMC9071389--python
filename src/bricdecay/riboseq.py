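"""Per-gene ribosome densities from paired ribo-seq / RNA-seq CDS counts.

The density of a gene is the ratio of its ribo-seq TPM to its RNA-seq TPM,
with TPMs computed over the union CDS length.  Lowly covered genes are
removed: raw ribo-seq count < 10, raw RNA-seq count < 50, ribo-seq TPM < 2
or RNA-seq TPM < 5 (all strict).  Because the density is a ratio of TPMs it
is invariant to either library's sequencing depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalize import tpm

__all__ = ["ribosome_density"]


def _as_series(table, value_col: str = "count") -> pd.Series:
    if isinstance(table, pd.Series):
        return table.astype(float)
    return table.set_index("gene_id")[value_col].astype(float)


def ribosome_density(
    ribo_counts,
    rna_counts,
    cds_lengths,
    ribo_raw_min: float = 10.0,
    rna_raw_min: float = 50.0,
    ribo_tpm_min: float = 2.0,
    rna_tpm_min: float = 5.0,
    value_col: str = "count",
) -> pd.DataFrame:
    """Ribosome density table for genes passing the coverage filters.

    Parameters are the raw-count and TPM floors (genes strictly below any
    floor are flagged, not kept).  ``cds_lengths`` maps gene_id to union CDS
    length in bp; genes present in only one count table are flagged
    ``mismatch`` and genes without CDS ``no_cds``.  TPMs are computed on the
    full gene set before filtering.

    Returns a DataFrame with gene_id, raw counts, TPMs, ``density``
    (TPM ratio), ``density_per_kb`` (ratio divided by CDS length in kb),
    ``kept`` and ``reason``.
    """
    ribo = _as_series(ribo_counts, value_col)
    rna = _as_series(rna_counts, value_col)
    lengths = pd.Series(cds_lengths).astype(float)

    genes = ribo.index.union(rna.index)
    out = pd.DataFrame(index=genes)
    out["raw_ribo"] = ribo.reindex(genes)
    out["raw_rna"] = rna.reindex(genes)

    mismatch = out["raw_ribo"].isna() | out["raw_rna"].isna()
    no_cds = (~mismatch) & (
        lengths.reindex(genes).isna() | (lengths.reindex(genes) <= 0)
    )
    usable = ~(mismatch | no_cds)

    shared = genes[usable]
    L = lengths.reindex(shared)
    tpm_ribo = tpm(ribo.loc[shared].to_frame("ribo"), L)["ribo"]
    tpm_rna = tpm(rna.loc[shared].to_frame("rna"), L)["rna"]
    out.loc[shared, "tpm_ribo"] = tpm_ribo
    out.loc[shared, "tpm_rna"] = tpm_rna

    reason = pd.Series("", index=genes, dtype=object)
    reason[mismatch] = "mismatch"
    reason[no_cds] = "no_cds"
    low = pd.Series("", index=shared, dtype=object)
    low[(tpm_rna < rna_tpm_min)] = "low_rna_tpm"
    low[(tpm_ribo < ribo_tpm_min)] = "low_ribo_tpm"
    low[out.loc[shared, "raw_rna"] < rna_raw_min] = "low_rna_raw"
    low[out.loc[shared, "raw_ribo"] < ribo_raw_min] = "low_ribo_raw"
    reason.loc[shared] = low

    kept = usable & (reason == "")
    out["kept"] = kept
    out["reason"] = reason
    with np.errstate(divide="ignore", invalid="ignore"):
        density = out["tpm_ribo"] / out["tpm_rna"]
    out["density"] = density.where(kept)
    out["density_per_kb"] = (
        out["density"] / (lengths.reindex(genes) / 1000.0)
    ).where(kept)
    out.index.name = "gene_id"
    return out.reset_index()
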