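"""Gene-model annotation: union exon/CDS lengths, chromosome groups,
housekeeping classification.

"RNA length" is the number of bases covered by the union of a gene's exons
across all its transcripts; CDS length is defined analogously.  The autosome
group "A" merges the main arms 2L, 2R, 3L and 3R; chromosome 4 is kept as its
own group (it is an ancestral sex chromosome and is excluded from A).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "union_length",
    "assign_chrom_group",
    "classify_housekeeping",
    "read_gtf_annotation",
    "write_annotation_tsv",
    "read_annotation_tsv",
]

AUTOSOME_ARMS = frozenset({"2L", "2R", "3L", "3R"})


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Bases covered by the union of 1-based closed genomic intervals.

    Intervals may overlap and come in any order (e.g. exons of several
    transcripts of one gene).
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    for s, e in ivs:
        if e < s:
            raise ValueError(f"negative-length interval ({s}, {e})")
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def assign_chrom_group(chromosome: str) -> str:
    """Map a chromosome name to {'X', 'A', '4', 'other'}."""
    name = str(chromosome)
    if name.startswith("chr"):
        name = name[3:]
    if name == "X":
        return "X"
    if name in AUTOSOME_ARMS:
        return "A"
    if name == "4":
        return "4"
    return "other"


def classify_housekeeping(
    tissue_matrix: pd.DataFrame,
    threshold: float = 6.0,
    required_tissues: int = 12,
) -> pd.Series:
    """Flag genes expressed above ``threshold`` in every tissue.

    A gene is housekeeping iff its expression is strictly greater than the
    threshold in all tissues (default 12, FlyAtlas-style); a gene above the
    threshold in 11 or fewer tissues is non-housekeeping.  Missing values are
    treated as not above the threshold, with a warning.

    ``tissue_matrix`` must contain a ``gene_id`` column; every other column is
    treated as a tissue.
    """
    tissues = [c for c in tissue_matrix.columns if c != "gene_id"]
    if len(tissues) < required_tissues:
        raise ValueError(
            f"need >= {required_tissues} tissue columns, got {len(tissues)}"
        )
    vals = tissue_matrix[tissues]
    if vals.isna().any().any():
        logger.warning(
            "tissue matrix contains missing values; treated as <= threshold"
        )
    flags = (vals > threshold).fillna(False).all(axis=1)
    return pd.Series(
        flags.to_numpy(),
        index=tissue_matrix["gene_id"].to_numpy(),
        name="housekeeping",
    )


def read_gtf_annotation(path) -> pd.DataFrame:
    """Parse a GTF into per-gene annotation.

    Returns a DataFrame with columns gene_id, chromosome, chrom_group,
    union_exon_len_bp and union_cds_len_bp.  Exon and CDS intervals of all
    transcripts of a gene are merged regardless of strand, matching
    gene-level read counting.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    chrom: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        gid = feat.attributes["gene_id"][0]
        if gid in chrom and chrom[gid] != feat.seqid:
            raise ValueError(f"gene {gid} has features on multiple chromosomes")
        chrom[gid] = feat.seqid
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(gid, []).append((feat.start, feat.end))

    rows = []
    for gid in chrom:
        rows.append(
            {
                "gene_id": gid,
                "chromosome": chrom[gid],
                "chrom_group": assign_chrom_group(chrom[gid]),
                "union_exon_len_bp": union_length(exons.get(gid, [])),
                "union_cds_len_bp": union_length(cds.get(gid, [])),
            }
        )
    return pd.DataFrame(rows)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str, "chrom_group": str})
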