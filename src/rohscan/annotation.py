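"""Gene annotation geometry: nearest gene, genes within a window, genes in a region.

Distances are edge-to-point gaps in bp on 1-based inclusive spans; a query
overlapping a gene has distance 0.  Strand is ignored.  Gene tables come
from :func:`rohscan.io.read_gene_intervals` (columns ``gene_id, chrom,
start_bp, end_bp``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HIT_COLUMNS = ["query", "gene_id", "relation", "distance_bp"]


def _distances(bp: int, genes: pd.DataFrame) -> np.ndarray:
    start = genes["start_bp"].to_numpy(dtype=np.int64)
    end = genes["end_bp"].to_numpy(dtype=np.int64)
    return np.maximum(0, np.maximum(start - bp, bp - end))


def nearest_gene(
    chrom: int, bp: int, genes: pd.DataFrame, query: str = ""
) -> dict | None:
    """Nearest gene on the same chromosome by edge distance, or None.

    Ties are broken by lower start position, then lexicographic gene id.
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return None
    d = _distances(bp, sub)
    best = d.min()
    cand = sub.loc[d == best].sort_values(["start_bp", "gene_id"], kind="mergesort")
    gene = cand.iloc[0]
    return {
        "query": query,
        "gene_id": gene["gene_id"],
        "relation": "contains" if best == 0 else "nearest",
        "distance_bp": int(best),
    }


def genes_within(
    chrom: int, bp: int, genes: pd.DataFrame, window: int = 1_000_000, query: str = ""
) -> pd.DataFrame:
    """All genes with edge distance <= window (inclusive) of the position."""
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return pd.DataFrame(columns=HIT_COLUMNS)
    d = _distances(bp, sub)
    hit = sub.loc[d <= window].copy()
    out = pd.DataFrame(
        {
            "query": query,
            "gene_id": hit["gene_id"].to_numpy(),
            "relation": np.where(d[d <= window] == 0, "contains", "within_window"),
            "distance_bp": d[d <= window].astype(int),
        }
    )
    return out.sort_values(["distance_bp", "gene_id"], kind="mergesort").reset_index(drop=True)


def genes_in_region(
    chrom: int, start_bp: int, end_bp: int, genes: pd.DataFrame, query: str = ""
) -> pd.DataFrame:
    """Genes overlapping the 1-based inclusive span by at least 1 bp."""
    sub = genes[
        (genes["chrom"] == chrom)
        & (genes["end_bp"] >= start_bp)
        & (genes["start_bp"] <= end_bp)
    ]
    return pd.DataFrame(
        {
            "query": query,
            "gene_id": sub["gene_id"].to_numpy(),
            "relation": "contains",
            "distance_bp": 0,
        },
        columns=HIT_COLUMNS,
    ).reset_index(drop=True)


def annotate_markers(
    markers: pd.DataFrame, genes: pd.DataFrame, window: int = 1_000_000
) -> pd.DataFrame:
    """Nearest-gene plus window hits for a table of (snp_id, chrom, bp) markers."""
    rows = []
    for m in markers.itertuples(index=False):
        near = nearest_gene(int(m.chrom), int(m.bp), genes, query=str(m.snp_id))
        if near is not None:
            rows.append(near)
        win = genes_within(int(m.chrom), int(m.bp), genes, window, query=str(m.snp_id))
        rows.extend(
            r for r in win.to_dict("records")
            if not (near and r["gene_id"] == near["gene_id"] and r["relation"] == near["relation"])
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def annotate_regions(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Contained-gene hits for a table of (chrom, start_bp, end_bp) regions."""
    rows = []
    for i, r in enumerate(regions.itertuples(index=False)):
        q = getattr(r, "cluster_id", None) or f"{r.chrom}:{r.start_bp}-{r.end_bp}"
        hits = genes_in_region(int(r.chrom), int(r.start_bp), int(r.end_bp), genes, query=str(q))
        rows.extend(hits.to_dict("records"))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
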