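"""Runs of homozygosity: consecutive-runs detection, length classes, F_ROH.

A run of homozygosity (ROH) is a contiguous stretch of SNPs at which an
individual is homozygous, indicating both chromosomes carry the same
haplotype.  Detection here is the windowless "consecutive runs" method: a
left-to-right scan per individual per chromosome grows a candidate run over
consecutive map SNPs, tolerating a bounded number of heterozygous and
missing calls and a bounded physical gap between adjacent SNPs.  A SNP that
would exceed a tolerance closes the run; scanning resumes immediately after
the violating position, so the runs of one individual never overlap.

Two parameter presets are provided: ``ISLAND_PARAMS`` (55 SNPs, 1 Mb, <=1
het, <=1 missing, gaps <=1 Mb) for per-population sweep mapping, and
``CLUSTER_PARAMS`` which adds a minimum SNP density of 1 SNP per 150 kb for
consensus-cluster detection.

The genomic inbreeding coefficient F_ROH is the fraction of the mapped
autosomal extent (L_AUTO) covered by an individual's runs:
``F_ROH = sum(L_ROH) / L_AUTO``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

LENGTH_CLASSES = ["lt6", "6to12", "12to24", "ge24"]
_CLASS_EDGES_BP = np.array([6_000_000, 12_000_000, 24_000_000])

SEGMENT_COLUMNS = [
    "sample_id",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "n_het",
    "n_missing",
    "length_bp",
    "length_class",
]


@dataclass(frozen=True)
class RohParams:
    """Constraints of the consecutive-runs scan.

    min_density_bp_per_snp, when set, requires length_bp / n_snps to stay at
    or below the given span per SNP (1 SNP per 150 kb in cluster mode).
    """

    min_snps: int = 55
    min_length_bp: int = 1_000_000
    max_het: int = 1
    max_missing: int = 1
    max_gap_bp: int = 1_000_000
    min_density_bp_per_snp: int | None = None


ISLAND_PARAMS = RohParams()
CLUSTER_PARAMS = RohParams(min_density_bp_per_snp=150_000)


def classify_length(length_bp: int) -> str:
    """Length class on half-open Mb bins [0,6), [6,12), [12,24), [24, inf)."""
    return LENGTH_CLASSES[int(np.searchsorted(_CLASS_EDGES_BP, length_bp, side="right"))]


def _scan_chromosome(geno: np.ndarray, bp: np.ndarray, p: RohParams) -> list[tuple]:
    """Consecutive-runs scan of one individual's calls on one chromosome.

    Returns (start_idx, end_idx) pairs of trimmed candidate runs that pass
    the emission thresholds.  Runs are anchored on homozygous non-missing
    SNPs at both ends; interior het/missing tolerances are enforced during
    growth and the violating SNP is excluded from the closed run.
    """
    n = len(bp)
    hom = (geno == 0) | (geno == 2)
    out = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        het = miss = 0
        k = i + 1
        viol_kind = None
        while k < n:
            if bp[k] - bp[k - 1] > p.max_gap_bp:
                viol_kind = "gap"
                break
            gk = geno[k]
            if gk == 1:
                if het >= p.max_het:
                    viol_kind = "geno"
                    break
                het += 1
            elif gk == MISSING:
                if miss >= p.max_missing:
                    viol_kind = "geno"
                    break
                miss += 1
            k += 1
        # trim trailing het/missing so the run ends on a homozygous SNP
        e = k - 1
        while e > i and not hom[e]:
            e -= 1
        n_snps = e - i + 1
        length = int(bp[e] - bp[i])
        if (
            n_snps >= p.min_snps
            and length >= p.min_length_bp
            and (
                p.min_density_bp_per_snp is None
                or length / n_snps <= p.min_density_bp_per_snp
            )
        ):
            out.append((i, e))
        if viol_kind == "geno":
            i = k + 1  # the violating SNP cannot anchor or join a run
        else:  # gap break or chromosome end: the SNP after the gap may anchor
            i = k
    return out


def detect_roh(g: GenotypeMatrix, params: RohParams | None = None) -> pd.DataFrame:
    """Detect ROH for every individual in the panel.

    The panel must be sorted by (chrom, bp) — loaders guarantee this.
    Returns one row per run with span, SNP/het/missing counts,
    ``length_bp = end_bp - start_bp`` and the length class.
    """
    p = params or ISLAND_PARAMS
    if not g.is_sorted():
        raise ValueError("panel SNP map is not sorted by (chrom, bp)")
    rows = []
    chroms = g.snps["chrom"].to_numpy()
    bps = g.snps["bp"].to_numpy(dtype=np.int64)
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        bp = bps[sel]
        block = g.calls[:, sel]
        for si, sid in enumerate(g.samples):
            geno = block[si]
            for i, e in _scan_chromosome(geno, bp, p):
                seg = geno[i : e + 1]
                length = int(bp[e] - bp[i])
                rows.append(
                    (
                        sid,
                        int(chrom),
                        int(bp[i]),
                        int(bp[e]),
                        e - i + 1,
                        int((seg == 1).sum()),
                        int((seg == MISSING).sum()),
                        length,
                        classify_length(length),
                    )
                )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def mapped_autosome_extent(snp_map: pd.DataFrame) -> int:
    """L_AUTO: sum over chromosomes of (last SNP bp - first SNP bp)."""
    if len(snp_map) == 0:
        raise ValueError("empty SNP map")
    span = snp_map.groupby("chrom")["bp"].agg(["min", "max"])
    return int((span["max"] - span["min"]).sum())


def compute_f_roh(
    segments: pd.DataFrame,
    snp_map: pd.DataFrame,
    samples: list[str] | None = None,
    l_auto_bp: int | None = None,
) -> pd.DataFrame:
    """Per-individual F_ROH, total and by length class.

    ``l_auto_bp`` overrides the denominator (e.g. to a published autosomal
    extent); by default it is the mapped extent of ``snp_map``.  ``samples``
    lists individuals to report, including those without any run (F_ROH 0).
    """
    l_auto = l_auto_bp if l_auto_bp is not None else mapped_autosome_extent(snp_map)
    if samples is None:
        samples = sorted(segments["sample_id"].unique())
    per_class = (
        segments.groupby(["sample_id", "length_class"], observed=True)["length_bp"]
        .sum()
        .unstack(fill_value=0)
        .reindex(index=samples, columns=LENGTH_CLASSES, fill_value=0)
        .fillna(0)
    )
    out = pd.DataFrame({"sample_id": samples})
    for cls in LENGTH_CLASSES:
        out[f"f_roh_{cls}"] = per_class[cls].to_numpy() / l_auto
    out["f_roh_total"] = out[[f"f_roh_{c}" for c in LENGTH_CLASSES]].sum(axis=1)
    out["l_auto_bp"] = l_auto
    return out


def summarize_roh(
    segments: pd.DataFrame, groups: pd.Series | None = None
) -> dict[str, pd.DataFrame]:
    """Descriptive ROH tables.

    Returns ``per_chrom_class`` (segment counts per chromosome per length
    class), ``per_sample`` (count and summed length per individual) and,
    when ``groups`` maps sample_id -> group, ``group_class_pct`` (percentage
    of a group's segments in each length class).
    """
    per_chrom = (
        segments.groupby(["chrom", "length_class"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=LENGTH_CLASSES, fill_value=0)
        .fillna(0)
        .astype(int)
    )
    per_sample = segments.groupby("sample_id").agg(
        n_segments=("length_bp", "size"), total_length_bp=("length_bp", "sum")
    )
    out = {"per_chrom_class": per_chrom, "per_sample": per_sample.reset_index()}
    if groups is not None:
        seg = segments.assign(group=segments["sample_id"].map(groups))
        counts = (
            seg.groupby(["group", "length_class"], observed=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=LENGTH_CLASSES, fill_value=0)
            .fillna(0)
        )
        out["group_class_pct"] = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return out
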