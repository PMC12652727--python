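"""Population-level homozygosity: in-ROH SNP frequencies, ROH islands,
consensus ROH clusters, and the genome-wide homozygosity association test.

An ROH *island* is a maximal run of consecutive map SNPs each lying inside
an ROH in at least a threshold fraction (default 50%) of a population's
individuals — the classical selective-sweep signal.  An ROH *cluster* is the
support-count analogue: a maximal run of SNPs covered by runs of at least
``min_support`` individuals (default 20) breed-wide, detected from segments
called with the density-constrained cluster parameter set.

The homozygosity association test cross-tabulates, at each cluster's lead
SNP (its first SNP by position), the binary in-ROH state against membership
in two disjoint sample groups: a Pearson chi-square (1 df, no continuity
correction) when all expected counts are >= 5, otherwise a two-sided Fisher
exact test, Bonferroni-corrected over the clusters tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ISLAND_COLUMNS = ["population", "chrom", "start_bp", "end_bp", "n_snps", "peak_freq", "mean_freq"]
CLUSTER_COLUMNS = [
    "cluster_id", "chrom", "start_bp", "end_bp", "n_snps",
    "support", "lead_snp", "lead_bp", "length_bp",
]


def _coverage_counts(
    segments: pd.DataFrame, snp_map: pd.DataFrame, samples: list[str]
) -> np.ndarray:
    """Number of ``samples`` whose ROH covers each map SNP (map order)."""
    chroms = snp_map["chrom"].to_numpy()
    bps = snp_map["bp"].to_numpy(dtype=np.int64)
    counts = np.zeros(len(snp_map) + 1, dtype=np.int64)
    offsets = {}
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        offsets[int(chrom)] = (idx[0], bps[idx])
    segs = segments[segments["sample_id"].isin(set(samples))]
    # merge each individual's spans per chromosome so an individual counts
    # once even if fed overlapping segments
    for (_, chrom), sub in segs.groupby(["sample_id", "chrom"]):
        if int(chrom) not in offsets:
            continue
        off, bp = offsets[int(chrom)]
        sub = sub.sort_values("start_bp")
        cur_s = cur_e = None
        spans = []
        for s, e in zip(sub["start_bp"], sub["end_bp"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                spans.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        spans.append((cur_s, cur_e))
        for s, e in spans:
            lo = off + np.searchsorted(bp, s, side="left")
            hi = off + np.searchsorted(bp, e, side="right")
            counts[lo] += 1
            counts[hi] -= 1
    return np.cumsum(counts[:-1])


def snp_roh_frequency(
    segments: pd.DataFrame, snp_map: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-population fraction of individuals in-ROH at every map SNP.

    ``groups`` maps sample_id -> population label and defines the
    per-population denominators (the post-QC population sizes).  A SNP is
    in-ROH for an individual iff some segment of that individual spans it.
    """
    unknown = segments.loc[~segments["sample_id"].isin(groups.index), "sample_id"]
    if len(unknown):
        raise ValueError(f"segments for samples without a group label: {sorted(set(unknown))[:5]}")
    frames = []
    for pop, members in groups.groupby(groups):
        samples = list(members.index)
        counts = _coverage_counts(segments, snp_map, samples)
        frames.append(
            pd.DataFrame(
                {
                    "population": pop,
                    "snp_id": snp_map["snp_id"].to_numpy(),
                    "chrom": snp_map["chrom"].to_numpy(),
                    "bp": snp_map["bp"].to_numpy(),
                    "n_in_roh": counts,
                    "n_total": len(samples),
                    "freq": counts / len(samples),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _threshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) index pairs, inclusive."""
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above) - 1]
    return list(zip(starts, ends))


def detect_islands(freqs: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """ROH islands: maximal consecutive-SNP runs with freq >= threshold.

    The threshold is inclusive ("at least 50% of individuals").  Input is
    the output of :func:`snp_roh_frequency`; islands are reported per
    population with the span of the first/last qualifying SNP.
    """
    rows = []
    for (pop, chrom), sub in freqs.groupby(["population", "chrom"], sort=True):
        sub = sub.sort_values("bp", kind="mergesort")
        f = sub["freq"].to_numpy()
        bp = sub["bp"].to_numpy()
        for s, e in _threshold_runs(f >= threshold):
            rows.append(
                (pop, int(chrom), int(bp[s]), int(bp[e]), e - s + 1,
                 float(f[s : e + 1].max()), float(f[s : e + 1].mean()))
            )
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS)


def detect_clusters(
    segments: pd.DataFrame,
    snp_map: pd.DataFrame,
    samples: list[str],
    min_support: int = 20,
) -> pd.DataFrame:
    """Consensus ROH clusters: maximal SNP runs covered by >= min_support individuals.

    Segments should come from cluster-mode detection (density-constrained).
    The lead SNP is the first SNP of the run by position and represents the
    cluster in association testing.  Single-SNP clusters are retained.
    """
    if min_support > len(samples):
        logger.warning(
            "min_support %d exceeds sample count %d; no clusters possible",
            min_support, len(samples),
        )
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    counts = _coverage_counts(segments, snp_map, samples)
    chroms = snp_map["chrom"].to_numpy()
    bps = snp_map["bp"].to_numpy(dtype=np.int64)
    ids = snp_map["snp_id"].to_numpy()
    rows = []
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        above = counts[idx] >= min_support
        for s, e in _threshold_runs(above):
            lo, hi = idx[s], idx[e]
            rows.append(
                (
                    f"cluster_{len(rows) + 1}",
                    int(chrom),
                    int(bps[lo]),
                    int(bps[hi]),
                    hi - lo + 1,
                    int(counts[lo : hi + 1].max()),
                    str(ids[lo]),
                    int(bps[lo]),
                    int(bps[hi] - bps[lo]),
                )
            )
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def in_roh_state(
    segments: pd.DataFrame, samples: list[str], chrom: int, bp: int
) -> np.ndarray:
    """Boolean in-ROH state of each sample at one position."""
    segs = segments[
        (segments["chrom"] == chrom)
        & (segments["start_bp"] <= bp)
        & (segments["end_bp"] >= bp)
    ]
    covered = set(segs["sample_id"])
    return np.array([s in covered for s in samples])


def homozygosity_association(
    clusters: pd.DataFrame,
    segments: pd.DataFrame,
    groups: pd.Series,
    comparison: tuple[set[str], set[str]],
    labels: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Case-control homozygosity association at each cluster's lead SNP.

    ``comparison`` gives two disjoint sets of group labels (A, B); samples
    are assigned through ``groups``.  For each cluster a 2x2 table (group x
    in-ROH state at the lead SNP) is tested with Pearson chi-square when all
    expected counts are >= 5, otherwise Fisher's exact test; p-values are
    Bonferroni-corrected over the clusters tested in this comparison.
    """
    set_a, set_b = (set(comparison[0]), set(comparison[1]))
    if set_a & set_b:
        raise ValueError("comparison groups overlap")
    samples_a = [s for s, grp in groups.items() if grp in set_a]
    samples_b = [s for s, grp in groups.items() if grp in set_b]
    if not samples_a or not samples_b:
        raise ValueError("both comparison sides must be non-empty")
    label = (
        f"{labels[0]}_vs_{labels[1]}"
        if labels
        else f"{'+'.join(sorted(set_a))}_vs_{'+'.join(sorted(set_b))}"
    )
    n_tests = len(clusters)
    rows = []
    for cl in clusters.itertuples(index=False):
        in_a = in_roh_state(segments, samples_a, cl.chrom, cl.lead_bp).sum()
        in_b = in_roh_state(segments, samples_b, cl.chrom, cl.lead_bp).sum()
        table = np.array(
            [[in_a, len(samples_a) - in_a], [in_b, len(samples_b) - in_b]], dtype=float
        )
        expected = stats.contingency.expected_freq(table)
        if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
            if (expected >= 5).all():
                res = stats.chi2_contingency(table, correction=False)
                statistic, p, method = float(res.statistic), float(res.pvalue), "chi2"
            else:
                res = stats.fisher_exact(table.astype(int), alternative="two-sided")
                statistic, p, method = float(res.statistic), float(res.pvalue), "fisher"
        else:  # degenerate margin: no information
            statistic, p, method = np.nan, 1.0, "none"
        p_bonf = min(1.0, p * n_tests)
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "comparison": label,
                "chrom": cl.chrom,
                "lead_bp": cl.lead_bp,
                "a_in_roh": int(in_a),
                "a_not_in_roh": len(samples_a) - int(in_a),
                "b_in_roh": int(in_b),
                "b_not_in_roh": len(samples_b) - int(in_b),
                "method": method,
                "statistic": statistic,
                "p_value": p,
                "p_bonferroni": p_bonf,
                "neg_log10_p": float(-np.log10(max(p, 1e-300))),
                "significant": p_bonf <= alpha,
            }
        )
    return pd.DataFrame(rows)
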