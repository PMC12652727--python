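"""Per-SNP Weir-Cockerham (1984) F_ST for two-population comparisons.

theta is estimated per SNP from the variance components

    a  — among populations,
    b  — among individuals within populations,
    c  — within individuals (heterozygosity),

computed from per-group complete-case sample sizes, allele frequencies and
observed heterozygote frequencies; ``theta = a / (a + b + c)``.  The
genome-wide summary is the weighted ratio ``sum(a) / sum(a + b + c)``.
Negative per-SNP estimates are reported as-is; SNPs monomorphic across both
groups (or with fewer than two non-missing genotypes in either group) have
undefined theta, recorded as NaN.

Scan designs follow the common within-breed usage: all pairwise group
comparisons, each group against the union of all others (one-vs-all), or a
designated pair of subgroups.  Markers with theta at or above a fixed
threshold (default 0.6) form the significant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

FST_COLUMNS = ["snp_id", "chrom", "bp", "n_a", "n_b", "a", "b", "c", "theta"]


def _group_freqs(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (n individuals, allele freq, observed het freq) over non-missing calls."""
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * n)
        h = (calls == 1).sum(axis=0) / n
    return n, p, h


def wc_fst_per_snp(
    g: GenotypeMatrix, group_a: list[str] | np.ndarray, group_b: list[str] | np.ndarray
) -> pd.DataFrame:
    """Two-population Weir-Cockerham variance components and theta per SNP.

    ``group_a`` / ``group_b`` are disjoint sample-id lists.  Returns one row
    per SNP with components a, b, c and theta (NaN where undefined).
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError("groups overlap")
    if not set_a or not set_b:
        raise ValueError("both groups must be non-empty")
    idx_a = [i for i, s in enumerate(g.samples) if s in set_a]
    idx_b = [i for i, s in enumerate(g.samples) if s in set_b]
    if len(idx_a) != len(set_a) or len(idx_b) != len(set_b):
        raise ValueError("group contains samples absent from the panel")

    n1, p1, h1 = _group_freqs(g.calls[idx_a])
    n2, p2, h2 = _group_freqs(g.calls[idx_b])

    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / np.where(denom != 0, denom, 1.0), np.nan)

    # undefined: fewer than 2 non-missing genotypes in a group, or monomorphic
    bad = (n1 < 2) | (n2 < 2) | (denom == 0) | ~np.isfinite(denom)
    for arr in (a, b, c, theta):
        arr[bad] = np.nan
    return pd.DataFrame(
        {
            "snp_id": g.snps["snp_id"].to_numpy(),
            "chrom": g.snps["chrom"].to_numpy(),
            "bp": g.snps["bp"].to_numpy(),
            "n_a": n1.astype(int),
            "n_b": n2.astype(int),
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
        }
    )


def weighted_fst(components: pd.DataFrame) -> float:
    """Genome-wide weighted theta: sum(a) / sum(a + b + c) over defined SNPs."""
    ok = components["theta"].notna()
    denom = (components.loc[ok, "a"] + components.loc[ok, "b"] + components.loc[ok, "c"]).sum()
    if denom == 0:
        return float("nan")
    return float(components.loc[ok, "a"].sum() / denom)


@dataclass
class FstScanResult:
    """One comparison's per-SNP components, weighted mean, significant set."""

    comparison: str
    components: pd.DataFrame
    weighted_theta: float
    significant: pd.DataFrame  # rows with theta >= threshold

    def manhattan_table(self) -> pd.DataFrame:
        return self.components[["chrom", "bp", "snp_id", "theta"]].copy()


def _design_comparisons(labels: list[str], design: str, subgroups=None):
    if design == "pairwise_all":
        return [((a,), (b,)) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    if design == "one_vs_all":
        return [((a,), tuple(b for b in labels if b != a)) for a in labels]
    if design == "subgroup_pair":
        if not subgroups or len(subgroups) != 2:
            raise ValueError("subgroup_pair design needs exactly two group labels")
        missing = [s for s in subgroups if s not in labels]
        if missing:
            raise ValueError(f"design references absent groups: {missing}")
        return [((subgroups[0],), (subgroups[1],))]
    raise ValueError(f"unknown design {design!r}")


def fst_scan(
    g: GenotypeMatrix,
    groups: pd.Series,
    design: str = "one_vs_all",
    threshold: float = 0.6,
    subgroups: tuple[str, str] | None = None,
) -> dict[str, FstScanResult]:
    """Run per-SNP F_ST for every comparison in a scan design.

    ``groups`` maps sample_id -> group label.  In the one-vs-all design the
    second population is the union of all remaining samples.  The
    significant set is inclusive: theta >= threshold.
    """
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for la, lb in _design_comparisons(labels, design, subgroups):
        samples_a = list(groups.index[groups.isin(la)])
        samples_b = list(groups.index[groups.isin(lb)])
        comp = wc_fst_per_snp(g, samples_a, samples_b)
        name = f"{'+'.join(la)}_vs_{'+'.join(lb) if design != 'one_vs_all' else 'rest'}"
        sig = comp[comp["theta"] >= threshold].reset_index(drop=True)
        out[name] = FstScanResult(name, comp, weighted_fst(comp), sig)
    return out
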