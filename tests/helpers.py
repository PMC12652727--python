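"""Shared fixtures-in-code: panel builders and independent brute-force oracles.

The oracles here deliberately recompute everything from whole-window or
double-loop first principles so they share no code path with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rohscan import MISSING, GenotypeMatrix
from rohscan.roh import RohParams, classify_length


def make_panel(calls, bp=None, chrom=None, samples=None, alleles=("A", "G")):
    """Build a GenotypeMatrix from a 2-D call array and optional positions."""
    calls = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    n_samples, n_snps = calls.shape
    bp = np.arange(1, n_snps + 1) * 10_000 if bp is None else np.asarray(bp)
    chrom = np.ones(n_snps, dtype=int) if chrom is None else np.asarray(chrom)
    samples = samples or [f"s{i}" for i in range(n_samples)]
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(n_snps)],
            "chrom": chrom,
            "bp": bp,
            "a1": alleles[0],
            "a2": alleles[1],
        }
    )
    return GenotypeMatrix(samples, snps, calls)


def _window_admissible(geno, bp, i, j, p: RohParams) -> bool:
    """Whole-window admissibility: recounted from scratch every call."""
    w = geno[i : j + 1]
    if int((w == 1).sum()) > p.max_het:
        return False
    if int((w == MISSING).sum()) > p.max_missing:
        return False
    gaps = np.diff(bp[i : j + 1])
    return bool((gaps <= p.max_gap_bp).all()) if len(gaps) else True


def brute_force_roh(geno, bp, p: RohParams) -> list[tuple[int, int]]:
    """Maximal admissible windows under the left-to-right scan-restart rule.

    Start at the leftmost homozygous SNP; extend while the whole window
    (re-checked by full recount) stays admissible; trim the end to the last
    homozygous SNP; emit if the thresholds pass; resume after the violating
    SNP (genotype violation) or at the SNP after the gap (gap violation).
    """
    n = len(bp)
    hom = (geno == 0) | (geno == 2)
    out = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and _window_admissible(geno, bp, i, j + 1, p):
            j += 1
        e = j
        while e > i and not hom[e]:
            e -= 1
        n_snps = e - i + 1
        length = int(bp[e] - bp[i])
        dens_ok = (
            p.min_density_bp_per_snp is None
            or length / n_snps <= p.min_density_bp_per_snp
        )
        if n_snps >= p.min_snps and length >= p.min_length_bp and dens_ok:
            out.append((int(bp[i]), int(bp[e])))
        if j + 1 >= n:
            break
        gap_broke = bp[j + 1] - bp[j] > p.max_gap_bp
        i = j + 1 if gap_broke else j + 2
    return out


def segments_to_spans(segs: pd.DataFrame, sample_id, chrom) -> list[tuple[int, int]]:
    sub = segs[(segs["sample_id"] == sample_id) & (segs["chrom"] == chrom)]
    return sorted(zip(sub["start_bp"].astype(int), sub["end_bp"].astype(int)))


def naive_grm(calls: np.ndarray) -> np.ndarray:
    """Double-loop GRM over standardized genotypes (missing -> mean)."""
    n, m = calls.shape
    z = np.empty((n, m))
    used = []
    for j in range(m):
        col = calls[:, j].astype(float)
        obs = col[col != MISSING]
        if len(obs) == 0:
            continue
        p = obs.sum() / (2.0 * len(obs))
        if p <= 0 or p >= 1:
            continue
        denom = np.sqrt(2 * p * (1 - p))
        zj = np.where(col == MISSING, 0.0, (col - 2 * p) / denom)
        z[:, len(used)] = zj
        used.append(j)
    m_used = len(used)
    g = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            acc = 0.0
            for j in range(m_used):
                acc += z[a, j] * z[b, j]
            g[a, b] = acc / m_used
    return g


def naive_in_roh_counts(segs: pd.DataFrame, snp_map: pd.DataFrame, samples) -> np.ndarray:
    """Per-SNP in-ROH counts by scanning every (individual, SNP, segment) triple."""
    counts = np.zeros(len(snp_map), dtype=int)
    for k, (chrom, bp) in enumerate(zip(snp_map["chrom"], snp_map["bp"])):
        for sid in samples:
            sub = segs[(segs["sample_id"] == sid) & (segs["chrom"] == chrom)]
            if ((sub["start_bp"] <= bp) & (sub["end_bp"] >= bp)).any():
                counts[k] += 1
    return counts


def random_roh_panel(rng, n_samples, n_snps, het_rate=0.03, miss_rate=0.02,
                     mean_gap=20_000, big_gap_rate=0.002):
    """Mostly-homozygous genotypes with sprinkled het/missing and rare big gaps."""
    gaps = rng.integers(5_000, 2 * mean_gap, size=n_snps)
    big = rng.random(n_snps) < big_gap_rate
    gaps[big] = 1_500_000
    bp = np.cumsum(gaps)
    hom = rng.choice([0, 2], size=(n_samples, n_snps), p=[0.35, 0.65])
    u = rng.random((n_samples, n_snps))
    hom[u < het_rate] = 1
    hom[(u >= het_rate) & (u < het_rate + miss_rate)] = MISSING
    return hom.astype(np.int8), bp
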