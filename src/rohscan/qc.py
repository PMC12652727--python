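"""Genotype quality control.

The cascade mirrors the conventional SNP-array pipeline for within-breed
panels: (1) drop samples with low call rate, (2) drop SNPs with low call
rate, (3) drop SNPs with low minor-allele frequency, (4) drop SNPs whose
observed/expected heterozygote-frequency ratio falls outside fixed bounds
(a ratio-based Hardy-Weinberg screen for genotyping artefacts).  Statistics
are recomputed after every stage, so each filter sees the panel the previous
one left behind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


class EmptyPanelError(ValueError):
    """A QC stage removed every remaining sample or SNP."""


@dataclass
class QCConfig:
    """Thresholds for the QC cascade.

    ``snp_call_rate_is_max_missing`` flips the SNP call-rate stage to read
    ``snp_call_rate`` as a PLINK ``--geno``-style missingness ceiling
    (retain SNPs with missingness <= value) instead of a call-rate floor.
    """

    sample_call_rate: float = 0.95
    snp_call_rate: float = 0.95
    maf_min: float = 0.01
    hwe_ratio_min: float = 0.05
    hwe_ratio_max: float = 1.1
    snp_call_rate_is_max_missing: bool = False


def marker_stats(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, MAF, observed/expected heterozygosity and O/E ratio.

    All statistics are computed over non-missing calls only.  For an
    all-missing SNP the call rate is 0 and frequency statistics are NaN;
    the O/E ratio is NaN whenever expected heterozygosity is 0.
    """
    if g.n_snps == 0:
        raise ValueError("empty panel")
    calls = g.calls
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0)
    call_rate = n / g.n_samples
    with np.errstate(divide="ignore", invalid="ignore"):
        alt = np.where(nonmiss, calls, 0).sum(axis=0)
        p = np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)
        maf = np.minimum(p, 1.0 - p)
        obs_het = np.where(n > 0, (calls == 1).sum(axis=0) / np.maximum(n, 1), np.nan)
        exp_het = 2.0 * p * (1.0 - p)
        oe_ratio = np.where(exp_het > 0, obs_het / exp_het, np.nan)
    return pd.DataFrame(
        {
            "snp_id": g.snps["snp_id"].to_numpy(),
            "call_rate": call_rate,
            "maf": maf,
            "obs_het": obs_het,
            "exp_het": exp_het,
            "oe_ratio": oe_ratio,
        }
    )


def _stage_row(stage, kind, removed, retained):
    return {"stage": stage, "filtered": kind, "removed": removed, "retained": retained}


def qc_pipeline(
    g: GenotypeMatrix, thresholds: QCConfig | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the four-stage QC cascade and report per-stage attrition.

    Stage order: sample call rate -> SNP call rate -> MAF -> HWE O/E ratio.
    Thresholds are retain-if: call rates ``>=``, MAF ``>=``, O/E ratio within
    ``[hwe_ratio_min, hwe_ratio_max]`` inclusive.  SNPs with an undefined
    O/E ratio surviving to stage 4 are retained (monomorphic SNPs are gone
    after the MAF stage whenever ``maf_min > 0``).
    """
    cfg = thresholds or QCConfig()
    report_rows = []

    # stage 1: sample call rate
    nonmiss = g.calls != MISSING
    sample_cr = nonmiss.sum(axis=1) / max(g.n_snps, 1)
    keep_s = np.flatnonzero(sample_cr >= cfg.sample_call_rate)
    report_rows.append(
        _stage_row("sample_call_rate", "samples", g.n_samples - len(keep_s), len(keep_s))
    )
    if len(keep_s) == 0:
        raise EmptyPanelError("no samples left after stage sample_call_rate")
    g = g.subset(sample_idx=keep_s)

    def snp_stage(g, name, keep_mask):
        keep = np.flatnonzero(keep_mask)
        report_rows.append(_stage_row(name, "snps", g.n_snps - len(keep), len(keep)))
        if len(keep) == 0:
            raise EmptyPanelError(f"no SNPs left after stage {name}")
        return g.subset(snp_idx=keep)

    stats = marker_stats(g)
    if cfg.snp_call_rate_is_max_missing:
        # value read as a missingness ceiling: retain missingness <= value
        keep_mask = (1.0 - stats["call_rate"].to_numpy()) <= cfg.snp_call_rate
    else:
        keep_mask = stats["call_rate"].to_numpy() >= cfg.snp_call_rate
    g = snp_stage(g, "snp_call_rate", keep_mask)

    stats = marker_stats(g)
    maf = stats["maf"].to_numpy()
    g = snp_stage(g, "maf", ~np.isnan(maf) & (maf >= cfg.maf_min))

    stats = marker_stats(g)
    oe = stats["oe_ratio"].to_numpy()
    ok = np.isnan(oe) | ((oe >= cfg.hwe_ratio_min) & (oe <= cfg.hwe_ratio_max))
    g = snp_stage(g, "hwe_oe_ratio", ok)

    return g, pd.DataFrame(report_rows)
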