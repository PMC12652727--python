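"""Population structure and morphometrics.

Genotype PCA follows the GRM-then-eigendecomposition convention: a genomic
relationship matrix is built from centered, frequency-standardized genotypes
(missing calls mean-imputed per SNP, zero-variance SNPs skipped) and its top
eigenpairs give the principal-component scores.  Morphometric PCA is a
column-standardized PCA of the trait table.

Trait comparisons across groups reproduce the standard workflow: per-group
Shapiro-Wilk normality checks, median-centered Levene homogeneity test,
one-way ANOVA, and — when the ANOVA is significant — Tukey-Kramer HSD with
a compact letter display (groups sharing a letter are not significantly
different at alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import MISSING, TRAIT_NAMES, GenotypeMatrix


@dataclass
class GRM:
    values: np.ndarray  # samples x samples
    pair_counts: np.ndarray  # SNPs non-missing in both members of each pair
    n_snps_used: int
    samples: list[str]


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x k
    eigenvalues: np.ndarray
    pve: np.ndarray  # eigenvalue_i / sum(all eigenvalues)
    samples: list[str]
    loadings: pd.DataFrame | None = None  # trait x component (morphometric mode)
    pve_topk: np.ndarray | None = None  # eigenvalue_i / sum(top-k eigenvalues)
    degenerate: bool = False


def compute_grm(g: GenotypeMatrix) -> GRM:
    """Genomic relationship matrix Z Z' / m from standardized genotypes.

    z_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) with missing calls imputed
    to the SNP mean (z = 0).  SNPs with zero variance after QC are skipped
    and counted; ``pair_counts`` reports, per sample pair, how many used
    SNPs were non-missing in both members.
    """
    calls = g.calls.astype(float)
    nonmiss = g.calls != MISSING
    n = nonmiss.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(nonmiss, calls, 0).sum(axis=0) / (2.0 * np.maximum(n, 1))
    usable = (n > 0) & (p > 0) & (p < 1)
    n_skipped = int((~usable).sum())
    if n_skipped:
        import logging

        logging.getLogger(__name__).info("GRM: skipped %d zero-variance SNPs", n_skipped)
    if not usable.any():
        raise ValueError("no polymorphic SNPs for GRM")
    p = p[usable]
    z = (np.where(nonmiss, calls, np.nan)[:, usable] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    nm = ~np.isnan(z)
    z = np.nan_to_num(z, nan=0.0)
    m = int(usable.sum())
    grm = z @ z.T / m
    pair_counts = nm.astype(np.int32) @ nm.astype(np.int32).T
    return GRM(grm, pair_counts, m, list(g.samples))


def pca_genotypes(grm: GRM, k: int = 2) -> PcaResult:
    """Top-k eigenpairs of the GRM; scores are eigenvectors scaled by
    sqrt(eigenvalue); each component's largest-magnitude entry is positive."""
    vals_all = linalg.eigvalsh(grm.values)[::-1]
    rank = int((vals_all > 1e-10).sum())
    if k > rank:
        if rank == 0:
            # all-identical individuals: zero relationship variance
            n = len(grm.samples)
            return PcaResult(
                np.zeros((n, k)), np.zeros(k), np.zeros(k), grm.samples, degenerate=True
            )
        raise ValueError(f"k={k} exceeds GRM rank {rank}")
    n = grm.values.shape[0]
    vals, vecs = linalg.eigh(grm.values, subset_by_index=[n - k, n - 1])
    vals, vecs = vals[::-1], vecs[:, ::-1]
    signs = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    scores = vecs * np.sqrt(np.maximum(vals, 0.0))
    total = float(vals_all[vals_all > 0].sum())
    pve = vals / total if total > 0 else np.zeros(k)
    return PcaResult(scores, vals, pve, grm.samples)


def pca_morphometrics(traits: pd.DataFrame, k: int = 5) -> PcaResult:
    """Column-standardized PCA of a samples x traits table.

    Rows with any missing trait are dropped (logged).  Eigenvalues are those
    of the trait correlation matrix; ``pve`` is the standard convention
    (lambda_i / sum of all) and ``pve_topk`` normalizes within the top k
    only.  ``loadings`` holds trait x component eigenvector weights.
    """
    trait_cols = [c for c in traits.columns if c in TRAIT_NAMES] or [
        c for c in traits.columns if np.issubdtype(traits[c].dtype, np.number)
    ]
    sample_ids = (
        traits["sample_id"].astype(str)
        if "sample_id" in traits.columns
        else traits.index.astype(str)
    )
    x = traits[trait_cols].to_numpy(dtype=float)
    complete = ~np.isnan(x).any(axis=1)
    if not complete.all():
        import logging

        logging.getLogger(__name__).info(
            "morphometric PCA: dropped %d incomplete rows", int((~complete).sum())
        )
    x = x[complete]
    samples = list(sample_ids[complete])
    if x.shape[0] <= k:
        raise ValueError(f"need more than k={k} complete samples, have {x.shape[0]}")
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    corr = np.cov(x, rowvar=False, ddof=1)
    vals_all, vecs_all = linalg.eigh(corr)
    vals_all, vecs_all = vals_all[::-1], vecs_all[:, ::-1]
    vals, vecs = vals_all[:k], vecs_all[:, :k]
    signs = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    scores = x @ vecs
    loadings = pd.DataFrame(vecs, index=trait_cols, columns=[f"PC{i+1}" for i in range(k)])
    return PcaResult(
        scores,
        vals,
        vals / vals_all.sum(),
        samples,
        loadings=loadings,
        pve_topk=vals / vals.sum(),
    )


def compact_letter_display(labels: list[str], different: np.ndarray) -> dict[str, str]:
    """Letters such that two groups share one iff they are NOT significantly
    different.

    ``different`` is a symmetric boolean matrix over ``labels``.  Letters are
    the maximal cliques of the not-different graph, ordered by first member,
    so the display is reconstructible from the significance matrix alone and
    independent of input order.
    """
    G = nx.Graph()
    G.add_nodes_from(range(len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if not different[i, j]:
                G.add_edge(i, j)
    cliques = sorted((sorted(c) for c in nx.find_cliques(G)), key=lambda c: (c[0], c))
    letters = {lab: "" for lab in labels}
    for li, clique in enumerate(cliques):
        ch = chr(ord("a") + li)
        for i in clique:
            letters[labels[i]] += ch
    return letters


def trait_group_tests(
    traits: pd.DataFrame,
    groups: pd.Series,
    trait_names: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-trait assumption checks, one-way ANOVA, and Tukey-Kramer HSD.

    ``groups`` maps sample_id -> group label; ``traits`` must carry a
    ``sample_id`` column plus trait columns in cm.  Shapiro-Wilk is run per
    group (minimum p reported), Levene is median-centered.  Tukey pairwise
    p-values and compact letters are produced only when the ANOVA p < alpha;
    otherwise all groups share letter "a".
    """
    trait_names = trait_names or [c for c in traits.columns if c in TRAIT_NAMES]
    df = traits.assign(group=traits["sample_id"].map(groups)).dropna(subset=["group"])
    labels = sorted(df["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for trait in trait_names:
        sub = df[["group", trait]].dropna()
        arrs = [sub.loc[sub["group"] == lab, trait].to_numpy() for lab in labels]
        if any(len(a) < 3 for a in arrs):
            raise ValueError(f"trait {trait!r}: every group needs >= 3 observations")
        if all(np.ptp(a) == 0 for a in arrs) and len({a[0] for a in arrs}) == 1:
            rows.append(
                {
                    "trait": trait, "shapiro_p": np.nan, "levene_p": np.nan,
                    "anova_F": 0.0, "anova_p": 1.0, "tukey": None,
                    "cld": {lab: "a" for lab in labels}, "flagged_constant": True,
                }
            )
            continue
        shapiro_p = min(
            (stats.shapiro(a).pvalue if np.ptp(a) > 0 else 1.0) for a in arrs
        )
        levene_p = float(stats.levene(*arrs, center="median").pvalue)
        anova = stats.f_oneway(*arrs)
        tukey_table = None
        if anova.pvalue < alpha:
            res = pairwise_tukeyhsd(
                sub[trait].to_numpy(), sub["group"].to_numpy(), alpha=alpha
            )
            tukey_table = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
            different = np.zeros((len(labels), len(labels)), dtype=bool)
            for (i, j), rej in zip(
                [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))],
                res.reject,
            ):
                different[i, j] = different[j, i] = bool(rej)
            cld = compact_letter_display(labels, different)
        else:
            cld = {lab: "a" for lab in labels}
        rows.append(
            {
                "trait": trait,
                "shapiro_p": float(shapiro_p),
                "levene_p": levene_p,
                "anova_F": float(anova.statistic),
                "anova_p": float(anova.pvalue),
                "tukey": tukey_table,
                "cld": cld,
                "flagged_constant": False,
            }
        )
    return pd.DataFrame(rows)


def table_summary(traits: pd.DataFrame, groups: pd.Series, tests: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per group with ANOVA asterisk and CLD letters, one row per trait."""
    df = traits.assign(group=traits["sample_id"].map(groups)).dropna(subset=["group"])
    labels = sorted(df["group"].unique())
    rows = []
    for rec in tests.itertuples(index=False):
        row = {"trait": rec.trait, "significant": "*" if rec.anova_p < 0.05 else ""}
        for lab in labels:
            vals = df.loc[df["group"] == lab, rec.trait].dropna()
            letter = rec.cld.get(lab, "") if isinstance(rec.cld, dict) else ""
            row[lab] = f"{vals.mean():.2f} +/- {vals.std(ddof=1):.2f} {letter}".strip()
        rows.append(row)
    return pd.DataFrame(rows)
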