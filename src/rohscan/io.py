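"""Genotype, metadata, and gene-interval I/O.

The internal data model is a :class:`GenotypeMatrix`: a samples x SNPs array
of diploid calls coded as counts of a "counted" allele (0, 1, 2) with -1 for
missing, plus a SNP map sorted by (chromosome, position).  Coordinates are
1-based inclusive everywhere inside the package; BED input is converted at
the boundary.

Supported formats: PLINK 1.9 text PED/MAP, VCF 4.2 (bi-allelic GT records),
BED4 / GFF3 gene intervals, and a tab-separated sample-metadata table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: canonical morphometric trait names (all measured in cm)
TRAIT_NAMES = [
    "eye_width",
    "snout_length",
    "outside_ear_length",
    "chest_width",
    "neck_girth",
    "chest_girth",
    "wither_height",
    "height_at_base_of_tail",
    "body_length",
    "tail_length",
    "upper_foreleg_length",
    "lower_foreleg_length",
    "fore_foot_length",
    "fore_foot_circumference",
    "upper_hind_leg_length",
    "lower_hind_leg_length",
    "hind_foot_length",
    "hind_foot_circumference",
]

SNP_COLUMNS = ["snp_id", "chrom", "bp", "a1", "a2"]


class ParseError(ValueError):
    """Malformed input file (message names the offending line)."""


class StructuralError(ValueError):
    """Inconsistent file structure (e.g. PED/MAP column-count mismatch)."""


@dataclass
class GenotypeMatrix:
    """Diploid genotype panel with a sorted autosomal SNP map.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``calls``).
    snps
        DataFrame with columns ``snp_id, chrom, bp, a1, a2`` sorted by
        (chrom, bp).  ``a2`` is the counted allele; ``a1`` the other.  ``"0"``
        marks an allele symbol that was never observed.
    calls
        ``(n_samples, n_snps)`` int8 array; values in {0, 1, 2, -1} counting
        copies of ``a2`` (-1 = missing).
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise StructuralError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise StructuralError(f"duplicate SNP id {dup!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def is_sorted(self) -> bool:
        c = self.snps["chrom"].to_numpy()
        b = self.snps["bp"].to_numpy()
        key = c.astype(np.int64) * (b.max() + 1 if len(b) else 1) + b
        return bool(np.all(np.diff(key) >= 0))

    def sort_map(self) -> "GenotypeMatrix":
        """Return a panel with SNPs sorted by (chrom, bp), calls permuted."""
        order = np.lexsort((self.snps["bp"].to_numpy(), self.snps["chrom"].to_numpy()))
        snps = self.snps.iloc[order].reset_index(drop=True)
        return GenotypeMatrix(list(self.samples), snps, self.calls[:, order])

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        sample_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            [self.samples[i] for i in sample_idx],
            self.snps.iloc[snp_idx].reset_index(drop=True),
            self.calls[np.ix_(sample_idx, snp_idx)],
        )


def _parse_chrom(token: str, n_autosomes: int) -> int | None:
    """Autosome index, or None for non-autosomal/unmapped records."""
    tok = token.removeprefix("chr")
    try:
        c = int(tok)
    except ValueError:
        return None
    return c if 1 <= c <= n_autosomes else None


def _counted_allele(alleles_a: np.ndarray, alleles_b: np.ndarray) -> tuple[str, str]:
    """Pick the counted (minor) allele from the observed symbols at one SNP.

    Ties at frequency 0.5 go to the lexicographically greater symbol so the
    choice is deterministic and write->read round trips are stable.  Returns
    ``(other, counted)``; unobserved symbols are reported as ``"0"``.
    """
    obs = np.concatenate([alleles_a, alleles_b])
    obs = obs[obs != "0"]
    syms, counts = np.unique(obs, return_counts=True)
    if len(syms) == 0:
        return "0", "0"
    if len(syms) == 1:
        return "0", str(syms[0])
    if len(syms) > 2:
        raise ParseError(f"more than two alleles observed: {list(syms)}")
    a, b = str(syms[0]), str(syms[1])
    ca, cb = counts[0], counts[1]
    if ca < cb:
        return b, a
    if cb < ca:
        return a, b
    return min(a, b), max(a, b)  # tie: counted = greater symbol


def read_ped_map(
    ped_path: str | Path, map_path: str | Path, n_autosomes: int = 38
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a PLINK 1.9 text PED/MAP pair.

    Calls count the minor allele observed at load time (ties broken toward
    the lexicographically greater symbol); ``0 0`` genotypes are missing.
    Non-autosomal and unmapped MAP rows are dropped with a logged count.
    Returns the sorted panel and a minimal metadata frame (sample_id, sex).
    """
    map_rows = []
    keep_cols = []
    n_map_total = 0
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 MAP fields, got {len(parts)}")
            chrom = _parse_chrom(parts[0], n_autosomes)
            try:
                bp = int(parts[3])
            except ValueError as exc:
                raise ParseError(f"{map_path}:{ln}: bad bp position {parts[3]!r}") from exc
            col = n_map_total
            n_map_total += 1
            if chrom is None or bp < 1:
                continue
            keep_cols.append(col)
            map_rows.append((parts[1], chrom, bp))
    dropped = n_map_total - len(map_rows)
    if dropped:
        logger.info("dropped %d non-autosomal/unmapped MAP rows", dropped)

    n_snps_all = n_map_total
    samples, sexes, geno_rows = [], [], []
    sex_map = {"1": "male", "2": "female"}
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps_all:
                raise StructuralError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps_all} fields "
                    f"for {n_snps_all} MAP SNPs, got {len(parts)}"
                )
            samples.append(parts[1])
            sexes.append(sex_map.get(parts[4], "unknown"))
            geno_rows.append(np.array(parts[6:], dtype="U8").reshape(n_snps_all, 2))
    if not samples:
        raise StructuralError(f"{ped_path}: no samples")

    geno = np.stack(geno_rows)[:, keep_cols, :]  # samples x kept snps x 2
    n_samples, n_snps = geno.shape[:2]
    calls = np.full((n_samples, n_snps), MISSING, dtype=np.int8)
    a1s, a2s = [], []
    for j in range(n_snps):
        a = geno[:, j, 0]
        b = geno[:, j, 1]
        a1, a2 = _counted_allele(a, b)
        a1s.append(a1)
        a2s.append(a2)
        ok = (a != "0") & (b != "0")
        calls[ok, j] = (a[ok] == a2).astype(np.int8) + (b[ok] == a2).astype(np.int8)

    snps = pd.DataFrame(map_rows, columns=["snp_id", "chrom", "bp"])
    snps["a1"] = a1s
    snps["a2"] = a2s
    g = GenotypeMatrix(samples, snps, calls).sort_map()
    meta = pd.DataFrame({"sample_id": samples, "sex": sexes})
    return g, meta


def write_ped_map(
    g: GenotypeMatrix,
    ped_path: str | Path,
    map_path: str | Path,
    metadata: pd.DataFrame | None = None,
) -> None:
    """Write a panel as PLINK 1.9 text PED/MAP (deterministic column order)."""
    with open(map_path, "w") as fh:
        for row in g.snps.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.bp}\n")
    sex_codes = {"male": "1", "female": "2"}
    sex_by_sample = {}
    if metadata is not None and "sex" in metadata.columns:
        sex_by_sample = dict(zip(metadata["sample_id"], metadata["sex"]))
    a1 = g.snps["a1"].to_numpy(dtype="U8")
    a2 = g.snps["a2"].to_numpy(dtype="U8")
    # genotype 0 = two copies of a1; an unobserved a1 symbol is written as N
    a1 = np.where(a1 == "0", "N", a1)
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            sex = sex_codes.get(sex_by_sample.get(sid, ""), "0")
            row = g.calls[i]
            first = np.where(row >= 1, a2, a1)
            second = np.where(row == 2, a2, a1)
            first = np.where(row == MISSING, "0", first)
            second = np.where(row == MISSING, "0", second)
            toks = np.empty(2 * len(row), dtype="U8")
            toks[0::2] = first
            toks[1::2] = second
            fh.write(f"{sid}\t{sid}\t0\t0\t{sex}\t-9\t" + "\t".join(toks) + "\n")


def read_vcf(vcf_path: str | Path, n_autosomes: int = 38) -> GenotypeMatrix:
    """Read bi-allelic GT records from a VCF 4.2 file.

    GT 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing; the counted
    allele is ALT.  Multi-allelic and non-autosomal records are skipped with
    a logged warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, cols = [], []
    n_multi = n_nonauto = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        chrom = _parse_chrom(rec.CHROM, n_autosomes)
        if chrom is None:
            n_nonauto += 1
            continue
        snp_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append((snp_id, chrom, rec.POS, rec.REF, rec.ALT[0]))
        cols.append(code[rec.gt_types])
    if n_multi:
        logger.warning("skipped %d multi-allelic VCF records", n_multi)
    if n_nonauto:
        logger.info("skipped %d non-autosomal VCF records", n_nonauto)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    calls = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, snps, calls).sort_map()


def write_vcf(g: GenotypeMatrix, vcf_path: str | Path) -> None:
    """Write a panel as uncompressed VCF 4.2 with GT-only records."""
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(g.snps["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, row in enumerate(g.snps.itertuples(index=False)):
            ref = row.a1 if row.a1 != "0" else "N"
            alt = row.a2 if row.a2 != "0" else "N"
            calls = "\t".join(gt[int(c)] for c in g.calls[:, j])
            fh.write(f"{row.chrom}\t{row.bp}\t{row.snp_id}\t{ref}\t{alt}\t.\t.\t.\tGT\t{calls}\n")


def read_gene_intervals(path: str | Path, dialect: str = "BED") -> pd.DataFrame:
    """Read gene intervals from BED4 or GFF3.

    BED half-open 0-based spans are converted to 1-based inclusive; GFF3 is
    taken as 1-based inclusive.  Returns a frame with columns
    ``gene_id, chrom, start_bp, end_bp`` sorted by (chrom, start_bp).
    """
    dialect = dialect.upper()
    if dialect == "BED":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id"], dtype={0: str},
        )
        genes = pd.DataFrame(
            {
                "gene_id": df["gene_id"].astype(str),
                "chrom": [int(str(c).removeprefix("chr")) for c in df["chrom"]],
                "start_bp": df["start"].astype(int) + 1,
                "end_bp": df["end"].astype(int),
            }
        )
    elif dialect == "GFF3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        rows = [
            (f.id, int(str(f.seqid).removeprefix("chr")), f.start, f.end)
            for f in db.features_of_type("gene")
        ]
        genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start_bp", "end_bp"])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    bad = genes["start_bp"] > genes["end_bp"]
    if bad.any():
        raise ValueError(
            f"gene {genes.loc[bad, 'gene_id'].iloc[0]!r} has start > end after conversion"
        )
    return genes.sort_values(["chrom", "start_bp"], kind="mergesort").reset_index(drop=True)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated sample-metadata table.

    Required columns: ``sample_id``, ``group``.  Optional: ``sex`` and any of
    the 18 canonical morphometric traits (cm).  Unknown trait-like columns
    are rejected to catch typos.
    """
    meta = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise StructuralError(f"metadata missing required column {col!r}")
    known = {"sample_id", "group", "sex", *TRAIT_NAMES}
    unknown = [c for c in meta.columns if c not in known]
    if unknown:
        raise StructuralError(f"unknown metadata columns: {unknown}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "group"] + [c for c in meta.columns if c not in ("sample_id", "group")]
    meta[cols].to_csv(path, sep="\t", index=False)
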