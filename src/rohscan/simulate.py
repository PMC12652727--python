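"""Synthetic genotype/phenotype panels with planted ground truth.

The generator emulates a within-breed SNP-array study: a mapped multi-
chromosome panel of bi-allelic SNPs, several usage groups drawn from the
Balding-Nichols model (population allele frequencies beta-distributed
around a shared ancestral frequency with drift parameter F, whose expected
value equals the Weir-Cockerham F_ST between the group and the ancestral
pool), planted autozygous tracts — per-individual runs or population-shared
sweeps — genotyping noise, and group-structured morphometrics.  Every
random stage draws from an independent sub-stream of the master seed, so
e.g. changing the noise rates never alters the drift draws, and the same
seed always reproduces the panel byte-for-byte.

Defaults mirror the structure of a US Siberian Husky usage-group panel:
four groups of 35/66/92/44 dogs, 10 chromosomes x 5,000 SNPs uniformly
spaced over 50 Mb (about 1 SNP per 10 kb), and the published group-wise
means and SDs of 18 morphometric traits in cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MISSING, TRAIT_NAMES, GenotypeMatrix

#: per-trait (mean, SD) in cm for the pet / show / sled usage groups
MORPHO_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "eye_width": {"pet": (4.45, 0.53), "show": (4.42, 0.64), "sled": (4.11, 0.81)},
    "snout_length": {"pet": (9.45, 0.97), "show": (9.19, 0.91), "sled": (9.42, 1.17)},
    "outside_ear_length": {"pet": (8.79, 1.30), "show": (8.43, 0.89), "sled": (8.38, 1.22)},
    "chest_width": {"pet": (13.94, 1.98), "show": (12.29, 1.40), "sled": (12.65, 1.35)},
    "neck_girth": {"pet": (35.99, 3.81), "show": (37.41, 3.86), "sled": (36.42, 3.81)},
    "chest_girth": {"pet": (67.23, 6.78), "show": (62.56, 4.55), "sled": (64.85, 4.47)},
    "wither_height": {"pet": (56.92, 3.84), "show": (56.85, 3.66), "sled": (60.22, 3.43)},
    "height_at_base_of_tail": {"pet": (55.32, 4.01), "show": (54.03, 4.04), "sled": (58.37, 5.97)},
    "body_length": {"pet": (61.85, 6.68), "show": (54.69, 4.52), "sled": (57.68, 4.34)},
    "tail_length": {"pet": (35.71, 4.67), "show": (35.84, 2.87), "sled": (34.42, 4.42)},
    "upper_foreleg_length": {"pet": (20.04, 2.41), "show": (19.10, 1.91), "sled": (17.83, 2.64)},
    "lower_foreleg_length": {"pet": (21.41, 2.03), "show": (20.93, 1.55), "sled": (21.29, 1.83)},
    "fore_foot_length": {"pet": (13.56, 1.60), "show": (12.50, 1.55), "sled": (12.83, 1.50)},
    "fore_foot_circumference": {"pet": (9.91, 0.86), "show": (10.24, 1.24), "sled": (10.13, 0.86)},
    "upper_hind_leg_length": {"pet": (30.51, 3.33), "show": (27.30, 2.36), "sled": (30.15, 3.38)},
    "lower_hind_leg_length": {"pet": (24.21, 2.92), "show": (23.60, 2.24), "sled": (22.00, 3.20)},
    "hind_foot_length": {"pet": (21.23, 2.01), "show": (20.80, 1.60), "sled": (20.24, 2.24)},
    "hind_foot_circumference": {"pet": (9.47, 0.86), "show": (9.63, 1.04), "sled": (9.68, 0.86)},
}


@dataclass(frozen=True)
class PlantedSegment:
    """An autozygous tract to plant: per-population carrier fractions.

    ``kind`` is ``individual_roh`` (each carrier homozygous for its own
    random haplotype) or ``shared_sweep`` (all carriers homozygous for one
    fixed haplotype, so the span enters population-level consensus).
    """

    chrom: int
    start_bp: int
    end_bp: int
    carriers: dict[str, float]
    kind: str = "individual_roh"


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 10
    snps_per_chrom: int = 5_000
    chrom_length_bp: int = 50_000_000
    populations: list[tuple[str, int, float]] = field(
        default_factory=lambda: [
            ("pet", 35, 0.03),
            ("show", 66, 0.05),
            ("sled_sprint", 92, 0.04),
            ("sled_distance", 44, 0.06),
        ]
    )
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    het_error_rate: float = 0.0005
    missing_rate: float = 0.002
    planted_segments: list[PlantedSegment] = field(default_factory=list)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel."""

    sample_pops: pd.Series  # sample_id -> population
    pop_freqs: dict[str, np.ndarray]  # population -> per-SNP frequency
    ancestral_freqs: np.ndarray
    planted: list[dict] = field(default_factory=list)  # segment, carriers, snp span

    def autozygous_fraction(self, snp_map: pd.DataFrame) -> pd.Series:
        """Per-individual fraction of the mapped extent inside planted tracts."""
        span = snp_map.groupby("chrom")["bp"].agg(["min", "max"])
        l_auto = float((span["max"] - span["min"]).sum())
        frac = {s: 0.0 for s in self.sample_pops.index}
        for rec in self.planted:
            seg = rec["segment"]
            for sid in rec["carriers"]:
                frac[sid] += (rec["last_bp"] - rec["first_bp"]) / l_auto
        return pd.Series(frac)


def _stream(seed: int, stage: int) -> np.random.Generator:
    """Independent generator for one pipeline stage of one master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def _make_map(cfg: SimConfig) -> pd.DataFrame:
    spacing = cfg.chrom_length_bp // cfg.snps_per_chrom
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        for i in range(cfg.snps_per_chrom):
            rows.append((f"chr{c}_snp{i + 1}", c, (i + 1) * spacing))
    snps = pd.DataFrame(rows, columns=["snp_id", "chrom", "bp"])
    snps["a1"] = "A"
    snps["a2"] = "B"
    return snps


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Draw a genotype panel under the Balding-Nichols model.

    Ancestral frequencies are uniform on ``ancestral_freq_range``; each
    population's frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws (equal
    to the ancestral frequencies when F = 0) and genotypes are
    Binomial(2, p_pop).  Planting and noise are applied afterwards when
    configured.  Returns the panel, a metadata frame, and the truth record.
    """
    if cfg.n_chrom < 1 or cfg.snps_per_chrom < 1 or not cfg.populations:
        raise ValueError("degenerate simulation config")
    if any(n < 1 for _, n, _ in cfg.populations):
        raise ValueError("every population needs at least one individual")
    snps = _make_map(cfg)
    m = len(snps)
    rng_freq = _stream(cfg.seed, 0)
    rng_geno = _stream(cfg.seed, 1)
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng_freq.uniform(lo, hi, size=m)
    samples, pops, blocks = [], [], []
    pop_freqs = {}
    for label, n, F in cfg.populations:
        if not 0 <= F < 1:
            raise ValueError(f"drift F for {label!r} must be in [0, 1)")
        if F == 0:
            p_pop = p_anc.copy()
        else:
            shape = (1.0 - F) / F
            p_pop = rng_freq.beta(p_anc * shape, (1.0 - p_anc) * shape)
        pop_freqs[label] = p_pop
        blocks.append(rng_geno.binomial(2, p_pop, size=(n, m)).astype(np.int8))
        samples.extend(f"{label}_{i + 1:03d}" for i in range(n))
        pops.extend([label] * n)
    g = GenotypeMatrix(samples, snps, np.vstack(blocks))
    meta = pd.DataFrame({"sample_id": samples, "group": pops})
    truth = SimTruth(
        sample_pops=pd.Series(pops, index=samples),
        pop_freqs=pop_freqs,
        ancestral_freqs=p_anc,
    )
    if cfg.planted_segments:
        g, truth = plant_autozygosity(g, truth, cfg.planted_segments, seed=cfg.seed)
    if cfg.het_error_rate > 0 or cfg.missing_rate > 0:
        g = inject_noise(
            g, cfg.het_error_rate, cfg.missing_rate, seed=cfg.seed, truth=truth
        )
    return g, meta, truth


def plant_autozygosity(
    g: GenotypeMatrix,
    truth: SimTruth,
    segments: list[PlantedSegment],
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overwrite carrier genotypes inside each segment span with homozygous calls.

    Carriers are sampled per population to hit the requested fraction
    (rounded to the nearest count).  ``individual_roh`` tracts give each
    carrier its own haplotype drawn from the population frequencies;
    ``shared_sweep`` tracts use one fixed haplotype for every carrier.
    """
    rng = _stream(seed, 2)
    calls = g.calls.copy()
    chroms = g.snps["chrom"].to_numpy()
    bps = g.snps["bp"].to_numpy(dtype=np.int64)
    sample_index = {s: i for i, s in enumerate(g.samples)}
    planted = list(truth.planted)
    for seg in segments:
        on_chrom = np.flatnonzero(chroms == seg.chrom)
        if len(on_chrom) == 0:
            raise ValueError(f"no SNPs on chromosome {seg.chrom}")
        bp_c = bps[on_chrom]
        lo = np.searchsorted(bp_c, seg.start_bp, side="left")
        hi = np.searchsorted(bp_c, seg.end_bp, side="right")
        span = on_chrom[lo:hi]
        if len(span) == 0:
            raise ValueError(
                f"planted segment {seg.chrom}:{seg.start_bp}-{seg.end_bp} covers no SNPs"
            )
        carriers = []
        for pop, frac in seg.carriers.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"carrier fraction {frac} outside [0, 1]")
            members = [s for s, p in truth.sample_pops.items() if p == pop]
            n_car = int(round(frac * len(members)))
            chosen = sorted(rng.choice(members, size=n_car, replace=False)) if n_car else []
            p_pop = truth.pop_freqs[pop][span]
            if seg.kind == "shared_sweep":
                hap = (rng.random(len(span)) < p_pop).astype(np.int8)
                for sid in chosen:
                    calls[sample_index[sid], span] = 2 * hap
            else:
                for sid in chosen:
                    hap = (rng.random(len(span)) < p_pop).astype(np.int8)
                    calls[sample_index[sid], span] = 2 * hap
            carriers.extend(chosen)
        planted.append(
            {
                "segment": seg,
                "carriers": carriers,
                "snp_lo": int(span[0]),
                "snp_hi": int(span[-1]),
                "first_bp": int(bps[span[0]]),
                "last_bp": int(bps[span[-1]]),
            }
        )
    new_truth = replace(truth, planted=planted)
    return GenotypeMatrix(list(g.samples), g.snps, calls), new_truth


def inject_noise(
    g: GenotypeMatrix,
    het_error_rate: float,
    missing_rate: float,
    seed: int = 0,
    truth: SimTruth | None = None,
    max_het: int = 1,
    max_missing: int = 1,
) -> GenotypeMatrix:
    """Flip calls to heterozygous (error) or missing, independently per call.

    When ``truth`` carries planted segments, flips inside a carrier's
    planted span are thinned to at most ``max_het`` heterozygous and
    ``max_missing`` missing calls (keeping the lowest-index flips), so
    planted tracts stay recoverable under the default run tolerances.
    """
    if not 0.0 <= het_error_rate <= 1.0 or not 0.0 <= missing_rate <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    if het_error_rate == 0 and missing_rate == 0:
        return g
    rng = _stream(seed, 3)
    calls = g.calls.copy()
    u = rng.random(calls.shape)
    het_mask = u < het_error_rate
    miss_mask = (u >= het_error_rate) & (u < het_error_rate + missing_rate)
    if truth is not None:
        sample_index = {s: i for i, s in enumerate(g.samples)}
        for rec in truth.planted:
            span = slice(rec["snp_lo"], rec["snp_hi"] + 1)
            for sid in rec["carriers"]:
                i = sample_index[sid]
                for mask, cap in ((het_mask, max_het), (miss_mask, max_missing)):
                    idx = np.flatnonzero(mask[i, span])
                    if len(idx) > cap:
                        mask[i, span.start + idx[cap:]] = False
    calls[het_mask] = 1
    calls[miss_mask] = MISSING
    return GenotypeMatrix(list(g.samples), g.snps, calls)


def simulate_morphometrics(
    n_per_group: dict[str, int] | int,
    morpho_params: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    trait_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a group-structured morphometric trait table (cm).

    ``n_per_group`` maps group -> sample count (an int applies to every
    group in ``morpho_params``).  Traits are independent normals at the
    configured means/SDs unless ``trait_corr`` supplies a trait x trait
    correlation matrix shared by all groups.
    """
    params = morpho_params or MORPHO_DEFAULTS
    traits = list(params.keys())
    group_labels = sorted({grp for tp in params.values() for grp in tp})
    if isinstance(n_per_group, int):
        n_per_group = {grp: n_per_group for grp in group_labels}
    for tp in params.values():
        if any(sd < 0 for _, sd in tp.values()):
            raise ValueError("trait SDs must be non-negative")
    rng = _stream(seed, 4)
    frames = []
    for grp in group_labels:
        n = n_per_group[grp]
        means = np.array([params[t][grp][0] for t in traits])
        sds = np.array([params[t][grp][1] for t in traits])
        if trait_corr is not None:
            cov = trait_corr * np.outer(sds, sds)
            x = rng.multivariate_normal(means, cov, size=n, method="cholesky")
        else:
            x = rng.normal(means, sds, size=(n, len(traits)))
        df = pd.DataFrame(x, columns=traits)
        df.insert(0, "group", grp)
        df.insert(0, "sample_id", [f"{grp}_{i + 1:03d}" for i in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
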