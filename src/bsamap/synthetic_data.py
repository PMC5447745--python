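"""Synthetic analogue of a recessive-sterility mapping study in melon.

The generator reproduces the study design end to end with known ground
truth: two inbred parents (sterile "P" line x fertile "M" line) differing
at planted SNPs, an F2 of 252 plants segregating one fully penetrant
recessive sterility locus, F3-style resolution of fertile genotypes,
30-plant sterile and homozygous-fertile bulks read at ~30x depth per
SNP, CAPS genotype tables and qPCR Ct replicate tables.

Physical scale is compressed — twelve 1-Mb chromosomes of ~100 cM each —
so that marker density per centimorgan and bulk allele-frequency signal
match a real cross while simulation stays desk-scale.  Meiosis is a
no-interference (Poisson crossover) process; bulk read depth is Poisson
with a binomial allele split and a symmetric per-read miscall error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Genome

__all__ = [
    "CrossConfig",
    "F2Population",
    "simulate_snp_map",
    "simulate_parents",
    "simulate_f2",
    "make_bulks_and_depths",
    "simulate_ct_table",
    "default_expression_truth",
    "simulate_study",
    "DOSE_TO_CODE",
]

#: P-allele dosage -> genotype code (a = homozygous sterile-parent allele)
DOSE_TO_CODE = {2: "a", 1: "h", 0: "b"}

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class CrossConfig:
    """Study-design parameters of the simulated cross.

    Defaults mirror the mapping study being emulated: 252 F2 plants from
    a sterile x fertile cross, 30-plant bulks at 30 reads per SNP, twelve
    chromosomes with the causal locus on chr9, per-read miscall 1%.
    ``recomb_rate`` is Morgans per bp (1e-6 -> 100 cM per 1-Mb
    chromosome); ``causal_chrom=None`` simulates a null cross with no
    sterility locus.
    """

    n_chromosomes: int = 12
    chrom_length_bp: int = 1_000_000
    snp_density: float = 2e-4
    n_f2: int = 252
    bulk_size: int = 30
    mean_depth: float = 30.0
    causal_chrom: str | None = "chr9"
    causal_pos: int = 500_000
    recomb_rate: float = 1e-6
    error_rate: float = 0.01
    min_snp_spacing: int = 50
    promoter_indel_bp: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("chromosome counts and lengths must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.snp_density < 0 or self.recomb_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_f2 < 1 or self.bulk_size < 1 or self.mean_depth < 0:
            raise ValueError("population sizes and depth must be positive")
        if self.causal_chrom is not None:
            if self.causal_chrom not in self.chrom_names:
                raise ValueError(f"unknown causal chromosome {self.causal_chrom!r}")
            if not (1 <= self.causal_pos <= self.chrom_length_bp):
                raise ValueError("causal_pos outside its chromosome")
        if self.snp_density * self.min_snp_spacing > 0.5:
            raise ValueError("snp_density too high for the minimum SNP spacing")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))


@dataclass
class F2Population:
    """Simulated F2 plants: P-allele dosage matrix plus trait truth.

    ``geno`` is (n_f2 x n_snps) with entries 2/1/0 for codes a/h/b;
    ``trait_dose`` is the dosage at the causal locus, ``phenotype``
    "sterile" iff trait_dose == 2 (fully penetrant recessive), and
    ``f3_resolved`` marks fertile plants whose zygosity is known from
    progeny testing (simulated truth).
    """

    snps: pd.DataFrame
    geno: np.ndarray
    phenotype: np.ndarray
    trait_dose: np.ndarray | None
    f3_resolved: np.ndarray
    causal_snp_index: int | None
    ids: list[str] = field(default_factory=list)

    def marker_ids(self) -> list[str]:
        return [f"{c}_{p}" for c, p in zip(self.snps["chrom"], self.snps["pos"])]

    def genotype_frame(self) -> pd.DataFrame:
        """Genotype matrix as a/h/b codes with phenotype and trait columns."""
        codes = np.vectorize(DOSE_TO_CODE.get)(self.geno)
        df = pd.DataFrame(codes, index=self.ids, columns=self.marker_ids())
        df["phenotype"] = self.phenotype
        if self.trait_dose is not None:
            trait = np.array([DOSE_TO_CODE[d] for d in self.trait_dose], dtype=object)
            trait[(self.phenotype == "fertile") & ~self.f3_resolved] = "-"
            df["trait"] = trait
        return df


def _rng(config: CrossConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


def _place_positions(
    rng: np.random.Generator, length: int, density: float, spacing: int
) -> np.ndarray:
    """Uniformly placed positions at the target density, rejection-sampled
    to keep a minimum spacing."""
    target = int(rng.poisson(density * length))
    if target == 0:
        return np.empty(0, dtype=int)
    positions = np.empty(0, dtype=int)
    for _ in range(200):
        need = target - positions.size
        if need <= 0:
            break
        draw = rng.integers(1, length + 1, size=2 * need)
        positions = np.unique(np.concatenate([positions, draw]))
        keep = [int(positions[0])]
        for p in positions[1:]:
            if p - keep[-1] >= spacing:
                keep.append(int(p))
        positions = np.array(keep, dtype=int)
        if positions.size > target:
            positions = np.sort(rng.choice(positions, size=target, replace=False))
    else:
        raise ValueError("snp_density too high to satisfy the minimum spacing")
    return positions


def simulate_snp_map(config: CrossConfig) -> pd.DataFrame:
    """Plant the parental SNP map: positions plus P/M alleles per SNP.

    Deterministic given the seed and shared with :func:`simulate_parents`
    so downstream stages can run without generating sequences.  A marker
    SNP is guaranteed within 1 kb of the causal position.
    """
    rng = _rng(config, 0)
    rows = []
    for chrom in config.chrom_names:
        pos = _place_positions(
            rng, config.chrom_length_bp, config.snp_density, config.min_snp_spacing
        )
        if chrom == config.causal_chrom:
            if pos.size == 0 or np.abs(pos - config.causal_pos).min() > 1000:
                pos = pos[np.abs(pos - config.causal_pos) >= config.min_snp_spacing]
                pos = np.sort(np.append(pos, config.causal_pos))
        for p in pos:
            p_allele = BASES[rng.integers(4)].decode()
            others = [b.decode() for b in BASES if b.decode() != p_allele]
            m_allele = others[rng.integers(3)]
            rows.append((chrom, int(p), p_allele, m_allele))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "allele_P", "allele_M"])
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_parents(config: CrossConfig) -> tuple[Genome, Genome, pd.DataFrame]:
    """Two inbred parental genomes differing only at the planted SNPs.

    The sterile (P) line carries ``allele_P`` at every SNP, the fertile
    (M) line ``allele_M``; sequences are otherwise identical.  With
    ``promoter_indel_bp > 0`` a short insertion is additionally planted
    in the P line 500 bp upstream of the causal position (sequence
    context only — it never enters the depth statistics; SNP coordinates
    stay on the M/reference frame).
    """
    snps = simulate_snp_map(config)
    rng = _rng(config, 1)
    seqs_p: dict[str, str] = {}
    seqs_m: dict[str, str] = {}
    for chrom in config.chrom_names:
        base = rng.integers(0, 4, size=config.chrom_length_bp)
        seq = BASES[base]
        chrom_snps = snps[snps["chrom"] == chrom]
        seq_p, seq_m = seq.copy(), seq.copy()
        if len(chrom_snps):
            idx = chrom_snps["pos"].to_numpy(dtype=int) - 1
            seq_p[idx] = np.array([a.encode() for a in chrom_snps["allele_P"]], dtype="S1")
            seq_m[idx] = np.array([a.encode() for a in chrom_snps["allele_M"]], dtype="S1")
        seqs_p[chrom] = seq_p.tobytes().decode()
        seqs_m[chrom] = seq_m.tobytes().decode()
    if config.promoter_indel_bp > 0 and config.causal_chrom is not None:
        at = max(config.causal_pos - 500, 1)
        ins = "".join(BASES[rng.integers(4)].decode() for _ in range(config.promoter_indel_bp))
        s = seqs_p[config.causal_chrom]
        seqs_p[config.causal_chrom] = s[: at - 1] + ins + s[at - 1 :]
    return Genome(seqs_p), Genome(seqs_m), snps


def _gamete(
    rng: np.random.Generator, positions: np.ndarray, length: int, recomb_rate: float
) -> np.ndarray:
    """One gamete's parental origin (0 = P, 1 = M) at each marker."""
    start = int(rng.integers(2))
    k = int(rng.poisson(recomb_rate * length))
    if k == 0:
        return np.full(positions.size, start, dtype=np.int8)
    breaks = np.sort(rng.uniform(0, length, size=k))
    crossings = np.searchsorted(breaks, positions)
    return ((start + crossings) % 2).astype(np.int8)


def simulate_f2(config: CrossConfig, snps: pd.DataFrame) -> F2Population:
    """Self an F1 to produce the F2: two independent gametes per plant.

    Crossovers per chromosome are Poisson with mean recomb_rate x length
    (no interference), breakpoints uniform; expected genotype frequencies
    at any locus are a:h:b = 1:2:1.  Phenotypes follow the causal locus
    recessively; fertile plants are F3-resolved (simulated progeny-test
    truth).
    """
    rng = _rng(config, 2)
    n_snps = len(snps)
    geno = np.zeros((config.n_f2, n_snps), dtype=np.int8)
    for chrom, grp in snps.groupby("chrom", sort=False):
        positions = grp["pos"].to_numpy(dtype=float)
        cols = grp.index.to_numpy()
        for i in range(config.n_f2):
            g1 = _gamete(rng, positions, config.chrom_length_bp, config.recomb_rate)
            g2 = _gamete(rng, positions, config.chrom_length_bp, config.recomb_rate)
            geno[i, cols] = (g1 == 0).astype(np.int8) + (g2 == 0).astype(np.int8)

    if config.causal_chrom is None:
        trait_dose = None
        causal_idx = None
        phenotype = np.full(config.n_f2, "fertile", dtype=object)
    else:
        on_chrom = snps[snps["chrom"] == config.causal_chrom]
        offsets = np.abs(on_chrom["pos"].to_numpy() - config.causal_pos)
        causal_idx = int(on_chrom.index[np.argmin(offsets)])
        trait_dose = geno[:, causal_idx].copy()
        phenotype = np.where(trait_dose == 2, "sterile", "fertile").astype(object)
    return F2Population(
        snps=snps,
        geno=geno,
        phenotype=phenotype,
        trait_dose=trait_dose,
        f3_resolved=np.full(config.n_f2, True),
        causal_snp_index=causal_idx,
        ids=[f"F2_{i + 1:03d}" for i in range(config.n_f2)],
    )


def make_bulks_and_depths(
    f2: F2Population, snps: pd.DataFrame, config: CrossConfig
) -> pd.DataFrame:
    """Sequence the two bulks: per-SNP allele depths Paa/Maa/Pab/Mab.

    The sterile (aa) bulk pools ``bulk_size`` sterile plants; the fertile
    (ab) bulk pools ``bulk_size`` homozygous-fertile plants selected with
    F3 progeny-test truth.  Per SNP and bulk, total depth is
    Poisson(mean_depth) and each read is drawn from the M allele with
    probability equal to the bulk's M-allele frequency, then miscalled
    with ``error_rate``.  In a null cross (no causal locus) the bulks
    are disjoint random samples of the F2.
    """
    rng = _rng(config, 3)
    n = f2.geno.shape[0]
    if config.causal_chrom is None:
        perm = rng.permutation(n)
        if n < 2 * config.bulk_size:
            raise ValueError("n_f2 too small for two disjoint bulks; raise n_f2")
        bulk_aa = perm[: config.bulk_size]
        bulk_ab = perm[config.bulk_size : 2 * config.bulk_size]
    else:
        sterile = np.where(f2.phenotype == "sterile")[0]
        hom_fertile = np.where(
            (f2.phenotype == "fertile") & (f2.trait_dose == 0) & f2.f3_resolved
        )[0]
        if sterile.size < config.bulk_size or hom_fertile.size < config.bulk_size:
            raise ValueError(
                "not enough eligible plants for the bulks "
                f"({sterile.size} sterile, {hom_fertile.size} homozygous fertile); "
                "raise n_f2"
            )
        bulk_aa = rng.choice(sterile, size=config.bulk_size, replace=False)
        bulk_ab = rng.choice(hom_fertile, size=config.bulk_size, replace=False)

    out = {"chrom": snps["chrom"].to_numpy(), "pos": snps["pos"].to_numpy()}
    for label, members in (("aa", bulk_aa), ("ab", bulk_ab)):
        m_freq = 1.0 - f2.geno[members].mean(axis=0) / 2.0
        total = rng.poisson(config.mean_depth, size=len(snps))
        p_read_m = m_freq * (1 - config.error_rate) + (1 - m_freq) * config.error_rate
        m_reads = rng.binomial(total, p_read_m)
        out[f"M{label}"] = m_reads
        out[f"P{label}"] = total - m_reads
    df = pd.DataFrame(out)
    return df[["chrom", "pos", "Paa", "Maa", "Pab", "Mab"]]


def default_expression_truth() -> dict[str, dict[tuple[str, str], float]]:
    """Planted fold changes (vs fertile 2-mm buds) for the six candidate
    genes of the study preset.

    The AMS transcription factor is strongly down in sterile plants at
    both stages and up at the fertile 5-mm stage; the other five genes
    are up in sterile plants.
    """
    truth: dict[str, dict[tuple[str, str], float]] = {
        "AMS": {("fs", "2mm"): 1.0, ("fs", "5mm"): 3.0, ("ms", "2mm"): 0.15, ("ms", "5mm"): 0.3},
    }
    for gene in ("GGT1", "LOC168", "PP7", "HSC70", "ATL52"):
        truth[gene] = {
            ("fs", "2mm"): 1.0,
            ("fs", "5mm"): 1.5,
            ("ms", "2mm"): 4.0,
            ("ms", "5mm"): 3.0,
        }
    return truth


def simulate_ct_table(
    true_folds: dict[str, dict[tuple[str, str], float]],
    seed: int = 0,
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    reference_ct: float = 20.0,
    baseline_delta_ct: float = 5.0,
) -> pd.DataFrame:
    """Simulate qPCR Ct replicates for planted fold changes.

    The reference gene runs at a constant Ct plus Gaussian noise
    (``noise_sd`` cycles, default 0.15); the target gene at
    reference + baseline ΔCt − log2(fold) plus its own noise.  Folds are
    relative to the calibrator condition (fertile 2-mm buds).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    rows = []
    for gene in sorted(true_folds):
        for (group, stage), fold in sorted(true_folds[gene].items()):
            if fold <= 0:
                raise ValueError(f"{gene} {(group, stage)}: fold must be positive")
            for rep in range(1, n_replicates + 1):
                ct_ref = reference_ct + rng.normal(0, noise_sd)
                ct_tgt = (
                    reference_ct
                    + baseline_delta_ct
                    - math.log2(fold)
                    + rng.normal(0, noise_sd)
                )
                rows.append(
                    {
                        "gene": gene,
                        "group": group,
                        "stage": stage,
                        "replicate": rep,
                        "ct_target": round(ct_tgt, 4),
                        "ct_reference": round(ct_ref, 4),
                    }
                )
    return pd.DataFrame(rows)


def simulate_study(
    config: CrossConfig | None = None, with_genomes: bool = False
) -> dict:
    """Generate a full study bundle with ground truth.

    Returns a dict with the SNP map, F2 population, bulk depth table, Ct
    table, (optionally) parental genomes, and a ``ground_truth`` record
    of the planted causal locus and fold changes.
    """
    config = config or CrossConfig()
    if with_genomes:
        genome_p, genome_m, snps = simulate_parents(config)
    else:
        genome_p = genome_m = None
        snps = simulate_snp_map(config)
    f2 = simulate_f2(config, snps)
    depths = make_bulks_and_depths(f2, snps, config)
    truth_folds = default_expression_truth()
    ct = simulate_ct_table(truth_folds, seed=config.seed)
    causal_snp_pos = (
        int(snps.loc[f2.causal_snp_index, "pos"])
        if f2.causal_snp_index is not None
        else None
    )
    return {
        "config": config,
        "snps": snps,
        "f2": f2,
        "depths": depths,
        "ct_table": ct,
        "genome_P": genome_p,
        "genome_M": genome_m,
        "ground_truth": {
            "causal_chrom": config.causal_chrom,
            "causal_pos": config.causal_pos,
            "causal_snp_pos": causal_snp_pos,
            # (group, stage) keys flattened to "group:stage" for JSON round-trips
            "true_folds": {
                gene: {f"{g}:{s}": fold for (g, s), fold in folds.items()}
                for gene, folds in truth_folds.items()
            },
            "promoter_indel_bp": config.promoter_indel_bp,
        },
    }
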