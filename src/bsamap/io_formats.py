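"""Standard-format readers/writers, run configuration and the pipeline driver.

Coordinates are 1-based inclusive everywhere in memory (matching how
genome positions are reported); BED output is converted to 0-based
half-open on the way out.  All tables are plain TSV; FASTA goes through
Biopython and VCF through pysam.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("bsamap")

__all__ = [
    "Genome",
    "PipelineConfig",
    "PipelineInputs",
    "setup_logging",
    "read_fasta",
    "write_fasta",
    "read_snp_table",
    "write_snp_table",
    "write_regions_bed",
    "read_regions_bed",
    "read_genotype_table",
    "write_genotype_table",
    "read_ct_table",
    "write_ct_table",
    "vcf_to_snp_table",
    "run_pipeline",
]

SNP_TABLE_COLUMNS = ("chrom", "pos", "allele_P", "allele_M", "Paa", "Maa", "Pab", "Mab")
_INT_COLUMNS = ("pos", "Paa", "Maa", "Pab", "Mab")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


class Genome(Mapping[str, str]):
    """Ordered chromosome name -> uppercase DNA sequence mapping.

    Names must be unique and sequences non-empty over {A, C, G, T};
    ``allow_n=True`` additionally permits N.
    """

    def __init__(self, chromosomes: Mapping[str, str] | list[tuple[str, str]], allow_n: bool = False):
        items = chromosomes.items() if isinstance(chromosomes, Mapping) else chromosomes
        self._chroms: dict[str, str] = {}
        alphabet = set("ACGTN" if allow_n else "ACGT")
        for name, seq in items:
            if name in self._chroms:
                raise ValueError(f"duplicate chromosome name {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            extra = set(seq) - alphabet
            if extra:
                raise ValueError(f"chromosome {name!r} has letters outside the alphabet: {sorted(extra)}")
            self._chroms[name] = seq

    def __getitem__(self, name: str) -> str:
        return self._chroms[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._chroms)

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chroms.items()}


def read_fasta(path, allow_n: bool = False) -> Genome:
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return Genome(records, allow_n=allow_n)


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_snp_table(path) -> pd.DataFrame:
    """Read a tab-separated SNP/bulk-depth table.

    Expected header: ``chrom pos allele_P allele_M Paa Maa Pab Mab`` with
    1-based positions.  Rows are returned sorted by (chrom, pos);
    malformed rows, negative depths and duplicated positions raise
    errors naming the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele_P": str, "allele_M": str})
    missing = [c for c in SNP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in _INT_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            raise ValueError(f"{path}: malformed {col!r} value on line {int(bad.idxmax()) + 2}")
        if (coerced % 1 != 0).any():
            raise ValueError(f"{path}: non-integer {col!r} value on line {int((coerced % 1 != 0).idxmax()) + 2}")
        df[col] = coerced.astype(int)
    for col in ("Paa", "Maa", "Pab", "Mab"):
        neg = df[col] < 0
        if neg.any():
            raise ValueError(f"{path}: negative depth on line {int(neg.idxmax()) + 2}")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ValueError(f"{path}: duplicated (chrom, pos) on line {int(dup.idxmax()) + 2}")
    return df[list(SNP_TABLE_COLUMNS)].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def write_snp_table(df: pd.DataFrame, path) -> None:
    df[list(SNP_TABLE_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_regions_bed(regions, path) -> None:
    """Write association regions as BED (0-based half-open).

    The score column is 1000 x the region's peak smoothed |Δ|, capped at
    1000; overlapping regions on a chromosome are flagged with a warning
    but written as-is.
    """
    regions = sorted(regions, key=lambda r: (r.chrom, r.start))
    for a, b in zip(regions, regions[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            logger.warning("overlapping regions on %s: %d-%d and %d-%d", a.chrom, a.start, a.end, b.start, b.end)
    with open(path, "w") as fh:
        for i, r in enumerate(regions, start=1):
            score = min(1000, round(1000 * r.peak_abs_delta))
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\t{score}\n")


def read_regions_bed(path) -> pd.DataFrame:
    """Read a BED file back into 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": int(parts[1]) + 1,
                    "end": int(parts[2]),
                    "name": parts[3] if len(parts) > 3 else "",
                    "score": int(parts[4]) if len(parts) > 4 else 0,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def read_genotype_table(path) -> pd.DataFrame:
    """Genotype matrix TSV: rows individuals, columns markers (+ optional
    ``phenotype`` and ``trait``), codes a/b/h/-."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="individual")


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "group": str, "stage": str})
    required = {"gene", "group", "stage", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def vcf_to_snp_table(
    path, sample_P: str, sample_M: str, sample_aa: str, sample_ab: str
) -> pd.DataFrame:
    """Convert a VCF with per-sample allelic depths into the SNP table.

    Only biallelic SNP records where both parents are homozygous for
    different alleles are kept (others are skipped with a logged count);
    bulk depths come from the AD field, mapped to parent-of-origin
    columns by the parental genotypes.
    """
    import pysam

    rows, skipped = [], 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped += 1
                continue
            gt_p = rec.samples[sample_P].get("GT")
            gt_m = rec.samples[sample_M].get("GT")
            if (
                gt_p is None or gt_m is None
                or None in gt_p or None in gt_m
                or len(set(gt_p)) != 1 or len(set(gt_m)) != 1
                or gt_p[0] == gt_m[0]
            ):
                skipped += 1
                continue
            ad_aa = rec.samples[sample_aa].get("AD")
            ad_ab = rec.samples[sample_ab].get("AD")
            if ad_aa is None or ad_ab is None or None in ad_aa or None in ad_ab:
                skipped += 1
                continue
            ip, im = gt_p[0], gt_m[0]
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "allele_P": rec.alleles[ip],
                    "allele_M": rec.alleles[im],
                    "Paa": int(ad_aa[ip]),
                    "Maa": int(ad_aa[im]),
                    "Pab": int(ad_ab[ip]),
                    "Mab": int(ad_ab[im]),
                }
            )
    logger.info("vcf_to_snp_table: kept %d records, skipped %d", len(rows), skipped)
    return pd.DataFrame(rows, columns=list(SNP_TABLE_COLUMNS))


@dataclass(frozen=True)
class PipelineConfig:
    """Run-wide constants: the Δ threshold, fragment size window, depth
    floor, smoothing/merging scales and the expression significance level."""

    seed: int = 0
    delta_threshold: float = 0.6
    fragment_min_bp: int = 260
    fragment_max_bp: int = 420
    min_depth: int = 4
    smoothing_window_bp: int = 100_000
    merge_gap_bp: int = 50_000
    min_markers: int = 5
    alpha_expression: float = 0.01
    band_tolerance_bp: int = 3
    band_floor_bp: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.delta_threshold <= 1):
            raise ValueError("delta_threshold must be in (0, 1]")
        if self.fragment_min_bp >= self.fragment_max_bp:
            raise ValueError("fragment_min_bp must be below fragment_max_bp")
        for name in ("fragment_min_bp", "min_depth", "smoothing_window_bp", "merge_gap_bp", "min_markers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha_expression < 1):
            raise ValueError("alpha_expression must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class PipelineInputs:
    """Paths to whatever stage inputs are available; absent stages are
    skipped (requesting them elsewhere without an input is an error)."""

    snp_table: str | None = None
    genome_fasta: str | None = None
    segregation_table: str | None = None
    genotype_table: str | None = None
    caps_assay_table: str | None = None
    caps_band_table: str | None = None
    ct_table: str | None = None


def _segregation_stage(path) -> list[dict]:
    from . import segregation as seg

    df = pd.read_csv(path, sep="\t", dtype={"generation": str})
    results = []
    for _, row in df.iterrows():
        observed = (int(row["sterile"]), int(row["fertile"]))
        if "ratio" in df.columns and isinstance(row["ratio"], str) and ":" in row["ratio"]:
            ratio = tuple(int(x) for x in row["ratio"].split(":"))
            test = seg.chi_square_test(observed, ratio)
            results.append(
                {
                    "generation": row["generation"],
                    "observed": list(observed),
                    "ratio": row["ratio"],
                    "statistic": round(test.statistic, 4),
                    "p_value": round(test.p_value, 6),
                }
            )
        else:
            call = seg.classify_inheritance(observed)
            results.append(
                {
                    "generation": row["generation"],
                    "observed": list(observed),
                    "best_ratio": ":".join(map(str, call.best_ratio)) if call.best_ratio else None,
                    "verdict": call.verdict,
                }
            )
    return results


def _read_caps_assays(path):
    from .caps import CapsAssay
    from .slaf import RestrictionEnzyme

    df = pd.read_csv(path, sep="\t", dtype=str)
    assays = {}
    for _, row in df.iterrows():
        assays[row["marker_id"]] = CapsAssay(
            marker_id=row["marker_id"],
            enzyme=RestrictionEnzyme(row["enzyme"], row["site"], int(row["cut_offset"])),
            fragments_allele_P=tuple(int(x) for x in row["fragments_P"].split(",")),
            fragments_allele_M=tuple(int(x) for x in row["fragments_M"].split(",")),
        )
    return assays


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs, out_dir) -> dict:
    """Run every stage whose input is present and write a JSON report.

    Stage order: segregation -> SLAF summary -> SNP-index association and
    region calling -> CAPS genotyping -> linkage -> expression.  The
    report (``report.json`` under ``out_dir``) has a stable key order, so
    identical seed and inputs reproduce it byte for byte.
    """
    from . import bsa_index, expression, linkage, slaf
    from .caps import genotype_f2

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    genome = read_fasta(inputs.genome_fasta) if inputs.genome_fasta else None
    snps = read_snp_table(inputs.snp_table) if inputs.snp_table else None
    if genome is not None and snps is not None:
        unknown = set(snps["chrom"]) - set(genome.names)
        if unknown:
            raise ValueError(f"SNP table names chromosomes absent from the genome: {sorted(unknown)}")

    if inputs.segregation_table:
        logger.info("stage segregation: %s", inputs.segregation_table)
        report["stages"]["segregation"] = _segregation_stage(inputs.segregation_table)

    if genome is not None:
        logger.info("stage slaf: %d chromosomes, window %d-%d bp", len(genome), config.fragment_min_bp, config.fragment_max_bp)
        loci = slaf.select_slaf_loci(genome, min_bp=config.fragment_min_bp, max_bp=config.fragment_max_bp)
        if snps is not None:
            slaf.annotate_locus_tags(loci, genome, snps)
        summary = slaf.summarize_chromosomes(loci, snps if snps is not None else pd.DataFrame(columns=["chrom", "pos"]))
        summary.to_csv(out_dir / "slaf_summary.tsv", sep="\t", index=False)
        report["stages"]["slaf"] = {
            "n_loci": len(loci),
            "summary": summary.to_dict(orient="records"),
        }

    if snps is not None:
        logger.info("stage bsa: %d SNPs, min_depth %d", len(snps), config.min_depth)
        indexed = bsa_index.compute_index_table(snps, min_depth=config.min_depth)
        smoothed = bsa_index.smooth_delta(indexed, window_bp=config.smoothing_window_bp, min_markers=config.min_markers)
        regions = bsa_index.call_regions(
            smoothed,
            delta_threshold=config.delta_threshold,
            min_markers=config.min_markers,
            merge_gap_bp=config.merge_gap_bp,
        )
        smoothed.to_csv(out_dir / "snp_index.tsv", sep="\t", index=False, float_format="%.6f")
        write_regions_bed(regions, out_dir / "regions.bed")
        report["stages"]["association"] = {
            "n_snps": int(len(snps)),
            "n_regions": len(regions),
            "regions": [
                {
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "size_mb": r.size_mb,
                    "n_markers": r.n_markers,
                    "peak_abs_delta": round(r.peak_abs_delta, 4),
                }
                for r in regions
            ],
        }

    if inputs.caps_band_table:
        if not inputs.caps_assay_table:
            raise ValueError("stage caps requested (band table given) but no caps_assay_table provided")
        logger.info("stage caps: %s", inputs.caps_band_table)
        assays = _read_caps_assays(inputs.caps_assay_table)
        bands = pd.read_csv(inputs.caps_band_table, sep="\t", dtype={"individual": str, "marker_id": str, "bands": str})
        phen = None
        if inputs.genotype_table:
            gt = read_genotype_table(inputs.genotype_table)
            if "phenotype" in gt.columns:
                phen = gt["phenotype"]
        geno, concordance = genotype_f2(
            assays, bands, phen, tolerance_bp=config.band_tolerance_bp, floor_bp=config.band_floor_bp
        )
        write_genotype_table(geno, out_dir / "caps_genotypes.tsv")
        report["stages"]["caps"] = {
            "n_individuals": int(len(geno)),
            "concordance": {k: (None if np.isnan(v) else round(v, 4)) for k, v in concordance.items()},
        }

    if inputs.genotype_table:
        gt = read_genotype_table(inputs.genotype_table)
        markers = [c for c in gt.columns if c not in ("phenotype", "trait")]
        logger.info("stage linkage: %d markers, %d individuals", len(markers), len(gt))
        groups = linkage.build_linkage_groups(gt[markers])
        stage: dict = {
            "groups": [
                {
                    "markers": list(g.markers),
                    "positions_cm": [round(p, 3) for p in g.positions_cm],
                }
                for g in groups
            ]
        }
        if "trait" in gt.columns:
            placement = linkage.place_trait_locus(gt["trait"], gt[markers])
            stage["trait_placement"] = [
                {"marker": m, "r": round(r, 5), "cm": round(cm, 3)} for m, r, cm in placement.nearest
            ]
            stage["n_trait_excluded"] = placement.n_excluded
        report["stages"]["linkage"] = stage

    if inputs.ct_table:
        logger.info("stage expression: %s", inputs.ct_table)
        ct = read_ct_table(inputs.ct_table)
        result = expression.analyze_ct_table(ct, alpha=config.alpha_expression)
        result.to_csv(out_dir / "expression.tsv", sep="\t", index=False, float_format="%.6f")
        report["stages"]["expression"] = [
            {
                "gene": row["gene"],
                "group": row["group"],
                "stage": row["stage"],
                "fold": round(row["fold"], 4),
                "p": round(row["p"], 6),
                "significant": bool(row["significant"]),
            }
            for _, row in result.iterrows()
        ]

    if not report["stages"]:
        raise ValueError("no inputs provided; nothing to run")

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
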