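"""CAPS (cleaved amplified polymorphic sequence) marker design and scoring.

A SNP that creates or destroys a restriction site inside a PCR amplicon
can be genotyped on a gel: digest the amplicon and read the band sizes.
This module finds candidate enzymes for a SNP from its flanking sequence,
predicts allele-specific fragment patterns, and scores individuals'
observed band patterns into a/b/h genotype codes (a = homozygous for the
sterile-parent allele).  Fragments below a detectability floor (7 bp
runs off a gel; default floor 20 bp) are ignored when matching patterns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .slaf import RestrictionEnzyme, digest, revcomp, _find_all

logger = logging.getLogger(__name__)

__all__ = [
    "CapsAssay",
    "CapsCandidate",
    "find_caps_enzymes",
    "predict_fragments",
    "score_genotype",
    "genotype_f2",
]

DEFAULT_TOLERANCE_BP = 3
DEFAULT_FLOOR_BP = 20


@dataclass(frozen=True)
class CapsCandidate:
    enzyme: RestrictionEnzyme
    cut_allele: str  # "P" or "M": the allele with more sites in the window
    sites_P: int
    sites_M: int


@dataclass(frozen=True)
class CapsAssay:
    """Allele-specific digest patterns for one amplicon + enzyme pair."""

    marker_id: str
    enzyme: RestrictionEnzyme
    fragments_allele_P: tuple[int, ...]
    fragments_allele_M: tuple[int, ...]
    chrom: str | None = None
    snp_pos: int | None = None
    amplicon_start: int | None = None
    amplicon_end: int | None = None

    def __post_init__(self) -> None:
        if sorted(self.fragments_allele_P) == sorted(self.fragments_allele_M):
            raise ValueError(
                f"{self.marker_id}: both alleles digest identically; not a CAPS"
            )
        if sum(self.fragments_allele_P) != sum(self.fragments_allele_M):
            raise ValueError(
                f"{self.marker_id}: allele fragment sizes imply different amplicon lengths"
            )

    @property
    def amplicon_length(self) -> int:
        return sum(self.fragments_allele_P)


def _count_sites_window(context: str, enzyme: RestrictionEnzyme) -> int:
    n = len(_find_all(context, enzyme.site))
    if not enzyme.is_palindromic:
        n += len(_find_all(context, revcomp(enzyme.site)))
    return n


def find_caps_enzymes(
    context: str,
    snp_index: int,
    allele_P: str,
    allele_M: str,
    enzymes: Iterable[RestrictionEnzyme],
) -> list[CapsCandidate]:
    """Enzymes whose recognition-site count differs between the two alleles.

    ``context`` is genomic flanking sequence with the SNP at 0-based
    ``snp_index``; for each enzyme a window of length 2*len(site)-1
    centered on the SNP (every site placement touching the SNP) is
    rescanned with each allele substituted.  The flank must extend at
    least len(site)-1 bases on both sides of the SNP.
    """
    context = context.upper()
    if not (0 <= snp_index < len(context)):
        raise ValueError("snp_index outside the provided context")
    candidates = []
    for enzyme in enzymes:
        half = len(enzyme.site) - 1
        if snp_index < half or len(context) - snp_index - 1 < half:
            raise ValueError(
                f"flank too short for {enzyme.name}: need {half} bp each side of the SNP"
            )
        window = slice(snp_index - half, snp_index + half + 1)
        counts = {}
        for label, allele in (("P", allele_P), ("M", allele_M)):
            sub = context[: snp_index] + allele.upper() + context[snp_index + 1 :]
            counts[label] = _count_sites_window(sub[window], enzyme)
        if counts["P"] != counts["M"]:
            candidates.append(
                CapsCandidate(
                    enzyme=enzyme,
                    cut_allele="P" if counts["P"] > counts["M"] else "M",
                    sites_P=counts["P"],
                    sites_M=counts["M"],
                )
            )
    return candidates


def predict_fragments(amplicon: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Digest fragment sizes of an amplicon, sorted descending.

    Sizes always sum to the amplicon length.
    """
    if len(amplicon) == 0:
        raise ValueError("amplicon must be non-empty")
    sizes = [end - start + 1 for start, end in digest(amplicon, enzyme)]
    return sorted(sizes, reverse=True)


def _visible(bands: Sequence[float], floor_bp: float) -> list[float]:
    return sorted(b for b in bands if b >= floor_bp)


def _merge_within(bands: Sequence[float], tolerance_bp: float) -> list[float]:
    """Collapse bands that co-migrate (within tolerance) into one band."""
    merged: list[float] = []
    for b in sorted(bands):
        if merged and b - merged[-1] <= tolerance_bp:
            continue
        merged.append(b)
    return merged


def _patterns_match(
    observed: Sequence[float], expected: Sequence[float], tolerance_bp: float
) -> bool:
    if len(observed) != len(expected):
        return False
    return all(abs(o - e) <= tolerance_bp for o, e in zip(sorted(observed), sorted(expected)))


def score_genotype(
    observed_bands: Sequence[float],
    assay: CapsAssay,
    tolerance_bp: float = DEFAULT_TOLERANCE_BP,
    floor_bp: float = DEFAULT_FLOOR_BP,
) -> str:
    """Call a genotype code from an observed gel band pattern.

    The P-allele pattern alone scores ``a``, the M-allele pattern alone
    ``b``, the union of both (a heterozygote runs both amplicon copies)
    ``h``; anything else, an empty lane, or an ambiguous match scores
    ``missing``.  Bands below ``floor_bp`` are invisible on the gel and
    dropped from both sides of every comparison.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be non-negative")
    obs = _visible(observed_bands, floor_bp)
    if not obs:
        return "missing"
    pat_a = _merge_within(_visible(assay.fragments_allele_P, floor_bp), tolerance_bp)
    pat_b = _merge_within(_visible(assay.fragments_allele_M, floor_bp), tolerance_bp)
    pat_h = _merge_within(pat_a + pat_b, tolerance_bp)
    matches = [
        code
        for code, pat in (("a", pat_a), ("b", pat_b), ("h", pat_h))
        if _patterns_match(obs, pat, tolerance_bp)
    ]
    return matches[0] if len(matches) == 1 else "missing"


def genotype_f2(
    assays: dict[str, CapsAssay],
    band_table: pd.DataFrame,
    phenotypes: pd.Series | None = None,
    tolerance_bp: float = DEFAULT_TOLERANCE_BP,
    floor_bp: float = DEFAULT_FLOOR_BP,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Score a whole F2 population and report marker-trait concordance.

    ``band_table`` has columns ``individual, marker_id, bands`` where
    bands is a comma-separated size list (or a Python sequence).  Returns
    the genotype matrix (individuals x markers, codes a/b/h/missing) and,
    when sterile/fertile ``phenotypes`` indexed by individual are given,
    per-marker concordance: the fraction of scoreable individuals whose
    marker call (a vs not-a) matches their phenotype (sterile vs
    fertile).  Missing calls leave the concordance denominator.
    """
    unknown = set(band_table["marker_id"]) - set(assays)
    if unknown:
        raise KeyError(f"unknown assay id(s): {sorted(unknown)}")
    individuals = list(dict.fromkeys(band_table["individual"]))
    geno = pd.DataFrame("missing", index=individuals, columns=list(assays))
    for _, row in band_table.iterrows():
        bands = row["bands"]
        if isinstance(bands, str):
            bands = [float(x) for x in bands.split(",") if x.strip()]
        geno.loc[row["individual"], row["marker_id"]] = score_genotype(
            bands, assays[row["marker_id"]], tolerance_bp, floor_bp
        )
    concordance: dict[str, float] = {}
    if phenotypes is not None:
        sterile = phenotypes.reindex(geno.index) == "sterile"
        for marker in geno.columns:
            calls = geno[marker]
            ok = calls != "missing"
            if ok.sum() == 0:
                concordance[marker] = float("nan")
                continue
            agree = (calls[ok] == "a") == sterile[ok]
            concordance[marker] = float(np.mean(agree))
    return geno, concordance
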