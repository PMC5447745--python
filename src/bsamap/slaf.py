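"""In-silico reduced-representation (SLAF-style) marker loci.

The wet protocol digests genomic DNA with MseI, ligates adapters, then
destroys a subset of fragments with HaeIII and BfaI before size-selecting
260-420 bp fragments on a gel.  The in-silico analogue keeps every
MseI-MseI fragment of the right size that contains no internal HaeIII or
BfaI recognition site, and classifies each retained locus by the number
of distinct allele "tags" it carries between the two parents: one tag is
monomorphic, two to four tags polymorphic, more than four repetitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "RestrictionEnzyme",
    "SlafLocus",
    "MSEI",
    "HAEIII",
    "BFAI",
    "digest",
    "cut_positions",
    "select_slaf_loci",
    "annotate_locus_tags",
    "summarize_chromosomes",
    "polymorphism_percent",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease: recognition motif plus cut offset.

    ``cut_offset`` is the number of bases of the motif left of the cut on
    the top strand (MseI T^TAA has offset 1, HaeIII GG^CC offset 2).
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.site.upper()
        object.__setattr__(self, "site", site)
        if len(site) < 4 or set(site) - set("ACGT"):
            raise ValueError(f"{self.name}: site must be >=4 bp over ACGT")
        if not (0 <= self.cut_offset <= len(site)):
            raise ValueError(f"{self.name}: cut offset outside the site")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.site) == self.site


MSEI = RestrictionEnzyme("MseI", "TTAA", 1)
HAEIII = RestrictionEnzyme("HaeIII", "GGCC", 2)
BFAI = RestrictionEnzyme("BfaI", "CTAG", 1)

DEFAULT_EXCLUDERS: tuple[RestrictionEnzyme, ...] = (HAEIII, BFAI)


@dataclass
class SlafLocus:
    """A size-selected restriction fragment usable as a sequencing locus.

    Coordinates are 1-based inclusive on the source genome.
    """

    chrom: str
    start: int
    end: int
    tags: set[str] = field(default_factory=set)
    status: str = "monomorphic"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _find_all(haystack: str, needle: str) -> list[int]:
    """0-based start indices of every (overlapping) occurrence."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Top-strand split points (0 < p < len) produced by the enzyme.

    Palindromic motifs are scanned on one strand; for non-palindromic
    motifs the reverse-strand occurrences (i.e. forward occurrences of
    the reverse complement) are cut at the mirrored offset.
    """
    seq = sequence.upper()
    n = len(seq)
    splits = {i + enzyme.cut_offset for i in _find_all(seq, enzyme.site)}
    if not enzyme.is_palindromic:
        mirrored = len(enzyme.site) - enzyme.cut_offset
        splits |= {i + mirrored for i in _find_all(seq, revcomp(enzyme.site))}
    return sorted(p for p in splits if 0 < p < n)


def digest(sequence: str, enzyme: RestrictionEnzyme) -> list[tuple[int, int]]:
    """Fragment intervals (1-based inclusive) of a complete digest.

    Every motif occurrence is cut, including overlapping ones; fragment
    lengths always sum to the sequence length.  An empty sequence yields
    an empty list.
    """
    if not sequence:
        return []
    bounds = [0, *cut_positions(sequence, enzyme), len(sequence)]
    return [(a + 1, b) for a, b in zip(bounds, bounds[1:])]


def has_site(sequence: str, enzyme: RestrictionEnzyme) -> bool:
    seq = sequence.upper()
    if enzyme.site in seq:
        return True
    return not enzyme.is_palindromic and revcomp(enzyme.site) in seq


def select_slaf_loci(
    genome,
    primary: RestrictionEnzyme = MSEI,
    excluders: tuple[RestrictionEnzyme, ...] = DEFAULT_EXCLUDERS,
    min_bp: int = 260,
    max_bp: int = 420,
) -> list[SlafLocus]:
    """Pick sequencing loci: primary-enzyme fragments of the selected size
    that carry no internal excluder-enzyme site.

    Parameters mirror the protocol defaults: MseI fragments of 260-420 bp
    surviving HaeIII and BfaI digestion.
    """
    if min_bp >= max_bp:
        raise ValueError("min_bp must be smaller than max_bp")
    loci: list[SlafLocus] = []
    for chrom, seq in genome.items():
        for start, end in digest(seq, primary):
            length = end - start + 1
            if not (min_bp <= length <= max_bp):
                continue
            frag = seq[start - 1 : end]
            if any(has_site(frag, e) for e in excluders):
                continue
            loci.append(SlafLocus(chrom=chrom, start=start, end=end))
    return loci


def annotate_locus_tags(
    loci: list[SlafLocus], genome, snps: pd.DataFrame
) -> list[SlafLocus]:
    """Attach allele tags to each locus from the parental SNPs it overlaps.

    A tag is one distinct haplotype sequence of the locus; between two
    inbred parents a locus overlapping at least one SNP carries exactly
    two tags (the two parental haplotypes) and is therefore polymorphic
    under the 2-4-tag rule.
    """
    by_chrom = {c: g.sort_values("pos") for c, g in snps.groupby("chrom")}
    for locus in loci:
        seq = genome[locus.chrom][locus.start - 1 : locus.end]
        tag_p, tag_m = list(seq), list(seq)
        chrom_snps = by_chrom.get(locus.chrom)
        if chrom_snps is not None:
            inside = chrom_snps[
                (chrom_snps["pos"] >= locus.start) & (chrom_snps["pos"] <= locus.end)
            ]
            for _, row in inside.iterrows():
                i = int(row["pos"]) - locus.start
                tag_p[i] = row["allele_P"]
                tag_m[i] = row["allele_M"]
        locus.tags = {"".join(tag_p), "".join(tag_m)}
        locus.status = classify_tag_count(len(locus.tags))
    return loci


def classify_tag_count(n_tags: int) -> str:
    """Locus status from its tag count: 1 monomorphic, 2-4 polymorphic,
    >4 repetitive."""
    if n_tags < 1:
        raise ValueError("a locus has at least one tag")
    if n_tags == 1:
        return "monomorphic"
    if n_tags <= 4:
        return "polymorphic"
    return "repetitive"


def polymorphism_percent(poly_count: int, slaf_count: int) -> float:
    """Share of polymorphic loci, in percent to two decimals (0.0 when the
    chromosome carries no loci)."""
    if slaf_count == 0:
        return 0.0
    return round(100.0 * poly_count / slaf_count, 2)


def summarize_chromosomes(
    loci: list[SlafLocus], snps: pd.DataFrame
) -> pd.DataFrame:
    """Per-chromosome marker summary with a totals row.

    Columns: ``chrom, slaf_count, snp_count, snp_on_slaf, poly_count,
    poly_percent`` where snp_on_slaf counts SNPs falling inside a locus
    and poly_percent = 100 * poly_count / slaf_count.
    """
    chroms = sorted(
        {l.chrom for l in loci} | set(snps["chrom"].unique()),
    )
    rows = []
    for chrom in chroms:
        cl = [l for l in loci if l.chrom == chrom]
        cs = snps[snps["chrom"] == chrom]
        on_slaf = sum(
            int(((cs["pos"] >= l.start) & (cs["pos"] <= l.end)).sum()) for l in cl
        )
        poly = sum(1 for l in cl if l.status == "polymorphic")
        rows.append(
            {
                "chrom": chrom,
                "slaf_count": len(cl),
                "snp_count": int(len(cs)),
                "snp_on_slaf": on_slaf,
                "poly_count": poly,
                "poly_percent": polymorphism_percent(poly, len(cl)),
            }
        )
    total = {
        "chrom": "Total",
        "slaf_count": sum(r["slaf_count"] for r in rows),
        "snp_count": sum(r["snp_count"] for r in rows),
        "snp_on_slaf": sum(r["snp_on_slaf"] for r in rows),
        "poly_count": sum(r["poly_count"] for r in rows),
    }
    total["poly_percent"] = polymorphism_percent(
        total["poly_count"], total["slaf_count"]
    )
    rows.append(total)
    return pd.DataFrame(rows)
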