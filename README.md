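# bsamap

Bulked-segregant mapping of a recessive locus from pooled sequencing, in
the style of a BSA + SLAF-seq study of genetic male sterility in melon
(*Cucumis melo*): an F2 from a sterile × fertile cross is phenotyped,
DNA from the two phenotypic extremes is pooled, and the causal region is
located by comparing pooled allele frequencies at parent-distinguishing
SNPs. The package is aimed at plant-genetics practitioners who want the
whole analysis chain — from Mendelian segregation tests to candidate
regions, CAPS genotyping, linkage distances and qPCR expression — as
reproducible, testable code driven either by real tables in standard
formats or by its own synthetic-cross generator with known ground truth.

## The statistics at the core

For each SNP distinguishing the sterile parent (P) from the fertile
parent (M), each bulk's **SNP-index** is the fraction of its reads
carrying the M allele, and the association statistic is their difference:

```
SNP_index(aa) = Maa / (Paa + Maa)        (sterile bulk)
SNP_index(ab) = Mab / (Pab + Mab)        (fertile bulk)
Δ(SNP-index)  = SNP_index(aa) − SNP_index(ab)
```

Δ = +1 when the sterile bulk is purely M genome and the fertile bulk
purely P genome, −1 in the mirror configuration, and ≈ 0 at unlinked
loci. Near a fully penetrant recessive sterility locus the sterile bulk
is fixed for P and a homozygous-fertile bulk for M, so |Δ| → 1. |Δ| is
smoothed along each chromosome (sliding-window mean, loess optional) and
maximal marker runs with smoothed |Δ| > 0.6 are called as candidate
regions.

Around that core sit: Pearson X² goodness-of-fit tests against Mendelian
ratios (1:3, 1:1, …); an in-silico reduced-representation model (MseI
fragments of 260–420 bp without internal HaeIII/BfaI sites, loci with
2–4 allele tags counted as polymorphic); CAPS marker design and gel-band
genotype scoring; two-point F2 recombination fractions by EM with
Kosambi map distances d = 25·ln((1+2r)/(1−2r)) cM; and 2^(−ΔΔCt)
relative expression with Welch tests on the ΔCt scale.

## Worked example

```python
import bsamap as b
from bsamap.synthetic_data import CrossConfig, simulate_study

# Mendelian segregation: 48 sterile vs 112 fertile F2 plants against 1:3
test = b.chi_square_test((48, 112), (1, 3))
print(f"X2 = {test.statistic:.2f}, p = {test.p_value:.3f}")

# a full synthetic cross: 252 F2, 30+30 bulks, ~30x depth, causal on chr9
study = simulate_study(CrossConfig(seed=1))
idx = b.compute_index_table(study["depths"], min_depth=4)
sm = b.smooth_delta(idx, window_bp=100_000, min_markers=5)
for r in b.call_regions(sm, delta_threshold=0.6):
    print(f"{r.chrom}:{r.start}-{r.end}  size={r.size_mb} Mb  "
          f"markers={r.n_markers}  peak|delta|={r.peak_abs_delta:.2f}")
print("planted causal SNP:", study["ground_truth"]["causal_snp_pos"])

print(f"kosambi_cm(0.0016) = {b.kosambi_cm(0.0016):.2f} cM")
```

prints

```
X2 = 2.13, p = 0.144
chr9:209520-791502  size=0.58 Mb  markers=99  peak|delta|=0.95
planted causal SNP: 500488
kosambi_cm(0.0016) = 0.16 cM
```

The segregation test does not reject a single-recessive-gene 1:3 ratio;
the association scan calls exactly one region, on the simulated causal
chromosome, containing the planted locus; and a recombination fraction
of 0.16% converts to 0.16 cM on the Kosambi scale.

The same analyses run from the shell on TSV/FASTA/VCF inputs:

```
bsamap --seed 1 --out-dir out simulate
bsamap --seed 1 --out-dir out bsa out/snp_table.tsv
bsamap --out-dir out segregation seg.tsv
bsamap --out-dir out qpcr out/ct_table.tsv
```

Each run writes stage outputs (TSV/BED) plus a `report.json` with a
stable key order, so a fixed seed reproduces it byte for byte.

## Layout

| module | contents |
| --- | --- |
| `bsamap.io_formats` | FASTA/VCF/BED/TSV readers and writers, `PipelineConfig`, `run_pipeline` |
| `bsamap.synthetic_data` | the synthetic cross: parents, F2 meiosis, bulks, Ct tables, ground truth |
| `bsamap.segregation` | Pearson X² ratio tests and inheritance-model classification |
| `bsamap.slaf` | restriction digest, size-selected locus choice, polymorphism summaries |
| `bsamap.bsa_index` | SNP-index, Δ(SNP-index), smoothing, region calling |
| `bsamap.caps` | CAPS enzyme discovery, fragment prediction, band-pattern scoring |
| `bsamap.linkage` | EM recombination fractions, Kosambi distances, seriation, trait placement |
| `bsamap.expression` | ΔCt / 2^(−ΔΔCt) analysis with Welch significance calls |

See `docs/methods.md` for the models, assumptions and numerical choices.
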