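"""CAPS marker discovery and gel-pattern genotype scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.caps import (
    CapsAssay,
    find_caps_enzymes,
    genotype_f2,
    predict_fragments,
    score_genotype,
)
from bsamap.slaf import BFAI, HAEIII, MSEI, RestrictionEnzyme, revcomp
import pandas as pd

ENZYMES = (MSEI, HAEIII, BFAI)


def bsa16_like_assay() -> CapsAssay:
    """The worked assay: a 502-bp amplicon uncut in the sterile line,
    cut to 495 + 7 bp in the fertile line."""
    return CapsAssay(
        marker_id="BSA16",
        enzyme=HAEIII,
        fragments_allele_P=(502,),
        fragments_allele_M=(495, 7),
    )


class TestFindCapsEnzymes:
    def test_g_to_t_snp_toggles_haeiii_site(self):
        # context ...G[G/T]CC...: the G allele completes GGCC, T destroys it
        context = "ATAGCTAGCTAGG" + "G" + "CCATTGCAATCGA"
        hits = find_caps_enzymes(context, 13, allele_P="T", allele_M="G", enzymes=[HAEIII])
        assert len(hits) == 1
        assert hits[0].cut_allele == "M"
        assert (hits[0].sites_P, hits[0].sites_M) == (0, 1)

    def test_snp_touching_no_site_gives_empty_list(self):
        context = "A" * 21
        assert find_caps_enzymes(context, 10, "C", "G", [HAEIII]) == []

    def test_flank_too_short_is_an_error(self):
        with pytest.raises(ValueError, match="flank"):
            find_caps_enzymes("ACGT", 0, "A", "C", [HAEIII])

    def test_matches_full_window_rescan_oracle(self, rng):
        """Candidate set equals a naive rescan of the whole substituted
        context, restricted to sites touching the SNP."""
        bases = np.array(list("ACGT"))
        for _ in range(50):
            context = "".join(rng.choice(bases, size=200))
            i = int(rng.integers(10, 190))
            a_p, a_m = rng.choice(bases, size=2, replace=False)
            got = {
                c.enzyme.name
                for c in find_caps_enzymes(context, i, a_p, a_m, ENZYMES)
            }
            expected = set()
            for enz in ENZYMES:
                counts = {}
                for allele in (a_p, a_m):
                    sub = context[:i] + allele + context[i + 1 :]
                    # count only placements overlapping the SNP position
                    n = sum(
                        1
                        for j in range(len(sub) - len(enz.site) + 1)
                        if sub[j : j + len(enz.site)] == enz.site
                        and j <= i <= j + len(enz.site) - 1
                    )
                    counts[allele] = n
                if counts[a_p] != counts[a_m]:
                    expected.add(enz.name)
            assert got == expected


class TestPredictFragments:
    def test_uncut_amplicon(self):
        amplicon = "ATG" * 167 + "C"  # 502 bp, no GGCC
        assert predict_fragments(amplicon, HAEIII) == [502]

    def test_single_cut_gives_495_and_7(self):
        # place GGCC so the cut (GG^CC) falls 495 bp from the left end
        left = ("ATG" * 165)[:493]
        amplicon = left + "GGCC" + "ATGAT"
        assert len(amplicon) == 502
        assert predict_fragments(amplicon, HAEIII) == [495, 7]

    def test_two_sites_conserve_length(self):
        amplicon = "ATA" * 40 + "GGCC" + "ATA" * 40 + "GGCC" + "ATA" * 40
        frags = predict_fragments(amplicon, HAEIII)
        assert len(frags) == 3
        assert sum(frags) == len(amplicon)


class TestScoreGenotype:
    @pytest.mark.parametrize(
        ("bands", "expected"),
        [
            ([502], "a"),  # sterile-parent pattern
            ([495], "b"),  # fertile-parent pattern (7-bp band invisible)
            ([502, 495], "h"),  # heterozygote shows both
            ([], "missing"),
            ([300], "missing"),
            ([502, 495, 300], "missing"),
        ],
    )
    def test_worked_assay_patterns(self, bands, expected):
        assert score_genotype(bands, bsa16_like_assay()) == expected

    def test_tolerance_window(self):
        assay = bsa16_like_assay()
        assert score_genotype([504], assay, tolerance_bp=3) == "a"
        assert score_genotype([508], assay, tolerance_bp=3) == "missing"

    def test_label_swap_swaps_a_and_b(self):
        assay = bsa16_like_assay()
        swapped = CapsAssay(
            marker_id="BSA16r",
            enzyme=assay.enzyme,
            fragments_allele_P=assay.fragments_allele_M,
            fragments_allele_M=assay.fragments_allele_P,
        )
        for bands in ([502], [495], [502, 495]):
            direct = score_genotype(bands, assay)
            flipped = score_genotype(bands, swapped)
            assert flipped == {"a": "b", "b": "a"}.get(direct, direct)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        bands=st.lists(st.integers(min_value=1, max_value=600), max_size=4),
        tol=st.integers(min_value=0, max_value=5),
    )
    def test_scoring_symmetry_property(self, bands, tol):
        assay = bsa16_like_assay()
        swapped = CapsAssay(
            marker_id="r",
            enzyme=assay.enzyme,
            fragments_allele_P=assay.fragments_allele_M,
            fragments_allele_M=assay.fragments_allele_P,
        )
        direct = score_genotype(bands, assay, tolerance_bp=tol)
        flipped = score_genotype(bands, swapped, tolerance_bp=tol)
        assert flipped == {"a": "b", "b": "a"}.get(direct, direct)

    def test_identical_patterns_are_not_a_caps(self):
        with pytest.raises(ValueError, match="not a CAPS"):
            CapsAssay("bad", HAEIII, (250, 252), (252, 250))


class TestGenotypeF2:
    def _bands_for(self, code):
        return {"a": "502", "b": "495,7", "h": "502,495,7"}[code]

    def test_marker_at_causal_locus_fully_concordant(self, small_f2):
        gt = small_f2.genotype_frame()
        codes = gt[small_f2.marker_ids()[small_f2.causal_snp_index]]
        bands = pd.DataFrame(
            {
                "individual": gt.index,
                "marker_id": "BSA16",
                "bands": [self._bands_for(c) for c in codes],
            }
        )
        geno, concord = genotype_f2(
            {"BSA16": bsa16_like_assay()}, bands, phenotypes=gt["phenotype"]
        )
        assert (geno["BSA16"] == codes).all()
        assert concord["BSA16"] == 1.0

    def test_linked_marker_concordance_near_expectation(self, rng):
        """A marker at recombination fraction r from the trait misclassifies
        a predictable share of plants."""
        from conftest import simulate_pair

        r = 0.05
        g_trait, g_marker = simulate_pair(rng, 2000, r)
        phen = np.where(np.asarray(g_trait) == "a", "sterile", "fertile")
        bands = pd.DataFrame(
            {
                "individual": [f"i{k}" for k in range(2000)],
                "marker_id": "m",
                "bands": [self._bands_for(c) for c in g_marker],
            }
        )
        geno, concord = genotype_f2(
            {"m": bsa16_like_assay()}, bands, phenotypes=pd.Series(phen.tolist(), index=bands["individual"].tolist())
        )
        # P(marker a | trait a) etc: discordance ~ P(geno class mismatch)
        from bsamap.linkage import two_locus_class_probs

        probs = two_locus_class_probs(r)
        expected = probs[2, 2] + probs[:2, :2].sum()  # (a,a) or (not-a, not-a)
        assert concord["m"] == pytest.approx(expected, abs=3 * math_se(expected, 2000))

    def test_uninterpretable_bands_excluded_from_denominator(self):
        bands = pd.DataFrame(
            {
                "individual": ["i1", "i2", "i3"],
                "marker_id": "m",
                "bands": ["502", "123", "495"],
            }
        )
        phen = pd.Series(["sterile", "sterile", "fertile"], index=["i1", "i2", "i3"])
        geno, concord = genotype_f2({"m": bsa16_like_assay()}, bands, phenotypes=phen)
        assert geno.loc["i2", "m"] == "missing"
        assert concord["m"] == 1.0

    def test_unknown_assay_id_is_an_error(self):
        bands = pd.DataFrame({"individual": ["i1"], "marker_id": ["nope"], "bands": ["502"]})
        with pytest.raises(KeyError):
            genotype_f2({"m": bsa16_like_assay()}, bands)


def math_se(p, n):
    return (p * (1 - p) / n) ** 0.5
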