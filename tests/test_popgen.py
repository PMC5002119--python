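"""Breed presence, breed-specific rules, silent sites and Watterson theta."""

import itertools

import pytest
from Bio.Seq import Seq

from poolvar import popgen
from poolvar.impact import ImpactClass
from poolvar.io_formats import GeneModel, PoolSpec

from conftest import make_record


BREEDS = ["Duroc", "Asian", "Iberian"]
MANIFEST = [
    PoolSpec("Duroc_1", "Duroc", 23),
    PoolSpec("Duroc_2", "Duroc", 22),
    PoolSpec("Asian", "Asian", 22),
    PoolSpec("Iberian", "Iberian", 13),
]


def rec(key="chr1_1_A_T", paaf=None, alt_reads=None, dp=None):
    return make_record(key, paaf=paaf, alt_reads=alt_reads, dp=dp, manifest=MANIFEST)


class TestBreedPresence:
    @pytest.mark.parametrize(
        "alt_reads,min_alt,expected",
        [
            ({"Duroc_1": 3, "Duroc_2": 0}, 2, True),
            ({"Duroc_1": 1, "Duroc_2": 0}, 2, False),
            ({"Duroc_1": 1, "Duroc_2": 0}, 1, True),
            ({"Duroc_1": 1, "Duroc_2": 1}, 2, True),
        ],
    )
    def test_summed_alt_reads_threshold(self, alt_reads, min_alt, expected):
        r = rec(
            paaf={p: alt_reads.get(p, 0) / 1000 for p in ("Duroc_1", "Duroc_2")},
            alt_reads=alt_reads,
        )
        pools = [p for p in MANIFEST if p.breed_label == "Duroc"]
        assert popgen.breed_presence(r, pools, min_alt) is expected

    def test_breed_without_pools_rejected(self):
        with pytest.raises(ValueError, match="no pools"):
            popgen.breed_presence(rec(paaf={"Asian": 0.1}), [], 2)


class TestBreedPaaf:
    def test_ploidy_weighted_over_covered_pools(self):
        r = rec(paaf={"Duroc_1": 0.5, "Duroc_2": 0.1})
        pools = [p for p in MANIFEST if p.breed_label == "Duroc"]
        assert popgen.breed_paaf(r, pools) == pytest.approx(
            (46 * 0.5 + 44 * 0.1) / 90
        )


class TestPerBreedCounts:
    def _records(self):
        records, classes = [], {}
        # 10 variants in Duroc only: 4 strong, 6 mild; 5 shared everywhere
        for i in range(10):
            k = f"chr1_{i}_A_T"
            records.append(rec(k, paaf={"Duroc_1": 0.2}, alt_reads={"Duroc_1": 200}))
            classes[k] = ImpactClass("H" if i < 4 else "L")
        for i in range(10, 15):
            k = f"chr1_{i}_A_T"
            records.append(
                rec(
                    k,
                    paaf={"Duroc_1": 0.2, "Asian": 0.2, "Iberian": 0.2},
                    alt_reads={"Duroc_1": 200, "Asian": 200, "Iberian": 200},
                )
            )
            classes[k] = ImpactClass("Mtol")
        return records, classes

    def test_totals_uniques_and_classes(self):
        records, classes = self._records()
        out = {
            s.breed: s
            for s in popgen.per_breed_counts(records, classes, MANIFEST, BREEDS)
        }
        assert out["Duroc"].n_variants == 15
        assert out["Duroc"].n_unique == 10
        assert out["Asian"].n_variants == 5 and out["Asian"].n_unique == 0
        assert out["Duroc"].class_counts == {"H": 4, "Mdel": 0, "Mtol": 5, "L": 6}

    def test_percent_strong_is_truncated_to_one_decimal(self):
        # 133 strong of 1042 = 12.764 % -> reported 12.7
        records, classes = [], {}
        for i in range(1042):
            k = f"chr2_{i}_A_T"
            records.append(rec(k, paaf={"Duroc_1": 0.3}, alt_reads={"Duroc_1": 300}))
            classes[k] = ImpactClass("H" if i < 133 else "L")
        (summary,) = popgen.per_breed_counts(records, classes, MANIFEST, ["Duroc"])
        assert summary.pct_strong == 12.7

    def test_variant_in_all_breeds_unique_nowhere(self):
        records, classes = self._records()
        summaries = popgen.per_breed_counts(records, classes, MANIFEST, BREEDS)
        assert sum(s.n_unique for s in summaries) == 10


class TestBreedSpecific:
    def test_rule_a_requires_min_frequency(self):
        present = rec("chr1_1_A_T", paaf={"Duroc_1": 0.15, "Asian": 0.0, "Iberian": 0.0},
                      alt_reads={"Duroc_1": 150, "Asian": 0, "Iberian": 0})
        low = rec("chr1_2_A_T", paaf={"Duroc_1": 0.05, "Asian": 0.0, "Iberian": 0.0},
                  alt_reads={"Duroc_1": 50, "Asian": 0, "Iberian": 0})
        hits = popgen.breed_specific_variants([present, low], MANIFEST, BREEDS)
        assert [(h[0], h[1], h[2]) for h in hits] == [("chr1_1_A_T", "Duroc", "A")]

    def test_rule_b_absent_in_exactly_one_breed(self):
        r = rec(
            "chr1_3_A_T",
            paaf={"Duroc_1": 0.6, "Duroc_2": 0.6, "Iberian": 0.7, "Asian": 0.0},
            alt_reads={"Duroc_1": 600, "Duroc_2": 600, "Iberian": 700, "Asian": 0},
        )
        hits = popgen.breed_specific_variants([r], MANIFEST, BREEDS)
        assert [(h[0], h[1], h[2]) for h in hits] == [("chr1_3_A_T", "Asian", "B")]

    def test_rules_mutually_exclusive(self):
        """No variant can be reported under both rules (A needs presence in
        exactly one breed, B needs presence in all but one)."""
        for paafs in itertools.product([0.0, 0.2, 0.8], repeat=3):
            r = rec(
                "chr1_9_A_T",
                paaf=dict(zip(["Duroc_1", "Asian", "Iberian"], paafs)),
                alt_reads={
                    p: int(1000 * f)
                    for p, f in zip(["Duroc_1", "Asian", "Iberian"], paafs)
                },
            )
            hits = popgen.breed_specific_variants([r], MANIFEST, BREEDS)
            assert len(hits) <= 1


class TestSilentSites:
    def test_third_position_mode_counts_codons(self):
        g = GeneModel("g", "chr1", "+", [(1, 300)], "GGG" * 100)
        per_gene, total = popgen.count_silent_sites([g], "third_position")
        assert per_gene["g"] == 100 and total == 100

    def test_tryptophan_has_no_synonymous_fraction(self):
        g = GeneModel("g", "chr1", "+", [(1, 3)], "TGG")
        _, total = popgen.count_silent_sites([g], "fractional")
        assert total == 0.0

    def test_fourfold_third_position_contributes_one(self):
        g = GeneModel("g", "chr1", "+", [(1, 3)], "GGG")
        _, total = popgen.count_silent_sites([g], "fractional")
        assert total == pytest.approx(1.0)

    def test_premature_stop_rejected(self):
        g = GeneModel("g", "chr1", "+", [(1, 6)], "TAAGGG")
        with pytest.raises(ValueError, match="stop"):
            popgen.count_silent_sites([g], "fractional")

    def test_fractional_matches_brute_force_for_all_sense_codons(self):
        """Independent oracle: enumerate the 9 single-base mutations of every
        sense codon and translate both sides with Biopython."""
        bases = "ACGT"
        sense = [
            a + b + c
            for a in bases for b in bases for c in bases
            if str(Seq(a + b + c).translate()) != "*"
        ]
        for codon in sense:
            n_syn = 0
            for i, alt in itertools.product(range(3), bases):
                if alt == codon[i]:
                    continue
                mutant = codon[:i] + alt + codon[i + 1:]
                if str(Seq(mutant).translate()) == str(Seq(codon).translate()):
                    n_syn += 1
            g = GeneModel("g", "chr1", "+", [(1, 3)], codon)
            _, got = popgen.count_silent_sites([g], "fractional")
            assert got == pytest.approx(n_syn / 3)
            assert 0 <= got < 3


class TestWatterson:
    @pytest.mark.parametrize(
        "S,n_chrom,L,expected",
        [
            (5, 2, 1000, 0.005),
            (5, 4, 1000, 5 / (1 + 0.5 + 1 / 3) / 1000),
            (0, 10, 1000, 0.0),
        ],
    )
    def test_estimates(self, S, n_chrom, L, expected):
        res = popgen.watterson_theta(S, n_chrom, L)
        assert res.theta_per_site == pytest.approx(expected)

    def test_requires_two_chromosomes(self):
        with pytest.raises(ValueError):
            popgen.watterson_theta(5, 1, 1000)


class TestMinDetectableMaf:
    @pytest.mark.parametrize(
        "n,expected", [(304, 0.0016), (1, 0.5), (50, 0.01)]
    )
    def test_one_copy_floor(self, n, expected):
        got = popgen.min_detectable_maf(n)
        # two significant figures, as the detection floor is quoted
        assert float(f"{got:.2g}") == expected
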