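"""Impact classes and the stratified variant summaries."""

import numpy as np
import pytest

from poolvar import impact as imp
from poolvar.io_formats import EffectAnnotation

from conftest import make_record


def ann(key, term, tier, sift="unknown", gene="g1", ppos=None, plen=None):
    return EffectAnnotation(key, gene, term, tier, sift, ppos, plen)


class TestClassifyImpact:
    @pytest.mark.parametrize(
        "term,tier,sift,expected",
        [
            ("stop_gained", "HIGH", "unknown", "H"),
            ("frame_shift", "HIGH", "unknown", "H"),
            ("splice_site_donor", "HIGH", "unknown", "H"),
            ("non_synonymous", "MODERATE", "deleterious", "Mdel"),
            ("non_synonymous", "MODERATE", "tolerated", "Mtol"),
            ("non_synonymous", "MODERATE", "unknown", "Mtol"),
            ("codon_change_or_deletion", "MODERATE", "deleterious", "Mdel"),
            ("synonymous", "LOW", "unknown", "L"),
            ("start_gained", "MODIFIER", "unknown", "L"),
        ],
    )
    def test_mapping(self, term, tier, sift, expected):
        cls = imp.classify_impact(ann("k", term, tier, sift))
        assert cls.value == expected
        assert cls.strong == (expected in {"H", "Mdel"})

    def test_partition_covers_every_annotation(self, rng):
        """Every valid annotation maps to exactly one of the four classes."""
        terms = sorted(
            {
                ("splice_site_acceptor", "HIGH"),
                ("stop_lost", "HIGH"),
                ("start_lost", "HIGH"),
                ("non_synonymous", "MODERATE"),
                ("synonymous", "LOW"),
                ("start_gained", "LOW"),
            }
        )
        counts = {"H": 0, "Mdel": 0, "Mtol": 0, "L": 0}
        n = 500
        for i in range(n):
            term, tier = terms[rng.integers(len(terms))]
            sift = ["deleterious", "tolerated", "unknown"][rng.integers(3)]
            counts[imp.classify_impact(ann(f"k{i}", term, tier, sift)).value] += 1
        assert sum(counts.values()) == n


def _bulk(prefix, gene, spec_counts):
    """Annotations realizing given per-category counts for one gene."""
    cat_term = {
        "splice": ("splice_site_donor", "HIGH", "unknown"),
        "stop_gained": ("stop_gained", "HIGH", "unknown"),
        "stop_lost": ("stop_lost", "HIGH", "unknown"),
        "start_lost": ("start_lost", "HIGH", "unknown"),
        "frame_shift": ("frame_shift", "HIGH", "unknown"),
        "Mdel": ("non_synonymous", "MODERATE", "deleterious"),
        "Mtol": ("non_synonymous", "MODERATE", "tolerated"),
        "synonymous": ("synonymous", "LOW", "unknown"),
        "start_gained": ("start_gained", "LOW", "unknown"),
    }
    out = []
    i = 0
    for cat, n in spec_counts.items():
        term, tier, sift = cat_term[cat]
        for _ in range(n):
            out.append(ann(f"{prefix}_{i}", term, tier, sift, gene=gene))
            i += 1
    return out


# the catalogue's printed per-category counts
TASR_COUNTS = dict(
    splice=1, stop_gained=3, stop_lost=1, start_lost=0, frame_shift=5,
    Mdel=34, Mtol=92, synonymous=80, start_gained=1,
)
AR_COUNTS = dict(
    splice=37, stop_gained=16, stop_lost=0, start_lost=4, frame_shift=17,
    Mdel=277, Mtol=615, synonymous=1559, start_gained=24,
)
FIXED_COUNTS = dict(
    splice=4, stop_gained=0, stop_lost=0, start_lost=0, frame_shift=4,
    Mdel=0, Mtol=9, synonymous=9, start_gained=1,
)


class TestImpactSummaryTable:
    @pytest.fixture()
    def table(self):
        anns = (
            _bulk("tasr", "TASR_GENE", TASR_COUNTS)
            + _bulk("ar", "AR_GENE", AR_COUNTS)
            + _bulk("fix", "AR_GENE", FIXED_COUNTS)
        )
        fixed = {a.variant_key for a in anns if a.variant_key.startswith("fix_")}
        gene_groups = {"TASR_GENE": "TASR", "AR_GENE": "AR"}
        return imp.impact_summary_table(anns, gene_groups, fixed)

    def test_group_totals_and_percent_strong(self, table):
        tasr = table[table.group == "TASR"].iloc[0]
        assert tasr.total == 217
        assert tasr.strong == 44
        assert tasr.pct_strong == 20.3

    def test_segregating_and_fixed_rows(self, table):
        seg = table[table.group == "Total segregating"].iloc[0]
        assert seg.total == 2766
        assert seg.strong == 395
        fixed = table[table.group == "Alternative allele fixed"].iloc[0]
        assert fixed.total == 27
        grand = table[table.group == "Total"].iloc[0]
        assert grand.total == 2793

    def test_empty_input_zero_table(self):
        t = imp.impact_summary_table([], {"g": "G"})
        assert (t["total"] == 0).all()

    def test_unassigned_gene_rejected(self):
        with pytest.raises(ValueError, match="not assigned"):
            imp.impact_summary_table([ann("k", "synonymous", "LOW")], {"other": "G"})


class TestFrequencyByImpact:
    def test_percentages_within_cell(self):
        records, classes, groups = [], {}, {}
        spec = [("very_rare", 28, 0.005), ("rare", 6, 0.015), ("common", 10, 0.1)]
        i = 0
        for _, n, pmaf in spec:
            for _ in range(n):
                k = f"v{i}"
                records.append(make_record(k + "_1_A_T", paaf={"P": pmaf}))
                records[-1].variant_key = k
                classes[k] = imp.ImpactClass("H")
                groups[k] = "TASR"
                i += 1
        t = imp.frequency_by_impact_table(records, classes, groups)
        row = t[(t.group == "TASR") & (t.strength == "strong")].iloc[0]
        assert row.total == 44
        assert row.very_rare == 28 and row.very_rare_pct == 63.6

    def test_single_variant_is_hundred_percent(self):
        r = make_record("v_1_A_T", paaf={"P": 0.3})
        t = imp.frequency_by_impact_table(
            [r], {r.variant_key: imp.ImpactClass("L")}, {r.variant_key: "G"}
        )
        assert t.iloc[0].common_pct == 100.0


class TestRareHighTable:
    def test_inclusion_rules(self):
        recs = [
            make_record("chr12_15398873_C_T", paaf={"P": 0.0017}),
            make_record("chr1_2_A_T", paaf={"P": 0.02}),
            make_record("chr1_3_A_T", paaf={"P": 0.001}),
        ]
        classes = {
            "chr12_15398873_C_T": imp.ImpactClass("H"),
            "chr1_2_A_T": imp.ImpactClass("H"),
            "chr1_3_A_T": imp.ImpactClass("Mdel"),
        }
        anns = {
            "chr12_15398873_C_T": [ann("chr12_15398873_C_T", "stop_gained", "HIGH", gene="ACE")],
            "chr1_2_A_T": [ann("chr1_2_A_T", "stop_gained", "HIGH")],
            "chr1_3_A_T": [ann("chr1_3_A_T", "non_synonymous", "MODERATE", "deleterious")],
        }
        t = imp.rare_high_table(recs, classes, anns)
        assert list(t.variant_key) == ["chr12_15398873_C_T"]
        assert t.iloc[0].effect == "STOP_GAINED"
        assert t.iloc[0].pmaf == pytest.approx(0.0017)


class TestProteinDeciles:
    @pytest.mark.parametrize(
        "pos,length,expected",
        [(95, 100, 10), (10, 100, 1), (11, 100, 2), (100, 100, 10), (1, 1000, 1)],
    )
    def test_bin_convention(self, pos, length, expected):
        assert imp.protein_decile_bin(pos, length) == expected

    def test_counts_cover_bins_and_skip_missing(self):
        records, classes, anns = {}, {}, []
        for i in range(20):
            k = f"v{i}"
            rec = make_record(k + "_1_A_T", paaf={"P": 0.1})
            rec.variant_key = k
            records[k] = rec
            classes[k] = imp.ImpactClass("Mdel")
            ppos = i * 50 + 1 if i < 19 else None
            anns.append(
                ann(k, "non_synonymous", "MODERATE", "deleterious",
                    ppos=ppos, plen=1000 if ppos else None)
            )
        table, skipped = imp.protein_decile_distribution(anns, classes, records)
        assert skipped == 1
        assert table.strong_count.sum() == 19
        assert set(table.bin) == set(range(1, 11))

    def test_uniform_positions_fill_bins_evenly(self, rng):
        n = 5000
        records, classes, anns = {}, {}, []
        for i in range(n):
            k = f"v{i}"
            rec = make_record(k + "_1_A_T", paaf={"P": 0.1})
            rec.variant_key = k
            records[k] = rec
            classes[k] = imp.ImpactClass("Mtol")
            plen = 500
            anns.append(
                ann(k, "non_synonymous", "MODERATE", "tolerated",
                    ppos=int(rng.integers(1, plen + 1)), plen=plen)
            )
        table, _ = imp.protein_decile_distribution(anns, classes, records)
        expected = n / 10
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert (np.abs(table.mild_count - expected) < 3 * sigma).all()
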