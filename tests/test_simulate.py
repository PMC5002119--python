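"""The synthetic-data generator: drift model, pooled reads, effects, truth."""

import numpy as np
import pandas as pd
import pytest

from poolvar import simulate as sim
from poolvar.contrast import fisher_exact_two_sided
from poolvar.frequencies import build_frequency_records
from poolvar.io_formats import PoolSpec, read_pooled_vcf


def small_config(**kw):
    defaults = dict(seed=5, n_variants=50, n_genes=10)
    defaults.update(kw)
    return sim.SimulationConfig(**defaults)


class TestBreedFrequencies:
    def test_zero_drift_child_equals_parent(self, rng):
        cfg = small_config(
            breed_tree=sim.DriftNode("root", 0.0, [sim.DriftNode("X", 0.0)])
        )
        f = sim.simulate_breed_frequencies(cfg)
        anc = sim._ancestral_frequencies(cfg, cfg.rng())
        assert np.allclose(f.loc["X"].to_numpy(), anc)

    def test_lost_allele_stays_lost(self, rng):
        p = np.zeros(100)
        child = sim._drift_child(p, 0.3, rng)
        assert np.all(child == 0.0)

    def test_drift_preserves_the_mean(self, rng):
        """Monte-Carlo: E[child] = parent under Balding-Nichols drift."""
        p = np.full(10_000, 0.3)
        child = sim._drift_child(p, 0.1, rng)
        se = np.sqrt(0.1 * 0.3 * 0.7 / 10_000)
        assert abs(child.mean() - 0.3) < 3 * se

    def test_invalid_drift_rejected(self):
        with pytest.raises(ValueError, match="drift"):
            sim.DriftNode("X", 1.0)

    def test_deterministic_under_seed(self):
        cfg = small_config()
        a = sim.simulate_breed_frequencies(cfg)
        b = sim.simulate_breed_frequencies(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestPoolReads:
    def _one_pool_sites(self, p, n=200, seed=3):
        pool = PoolSpec("P", "B", 22)
        cfg = small_config(seed=seed, n_variants=n, multiallelic_fraction=0.0)
        freqs = pd.DataFrame([np.full(n, p)], index=["B"])
        return sim.simulate_pool_reads(freqs, [pool], cfg)

    def test_absent_allele_never_read(self):
        sites = self._one_pool_sites(0.0)
        assert all(s.depths["P"].alt_reads == (0,) for s in sites)

    def test_fixed_allele_no_reference_reads(self):
        sites = self._one_pool_sites(1.0)
        assert all(s.depths["P"].ref_reads == 0 for s in sites)

    def test_depth_capped(self):
        sites = self._one_pool_sites(0.5)
        assert all(s.depths["P"].dp <= 1000 for s in sites)

    def test_compound_binomial_mean_is_half(self):
        """At p=0.5, ploidy 44, the mean read fraction over replicates is 0.5:
        the chromosome and read sampling stages are both unbiased."""
        rng = np.random.default_rng(8)
        pool = PoolSpec("P", "B", 22)
        cfg = small_config(multiallelic_fraction=0.0)
        fracs = []
        for _ in range(2000):
            d = sim._pool_allele_depth([0.5], pool.ploidy, cfg, rng)
            if d.dp:
                fracs.append(d.alt_reads[0] / d.dp)
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.01)

    def test_zero_ploidy_rejected(self, rng):
        with pytest.raises(ValueError, match="ploidy"):
            sim._pool_allele_depth([0.5], 0, small_config(), rng)


class TestEffects:
    def test_single_category_propagates(self):
        cfg = small_config(effect_proportions={"synonymous": 1.0})
        anns = sim.simulate_effects(cfg, [f"k{i}" for i in range(30)])
        assert all(a.effect_term == "synonymous" and a.impact_tier == "LOW" for a in anns)

    def test_frame_shift_always_high(self):
        cfg = small_config(effect_proportions={"frame_shift": 1.0})
        anns = sim.simulate_effects(cfg, [f"k{i}" for i in range(30)])
        assert all(a.impact_tier == "HIGH" for a in anns)

    def test_default_mix_reproduces_catalogue_proportions(self):
        """Synonymous draws at the catalogue size land within 3 sigma of the
        published count (16,390-ish out of 27,660 at ten times the mix)."""
        n = 27_660
        cfg = small_config(seed=11)
        anns = sim.simulate_effects(cfg, [f"k{i}" for i in range(n)])
        p_syn = sim.DEFAULT_EFFECT_COUNTS["synonymous"] / sum(
            sim.DEFAULT_EFFECT_COUNTS.values()
        )
        n_syn = sum(a.effect_term == "synonymous" for a in anns)
        sigma = np.sqrt(n * p_syn * (1 - p_syn))
        assert abs(n_syn - n * p_syn) < 3 * sigma

    def test_protein_position_within_length(self):
        cfg = small_config(effect_proportions={"mdel": 1.0})
        anns = sim.simulate_effects(cfg, [f"k{i}" for i in range(100)])
        assert all(1 <= a.protein_pos <= a.protein_len for a in anns)


class TestF2Pools:
    def test_no_shift_keeps_pools_identical_in_law(self, rng):
        cfg = small_config()
        base = np.array([0.2, 0.5, 0.8])
        dF, dL, truth = sim.simulate_f2_pools(base, np.zeros(3, bool), cfg, rng)
        assert truth.sum() == 0
        assert len(dF) == len(dL) == 3

    def test_empty_causal_set_empty_truth(self, rng):
        cfg = small_config()
        _, _, truth = sim.simulate_f2_pools(np.array([0.5]), np.array([False]), cfg, rng)
        assert not truth.any()

    def test_planted_divergence_is_detectable(self):
        """At frequencies 0.1 vs 0.9 with 38 chromosomes per pool and depth
        1000, the Fisher p (chromosome counts) beats the catalogue's
        multiple-testing threshold in at least 95% of replicates."""
        rng = np.random.default_rng(12)
        cfg = small_config(f2_delta=0.8, multiallelic_fraction=0.0)
        base = np.full(200, 0.5)
        causal = np.ones(200, bool)
        dF, dL, _ = sim.simulate_f2_pools(base, causal, cfg, rng)
        hits = 0
        for f, l in zip(dF, dL):
            aF = round(f.alt_reads[0] / f.dp * 38)
            aL = round(l.alt_reads[0] / l.dp * 38)
            p = fisher_exact_two_sided(((aF, aL), (38 - aF, 38 - aL)))
            hits += p < 0.00003
        assert hits / 200 >= 0.95


class TestGenotypes:
    def test_fixed_frequencies_give_constant_dosages(self, rng):
        freqs = pd.DataFrame([[0.0, 1.0]], index=["B"])
        gm = sim.simulate_genotypes(freqs, "B", 20, rng)
        assert (gm.genotypes[:, 0] == 0).all()
        assert (gm.genotypes[:, 1] == 2).all()

    def test_heterozygosity_matches_hardy_weinberg(self, rng):
        freqs = pd.DataFrame([[0.5]], index=["B"])
        gm = sim.simulate_genotypes(freqs, "B", 10_000, rng)
        het = (gm.genotypes[:, 0] == 1).mean()
        assert het == pytest.approx(0.5, abs=0.015)

    def test_unknown_breed_rejected(self, rng):
        with pytest.raises(ValueError, match="absent"):
            sim.simulate_genotypes(pd.DataFrame([[0.5]], index=["B"]), "X", 5, rng)


class TestDataset:
    def test_emitted_vcf_is_byte_identical_under_seed(self, tmp_path):
        cfg = small_config(seed=77)
        p1 = sim.emit_dataset(cfg, tmp_path / "a")
        p2 = sim.emit_dataset(cfg, tmp_path / "b")
        for key in p1:
            with open(p1[key], "rb") as f1, open(p2[key], "rb") as f2:
                assert f1.read() == f2.read(), key

    def test_frequency_recovery(self, tmp_path):
        """Global pAAF tracks the true chromosome-weighted frequency with
        r^2 >= 0.95 across 2,000 variants at depth >= 500."""
        cfg = sim.SimulationConfig(seed=9, n_variants=2000, n_genes=60)
        paths = sim.emit_dataset(cfg, tmp_path / "d")
        from poolvar.io_formats import read_pool_manifest

        manifest = read_pool_manifest(paths["manifest"])
        sites = read_pooled_vcf(paths["vcf"], manifest)
        breed_manifest = [p for p in manifest if not p.breed_label.startswith("F2")]
        keep = {p.pool_id for p in breed_manifest}
        for s in sites:  # estimate over the breed pools only
            s.depths = {k: v for k, v in s.depths.items() if k in keep}
        records = build_frequency_records(sites, breed_manifest)
        truth = pd.read_csv(
            paths["true_frequencies"], sep="\t", index_col="variant_key"
        )
        ploidy_by_breed = {}
        for p in breed_manifest:
            ploidy_by_breed[p.breed_label] = ploidy_by_breed.get(p.breed_label, 0) + p.ploidy
        w = pd.Series(ploidy_by_breed)
        w = w / w.sum()
        true_global = (truth[w.index] * w).sum(axis=1)
        est, tru = [], []
        for r in records:
            if r.variant_key in true_global.index:
                est.append(r.global_aaf)
                tru.append(true_global[r.variant_key])
        r2 = np.corrcoef(est, tru)[0, 1] ** 2
        assert len(est) >= 1900
        assert r2 >= 0.95
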