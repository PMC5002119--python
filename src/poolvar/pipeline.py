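"""End-to-end orchestration: simulate (optionally), then analyze and report.

``run_all`` drives the stage sequence io -> frequencies -> impact -> popgen
-> tree -> contrast -> validation, writing one TSV per result table, a Newick
tree, and a machine-readable ``summary.json`` with the headline numbers.
Every output carries the configuration hash in a leading comment line, the
run is deterministic under a fixed seed, and each stage logs its input and
output row counts so catalogue totals are auditable from the log alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from poolvar import (
    contrast as contrast_mod,
    frequencies as freq_mod,
    impact as impact_mod,
    io_formats,
    popgen,
    simulate as sim_mod,
    tree as tree_mod,
    validation as valid_mod,
)

__all__ = ["PipelineError", "RunConfig", "run_all"]

log = logging.getLogger("poolvar")


class PipelineError(RuntimeError):
    """Raised when a stage fails; names the stage and the cause."""


@dataclass
class RunConfig:
    """All inputs, thresholds and mode flags of one pipeline run.

    With ``simulate=True`` the inputs are generated first (into ``outdir``)
    from ``sim`` and ``seed``; otherwise the four input paths must point to
    existing files.  Threshold defaults are the catalogue's operating point:
    total depth >= 1000, per-pool down-sampling cap 1000, presence at >= 2
    alt reads, breed-specific pAAF >= 0.1 (rule A) / >= 0.5 everywhere but
    one absent breed (rule B), alpha 0.05.
    """

    outdir: str = "results"
    seed: int = 0
    simulate: bool = True
    sim: sim_mod.SimulationConfig | None = None
    vcf: str | None = None
    manifest: str | None = None
    annotations: str | None = None
    gene_models: str | None = None
    gene_groups: str | None = None  # optional TSV: gene_id, group
    min_total_dp: int = 1000
    depth_cap: int = 1000
    dense_window_bp: int = 100
    dense_max_variants: int = 5
    presence_min_alt: int = 2
    breed_specific_paaf: float = 0.1
    absent_in_one_paaf: float = 0.5
    alpha: float = 0.05
    bootstrap_B: int = 1000
    fisher_mode: str = "chromosomes"
    silent_mode: str = "fractional"
    distance_transform: str = "one_minus_r"
    weights: str = "ploidy"
    f2_pools: tuple[str, str] = ("F2_F", "F2_L")
    validation_fraction: float = 0.78  # ~237 of 304 animals genotyped

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        payload = _as_jsonable(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    return obj


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _write(df: pd.DataFrame, path: str, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict (also written as
    ``summary.json`` in ``config.outdir``)."""
    os.makedirs(config.outdir, exist_ok=True)
    cfg_hash = config.config_hash()
    summary: dict = {"config_hash": cfg_hash, "seed": config.seed}
    rng = np.random.default_rng(config.seed)

    # ---- inputs -----------------------------------------------------------
    truth_freqs = None
    if config.simulate:
        sim = config.sim or sim_mod.SimulationConfig(seed=config.seed)
        paths = _simulate_inputs(sim, os.path.join(config.outdir, "inputs"))
        truth_freqs = pd.read_csv(
            paths["true_frequencies"], sep="\t", index_col="variant_key"
        )
    else:
        paths = {
            "vcf": config.vcf,
            "manifest": config.manifest,
            "annotations": config.annotations,
            "gene_models": config.gene_models,
        }
    sites, manifest, models = _load_inputs(paths)
    log.info("io: %d sites, %d pools", len(sites), len(manifest))
    summary["n_sites"] = len(sites)
    summary["n_pools"] = len(manifest)

    # ---- frequencies ------------------------------------------------------
    records, freq_summary = _frequencies_stage(sites, manifest, config, rng)
    _write(
        freq_mod.frequency_table(records, manifest),
        os.path.join(config.outdir, "frequency_table.tsv"),
        cfg_hash,
    )
    summary.update(freq_summary)
    segregating = [r for r in records if not r.fixed_alt]

    # ---- impact -----------------------------------------------------------
    annotations, classes, groups_by_key, impact_tables = _impact_stage(
        segregating, records, paths.get("annotations"), config
    )
    for name, df in impact_tables.items():
        _write(df, os.path.join(config.outdir, f"{name}.tsv"), cfg_hash)
    summary["n_classified"] = len(classes)
    summary["n_strong"] = sum(1 for c in classes.values() if c.strong)

    # ---- popgen -----------------------------------------------------------
    popgen_tables, popgen_summary = _popgen_stage(
        segregating, classes, annotations, manifest, models, config
    )
    for name, df in popgen_tables.items():
        _write(df, os.path.join(config.outdir, f"{name}.tsv"), cfg_hash)
    summary.update(popgen_summary)

    # ---- tree -------------------------------------------------------------
    tree_summary = _tree_stage(segregating, manifest, config, cfg_hash)
    summary.update(tree_summary)

    # ---- contrast ---------------------------------------------------------
    contrast_summary = _contrast_stage(
        segregating, annotations, manifest, config, cfg_hash
    )
    summary.update(contrast_summary)

    # ---- validation -------------------------------------------------------
    if truth_freqs is not None:
        validation_summary = _validation_stage(
            segregating, truth_freqs, manifest, config, cfg_hash, rng
        )
        summary.update(validation_summary)

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary


@_stage("simulate")
def _simulate_inputs(sim: sim_mod.SimulationConfig, outdir: str) -> dict:
    return sim_mod.emit_dataset(sim, outdir)


@_stage("io")
def _load_inputs(paths: Mapping[str, str | None]):
    manifest = io_formats.read_pool_manifest(paths["manifest"])
    sites = io_formats.read_pooled_vcf(paths["vcf"], manifest)
    models = (
        io_formats.read_gene_models(paths["gene_models"])
        if paths.get("gene_models")
        else []
    )
    return sites, manifest, models


@_stage("frequencies")
def _frequencies_stage(sites, manifest, config: RunConfig, rng):
    kept = freq_mod.site_depth_filter(sites, config.min_total_dp)
    kept = [freq_mod.downsample_site(s, config.depth_cap, rng) for s in kept]
    retained, flagged = freq_mod.filter_dense_regions(
        kept, config.dense_window_bp, config.dense_max_variants
    )
    records = freq_mod.build_frequency_records(retained, manifest, config.weights)
    n_fixed = sum(1 for r in records if r.fixed_alt)
    log.info(
        "frequencies: %d sites pass DP, %d dense-flagged, %d records (%d fixed-alt)",
        len(kept), len(flagged), len(records), n_fixed,
    )
    return records, {
        "n_pass_depth": len(kept),
        "n_dense_flagged": len(flagged),
        "n_records": len(records),
        "n_fixed_alt": n_fixed,
        "n_segregating": len(records) - n_fixed,
    }


@_stage("impact")
def _impact_stage(segregating, records, annotations_path, config: RunConfig):
    if annotations_path is None or not os.path.exists(annotations_path):
        raise FileNotFoundError(
            f"annotation table not found: {annotations_path!r}"
        )
    annotations = io_formats.read_effect_annotations(annotations_path)
    classes: dict[str, impact_mod.ImpactClass] = {}
    gene_by_key: dict[str, str] = {}
    for key, anns in annotations.items():
        classes[key] = impact_mod.classify_impact(anns[0])
        gene_by_key[key] = anns[0].gene_id
    if config.gene_groups:
        gg = pd.read_csv(config.gene_groups, sep="\t")
        gene_groups = dict(zip(gg["gene_id"], gg["group"]))
    else:
        gene_groups = {g: "ALL" for g in set(gene_by_key.values())}
    fixed_keys = {r.variant_key for r in records if r.fixed_alt}
    # summaries cover the curated catalogue only (post depth/dense filters)
    record_keys = {r.variant_key for r in records}
    flat = [
        a
        for anns in annotations.values()
        for a in anns
        if a.variant_key in record_keys
    ]
    groups_by_key = {k: gene_groups.get(g) for k, g in gene_by_key.items()}
    tables = {
        "impact_summary": impact_mod.impact_summary_table(
            flat, gene_groups, fixed_keys
        ),
        "freq_by_impact": impact_mod.frequency_by_impact_table(
            segregating, classes, groups_by_key
        ),
        "rare_high": impact_mod.rare_high_table(segregating, classes, annotations),
    }
    decile, skipped = impact_mod.protein_decile_distribution(
        flat, classes, segregating
    )
    log.info("impact: %d classified, %d without protein coordinates", len(classes), skipped)
    tables["decile_distribution"] = decile
    return annotations, classes, groups_by_key, tables


@_stage("popgen")
def _popgen_stage(segregating, classes, annotations, manifest, models, config: RunConfig):
    breeds = [
        b
        for b in popgen.breed_pools(manifest)
        if b not in config.f2_pools
    ]
    summaries = popgen.per_breed_counts(
        segregating, classes, manifest, breeds, config.presence_min_alt
    )
    specific = popgen.breed_specific_variants(
        segregating,
        manifest,
        breeds,
        config.presence_min_alt,
        config.breed_specific_paaf,
        config.absent_in_one_paaf,
    )
    tables = {
        "breed_summary": popgen.breed_summary_table(summaries),
        "breed_specific": pd.DataFrame(
            specific, columns=["variant_key", "breed", "rule", "breed_paaf"]
        ),
    }
    out = {
        "n_breed_specific": len(specific),
        "min_detectable_maf": popgen.min_detectable_maf(
            sum(p.n_individuals for p in manifest)
        ),
    }
    if models and any(m.cds_sequence for m in models):
        _, L_silent = popgen.count_silent_sites(models, config.silent_mode)
        syn_keys = {
            k
            for k, anns in annotations.items()
            if any(a.effect_term == "synonymous" for a in anns)
        }
        by_breed = popgen.breed_pools(manifest)
        rows = []
        for b in breeds:
            pools = by_breed[b]
            S = sum(
                1
                for r in segregating
                if r.variant_key in syn_keys
                and popgen.breed_presence(r, pools, config.presence_min_alt)
            )
            n_chrom = sum(p.ploidy for p in pools)
            res = popgen.watterson_theta(S, n_chrom, L_silent, b)
            rows.append(dataclasses.asdict(res))
        tables["watterson"] = pd.DataFrame(rows)
        out["L_silent"] = L_silent
    log.info("popgen: %d breeds, %d breed-specific hits", len(breeds), len(specific))
    return tables, out


@_stage("tree")
def _tree_stage(segregating, manifest, config: RunConfig, cfg_hash: str):
    breeds = [
        b for b in popgen.breed_pools(manifest) if b not in config.f2_pools
    ]
    matrix = tree_mod.select_tree_variants(segregating, manifest, breeds)
    dendro = tree_mod.bootstrap_support(
        matrix,
        B=config.bootstrap_B,
        rng=np.random.default_rng(config.seed + 1),
        transform=config.distance_transform,
    )
    dist = tree_mod.correlation_distance_matrix(matrix, config.distance_transform)
    _write(
        dist.reset_index(names="breed"),
        os.path.join(config.outdir, "distance_matrix.tsv"),
        cfg_hash,
    )
    io_formats.write_newick(dendro, os.path.join(config.outdir, "tree.nwk"))
    log.info("tree: %d variants, %d leaves", matrix.shape[1], len(dendro.leaves))
    return {
        "n_tree_variants": int(matrix.shape[1]),
        "newick": tree_mod.to_newick(dendro),
        "min_support": min(dendro.supports.values()) if dendro.supports else None,
    }


@_stage("contrast")
def _contrast_stage(segregating, annotations, manifest, config: RunConfig, cfg_hash):
    poolF, poolL = config.f2_pools
    pool_ids = {p.pool_id for p in manifest}
    if poolF not in pool_ids or poolL not in pool_ids:
        log.info("contrast: pools %s/%s absent, stage skipped", poolF, poolL)
        return {"n_contrast_tests": 0}
    results = contrast_mod.run_contrast(
        segregating, poolF, poolL, manifest, config.fisher_mode, config.alpha
    )
    rows = [
        {
            "variant_key": r.variant_key,
            "alt_F": r.table[0][0],
            "alt_L": r.table[0][1],
            "ref_F": r.table[1][0],
            "ref_L": r.table[1][1],
            "p_value": r.p_value,
            "nominal": r.nominal,
            "bonferroni_sig": r.bonferroni_sig,
        }
        for r in results
    ]
    _write(
        pd.DataFrame(rows),
        os.path.join(config.outdir, "contrast_results.tsv"),
        cfg_hash,
    )
    _write(
        contrast_mod.contrast_report(results, annotations, config.fisher_mode),
        os.path.join(config.outdir, "contrast_genes.tsv"),
        cfg_hash,
    )
    m = len(results)
    log.info("contrast: %d tests", m)
    return {
        "n_contrast_tests": m,
        "bonferroni_threshold": contrast_mod.bonferroni_threshold(config.alpha, m)
        if m
        else None,
        "n_nominal": sum(r.nominal for r in results),
        "n_bonferroni": sum(r.bonferroni_sig for r in results),
    }


@_stage("validation")
def _validation_stage(segregating, truth_freqs, manifest, config: RunConfig, cfg_hash, rng):
    breeds = [
        b for b in popgen.breed_pools(manifest) if b not in config.f2_pools
    ]
    by_breed = popgen.breed_pools(manifest)
    keys = [r.variant_key for r in segregating if r.variant_key in truth_freqs.index]
    truth = truth_freqs.loc[keys]
    genotyped: dict[str, sim_mod.GenotypeMatrix] = {}
    for b in breeds:
        n_total = sum(p.n_individuals for p in by_breed[b])
        n_geno = max(1, int(round(config.validation_fraction * n_total)))
        genotyped[b] = sim_mod.simulate_genotypes(
            truth[b].to_frame().T.rename(index={b: b}), b, n_geno, rng, keys
        )
    recs = {r.variant_key: r for r in segregating}
    rows = []
    for i, k in enumerate(keys):
        dosages = np.concatenate([genotyped[b].genotypes[:, i] for b in breeds])
        obs = valid_mod.observed_maf(list(dosages))
        per_breed = {
            b: list(genotyped[b].genotypes[:, i]) for b in breeds
        }
        pvals, min_p, in_hwe = valid_mod.hwe_by_breed(per_breed, config.alpha)
        rows.append(
            {
                "variant_key": k,
                "pmaf": recs[k].pmaf,
                "observed_maf": obs,
                "hwe_min_p": min_p,
                "hwe_ok": in_hwe,
                "n_called": len(dosages),
            }
        )
    df = pd.DataFrame(rows)
    _write(df, os.path.join(config.outdir, "validation.tsv"), cfg_hash)
    poly = df[(df["pmaf"] > 0) | (df["observed_maf"] > 0)]
    slope, intercept, r2, n = valid_mod.predicted_vs_observed(
        poly["pmaf"], poly["observed_maf"]
    )
    log.info("validation: %d variants, r^2=%.3f", n, r2)
    return {
        "validation_slope": slope,
        "validation_r2": r2,
        "validation_n": n,
        "hwe_fraction_ok": float(df["hwe_ok"].mean()),
    }
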