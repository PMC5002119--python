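"""Synthetic pooled-sequencing datasets with known truth.

The generator emulates the design of the study the pipeline targets: 304
diploid animals in 16 DNA pools — ten breeds (some split over two pools,
12-24 animals per pool) plus two phenotypically divergent F2 pools of 19
animals each — sequenced to a mean depth around 72x per haploid pool member
and down-sampled to at most 1,000 reads per position.

True breed allele frequencies evolve along a rooted breed tree under
Balding-Nichols drift: a child frequency is Beta-distributed with mean equal
to the parent frequency and variance c*p*(1-p) for the branch's drift
parameter c.  Pooled read counts then arise in two stages — allele copies
among the pool's chromosomes (binomial in the pool ploidy), then reads among
the copies (binomial in the site depth) — which captures the finite-pool
variance a single binomial on reads would miss.  Site depth is negative
binomial with a hard down-sampling cap.  The ancestral frequency law mixes a
Uniform(0, 0.5) component with a rare-variant point mass so detection down to
a single allele copy in all sampled chromosomes is exercised.

Variant effects are drawn from the segregating-category mix of the real
catalogue (proportions configurable), and individual genotypes for validation
follow Hardy-Weinberg proportions at the breed frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from poolvar.io_formats import (
    AlleleDepth,
    EffectAnnotation,
    GeneModel,
    PoolSpec,
    VariantSite,
)

__all__ = [
    "DriftNode",
    "GenotypeMatrix",
    "SimulationConfig",
    "default_breed_tree",
    "default_manifest",
    "emit_dataset",
    "simulate_breed_frequencies",
    "simulate_effects",
    "simulate_f2_pools",
    "simulate_gene_models",
    "simulate_genotypes",
    "simulate_pool_reads",
    "two_clade_tree",
]

_BASES = "ACGT"

#: Default effect-category mix: the segregating-variant counts of the real
#: catalogue (splice 38, stop gained 19, stop lost 1, start lost 4, frame
#: shift 22, Mdel 311, Mtol 707, synonymous 1639, start gained 25; total 2766).
DEFAULT_EFFECT_COUNTS = {
    "splice": 38,
    "stop_gained": 19,
    "stop_lost": 1,
    "start_lost": 4,
    "frame_shift": 22,
    "mdel": 311,
    "mtol": 707,
    "synonymous": 1639,
    "start_gained": 25,
}


@dataclass
class DriftNode:
    """Node of the breed tree; ``c`` is the drift along the branch above it."""

    name: str
    c: float = 0.0
    children: list["DriftNode"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"drift parameter must lie in [0, 1): {self.c}")

    @property
    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        return [leaf for ch in self.children for leaf in ch.leaves]


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages (0/1/2, -1 = missing) for individuals x variants."""

    individuals: list[str]
    variant_keys: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.individuals), len(self.variant_keys)):
            raise ValueError("genotype matrix shape mismatch")
        valid = np.isin(self.genotypes, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.genotypes, index=self.individuals, columns=self.variant_keys
        ).astype("Int64")
        return df.mask(df == -1)


def default_manifest() -> list[PoolSpec]:
    """The 16-pool design: ten breeds (304 animals with the F2s) in 14 pools
    of 12-24 animals plus the two divergent F2 pools of 19 each."""
    return [
        PoolSpec("Duroc_1", "Duroc", 23),
        PoolSpec("Duroc_2", "Duroc", 22),
        PoolSpec("Pietrain_1", "Pietrain", 21),
        PoolSpec("Pietrain_2", "Pietrain", 20),
        PoolSpec("LargeWhite_1", "LargeWhite", 20),
        PoolSpec("LargeWhite_2", "LargeWhite", 19),
        PoolSpec("Landrace_1", "Landrace", 20),
        PoolSpec("Landrace_2", "Landrace", 20),
        PoolSpec("Bazna", "Bazna", 15),
        PoolSpec("Mangalitza", "Mangalitza", 12),
        PoolSpec("Iberian", "Iberian", 13),
        PoolSpec("MajorcanBlack", "MajorcanBlack", 17),
        PoolSpec("WildBoar", "WildBoar", 22),
        PoolSpec("Asian", "Asian", 22),
        PoolSpec("F2_F", "F2_F", 19),
        PoolSpec("F2_L", "F2_L", 19),
    ]


def default_breed_tree() -> DriftNode:
    """A breed tree shaped like the published dendrogram: the Asian pool on
    its own branch; within the Western cluster the Duroc apart, the
    commercial breeds together, and the ancient breeds with the wild boar."""
    return DriftNode(
        "root",
        0.0,
        [
            DriftNode("Asian", 0.18),
            DriftNode(
                "Western",
                0.03,
                [
                    DriftNode("Duroc", 0.10),
                    DriftNode(
                        "WesternCore",
                        0.02,
                        [
                            DriftNode(
                                "Commercial",
                                0.02,
                                [
                                    DriftNode("LargeWhite", 0.04),
                                    DriftNode("Landrace", 0.04),
                                    DriftNode("Pietrain", 0.04),
                                ],
                            ),
                            DriftNode(
                                "Ancient",
                                0.02,
                                [
                                    DriftNode("WildBoar", 0.05),
                                    DriftNode("Iberian", 0.06),
                                    DriftNode("MajorcanBlack", 0.06),
                                    DriftNode("Mangalitza", 0.08),
                                    DriftNode("Bazna", 0.07),
                                ],
                            ),
                        ],
                    ),
                ],
            ),
        ],
    )


def two_clade_tree(
    clade_a: Sequence[str],
    clade_b: Sequence[str],
    c_between: float = 0.2,
    c_within: float = 0.01,
) -> DriftNode:
    """Two well-separated clades — the standard topology-recovery benchmark."""
    return DriftNode(
        "root",
        0.0,
        [
            DriftNode("cladeA", c_between, [DriftNode(n, c_within) for n in clade_a]),
            DriftNode("cladeB", c_between, [DriftNode(n, c_within) for n in clade_b]),
        ],
    )


@dataclass
class SimulationConfig:
    seed: int = 0
    breed_tree: DriftNode = field(default_factory=default_breed_tree)
    pools: list[PoolSpec] = field(default_factory=default_manifest)
    n_variants: int = 2000
    n_genes: int = 200
    uniform_low: float = 0.0
    uniform_high: float = 0.5
    rare_mass: float = 0.3
    rare_freq: float = 0.003
    depth_mean_per_copy: float = 72.0
    depth_dispersion: float = 8.0
    depth_cap: int = 1000
    effect_proportions: dict[str, float] = field(
        default_factory=lambda: _normalize(DEFAULT_EFFECT_COUNTS)
    )
    multiallelic_fraction: float = 0.0015
    f2_causal_fraction: float = 0.005
    f2_delta: float = 0.8
    f2_pool_ids: tuple[str, str] = ("F2_F", "F2_L")

    def __post_init__(self) -> None:
        total = sum(self.effect_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("effect proportions must sum to 1")
        if not 0 < self.f2_delta <= 1:
            raise ValueError("f2_delta must lie in (0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _normalize(counts: Mapping[str, float]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# breed frequencies


def _ancestral_frequencies(config: SimulationConfig, rng: np.random.Generator):
    p = rng.uniform(config.uniform_low, config.uniform_high, size=config.n_variants)
    rare = rng.random(config.n_variants) < config.rare_mass
    p[rare] = config.rare_freq
    return p


def _drift_child(p: np.ndarray, c: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols: Beta with mean p and variance c*p*(1-p)."""
    if c == 0.0:
        return p.copy()
    out = p.copy()
    inner = (p > 0) & (p < 1)
    scale = (1.0 - c) / c
    out[inner] = rng.beta(p[inner] * scale, (1.0 - p[inner]) * scale)
    return out


def simulate_breed_frequencies(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """True alt-allele frequency per (breed, variant), drifted along the tree.

    Rows are the leaf names of ``config.breed_tree`` in pre-order; columns
    are variant indices.  Deterministic under a fixed seed.
    """
    rng = config.rng() if rng is None else rng
    ancestral = _ancestral_frequencies(config, rng)
    rows: dict[str, np.ndarray] = {}

    def descend(node: DriftNode, p: np.ndarray) -> None:
        p_here = _drift_child(p, node.c, rng)
        if not node.children:
            rows[node.name] = p_here
        for ch in node.children:
            descend(ch, p_here)

    descend(config.breed_tree, ancestral)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# gene models and variant placement


def simulate_gene_models(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Random gene models: CDS of 100-1000 codons from sense codons only,
    split into 1-8 exon intervals, spread over 18 autosomes."""
    rng = config.rng() if rng is None else rng
    sense = [
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in {"TAA", "TAG", "TGA"}
    ]
    models = []
    offsets = {f"chr{i}": 1000 for i in range(1, 19)}
    for gi in range(config.n_genes):
        chrom = f"chr{(gi % 18) + 1}"
        n_codons = int(rng.integers(100, 1001))
        seq = "".join(rng.choice(sense, size=n_codons))
        cds_len = 3 * n_codons
        n_exons = int(rng.integers(1, 9))
        cuts = np.sort(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        pieces = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        start = offsets[chrom]
        intervals = []
        for piece in pieces:
            intervals.append((start, start + int(piece) - 1))
            start += int(piece) + int(rng.integers(100, 2000))  # intron
        offsets[chrom] = start + int(rng.integers(5000, 20000))
        models.append(GeneModel(f"gene{gi:04d}", chrom, "+", intervals, seq))
    return models


def _cds_to_genomic(model: GeneModel, offset: int) -> tuple[str, int]:
    """Genomic coordinate of 0-based CDS offset."""
    for a, b in model.cds_intervals:
        span = b - a + 1
        if offset < span:
            return model.chrom, a + offset
        offset -= span
    raise IndexError("CDS offset beyond gene length")


def place_variants(
    config: SimulationConfig,
    models: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, str, str, str]]:
    """Assign each variant a unique genomic position inside a gene's CDS.

    Returns ``(chrom, pos, ref, alt, gene_id)`` per variant; genes are chosen
    with probability proportional to CDS length, the position uniformly
    within the CDS, the ref base from the CDS sequence.
    """
    rng = config.rng() if rng is None else rng
    lengths = np.array([m.cds_length for m in models], dtype=float)
    weights = lengths / lengths.sum()
    used: set[tuple[str, int]] = set()
    placed = []
    while len(placed) < config.n_variants:
        m = models[int(rng.choice(len(models), p=weights))]
        off = int(rng.integers(0, m.cds_length))
        chrom, pos = _cds_to_genomic(m, off)
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = m.cds_sequence[off]
        alt = rng.choice([b for b in _BASES if b != ref])
        placed.append((chrom, pos, ref, str(alt), m.gene_id))
    placed.sort(key=lambda t: (int(t[0][3:]), t[1]))
    return placed


# ---------------------------------------------------------------------------
# pooled reads


def _pool_depth(config: SimulationConfig, ploidy: int, rng) -> int:
    mean = config.depth_mean_per_copy * ploidy
    k = config.depth_dispersion
    return int(rng.negative_binomial(k, k / (k + mean)))


def _pool_allele_depth(
    alt_freqs: Sequence[float],
    ploidy: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> AlleleDepth:
    """Two-stage sampling for one pool at one site, with the depth cap."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    probs = np.array([max(0.0, 1.0 - sum(alt_freqs)), *alt_freqs])
    copies = rng.multinomial(ploidy, probs / probs.sum())
    depth = _pool_depth(config, ploidy, rng)
    if depth == 0:
        return AlleleDepth(0, (0,) * len(alt_freqs))
    reads = rng.multinomial(depth, copies / ploidy)
    if depth > config.depth_cap:
        reads = rng.multivariate_hypergeometric(reads, config.depth_cap)
    return AlleleDepth(int(reads[0]), tuple(int(x) for x in reads[1:]))


def simulate_pool_reads(
    freqs: pd.DataFrame,
    pools: Sequence[PoolSpec],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    placements: Sequence[tuple[str, int, str, str, str]] | None = None,
) -> list[VariantSite]:
    """Pooled read counts for every variant and pool.

    ``freqs`` holds the true alt frequency per breed (rows) and variant
    (columns); each pool draws from its breed's frequency.  A small fraction
    of variants (``multiallelic_fraction``) receives a second alternative
    allele at low frequency shared across breeds.  Positions come from
    ``placements`` when given, otherwise variants are laid on chr1 at 150 bp
    spacing with random alleles.
    """
    rng = config.rng() if rng is None else rng
    n = freqs.shape[1]
    if placements is None:
        refs = [str(x) for x in rng.choice(list(_BASES), size=n)]
        placements = [
            ("chr1", 1000 + 150 * j, refs[j], str(rng.choice([b for b in _BASES if b != refs[j]])), "")
            for j in range(n)
        ]
    multi = rng.random(n) < config.multiallelic_fraction
    second_freq = rng.uniform(0.0, 0.05, size=n)
    sites = []
    for j in range(n):
        chrom, pos, ref, alt, _gene = placements[j]
        alts: tuple[str, ...] = (alt,)
        if multi[j]:
            extra = [b for b in _BASES if b not in (ref, alt)]
            alts = (alt, str(rng.choice(extra)))
        depths = {}
        for pool in pools:
            p1 = float(freqs.loc[pool.breed_label].iloc[j])
            alt_freqs = [p1]
            if multi[j]:
                alt_freqs.append(min(second_freq[j], 1.0 - p1))
            depths[pool.pool_id] = _pool_allele_depth(
                alt_freqs, pool.ploidy, config, rng
            )
        sites.append(VariantSite(chrom, pos, ref, alts, depths))
    return sites


# ---------------------------------------------------------------------------
# effects


def simulate_effects(
    config: SimulationConfig,
    variant_keys: Sequence[str],
    gene_by_key: Mapping[str, str] | None = None,
    gene_models: Sequence[GeneModel] | None = None,
    rng: np.random.Generator | None = None,
) -> list[EffectAnnotation]:
    """One annotation per variant key, drawn from the effect-category mix.

    Protein position is uniform over [1, protein_len]; protein length comes
    from the variant's gene model when available, otherwise 100-1000 codons.
    """
    rng = config.rng() if rng is None else rng
    cats = list(config.effect_proportions)
    probs = np.array([config.effect_proportions[c] for c in cats])
    lens_by_gene = (
        {m.gene_id: len(m.cds_sequence) // 3 for m in gene_models if m.cds_sequence}
        if gene_models
        else {}
    )
    draws = rng.choice(len(cats), size=len(variant_keys), p=probs)
    annotations = []
    for key, ci in zip(variant_keys, draws):
        cat = cats[ci]
        gene = gene_by_key.get(key, "geneX") if gene_by_key else "geneX"
        plen = lens_by_gene.get(gene) or int(rng.integers(100, 1001))
        ppos = int(rng.integers(1, plen + 1))
        if cat == "splice":
            term = str(rng.choice(["splice_site_donor", "splice_site_acceptor"]))
            tier, sift = "HIGH", "unknown"
            ppos_out = None  # splice variants carry no protein coordinate
        elif cat in {"stop_gained", "stop_lost", "start_lost", "frame_shift"}:
            term, tier, sift = cat, "HIGH", "unknown"
            ppos_out = ppos
        elif cat == "mdel":
            term, tier, sift = "non_synonymous", "MODERATE", "deleterious"
            ppos_out = ppos
        elif cat == "mtol":
            term, tier = "non_synonymous", "MODERATE"
            sift = str(rng.choice(["tolerated", "unknown"], p=[0.8, 0.2]))
            ppos_out = ppos
        elif cat == "synonymous":
            term, tier, sift = "synonymous", "LOW", "unknown"
            ppos_out = ppos
        elif cat == "start_gained":
            term, tier, sift = "start_gained", "LOW", "unknown"
            ppos_out = None
        else:  # pragma: no cover
            raise ValueError(f"unknown effect category: {cat}")
        annotations.append(
            EffectAnnotation(
                variant_key=key,
                gene_id=gene,
                effect_term=term,
                impact_tier=tier,
                sift_class=sift,
                protein_pos=ppos_out,
                protein_len=plen if ppos_out is not None else None,
            )
        )
    return annotations


# ---------------------------------------------------------------------------
# divergent F2 pools


def simulate_f2_pools(
    freqs_base: np.ndarray,
    causal: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    pools: Sequence[PoolSpec] | None = None,
) -> tuple[list[AlleleDepth], list[AlleleDepth], np.ndarray]:
    """Read counts for the two divergent pools, plus the causal truth mask.

    Non-causal variants share the base frequency in both pools; causal ones
    are shifted apart by ``f2_delta`` symmetrically around the base, clipped
    to [0, 1].  Returns per-variant depths for the high and low pool.
    """
    rng = config.rng() if rng is None else rng
    freqs_base = np.asarray(freqs_base, dtype=float)
    causal = np.asarray(causal, dtype=bool)
    if causal.shape != freqs_base.shape:
        raise ValueError("causal mask must align with the frequency vector")
    delta = config.f2_delta
    pF = freqs_base.copy()
    pL = freqs_base.copy()
    pF[causal] = np.clip(freqs_base[causal] + delta / 2.0, 0.0, 1.0)
    pL[causal] = np.clip(pF[causal] - delta, 0.0, 1.0)
    if pools is None:
        by_id = {p.pool_id: p for p in config.pools}
        pools = [by_id[pid] for pid in config.f2_pool_ids]
    poolF, poolL = pools
    depths_F = [
        _pool_allele_depth([p], poolF.ploidy, config, rng) for p in pF
    ]
    depths_L = [
        _pool_allele_depth([p], poolL.ploidy, config, rng) for p in pL
    ]
    return depths_F, depths_L, causal


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    freqs: pd.DataFrame,
    breed: str,
    n_individuals: int,
    rng: np.random.Generator | int | None = None,
    variant_keys: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: dosage ~ Binomial(2, p) per individual."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if breed not in freqs.index:
        raise ValueError(f"breed {breed!r} absent from the frequency table")
    rng = np.random.default_rng(rng)
    p = freqs.loc[breed].to_numpy(dtype=float)
    dosages = rng.binomial(2, p[None, :].repeat(n_individuals, axis=0))
    keys = (
        list(variant_keys)
        if variant_keys is not None
        else [str(c) for c in freqs.columns]
    )
    individuals = [f"{breed}_{i + 1:03d}" for i in range(n_individuals)]
    return GenotypeMatrix(individuals, keys, dosages.astype(np.int16))


# ---------------------------------------------------------------------------
# full dataset emission


def emit_dataset(config: SimulationConfig, outdir) -> dict[str, str]:
    """Simulate and write a complete input set: pooled VCF, manifest,
    annotation TSV, gene models, and truth tables (true frequencies and
    planted causal variants).  Byte-identical output under a fixed seed.
    """
    import os

    from poolvar import io_formats

    os.makedirs(outdir, exist_ok=True)
    rng = config.rng()
    models = simulate_gene_models(config, rng)
    placements = place_variants(config, models, rng)
    breed_pools = [p for p in config.pools if p.pool_id not in config.f2_pool_ids]
    f2_pools = [p for p in config.pools if p.pool_id in config.f2_pool_ids]
    freqs = simulate_breed_frequencies(config, rng)
    sites = simulate_pool_reads(freqs, breed_pools, config, rng, placements)
    truth_keys = [s.allele_key(0) for s in sites]

    causal = np.zeros(len(sites), dtype=bool)
    if f2_pools:
        # the F2 resource derives from commercial founders: base frequency is
        # the mean over the founder-like breeds present in the tree
        founder_breeds = [
            b for b in ("LargeWhite", "Duroc") if b in freqs.index
        ] or list(freqs.index[:2])
        base = freqs.loc[founder_breeds].mean(axis=0).to_numpy()
        n_causal = int(round(config.f2_causal_fraction * len(sites)))
        eligible = np.where((base > 0.02) & (base < 0.98))[0]
        chosen = rng.choice(eligible, size=min(n_causal, eligible.size), replace=False)
        causal[chosen] = True
        dF, dL, _ = simulate_f2_pools(base, causal, config, rng, f2_pools)
        for site, f, l in zip(sites, dF, dL):
            pad = (0,) * (len(site.alts) - 1)
            site.depths[f2_pools[0].pool_id] = AlleleDepth(f.ref_reads, f.alt_reads + pad)
            site.depths[f2_pools[1].pool_id] = AlleleDepth(l.ref_reads, l.alt_reads + pad)

    gene_by_key = {
        s.allele_key(a): placements[j][4]
        for j, s in enumerate(sites)
        for a in range(len(s.alts))
    }
    all_keys = [k for s in sites for k in (s.allele_key(a) for a in range(len(s.alts)))]
    annotations = simulate_effects(config, all_keys, gene_by_key, models, rng)

    paths = {
        "vcf": os.path.join(outdir, "pools.vcf"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "gene_models": os.path.join(outdir, "gene_models.tsv"),
        "true_frequencies": os.path.join(outdir, "true_frequencies.tsv"),
        "causal_truth": os.path.join(outdir, "causal_truth.tsv"),
    }
    io_formats.write_pooled_vcf(sites, config.pools, paths["vcf"])
    io_formats.write_pool_manifest(config.pools, paths["manifest"])
    io_formats.write_effect_annotations(annotations, paths["annotations"])
    io_formats.write_gene_models(models, paths["gene_models"])
    truth = freqs.copy()
    truth.columns = truth_keys
    truth.T.rename_axis("variant_key").to_csv(paths["true_frequencies"], sep="\t")
    pd.DataFrame(
        {"variant_key": truth_keys, "causal": causal.astype(int)}
    ).to_csv(paths["causal_truth"], sep="\t", index=False)
    return paths
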