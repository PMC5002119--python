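"""Domain types and readers/writers for the external file formats.

The analysis consumes a multi-sample VCF in which each "sample" is a DNA pool
carrying per-allele read depths (FORMAT/AD, FORMAT/DP), a tab-separated pool
manifest, a sidecar variant-effect annotation table, and gene models with CDS
intervals for silent-site counting.  It emits tab-separated result tables and
Newick trees.

Coordinates are 1-based inclusive (VCF convention).  Variant identifiers
follow the underscore convention ``chrom_pos_ref_alt`` with multi-allelic
sites joining alternative alleles by commas (e.g. ``chr16_66618438_C_A,T``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "AlleleDepth",
    "EffectAnnotation",
    "GeneModel",
    "PoolSpec",
    "VariantSite",
    "EFFECT_TERMS",
    "IMPACT_TIERS",
    "SIFT_CLASSES",
    "expected_impact_tier",
    "parse_variant_key",
    "read_effect_annotations",
    "read_gene_models",
    "read_pool_manifest",
    "read_pooled_vcf",
    "write_effect_annotations",
    "write_gene_models",
    "write_newick",
    "write_pool_manifest",
    "write_pooled_vcf",
    "write_table",
]

#: snpEff-style effect terms consumed by the pipeline, and the impact tier each
#: term is expected to carry.  LOW-tier terms are also accepted as MODIFIER.
_EFFECT_IMPACT = {
    "splice_site_donor": "HIGH",
    "splice_site_acceptor": "HIGH",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frame_shift": "HIGH",
    "non_synonymous": "MODERATE",
    "codon_change_or_deletion": "MODERATE",
    "synonymous": "LOW",
    "start_gained": "LOW",
}

EFFECT_TERMS = frozenset(_EFFECT_IMPACT)
IMPACT_TIERS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})
SIFT_CLASSES = frozenset({"deleterious", "tolerated", "unknown"})


def expected_impact_tier(effect_term: str) -> str:
    """Impact tier implied by an effect term (HIGH/MODERATE/LOW)."""
    try:
        return _EFFECT_IMPACT[effect_term]
    except KeyError:
        raise ValueError(f"unknown effect term: {effect_term!r}") from None


@dataclass(frozen=True)
class PoolSpec:
    """One sequenced DNA pool: its breed label and composition.

    The pool ploidy (number of chromosome sets it carries) is twice the
    number of diploid individuals pooled.
    """

    pool_id: str
    breed_label: str
    n_individuals: int

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError(
                f"pool {self.pool_id!r}: n_individuals must be positive"
            )

    @property
    def ploidy(self) -> int:
        return 2 * self.n_individuals


@dataclass(frozen=True)
class AlleleDepth:
    """Per-pool read counts at one site: reference reads and one count per alt."""

    ref_reads: int
    alt_reads: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alt_reads", tuple(int(x) for x in self.alt_reads))
        if self.ref_reads < 0 or any(a < 0 for a in self.alt_reads):
            raise ValueError("read counts must be non-negative")

    @property
    def dp(self) -> int:
        """Total read depth at the position (ref + all alts)."""
        return self.ref_reads + sum(self.alt_reads)


@dataclass
class VariantSite:
    """A variant position with per-pool allele depths.

    ``alts`` keeps the VCF allele order; multi-allelic records are preserved
    joint.  Pools absent from ``depths`` (or with missing AD) are recorded as
    zero depth.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    depths: dict[str, AlleleDepth]

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        if not self.ref or not self.alts or any(not a for a in self.alts):
            raise ValueError("alleles must be non-empty")

    @property
    def id_key(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{','.join(self.alts)}"

    def allele_key(self, alt_index: int) -> str:
        """Identifier for one alternative allele of this site."""
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alts[alt_index]}"


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    """Split ``chrom_pos_ref_alt`` back into its components."""
    try:
        chrom, pos, ref, alt = key.rsplit("_", 3)
        return chrom, int(pos), ref, alt
    except ValueError:
        raise ValueError(f"malformed variant key: {key!r}") from None


@dataclass(frozen=True)
class EffectAnnotation:
    """A snpEff/SIFT-style annotation for one (variant, allele, gene)."""

    variant_key: str
    gene_id: str
    effect_term: str
    impact_tier: str
    sift_class: str = "unknown"
    protein_pos: int | None = None
    protein_len: int | None = None

    def __post_init__(self) -> None:
        expected = expected_impact_tier(self.effect_term)
        allowed = {expected} | ({"MODIFIER"} if expected == "LOW" else set())
        if self.impact_tier not in allowed:
            raise ValueError(
                f"{self.variant_key}: effect {self.effect_term!r} cannot carry "
                f"impact tier {self.impact_tier!r}"
            )
        if self.sift_class not in SIFT_CLASSES:
            raise ValueError(f"unknown SIFT class: {self.sift_class!r}")
        if self.protein_pos is not None and self.protein_pos <= 0:
            raise ValueError("protein_pos must be positive")
        if (
            self.protein_pos is not None
            and self.protein_len is not None
            and self.protein_pos > self.protein_len
        ):
            raise ValueError(
                f"{self.variant_key}: protein_pos {self.protein_pos} beyond "
                f"protein_len {self.protein_len}"
            )


@dataclass
class GeneModel:
    """CDS intervals (1-based closed, sorted, non-overlapping) of one gene."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    cds_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ivals = sorted((int(a), int(b)) for a, b in self.cds_intervals)
        for (a, b), (c, _) in zip(ivals, ivals[1:]):
            if c <= b:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        if any(a > b for a, b in ivals):
            raise ValueError(f"{self.gene_id}: interval start beyond end")
        self.cds_intervals = ivals
        if self.cds_sequence is not None:
            self.cds_sequence = self.cds_sequence.upper()
            if len(self.cds_sequence) % 3 != 0:
                raise ValueError(
                    f"{self.gene_id}: CDS length not divisible by 3"
                )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_intervals)


# ---------------------------------------------------------------------------
# manifest


def read_pool_manifest(path: str | os.PathLike) -> list[PoolSpec]:
    """Read the tab-separated pool manifest.

    Expected header: ``pool_id  breed_label  n_individuals``.  Pool ploidy is
    derived as twice the number of individuals.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pool_id": str, "breed_label": str})
    required = {"pool_id", "breed_label", "n_individuals"}
    if missing := required - set(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["pool_id"].duplicated().any():
        dupes = df.loc[df["pool_id"].duplicated(), "pool_id"].tolist()
        raise ValueError(f"duplicate pool_id in manifest: {dupes}")
    return [
        PoolSpec(row.pool_id, row.breed_label, int(row.n_individuals))
        for row in df.itertuples()
    ]


def write_pool_manifest(pools: Sequence[PoolSpec], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "pool_id": [p.pool_id for p in pools],
            "breed_label": [p.breed_label for p in pools],
            "n_individuals": [p.n_individuals for p in pools],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pooled VCF


def read_pooled_vcf(
    path: str | os.PathLike, manifest: Sequence[PoolSpec]
) -> list[VariantSite]:
    """Read a multi-pool VCF with per-sample AD into ``VariantSite`` records.

    Every VCF sample must appear in the manifest.  Missing AD entries are
    recorded as zero depth for that pool.
    """
    pool_ids = {p.pool_id for p in manifest}
    sites: list[VariantSite] = []
    with pysam.VariantFile(os.fspath(path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = [s for s in samples if s not in pool_ids]
        if unknown:
            raise ValueError(f"VCF samples absent from manifest: {unknown}")
        for rec in vcf:
            alts = tuple(rec.alts or ())
            if not alts:
                continue
            depths: dict[str, AlleleDepth] = {}
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or any(x is None for x in ad):
                    depths[s] = AlleleDepth(0, (0,) * len(alts))
                    continue
                if len(ad) != len(alts) + 1:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos} sample {s}: AD has {len(ad)} "
                        f"entries for {len(alts)} alt allele(s)"
                    )
                depths[s] = AlleleDepth(int(ad[0]), tuple(int(x) for x in ad[1:]))
            sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, alts, depths))
    return sites


def write_pooled_vcf(
    sites: Sequence[VariantSite],
    manifest: Sequence[PoolSpec],
    path: str | os.PathLike,
) -> None:
    """Write sites as an uncompressed VCF 4.2 with per-sample AD and DP."""
    header = pysam.VariantHeader()
    contigs: dict[str, int] = {}
    for site in sites:
        contigs[site.chrom] = max(contigs.get(site.chrom, 0), site.pos + 1000)
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Read depth per allele (ref first)">'
    )
    header.add_line(
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">'
    )
    for p in manifest:
        header.add_sample(p.pool_id)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for site in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                alleles=(site.ref, *site.alts),
            )
            for p in manifest:
                d = site.depths.get(p.pool_id)
                if d is None:
                    d = AlleleDepth(0, (0,) * len(site.alts))
                rec.samples[p.pool_id]["AD"] = (d.ref_reads, *d.alt_reads)
                rec.samples[p.pool_id]["DP"] = d.dp
            out.write(rec)


# ---------------------------------------------------------------------------
# effect annotations


def read_effect_annotations(
    path: str | os.PathLike,
) -> dict[str, list[EffectAnnotation]]:
    """Read the sidecar annotation TSV, keyed by per-allele variant key.

    Multi-allelic positions may carry one annotation per allele, hence the
    list values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "variant_key",
        "gene_id",
        "effect_term",
        "impact_tier",
        "sift_class",
        "protein_pos",
        "protein_len",
    }
    if missing := required - set(df.columns):
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out: dict[str, list[EffectAnnotation]] = {}
    for row in df.itertuples():
        ann = EffectAnnotation(
            variant_key=row.variant_key,
            gene_id=row.gene_id,
            effect_term=row.effect_term,
            impact_tier=row.impact_tier,
            sift_class=row.sift_class if isinstance(row.sift_class, str) else "unknown",
            protein_pos=_opt_int(row.protein_pos),
            protein_len=_opt_int(row.protein_len),
        )
        out.setdefault(ann.variant_key, []).append(ann)
    return out


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return int(float(s)) if s and s.lower() not in {"na", "nan", ""} else None


def write_effect_annotations(
    annotations: Iterable[EffectAnnotation], path: str | os.PathLike
) -> None:
    rows = [
        {
            "variant_key": a.variant_key,
            "gene_id": a.gene_id,
            "effect_term": a.effect_term,
            "impact_tier": a.impact_tier,
            "sift_class": a.sift_class,
            "protein_pos": a.protein_pos if a.protein_pos is not None else "",
            "protein_len": a.protein_len if a.protein_len is not None else "",
        }
        for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from a TSV with comma-joined ``start-end`` CDS intervals."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = []
    for row in df.itertuples():
        intervals = [
            tuple(int(x) for x in chunk.split("-"))
            for chunk in row.cds_intervals.split(",")
        ]
        seq = row.cds_sequence if isinstance(row.cds_sequence, str) else None
        models.append(GeneModel(row.gene_id, row.chrom, row.strand, intervals, seq))
    return models


def write_gene_models(models: Iterable[GeneModel], path: str | os.PathLike) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "cds_intervals": ",".join(f"{a}-{b}" for a, b in g.cds_intervals),
            "cds_sequence": g.cds_sequence or "",
        }
        for g in models
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees and tables


def write_newick(tree, path: str | os.PathLike) -> None:
    """Serialize a dendrogram to Newick, supports as internal node labels."""
    from poolvar.tree import to_newick

    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def write_table(df: pd.DataFrame, path: str | os.PathLike, **kwargs) -> None:
    """Write a result table as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False, **kwargs)
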