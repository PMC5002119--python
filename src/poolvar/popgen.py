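"""Per-breed variant presence, breed-specific variants, and Watterson diversity.

A variant is called present in a breed when the alternative-allele reads
summed over that breed's pools reach a small threshold (default 2 reads, to
resist single-read noise at DP ~1000).  Breed-level pAAF is the
ploidy-weighted mean over the breed's pools.  Diversity at neutrally evolving
synonymous sites is summarised by the Watterson estimator, corrected by the
pool chromosome count (harmonic number) and by the expected number of silent
sites in the sequenced CDS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

from poolvar.frequencies import FrequencyRecord
from poolvar.impact import ImpactClass
from poolvar.io_formats import GeneModel, PoolSpec

__all__ = [
    "BreedSummary",
    "WattersonResult",
    "breed_paaf",
    "breed_pools",
    "breed_presence",
    "breed_specific_variants",
    "breed_summary_table",
    "count_silent_sites",
    "harmonic_number",
    "min_detectable_maf",
    "per_breed_counts",
    "watterson_theta",
]

_BASES = "ACGT"
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


@dataclass
class BreedSummary:
    breed: str
    n_variants: int
    n_unique: int
    class_counts: dict[str, int]
    pct_strong: float
    breed_specific_keys: list[str] = field(default_factory=list)


@dataclass
class WattersonResult:
    """Watterson estimate for one breed.

    theta_per_site = S_syn / a_n / L_silent where a_n is the harmonic number
    over n_chrom - 1 and L_silent the expected silent sites in the CDS.
    """

    breed: str
    S_syn: int
    n_chrom: int
    a_n: float
    L_silent: float
    theta_per_site: float


def breed_pools(manifest: Sequence[PoolSpec]) -> dict[str, list[PoolSpec]]:
    """Group manifest pools by breed label, preserving manifest order."""
    out: dict[str, list[PoolSpec]] = {}
    for p in manifest:
        out.setdefault(p.breed_label, []).append(p)
    return out


def breed_presence(
    record: FrequencyRecord,
    pools: Sequence[PoolSpec],
    min_alt_reads: int = 2,
) -> bool:
    """Presence of the alternative allele in a breed.

    True when the alt reads summed over the breed's pools reach
    ``min_alt_reads``; set to 1 to call presence from any single read.
    """
    if not pools:
        raise ValueError("breed has no pools")
    total = sum(record.alt_reads.get(p.pool_id, 0) for p in pools)
    return total >= min_alt_reads


def breed_paaf(
    record: FrequencyRecord, pools: Sequence[PoolSpec]
) -> float | None:
    """Ploidy-weighted mean pAAF over a breed's covered pools; None if none."""
    num = den = 0.0
    for p in pools:
        f = record.paaf.get(p.pool_id)
        if f is not None:
            num += p.ploidy * f
            den += p.ploidy
    return num / den if den else None


def per_breed_counts(
    records: Sequence[FrequencyRecord],
    classes: Mapping[str, ImpactClass],
    manifest: Sequence[PoolSpec],
    breeds: Sequence[str] | None = None,
    min_alt_reads: int = 2,
) -> list[BreedSummary]:
    """Per-breed variant totals, impact-class breakdown and unique counts.

    ``pct_strong`` is 100*(H + Mdel)/total truncated to one decimal (the
    reporting convention of the per-breed table; the gene-group summary
    rounds instead).  A variant is unique to a breed when present there and
    in no other breed.
    """
    by_breed = breed_pools(manifest)
    if breeds is None:
        breeds = list(by_breed)
    presence: dict[str, dict[str, bool]] = {
        b: {} for b in breeds
    }
    for r in records:
        for b in breeds:
            presence[b][r.variant_key] = breed_presence(
                r, by_breed[b], min_alt_reads
            )
    summaries = []
    for b in breeds:
        present_keys = [k for k, v in presence[b].items() if v]
        counts = {c: 0 for c in ("H", "Mdel", "Mtol", "L")}
        for k in present_keys:
            cls = classes.get(k)
            if cls is not None:
                counts[cls.value] += 1
        total = len(present_keys)
        strong = counts["H"] + counts["Mdel"]
        pct = math.floor(1000 * strong / total) / 10 if total else 0.0
        unique = sum(
            1
            for k in present_keys
            if not any(presence[ob].get(k, False) for ob in breeds if ob != b)
        )
        summaries.append(
            BreedSummary(
                breed=b,
                n_variants=total,
                n_unique=unique,
                class_counts=counts,
                pct_strong=pct,
            )
        )
    return summaries


def breed_summary_table(summaries: Sequence[BreedSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "breed": s.breed,
                "n_variants": s.n_variants,
                "n_unique": s.n_unique,
                "pct_unique": round(100 * s.n_unique / s.n_variants, 1)
                if s.n_variants
                else 0.0,
                "H": s.class_counts["H"],
                "Mdel": s.class_counts["Mdel"],
                "Mtol": s.class_counts["Mtol"],
                "L": s.class_counts["L"],
                "strong": s.class_counts["H"] + s.class_counts["Mdel"],
                "pct_strong": s.pct_strong,
            }
        )
    return pd.DataFrame(rows)


def breed_specific_variants(
    records: Sequence[FrequencyRecord],
    manifest: Sequence[PoolSpec],
    breeds: Sequence[str] | None = None,
    min_alt_reads: int = 2,
    min_paaf: float = 0.1,
    high_paaf: float = 0.5,
) -> list[tuple[str, str, str, float]]:
    """Variants uniquely present in, or uniquely absent from, one breed.

    Rule A: present in exactly one breed with breed pAAF >= ``min_paaf``.
    Rule B: pAAF >= ``high_paaf`` in every breed except exactly one where the
    allele is absent.  Returns ``(variant_key, breed, rule, breed_paaf)``
    tuples; the two rules are mutually exclusive for a given variant.
    """
    by_breed = breed_pools(manifest)
    if breeds is None:
        breeds = list(by_breed)
    hits = []
    for r in records:
        present = {b: breed_presence(r, by_breed[b], min_alt_reads) for b in breeds}
        paafs = {b: breed_paaf(r, by_breed[b]) for b in breeds}
        present_in = [b for b in breeds if present[b]]
        if len(present_in) == 1:
            b = present_in[0]
            f = paafs[b]
            if f is not None and f >= min_paaf:
                hits.append((r.variant_key, b, "A", f))
            continue
        absent_in = [b for b in breeds if not present[b]]
        if len(absent_in) == 1 and all(
            paafs[b] is not None and paafs[b] >= high_paaf
            for b in breeds
            if b != absent_in[0]
        ):
            hits.append((r.variant_key, absent_in[0], "B", paafs[absent_in[0]] or 0.0))
    return hits


# ---------------------------------------------------------------------------
# silent sites and Watterson diversity


def _codon_syn_fraction_sites(codon: str) -> float:
    """Nei-Gojobori synonymous sites of one codon.

    Each of the three positions contributes (synonymous changes at that
    position)/3; changes creating a stop codon count as non-synonymous.
    Result lies in [0, 3).
    """
    fwd = _STANDARD_TABLE.forward_table
    if codon not in fwd:
        raise ValueError(f"premature stop or invalid codon in frame: {codon!r}")
    aa = fwd[codon]
    n_syn = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            mutant = codon[:i] + b + codon[i + 1 :]
            if fwd.get(mutant) == aa:
                n_syn += 1
    return n_syn / 3


def count_silent_sites(
    gene_models: Iterable[GeneModel], mode: str = "fractional"
) -> tuple[dict[str, float], float]:
    """Expected silent sites per gene and in total.

    ``fractional`` (default) uses Nei-Gojobori counting over the CDS codons;
    ``third_position`` simply counts one site per codon (CDS length / 3).
    Requires the CDS sequence, in frame and without premature stops.
    """
    if mode not in {"fractional", "third_position"}:
        raise ValueError(f"unknown silent-site mode: {mode!r}")
    per_gene: dict[str, float] = {}
    for g in gene_models:
        if g.cds_sequence is None:
            raise ValueError(f"{g.gene_id}: CDS sequence required")
        seq = g.cds_sequence
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        # a trailing stop codon is allowed and not counted
        if codons and codons[-1] in _STANDARD_TABLE.stop_codons:
            codons = codons[:-1]
        if mode == "third_position":
            per_gene[g.gene_id] = float(len(codons))
        else:
            per_gene[g.gene_id] = sum(_codon_syn_fraction_sites(c) for c in codons)
    return per_gene, sum(per_gene.values())


def harmonic_number(n_minus_1: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i, the Watterson normalizer for n chromosomes."""
    return sum(1.0 / i for i in range(1, n_minus_1 + 1))


def watterson_theta(
    S_syn: int, n_chrom: int, L_silent: float, breed: str = ""
) -> WattersonResult:
    """Pool-corrected Watterson estimate per silent site.

    ``n_chrom`` is the chromosome count of the breed (summed ploidy of its
    pools), correcting the segregating-site count for sample size; dividing
    by ``L_silent`` puts the estimate on a per-site scale.
    """
    if n_chrom < 2:
        raise ValueError("watterson_theta requires n_chrom >= 2")
    if L_silent <= 0:
        raise ValueError("L_silent must be positive")
    a_n = harmonic_number(n_chrom - 1)
    return WattersonResult(
        breed=breed,
        S_syn=S_syn,
        n_chrom=n_chrom,
        a_n=a_n,
        L_silent=L_silent,
        theta_per_site=S_syn / a_n / L_silent,
    )


def min_detectable_maf(total_individuals: int) -> float:
    """Lowest detectable MAF: one allele copy among all sampled chromosomes."""
    if total_individuals <= 0:
        raise ValueError("total_individuals must be positive")
    return 1.0 / (2 * total_individuals)
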