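"""Predicted allele frequencies from pooled read counts, and site-level filters.

The proportion of reads carrying an allele in a pool estimates that pool's
allele frequency: pAAF for the alternative allele, pMAF for the minor allele
after combining pools.  Sites are filtered on total depth (DP summed over
pools), per-pool depths are down-sampled to a fixed cap without replacement,
and sites where the alternative allele is fixed in every covered pool are
flagged as likely reference errors or variants private to the reference
animal, to be excluded from segregating-variant summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from poolvar.io_formats import AlleleDepth, PoolSpec, VariantSite

__all__ = [
    "FrequencyRecord",
    "VERY_RARE_MAX",
    "RARE_MAX",
    "build_frequency_records",
    "classify_frequency",
    "combine_global_frequency",
    "downsample_counts",
    "downsample_site",
    "estimate_paaf",
    "filter_dense_regions",
    "flag_fixed_alternative",
    "frequency_table",
    "site_depth_filter",
]

#: pMAF class cut-points: very rare below 0.010, rare in [0.010, 0.020),
#: common at or above 0.020.
VERY_RARE_MAX = 0.010
RARE_MAX = 0.020


@dataclass
class FrequencyRecord:
    """Frequency summary for one alternative allele of one site.

    ``paaf`` holds per-pool read proportions for pools with coverage only;
    uncovered pools (dp = 0) carry no entry — absence of coverage is not
    evidence of absence.  ``alt_reads``/``dp`` keep the underlying counts so
    downstream presence rules and contingency tables can reuse them.
    """

    variant_key: str
    chrom: str
    pos: int
    n_alts: int
    paaf: dict[str, float]
    alt_reads: dict[str, int]
    dp: dict[str, int]
    global_aaf: float
    pmaf: float
    freq_class: str
    fixed_alt: bool

    def __post_init__(self) -> None:
        if not np.isclose(self.pmaf, min(self.global_aaf, 1 - self.global_aaf)):
            raise ValueError("pmaf must be the folded global_aaf")


def estimate_paaf(depth: AlleleDepth, alt_index: int = 0) -> float | None:
    """Proportion of reads carrying the given alt allele; None when dp = 0."""
    if alt_index < 0 or alt_index >= len(depth.alt_reads):
        raise IndexError(f"alt_index {alt_index} out of range")
    if depth.dp == 0:
        return None
    return depth.alt_reads[alt_index] / depth.dp


def site_depth_filter(
    sites: Sequence[VariantSite], min_total_dp: int = 1000
) -> list[VariantSite]:
    """Retain sites whose depth summed over all pools reaches ``min_total_dp``.

    The boundary is inclusive: a site with total DP exactly at the threshold
    is kept.
    """
    return [
        s
        for s in sites
        if sum(d.dp for d in s.depths.values()) >= min_total_dp
    ]


def downsample_counts(
    depth: AlleleDepth,
    cap: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> AlleleDepth:
    """Down-sample a pool's reads to at most ``cap`` without replacement.

    A multivariate hypergeometric draw over the (ref, alt...) read classes,
    i.e. a uniform subsample of the physical reads.  Depths at or below the
    cap are returned unchanged.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    if depth.dp <= cap:
        return depth
    rng = np.random.default_rng(rng)
    colors = np.array([depth.ref_reads, *depth.alt_reads])
    sub = rng.multivariate_hypergeometric(colors, cap)
    return AlleleDepth(int(sub[0]), tuple(int(x) for x in sub[1:]))


def downsample_site(
    site: VariantSite, cap: int = 1000, rng: np.random.Generator | int | None = None
) -> VariantSite:
    """Apply :func:`downsample_counts` to every pool of a site."""
    rng = np.random.default_rng(rng)
    return VariantSite(
        site.chrom,
        site.pos,
        site.ref,
        site.alts,
        {pid: downsample_counts(d, cap, rng) for pid, d in site.depths.items()},
    )


def combine_global_frequency(
    paaf: Mapping[str, float],
    manifest: Sequence[PoolSpec],
    weights: str = "ploidy",
    dp: Mapping[str, int] | None = None,
) -> tuple[float, float]:
    """Pool per-pool pAAFs into a global alternative-allele frequency and pMAF.

    Pools are weighted by their ploidy (chromosome count) by default, so the
    global estimate targets the population-level frequency over all sampled
    chromosome sets; ``weights="reads"`` weights by read depth instead.
    Only pools with a defined pAAF (coverage) contribute.
    """
    ploidy = {p.pool_id: p.ploidy for p in manifest}
    pools = [pid for pid in paaf if paaf[pid] is not None]
    if not pools:
        raise ValueError("no pool with a defined pAAF")
    if weights == "ploidy":
        w = np.array([ploidy[pid] for pid in pools], dtype=float)
    elif weights == "reads":
        if dp is None:
            raise ValueError("read weighting requires per-pool depths")
        w = np.array([dp[pid] for pid in pools], dtype=float)
    else:
        raise ValueError(f"unknown weighting: {weights!r}")
    freqs = np.array([paaf[pid] for pid in pools], dtype=float)
    aaf = float(np.average(freqs, weights=w))
    return aaf, min(aaf, 1.0 - aaf)


def classify_frequency(pmaf: float) -> str:
    """Map a pMAF to its frequency class (very_rare / rare / common)."""
    if not 0.0 <= pmaf <= 0.5:
        raise ValueError(f"pMAF out of range [0, 0.5]: {pmaf}")
    if pmaf < VERY_RARE_MAX:
        return "very_rare"
    if pmaf < RARE_MAX:
        return "rare"
    return "common"


def flag_fixed_alternative(paaf: Mapping[str, float]) -> bool:
    """True when the alternative allele is fixed in every covered pool.

    Such sites are likely reference errors or variants private to the
    reference animal.  Pools without coverage are ignored; a site covered in
    no pool is not flagged.
    """
    defined = [v for v in paaf.values() if v is not None]
    return bool(defined) and all(v == 1.0 for v in defined)


def filter_dense_regions(
    sites: Sequence[VariantSite],
    window_bp: int = 100,
    max_variants: int = 5,
) -> tuple[list[VariantSite], list[VariantSite]]:
    """Flag variants clustering in high-density windows (likely mismapping).

    A site is flagged when any sliding window of ``window_bp`` on its
    chromosome contains it together with more than ``max_variants`` sites in
    total.  Returns ``(retained, flagged)``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    flagged_idx: set[int] = set()
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    for idx in by_chrom.values():
        idx.sort(key=lambda i: sites[i].pos)
        pos = [sites[i].pos for i in idx]
        j = 0
        for i in range(len(pos)):
            # widest window starting at pos[i]
            while j < len(pos) and pos[j] <= pos[i] + window_bp - 1:
                j += 1
            if j - i > max_variants:
                flagged_idx.update(idx[i:j])
    retained = [s for i, s in enumerate(sites) if i not in flagged_idx]
    flagged = [s for i, s in enumerate(sites) if i in flagged_idx]
    return retained, flagged


def build_frequency_records(
    sites: Iterable[VariantSite],
    manifest: Sequence[PoolSpec],
    weights: str = "ploidy",
) -> list[FrequencyRecord]:
    """Compute one :class:`FrequencyRecord` per (site, alternative allele).

    Multi-allelic sites yield one record per alt, each carrying the per-allele
    variant key; ``n_alts`` lets downstream steps exclude multi-allelic sites.
    Sites covered in no pool are skipped.
    """
    records: list[FrequencyRecord] = []
    for site in sites:
        for ai in range(len(site.alts)):
            paaf: dict[str, float] = {}
            alt_reads: dict[str, int] = {}
            dp: dict[str, int] = {}
            for pid, depth in site.depths.items():
                dp[pid] = depth.dp
                alt_reads[pid] = depth.alt_reads[ai]
                p = estimate_paaf(depth, ai)
                if p is not None:
                    paaf[pid] = p
            if not paaf:
                continue
            aaf, pmaf = combine_global_frequency(paaf, manifest, weights, dp)
            records.append(
                FrequencyRecord(
                    variant_key=site.allele_key(ai),
                    chrom=site.chrom,
                    pos=site.pos,
                    n_alts=len(site.alts),
                    paaf=paaf,
                    alt_reads=alt_reads,
                    dp=dp,
                    global_aaf=aaf,
                    pmaf=pmaf,
                    freq_class=classify_frequency(pmaf),
                    fixed_alt=flag_fixed_alternative(paaf),
                )
            )
    return records


def frequency_table(records: Sequence[FrequencyRecord], manifest: Sequence[PoolSpec]):
    """Tabulate records: one pAAF column per pool plus the global summaries."""
    import pandas as pd

    rows = []
    for r in records:
        row: dict[str, object] = {"variant_key": r.variant_key}
        for p in manifest:
            row[f"paaf_{p.pool_id}"] = r.paaf.get(p.pool_id, float("nan"))
        row.update(
            global_aaf=r.global_aaf,
            pmaf=r.pmaf,
            freq_class=r.freq_class,
            fixed_alt=r.fixed_alt,
        )
        rows.append(row)
    return pd.DataFrame(rows)
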