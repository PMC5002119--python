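"""Fisher-exact allele-frequency contrasts between two divergent pools.

Bi-allelic variants covered in both pools and segregating in the resource are
compared with a two-sided Fisher exact test on a 2x2 table of allele counts.
The table can be built from chromosome-scale counts (pAAF rounded to the pool
ploidy; the default, since read counts at DP ~ 1000 pseudo-replicate the few
dozen underlying chromosomes and overstate significance) or from the raw read
counts.  Multiple testing is controlled by Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from poolvar.frequencies import FrequencyRecord
from poolvar.io_formats import EffectAnnotation, PoolSpec

__all__ = [
    "ContrastResult",
    "bonferroni_threshold",
    "build_contrast_table",
    "contrast_report",
    "display_truncated",
    "eligible_variants",
    "fisher_exact_two_sided",
    "run_contrast",
]


@dataclass
class ContrastResult:
    variant_key: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows alt/ref, cols poolF/poolL
    p_value: float
    m_tests: int
    nominal: bool
    bonferroni_sig: bool

    def __post_init__(self) -> None:
        if self.bonferroni_sig and not self.nominal:
            raise ValueError("Bonferroni significance implies nominal significance")


def eligible_variants(
    records: Sequence[FrequencyRecord], poolF: str, poolL: str
) -> list[FrequencyRecord]:
    """Bi-allelic variants covered in both pools and segregating there.

    Multi-allelic sites and variants with no read count in at least one pool
    are excluded; "segregating" requires both alleles to be seen across the
    two pools combined.
    """
    out = []
    for r in records:
        if r.n_alts != 1:
            continue
        dpF, dpL = r.dp.get(poolF, 0), r.dp.get(poolL, 0)
        if dpF == 0 or dpL == 0:
            continue
        alt = r.alt_reads.get(poolF, 0) + r.alt_reads.get(poolL, 0)
        ref = dpF + dpL - alt
        if alt == 0 or ref == 0:
            continue
        out.append(r)
    return out


def build_contrast_table(
    record: FrequencyRecord,
    poolF: str,
    poolL: str,
    manifest: Sequence[PoolSpec] | None = None,
    mode: str = "chromosomes",
) -> tuple[tuple[int, int], tuple[int, int]]:
    """2x2 allele-count table (rows alt/ref, columns poolF/poolL).

    ``chromosomes`` mode converts each pool's pAAF to allele copies out of the
    pool ploidy (round(pAAF * ploidy)); ``reads`` mode passes the raw read
    counts through unchanged.
    """
    if mode == "reads":
        altF = record.alt_reads[poolF]
        altL = record.alt_reads[poolL]
        refF = record.dp[poolF] - altF
        refL = record.dp[poolL] - altL
    elif mode == "chromosomes":
        if manifest is None:
            raise ValueError("chromosomes mode requires the pool manifest")
        ploidy = {p.pool_id: p.ploidy for p in manifest}
        if poolF not in ploidy or poolL not in ploidy:
            raise ValueError("pool ploidy missing from manifest")
        altF = round(record.paaf[poolF] * ploidy[poolF])
        altL = round(record.paaf[poolL] * ploidy[poolL])
        refF = ploidy[poolF] - altF
        refL = ploidy[poolL] - altL
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return ((altF, altL), (refF, refL))


def fisher_exact_two_sided(
    table: tuple[tuple[int, int], tuple[int, int]],
) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the hypergeometric probabilities (same margins) of every table whose
    point probability does not exceed the observed one.  Computed in exact
    integer arithmetic, so ties are handled without a float tolerance.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if 0 in (r1, r2, c1, c2):
        raise ValueError("both margins must be positive")
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / math.comb(n, c1)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def display_truncated(value: float, decimals: int) -> str:
    """Format a threshold truncated (not rounded) to the displayed precision."""
    scaled = math.floor(value * 10**decimals)
    return f"{scaled / 10**decimals:.{decimals}f}"


def run_contrast(
    records: Sequence[FrequencyRecord],
    poolF: str,
    poolL: str,
    manifest: Sequence[PoolSpec] | None = None,
    mode: str = "chromosomes",
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """Test every eligible variant; flags use alpha and alpha/m (Bonferroni)."""
    eligible = eligible_variants(records, poolF, poolL)
    m = len(eligible)
    if m == 0:
        return []
    thr = bonferroni_threshold(alpha, m)
    results = []
    for r in eligible:
        tab = build_contrast_table(r, poolF, poolL, manifest, mode)
        p = fisher_exact_two_sided(tab) if _testable(tab) else 1.0
        results.append(
            ContrastResult(
                variant_key=r.variant_key,
                table=tab,
                p_value=p,
                m_tests=m,
                nominal=p <= alpha,
                bonferroni_sig=p <= thr,
            )
        )
    return results


def _testable(table) -> bool:
    (a, b), (c, d) = table
    return a + b > 0 and c + d > 0 and a + c > 0 and b + d > 0


def contrast_report(
    results: Sequence[ContrastResult],
    annotations: Mapping[str, Sequence[EffectAnnotation]],
    mode: str = "chromosomes",
) -> pd.DataFrame:
    """Per-gene summary of nominal hits: counts by effect, p range, survivors.

    Genes without a nominal hit are omitted.  ``count_basis`` records which
    table mode produced the p-values.
    """
    per_gene: dict[str, list[tuple[ContrastResult, EffectAnnotation]]] = {}
    tested_per_gene: dict[str, int] = {}
    for res in results:
        for ann in annotations.get(res.variant_key, ()):
            tested_per_gene[ann.gene_id] = tested_per_gene.get(ann.gene_id, 0) + 1
            if res.nominal:
                per_gene.setdefault(ann.gene_id, []).append((res, ann))
    rows = []
    for gene in sorted(per_gene):
        hits = per_gene[gene]
        by_effect: dict[str, int] = {}
        for _, ann in hits:
            by_effect[ann.effect_term] = by_effect.get(ann.effect_term, 0) + 1
        ps = [res.p_value for res, _ in hits]
        rows.append(
            {
                "gene": gene,
                "n_tested": tested_per_gene[gene],
                "n_significant": len(hits),
                "effects": "; ".join(
                    f"{n} {e}" for e, n in sorted(by_effect.items())
                ),
                "p_min": min(ps),
                "p_max": max(ps),
                "n_bonferroni": sum(1 for res, _ in hits if res.bonferroni_sig),
                "count_basis": mode,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_tested",
            "n_significant",
            "effects",
            "p_min",
            "p_max",
            "n_bonferroni",
            "count_basis",
        ],
    )
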