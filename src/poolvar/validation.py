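"""Validation of pool-predicted frequencies against individual genotypes.

Compares the pool-based pMAF with the minor-allele frequency observed in
genotyped individuals (ordinary least squares plus squared Pearson
correlation) and tests Hardy-Weinberg equilibrium per breed with the exact
conditional test.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "hwe_by_breed",
    "hwe_exact_test",
    "observed_maf",
    "predicted_vs_observed",
]


def observed_maf(dosages: Sequence[int | None]) -> float:
    """Minor-allele frequency from 0/1/2 alt dosages, folded to <= 0.5.

    Missing calls (None/NaN) are dropped; at least one non-missing call is
    required.
    """
    called = [
        int(d)
        for d in dosages
        if d is not None and not (isinstance(d, float) and math.isnan(d))
    ]
    if not called:
        raise ValueError("no non-missing genotype calls")
    if any(d not in (0, 1, 2) for d in called):
        raise ValueError("dosages must be 0, 1 or 2")
    aaf = sum(called) / (2 * len(called))
    return min(aaf, 1.0 - aaf)


def predicted_vs_observed(
    predicted: Sequence[float], observed: Sequence[float]
) -> tuple[float, float, float, int]:
    """OLS of observed on predicted MAF: (slope, intercept, r_squared, n)."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired variants")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance in predicted or observed frequencies")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2), int(x.size)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of matching parity, the probabilities not exceeding that of the
    observed configuration.  Exact integer arithmetic throughout.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * n_aa + n_Aa  # alt-allele copies
    # weight of h heterozygotes given allele counts: n! / (nAA! h! naa!) * 2^h
    f = math.factorial
    weights: dict[int, int] = {}
    m = min(n_a, 2 * n - n_a)  # minor-allele copies bound h; parity matches
    for h in range(m % 2, m + 1, 2):
        aa = (n_a - h) // 2
        AA = n - aa - h
        weights[h] = f(n) // (f(AA) * f(h) * f(aa)) * 2**h
    w_obs = weights[n_Aa]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= w_obs) / total


def hwe_by_breed(
    genotypes: Mapping[str, Sequence[int | None]],
    alpha: float = 0.05,
) -> tuple[dict[str, float], float, bool]:
    """Per-breed HWE p-values for one variant, plus an across-breed verdict.

    ``genotypes`` maps breed label to that breed's dosage vector.  Testing is
    within breed only (pooling breeds would manufacture Wahlund-effect
    departures); the across-breed summary is the minimum p with Bonferroni
    correction over the number of breeds tested.
    """
    pvals: dict[str, float] = {}
    for breed, dosages in genotypes.items():
        called = [
            int(d)
            for d in dosages
            if d is not None and not (isinstance(d, float) and math.isnan(d))
        ]
        if not called:
            continue
        counts = (
            called.count(0),
            called.count(1),
            called.count(2),
        )
        pvals[breed] = hwe_exact_test(*counts)
    if not pvals:
        raise ValueError("no breed with genotype calls")
    min_p = min(pvals.values())
    in_hwe = min_p > alpha / len(pvals)
    return pvals, min_p, in_hwe
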