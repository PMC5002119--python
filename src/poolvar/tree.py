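"""UPGMA breed dendrogram from allele-frequency correlations, with bootstrap.

Breeds are clustered on the distance 1 - r, where r is the pairwise Pearson
correlation of per-breed alternative-allele frequency vectors.  UPGMA proper
(size-weighted average linkage) is used, so the tree is ultrametric; node
support is the fraction of trees, rebuilt from variant columns resampled with
replacement, that contain the identical leaf cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from poolvar.frequencies import FrequencyRecord
from poolvar.io_formats import PoolSpec
from poolvar.popgen import breed_paaf, breed_pools

__all__ = [
    "Dendrogram",
    "bootstrap_support",
    "correlation_distance_matrix",
    "select_tree_variants",
    "to_newick",
    "upgma",
]

_TRANSFORMS = {
    "one_minus_r": lambda r: 1.0 - r,
    "half_one_minus_r": lambda r: (1.0 - r) / 2.0,
    "one_minus_r2": lambda r: 1.0 - r**2,
}


@dataclass
class Dendrogram:
    """Rooted ultrametric tree as an ordered list of merges.

    Each merge joins two clusters (frozensets of leaf labels) at a height;
    heights are non-decreasing.  ``supports`` maps merged clusters to
    bootstrap support in [0, 1].
    """

    leaves: list[str]
    merges: list[tuple[frozenset, frozenset, float]]
    supports: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.merges) != len(self.leaves) - 1:
            raise ValueError("a rooted binary tree needs n_leaves - 1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def clusters(self) -> list[frozenset]:
        """Internal-node leaf sets in merge order (the last is the root)."""
        return [a | b for a, b, _ in self.merges]


def select_tree_variants(
    records: Sequence[FrequencyRecord],
    manifest: Sequence[PoolSpec],
    breeds: Sequence[str],
) -> pd.DataFrame:
    """Breed x variant matrix of pAAFs for tree building.

    Keeps variants with a defined breed-level pAAF in every listed breed and
    with the alternative allele present (pAAF > 0) in at least one of them;
    variants private to unlisted pools (e.g. the divergent F2 pools) drop out
    by the presence rule.
    """
    if len(breeds) < 2:
        raise ValueError("need at least two breeds")
    by_breed = breed_pools(manifest)
    cols: dict[str, list[float]] = {}
    for r in records:
        fs = [breed_paaf(r, by_breed[b]) for b in breeds]
        if any(f is None for f in fs):
            continue
        if all(f == 0.0 for f in fs):
            continue
        cols[r.variant_key] = fs  # type: ignore[assignment]
    return pd.DataFrame(cols, index=list(breeds))


def correlation_distance_matrix(
    freq_matrix: pd.DataFrame, transform: str = "one_minus_r"
) -> pd.DataFrame:
    """Pairwise distance between breed rows from Pearson correlation."""
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform: {transform!r}")
    X = freq_matrix.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two variants")
    sd = X.std(axis=1)
    for label, s in zip(freq_matrix.index, sd):
        if s == 0:
            raise ValueError(f"zero-variance frequency vector for breed {label!r}")
    d = _TRANSFORMS[transform](np.corrcoef(X))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=freq_matrix.index, columns=freq_matrix.index)


def upgma(distance_matrix: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration (size-weighted average linkage, merge height d/2).

    Ties are broken by the lexicographically smallest pair of cluster leaf
    sets, making the output deterministic.
    """
    labels = list(distance_matrix.index)
    D = distance_matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    if len(labels) < 2:
        raise ValueError("need at least two leaves")
    # active clusters: id -> (leafset, size); distances between active ids
    clusters: dict[int, tuple[frozenset, int]] = {
        i: (frozenset([lab]), 1) for i, lab in enumerate(labels)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
    }
    merges: list[tuple[frozenset, frozenset, float]] = []
    next_id = len(labels)
    while len(clusters) > 1:
        def sort_key(pair: tuple[int, int]):
            i, j = pair
            a = tuple(sorted(clusters[i][0]))
            b = tuple(sorted(clusters[j][0]))
            lo, hi = sorted((a, b))
            return (dist[pair], lo, hi)

        (i, j) = min(dist, key=sort_key)
        d = dist[(i, j)]
        (set_i, n_i), (set_j, n_j) = clusters[i], clusters[j]
        a, b = sorted((set_i, set_j), key=lambda s: tuple(sorted(s)))
        merges.append((a, b, d / 2.0))
        clusters.pop(i)
        clusters.pop(j)
        new_set, new_n = set_i | set_j, n_i + n_j
        for k in list(clusters):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(k, next_id), max(k, next_id))] = (
                n_i * dik + n_j * djk
            ) / new_n
        del dist[(i, j)]
        clusters[next_id] = (new_set, new_n)
        next_id += 1
    return Dendrogram(leaves=labels, merges=merges)


def bootstrap_support(
    freq_matrix: pd.DataFrame,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    transform: str = "one_minus_r",
) -> Dendrogram:
    """Build the UPGMA tree and attach bootstrap supports to its nodes.

    Variant columns are resampled with replacement B times; support of an
    internal node is the fraction of replicate trees containing the identical
    leaf cluster.  Replicates in which some breed becomes constant (no
    defined correlation) are rebuilt from a fresh resample.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    tree = upgma(correlation_distance_matrix(freq_matrix, transform))
    counts = {c: 0 for c in tree.clusters}
    n = freq_matrix.shape[1]
    done = 0
    while done < B:
        cols = rng.integers(0, n, size=n)
        resampled = freq_matrix.iloc[:, cols]
        try:
            boot = upgma(correlation_distance_matrix(resampled, transform))
        except ValueError:
            continue  # degenerate resample; redraw
        for c in boot.clusters:
            if c in counts:
                counts[c] += 1
        done += 1
    tree.supports = {c: counts[c] / B for c in counts}
    return tree


def to_newick(tree: Dendrogram, support_digits: int = 2) -> str:
    """Newick string with branch lengths as height differences and supports
    as internal node labels (the root is unlabeled)."""
    if len(tree.leaves) < 2:
        raise ValueError("tree must have at least two leaves")
    # cluster -> (newick fragment, height)
    nodes: dict[frozenset, tuple[str, float]] = {
        frozenset([lab]): (lab, 0.0) for lab in tree.leaves
    }
    root = None
    for a, b, h in tree.merges:
        (na, ha), (nb, hb) = nodes.pop(a), nodes.pop(b)
        cluster = a | b
        parts = f"({na}:{_fmt(h - ha)},{nb}:{_fmt(h - hb)})"
        label = ""
        if cluster in tree.supports and len(cluster) < len(tree.leaves):
            label = f"{tree.supports[cluster]:.{support_digits}f}"
        nodes[cluster] = (parts + label, h)
        root = cluster
    return nodes[root][0] + ";"


def _fmt(x: float) -> str:
    return f"{x:g}"
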