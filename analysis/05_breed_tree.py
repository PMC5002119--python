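"""Breed dendrogram from allele-frequency correlations with bootstrap support.

Keeps variants with breed-level pAAF defined in every breed and present in at
least one, clusters breeds by UPGMA on 1 - Pearson r, and attaches supports
from 1,000 resamplings of the variant columns.
"""

import sys

import numpy as np

sys.path.insert(0, "analysis")
from common import SEED, frequency_records, load_inputs, out_path

from poolvar import popgen, tree as tr
from poolvar.io_formats import write_newick, write_table


def main():
    sites, manifest, _, _ = load_inputs()
    records, _ = frequency_records(sites, manifest)
    segregating = [r for r in records if not r.fixed_alt]
    breeds = [b for b in popgen.breed_pools(manifest) if not b.startswith("F2")]

    matrix = tr.select_tree_variants(segregating, manifest, breeds)
    dendro = tr.bootstrap_support(matrix, B=1000, rng=np.random.default_rng(SEED))
    dist = tr.correlation_distance_matrix(matrix)
    write_table(dist.reset_index(names="breed"), out_path("distance_matrix.tsv"))
    write_newick(dendro, out_path("tree.nwk"))

    print(f"{matrix.shape[1]} variants informative in all {len(breeds)} breeds")
    print("tree:", tr.to_newick(dendro))
    low = {tuple(sorted(c)): s for c, s in dendro.supports.items() if s < 0.8}
    print("nodes with bootstrap < 0.8:", low or "none")


if __name__ == "__main__":
    main()
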