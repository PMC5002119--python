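"""Validate pool-predicted frequencies against individual genotypes.

Draws Hardy-Weinberg genotypes for ~78% of the pooled animals (mirroring the
fraction with DNA left for genotyping) from the true breed frequencies,
regresses the genotype-observed MAF on the pool pMAF, and tests HWE within
each breed.
"""

import sys

import numpy as np
import pandas as pd

sys.path.insert(0, "analysis")
from common import SEED, frequency_records, input_path, load_inputs, out_path

from poolvar import popgen, validation as vd
from poolvar.io_formats import write_table
from poolvar.simulate import simulate_genotypes


def main():
    sites, manifest, _, _ = load_inputs()
    records, _ = frequency_records(sites, manifest)
    segregating = [r for r in records if not r.fixed_alt]
    truth = pd.read_csv(
        input_path("true_frequencies.tsv"), sep="\t", index_col="variant_key"
    )
    breeds = [b for b in popgen.breed_pools(manifest) if not b.startswith("F2")]
    by_breed = popgen.breed_pools(manifest)
    keys = [r.variant_key for r in segregating if r.variant_key in truth.index]
    rng = np.random.default_rng(SEED)

    matrices = {}
    for b in breeds:
        n = max(1, round(0.78 * sum(p.n_individuals for p in by_breed[b])))
        matrices[b] = simulate_genotypes(truth.loc[keys, [b]].T, b, n, rng, keys)

    recs = {r.variant_key: r for r in segregating}
    rows = []
    for i, k in enumerate(keys):
        dosages = np.concatenate([matrices[b].genotypes[:, i] for b in breeds])
        per_breed = {b: list(matrices[b].genotypes[:, i]) for b in breeds}
        _, min_p, ok = vd.hwe_by_breed(per_breed)
        rows.append({
            "variant_key": k,
            "pmaf": recs[k].pmaf,
            "observed_maf": vd.observed_maf(list(dosages)),
            "hwe_min_p": min_p,
            "hwe_ok": ok,
            "n_called": len(dosages),
        })
    df = pd.DataFrame(rows)
    write_table(df, out_path("validation.tsv"))

    poly = df[(df.pmaf > 0) | (df.observed_maf > 0)]
    slope, intercept, r2, n = vd.predicted_vs_observed(poly.pmaf, poly.observed_maf)
    print(f"{n} variants compared; genotyped animals per variant: "
          f"{df.n_called.iloc[0]}")
    print(f"observed ~ predicted MAF: slope {slope:.3f}, r^2 = {r2:.3f}")
    print(f"variants consistent with HWE in every breed: "
          f"{df.hwe_ok.mean():.1%}")


if __name__ == "__main__":
    main()
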