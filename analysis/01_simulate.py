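"""Generate the synthetic pooled-sequencing dataset all later steps analyze.

Emulates the study design: 304 pigs in 16 pools (ten breeds plus two
divergent F2 pools), ~2,000 coding variants placed in simulated gene models,
depth ~72x per haploid pool member capped at 1,000 reads/position, effect
categories in the catalogue's segregating proportions, and ~0.5% of variants
planted with an allele-frequency differential of 0.8 between the F2 pools.
"""

import sys

sys.path.insert(0, "analysis")
from common import INPUTS, SEED

from poolvar.simulate import SimulationConfig, emit_dataset


def main():
    config = SimulationConfig(seed=SEED, n_variants=2000, n_genes=200)
    paths = emit_dataset(config, INPUTS)
    print(f"simulated {config.n_variants} variants for {len(config.pools)} pools")
    print(f"animals: {sum(p.n_individuals for p in config.pools)}, "
          f"chromosome sets: {sum(p.ploidy for p in config.pools)}")
    for name, path in paths.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
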