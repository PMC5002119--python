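"""Shared plumbing for the numbered analysis drivers.

Each driver loads the simulated inputs written by ``01_simulate.py`` and
recomputes the frequency records it needs; recomputation is cheap and keeps
every script runnable on its own (after 01).
"""

import os

import numpy as np

from poolvar import frequencies as fq
from poolvar import io_formats as io

INPUTS = os.path.join("results", "inputs")
RESULTS = "results"
SEED = 1


def input_path(name):
    return os.path.join(INPUTS, name)


def out_path(name):
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def load_inputs():
    manifest = io.read_pool_manifest(input_path("manifest.tsv"))
    sites = io.read_pooled_vcf(input_path("pools.vcf"), manifest)
    annotations = io.read_effect_annotations(input_path("annotations.tsv"))
    models = io.read_gene_models(input_path("gene_models.tsv"))
    return sites, manifest, annotations, models


def frequency_records(sites, manifest, min_total_dp=1000, cap=1000):
    """The standard site-filtering + estimation path used by every driver."""
    kept = fq.site_depth_filter(sites, min_total_dp)
    rng = np.random.default_rng(SEED)
    kept = [fq.downsample_site(s, cap, rng) for s in kept]
    retained, flagged = fq.filter_dense_regions(kept)
    records = fq.build_frequency_records(retained, manifest)
    return records, len(flagged)


def gene_groups(models, n_receptor=10):
    """Two-group gene layout mirroring the receptor vs pathway split: the
    first ``n_receptor`` simulated genes stand in for the receptor family."""
    receptor = {m.gene_id for m in models[:n_receptor]}
    return {
        m.gene_id: ("TASR" if m.gene_id in receptor else "AR") for m in models
    }
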