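"""Shared fixtures: small synthetic genomes and profiles built in memory."""

import numpy as np
import pytest

from mfaterm import (
    GenomeMap,
    MarkerFrequencyProfile,
    Origin,
    Replicon,
    ReplicationParameters,
    SyntheticSpec,
    expected_profile,
    sample_counts,
    segments_between,
    trim_outlier_bins,
    normalize_profiles,
)


@pytest.fixture
def two_origin_genome():
    """2 Mb circle with origins at 0 and 1,000,000 (two 1 Mb segments)."""
    genome = GenomeMap({"c": Replicon("c", 2_000_000)}, {})
    origins = [Origin("c", 0, 0.0, name="o1"),
               Origin("c", 1_000_000, 0.0, name="o2")]
    params = ReplicationParameters(tau=40.0, v=30_000.0)
    return genome, origins, params


def make_segment_dataset(
    genome, origins, params, *, sigma=0.0, mean_depth=None, seed=0,
    bin_size=1000, perturbations=(),
):
    """Expected profile (and optionally a Poisson-sampled, trimmed,
    normalised profile) for the first replicon."""
    rep = next(iter(genome.replicons.values()))
    spec = SyntheticSpec(
        genome=genome, origins=origins, params=params, bin_size=bin_size,
        mean_depth=mean_depth or 200.0, sigma={rep.name: sigma},
        perturbations=list(perturbations), seed=seed,
    )
    exp = expected_profile(spec)[0]
    if mean_depth is None:
        return exp, None
    cov = trim_outlier_bins(sample_counts(exp, mean_depth, seed))
    prof = normalize_profiles([cov], rep.name)[0]
    return exp, prof


@pytest.fixture
def noiseless_v_profile(two_origin_genome):
    """Noise-free piecewise-linear profile with fcps at the midpoints."""
    genome, origins, params = two_origin_genome
    exp, _ = make_segment_dataset(genome, origins, params)
    segs = segments_between(origins, genome.replicon("c"))
    return exp, segs
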