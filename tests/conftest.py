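import numpy as np
import pandas as pd
import pytest

from fermquant.containers import validate_sample_info
from fermquant.simulate import SimulationParams, TaxonSpec, simulate_timecourse


def make_taxon(genome_id, domain="bacteria", size=3_000_000, copies=5, n0=1e6,
               r=0.0, k=1e8, d=0.0, genes=5, act_out=0.1):
    return TaxonSpec(
        genome_id=genome_id,
        domain=domain,
        genome_size_bp=size,
        marker_copies=copies,
        initial_density=n0,
        growth_rate=r,
        carrying_capacity=k,
        decay_rate=d,
        gene_count=genes,
        activity_profile={"meju_in": 1.0, "meju_out": act_out},
    )


@pytest.fixture
def small_params():
    """Three bacteria + two fungi over the study's six sampling days."""
    taxa = [
        make_taxon("B1", copies=5, n0=2e5, r=0.1, k=4e6, d=0.06),
        make_taxon("B2", copies=10, n0=1e5, r=0.08, k=1e6, d=0.05, size=4_000_000),
        make_taxon("B3", copies=1, n0=5e4, r=0.05, k=2e5, d=0.02, size=2_400_000),
        make_taxon("F1", domain="fungi", copies=5, n0=1e3, r=0.1, k=8e4, d=0.08, size=24_000_000),
        make_taxon("F2", domain="fungi", copies=1, n0=2e3, r=0.15, k=2e4, d=0.1, size=20_000_000),
    ]
    return SimulationParams(taxa=taxa, seed=11, qpcr_cv=0.0)


@pytest.fixture
def small_truth(small_params):
    return simulate_timecourse(small_params)


@pytest.fixture
def toy_counts():
    """A tiny hand-checkable taxon count table."""
    return pd.DataFrame(
        {"s1": [3, 1, 1], "s2": [5, 5, 0], "s3": [10, 0, 0]},
        index=pd.Index(["A", "B", "C"], name="feature_id"),
    )


@pytest.fixture
def toy_samples():
    frame = pd.DataFrame(
        {
            "day": [0, 60, 180],
            "phase": ["meju_in", "meju_in", "meju_out"],
            "qpcr_bacteria": [4.8e7, 2.4e7, 1.0e6],
            "qpcr_fungi": [4.6e5, 2.0e5, 1.0e4],
            "spike_in_reads": [100, 200, 400],
            "total_mrna_mapped_reads": [1_000_000, 2_000_000, 1_000_000],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return validate_sample_info(frame)


def random_count_frame(rng, n_features=8, n_samples=4, max_count=30):
    data = rng.integers(0, max_count + 1, size=(n_features, n_samples))
    return pd.DataFrame(
        data,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
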