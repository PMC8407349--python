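"""MAG filtering, genome-size normalization, copy-number-corrected densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fermquant.containers import AbundanceProfile, validate_sample_info
from fermquant.metagenome import (
    CopyNumberCorrector,
    absolute_genome_abundance,
    filter_high_quality_mags,
    mapping_rate,
    size_normalized_relative_abundance,
)
from fermquant.pipeline import fixture_mag_quality
from fermquant.simulate import (
    SimulationParams,
    sample_metagenome_counts,
    simulate_qpcr,
    simulate_timecourse,
)

from conftest import make_taxon


def make_registry(rows):
    frame = pd.DataFrame(
        rows, columns=["genome_id", "domain", "genome_size_bp", "marker_copies"]
    ).set_index("genome_id")
    frame["taxon_label"] = frame.index
    frame["source"] = "MAG"
    frame["marker_copies_estimated"] = False
    return frame


class TestMagFilter:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (95.0, 2.0, True),
            (89.9, 2.0, False),
            (90.0, 5.0, True),  # inclusive boundaries
            (95.0, 5.1, False),
        ],
    )
    def test_threshold_boundaries(self, completeness, contamination, kept):
        records = pd.DataFrame(
            {"completeness": [completeness], "contamination": [contamination]}, index=["m1"]
        )
        out = filter_high_quality_mags(records)
        assert ("m1" in out.index) is kept

    def test_fifteen_records_ten_kept(self):
        records = fixture_mag_quality()
        kept = filter_high_quality_mags(records)
        assert len(records) == 15
        assert len(kept) == 10
        assert list(kept.index) == [f"KG{i}" for i in range(1, 11)]

    def test_order_preserved(self):
        records = pd.DataFrame(
            {"completeness": [99, 50, 95], "contamination": [1, 1, 1]}, index=["a", "b", "c"]
        )
        assert list(filter_high_quality_mags(records).index) == ["a", "c"]


class TestSizeNormalization:
    def test_hand_computation_two_sizes(self):
        registry = make_registry([("A", "bacteria", 2_000_000, 1), ("B", "bacteria", 4_000_000, 1)])
        counts = pd.DataFrame({"s": [100, 100]}, index=["A", "B"])
        rel = size_normalized_relative_abundance(counts, registry)
        assert rel.data["s"].tolist() == pytest.approx([2 / 3, 1 / 3])
        assert rel.basis == "genomes"

    def test_equal_sizes_reduce_to_raw_proportions(self):
        registry = make_registry([("A", "bacteria", 3_000_000, 1), ("B", "bacteria", 3_000_000, 1)])
        counts = pd.DataFrame({"s": [30, 10]}, index=["A", "B"])
        rel = size_normalized_relative_abundance(counts, registry)
        assert rel.data["s"].tolist() == pytest.approx([0.75, 0.25])

    def test_single_genome_is_one(self):
        registry = make_registry([("A", "bacteria", 3_000_000, 1)])
        counts = pd.DataFrame({"s": [5]}, index=["A"])
        assert size_normalized_relative_abundance(counts, registry).data.loc["A", "s"] == 1.0

    def test_unknown_genome_named_in_error(self):
        registry = make_registry([("A", "bacteria", 3_000_000, 1)])
        counts = pd.DataFrame({"s": [5, 5]}, index=["A", "mystery"])
        with pytest.raises(ValueError, match="mystery"):
            size_normalized_relative_abundance(counts, registry)

    def test_domain_scope_restricts_and_renormalizes(self):
        registry = make_registry(
            [("A", "bacteria", 2_000_000, 1), ("B", "fungi", 2_000_000, 1), ("C", "bacteria", 2_000_000, 1)]
        )
        counts = pd.DataFrame({"s": [10, 100, 30]}, index=["A", "B", "C"])
        rel = size_normalized_relative_abundance(counts, registry, scope="bacteria")
        assert rel.data["s"].tolist() == pytest.approx([0.25, 0.75])
        assert rel.domain_scope == "bacteria"

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        registry = make_registry(
            [(f"g{i}", "bacteria", int(s), 1) for i, s in enumerate(rng.integers(1e6, 9e6, 6))]
        )
        counts = pd.DataFrame(
            rng.integers(0, 50, (6, 4)) + 1, index=registry.index, columns=list("wxyz")
        )
        rel = size_normalized_relative_abundance(counts, registry)
        assert np.allclose(rel.data.sum(axis=0), 1.0, atol=1e-9)


def _sample_table(qpcr_bacteria, qpcr_fungi=0.0, samples=("s1",)):
    frame = pd.DataFrame(
        {
            "day": range(0, 10 * len(samples), 10),
            "phase": ["meju_in"] * len(samples),
            "qpcr_bacteria": qpcr_bacteria,
            "qpcr_fungi": qpcr_fungi,
            "spike_in_reads": 1,
            "total_mrna_mapped_reads": 1,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return validate_sample_info(frame)


class TestAbsoluteGenomeAbundance:
    def test_uniform_copy_number_reduces_to_direct_division(self):
        # both genomes carry 5 marker copies: 0.5 × 4.8e7 / 5 = 4.8e6 genomes/ml
        registry = make_registry([("A", "bacteria", 2_400_000, 5), ("B", "bacteria", 2_400_000, 5)])
        rel = AbundanceProfile(
            pd.DataFrame({"s1": [0.5, 0.5]}, index=["A", "B"]),
            kind="relative", domain_scope="bacteria", basis="genomes",
        )
        out = absolute_genome_abundance(rel, _sample_table([4.8e7]), registry, "bacteria")
        assert out.data.loc["A", "s1"] == pytest.approx(4.8e6)
        assert out.kind == "genomes_per_ml"

    def test_unequal_copy_numbers_recover_equal_densities(self):
        # equal genome-proportional shares, copies 10 vs 1: the qPCR total is
        # 11d, and both corrected densities must equal d
        registry = make_registry([("A", "bacteria", 3_000_000, 10), ("B", "bacteria", 3_000_000, 1)])
        d = 1e6
        rel = AbundanceProfile(
            pd.DataFrame({"s1": [0.5, 0.5]}, index=["A", "B"]),
            kind="relative", domain_scope="bacteria", basis="genomes",
        )
        out = absolute_genome_abundance(rel, _sample_table([11 * d]), registry, "bacteria")
        assert out.data.loc["A", "s1"] == pytest.approx(d)
        assert out.data.loc["B", "s1"] == pytest.approx(d)

    def test_copy_basis_profile_uses_direct_per_genome_division(self):
        # amplicon-derived shares are already copy-proportional: d*10 : d*1
        registry = make_registry([("A", "bacteria", 3_000_000, 10), ("B", "bacteria", 3_000_000, 1)])
        d = 1e6
        rel = AbundanceProfile(
            pd.DataFrame({"s1": [10 / 11, 1 / 11]}, index=["A", "B"]),
            kind="relative", domain_scope="bacteria", basis="marker_copies",
        )
        out = absolute_genome_abundance(rel, _sample_table([11 * d]), registry, "bacteria")
        assert out.data.loc["A", "s1"] == pytest.approx(d)
        assert out.data.loc["B", "s1"] == pytest.approx(d)

    def test_zero_share_stays_zero(self):
        registry = make_registry([("A", "bacteria", 3_000_000, 2), ("B", "bacteria", 3_000_000, 4)])
        rel = AbundanceProfile(
            pd.DataFrame({"s1": [1.0, 0.0]}, index=["A", "B"]),
            kind="relative", domain_scope="bacteria", basis="genomes",
        )
        out = absolute_genome_abundance(rel, _sample_table([1e6]), registry, "bacteria")
        assert out.data.loc["B", "s1"] == 0.0

    def test_missing_marker_copies_errors(self):
        registry = make_registry([("A", "bacteria", 3_000_000, 2)])
        rel = AbundanceProfile(
            pd.DataFrame({"s1": [0.5, 0.5]}, index=["A", "B"]),
            kind="relative", domain_scope="bacteria", basis="genomes",
        )
        with pytest.raises(ValueError, match="B"):
            absolute_genome_abundance(rel, _sample_table([1e6]), registry, "bacteria")

    def test_full_community_profile_restricted_to_domain(self):
        registry = make_registry(
            [("A", "bacteria", 2e6, 2), ("B", "bacteria", 2e6, 2), ("F", "fungi", 2e7, 1)]
        )
        rel = AbundanceProfile(
            pd.DataFrame({"s1": [0.45, 0.45, 0.10]}, index=["A", "B", "F"]),
            kind="relative", domain_scope="all", basis="genomes",
        )
        out = absolute_genome_abundance(rel, _sample_table([4e6], [1e5]), registry, "bacteria")
        # within-domain shares are 0.5/0.5; both genomes: 0.5 * 4e6 / 2 = 1e6
        assert out.data.loc["A", "s1"] == pytest.approx(1e6)
        assert "F" not in out.data.index

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.01, max_value=100.0), st.integers(min_value=0, max_value=10_000))
    def test_correction_invariant_to_profile_rescaling(self, scale, seed):
        # restricting + renormalizing cancels: the corrector gives the same
        # densities for any positive rescaling of the domain profile
        rng = np.random.default_rng(seed)
        registry = make_registry(
            [(f"g{i}", "bacteria", 3_000_000, int(c)) for i, c in enumerate(rng.integers(1, 11, 5))]
        )
        shares = rng.dirichlet(np.ones(5))
        samples = _sample_table([3.3e7])
        corrector = CopyNumberCorrector(registry=registry, samples=samples, domain="bacteria").fit()
        rel = AbundanceProfile(
            pd.DataFrame({"s1": shares}, index=registry.index),
            kind="relative", domain_scope="bacteria", basis="genomes",
        )
        base = corrector.transform(rel).data
        # rescaled profile enters through the unnormalized pathway
        raw = pd.DataFrame({"s1": shares * scale}, index=registry.index)
        mc = registry["marker_copies"].astype(float)
        manual = raw["s1"] * 3.3e7 / (raw["s1"] * mc).sum()
        assert np.allclose(base["s1"], manual, rtol=1e-9)

    def test_end_to_end_recovery_from_simulated_counts(self):
        # equal true densities, copies 10 vs 1, fed through the simulator and
        # the full metagenome chain: estimates agree within sampling error
        taxa = [
            make_taxon("A", copies=10, n0=1e6, r=0.0),
            make_taxon("B", copies=1, n0=1e6, r=0.0),
        ]
        params = SimulationParams(taxa=taxa, sample_days=(0,), qpcr_cv=0.0, seed=21)
        truth = simulate_timecourse(params)
        counts = sample_metagenome_counts(truth, 200_000)
        qpcr = simulate_qpcr(truth)
        samples = _sample_table([qpcr.loc["D000", "qpcr_bacteria"]], samples=("D000",))
        rel = size_normalized_relative_abundance(counts, truth.registry, scope="bacteria")
        out = absolute_genome_abundance(rel, samples, truth.registry, "bacteria")
        assert out.data.loc["A", "D000"] == pytest.approx(1e6, rel=0.05)
        assert out.data.loc["B", "D000"] == pytest.approx(1e6, rel=0.05)


class TestMappingRate:
    def test_fraction(self):
        assert mapping_rate(915, 1000) == pytest.approx(0.915)

    def test_bounds(self):
        assert mapping_rate(0, 10) == 0.0
        assert mapping_rate(10, 10) == 1.0

    def test_mapped_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            mapping_rate(11, 10)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            mapping_rate(0, 0)
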