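"""RPKM, spike-in scale factors, normalization and per-taxon expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fermquant.containers import ExpressionMatrix, validate_sample_info
from fermquant.simulate import SimulationParams, sample_metatranscriptome_counts, simulate_timecourse
from fermquant.transcriptome import (
    SpikeInNormalizer,
    normalize_expression,
    relative_expression_by_taxon,
    rpkm,
    scale_to_reference_sample,
    spikein_scale_factors,
    taxon_expression_totals,
)

from conftest import make_taxon


def make_annotations(rows):
    frame = pd.DataFrame(rows, columns=["gene_id", "genome_id", "length_bp"]).set_index("gene_id")
    frame["ko_id"] = ""
    frame["kegg_level2"] = ""
    frame["kegg_level3"] = ""
    return frame


def make_samples(total_reads, spike_reads=None, samples=None):
    samples = samples or [f"s{i + 1}" for i in range(len(total_reads))]
    spike_reads = spike_reads or [100] * len(total_reads)
    frame = pd.DataFrame(
        {
            "day": [10 * i for i in range(len(samples))],
            "phase": "meju_in",
            "qpcr_bacteria": 1e6,
            "qpcr_fungi": 1e4,
            "spike_in_reads": spike_reads,
            "total_mrna_mapped_reads": total_reads,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return validate_sample_info(frame)


class TestRpkm:
    def test_unit_case(self):
        ann = make_annotations([("g1", "G", 1000)])
        counts = pd.DataFrame({"s1": [10]}, index=["g1"])
        out = rpkm(counts, ann, make_samples([1_000_000]))
        assert out.data.loc["g1", "s1"] == pytest.approx(10.0)

    def test_direct_evaluation(self):
        ann = make_annotations([("g1", "G", 500)])
        counts = pd.DataFrame({"s1": [6]}, index=["g1"])
        out = rpkm(counts, ann, make_samples([2_000_000]))
        assert out.data.loc["g1", "s1"] == pytest.approx(6.0)

    def test_zero_counts_zero_rpkm(self):
        ann = make_annotations([("g1", "G", 800)])
        counts = pd.DataFrame({"s1": [0]}, index=["g1"])
        out = rpkm(counts, ann, make_samples([1_000]))
        assert out.data.loc["g1", "s1"] == 0.0

    def test_zero_library_with_nonzero_counts_rejected(self):
        ann = make_annotations([("g1", "G", 800)])
        counts = pd.DataFrame({"s1": [5]}, index=["g1"])
        with pytest.raises(ValueError, match="s1"):
            rpkm(counts, ann, make_samples([0]))

    def test_library_smaller_than_column_sum_rejected(self):
        ann = make_annotations([("g1", "G", 800), ("g2", "G", 400)])
        counts = pd.DataFrame({"s1": [5, 6]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="s1"):
            rpkm(counts, ann, make_samples([10]))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_samples = int(rng.integers(2, 20)), int(rng.integers(1, 6))
        counts = pd.DataFrame(
            rng.integers(0, 100, (n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j + 1}" for j in range(n_samples)],
        )
        lengths = rng.integers(100, 5000, n_genes)
        ann = make_annotations([(f"g{i}", "G", int(lengths[i])) for i in range(n_genes)])
        libs = counts.sum(axis=0).to_numpy() + rng.integers(1, 1000, n_samples)
        out = rpkm(counts, ann, make_samples(list(libs)))
        for i in range(n_genes):
            for j in range(n_samples):
                expected = counts.iloc[i, j] / (lengths[i] / 1000) / (libs[j] / 1e6)
                assert out.data.iloc[i, j] == pytest.approx(expected, abs=1e-12)


class TestSpikeFactors:
    def test_identical_fractions_give_unit_factors(self):
        samples = make_samples([1_000_000, 2_000_000], spike_reads=[100, 200])
        factors = spikein_scale_factors(samples, "s1")
        assert np.allclose(factors, 1.0)

    def test_half_spike_fraction_doubles_factor(self):
        # sample with half the reference's spike fraction has twice the RNA pool
        samples = make_samples([1_000_000, 1_000_000], spike_reads=[100, 50])
        factors = spikein_scale_factors(samples, "s1")
        assert factors["s2"] == pytest.approx(2.0)

    def test_reference_factor_is_one(self):
        samples = make_samples([5_000, 9_999, 123_456], spike_reads=[7, 11, 13])
        for ref in ("s1", "s2", "s3"):
            assert spikein_scale_factors(samples, ref)[ref] == 1.0

    def test_raw_count_variant(self):
        samples = make_samples([1_000_000, 500_000], spike_reads=[100, 400])
        factors = spikein_scale_factors(samples, "s1", variant="raw_count")
        assert factors["s2"] == pytest.approx(0.25)

    def test_zero_spike_reads_named(self):
        samples = make_samples([1000, 1000], spike_reads=[100, 0])
        with pytest.raises(ValueError, match="s2"):
            spikein_scale_factors(samples, "s1")

    def test_unknown_reference_rejected(self):
        samples = make_samples([1000])
        with pytest.raises(ValueError, match="nope"):
            spikein_scale_factors(samples, "nope")


class TestNormalization:
    def test_unit_factors_identity(self):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["g1", "g2"]))
        out = normalize_expression(expr, pd.Series({"s1": 1.0}))
        pd.testing.assert_frame_equal(out.data, expr.data)
        assert out.normalized

    def test_renormalization_refused(self):
        expr = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["g1"]))
        once = normalize_expression(expr, pd.Series({"s1": 2.0}))
        with pytest.raises(ValueError, match="already"):
            normalize_expression(once, pd.Series({"s1": 2.0}))

    def test_single_sample_as_own_reference_unchanged(self):
        samples = make_samples([1_000_000], spike_reads=[250])
        expr = ExpressionMatrix(pd.DataFrame({"s1": [3.5]}, index=["g1"]))
        out = SpikeInNormalizer(samples=samples, reference_sample="s1").fit().transform(expr)
        assert out.data.loc["g1", "s1"] == pytest.approx(3.5)
        assert out.reference_sample == "s1"

    def test_depth_invariance_exact(self):
        # scaling one sample's counts, spike reads and library by c leaves its
        # normalized expression unchanged to 1e-9 relative
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            {"a": rng.integers(0, 50, 10), "b": rng.integers(0, 50, 10)},
            index=[f"g{i}" for i in range(10)],
        )
        c = 7
        counts["b"] = counts["a"] * c
        ann = make_annotations([(f"g{i}", "G", int(l)) for i, l in
                                enumerate(rng.integers(200, 3000, 10))])
        samples = make_samples([10_000, 10_000 * c], spike_reads=[40, 40 * c],
                               samples=["a", "b"])
        expr = rpkm(counts, ann, samples)
        factors = spikein_scale_factors(samples, "a")
        out = normalize_expression(expr, factors)
        ratio = out.data["b"] / out.data["a"].replace(0, np.nan)
        assert np.allclose(ratio.dropna(), 1.0, rtol=1e-9)

    def test_simulator_depth_doubling_recovers_same_totals(self):
        # two samples drawn from identical transcript pools at 1x and 2x depth:
        # spike-normalized per-taxon totals agree within sampling error
        taxa = [make_taxon("A", r=0.0, genes=30), make_taxon("B", r=0.0, n0=3e5, genes=30)]
        params = SimulationParams(taxa=taxa, sample_days=(0, 20), seed=13)
        truth = simulate_timecourse(params)
        assert np.allclose(truth.transcript_weight["D000"], truth.transcript_weight["D020"])
        counts1, spike1 = sample_metatranscriptome_counts(truth, 100_000)
        counts2, spike2 = sample_metatranscriptome_counts(truth, 200_000)
        ann = truth.genes.drop(columns=["expression_weight"])
        counts = pd.DataFrame({"x1": counts1.data["D000"], "x2": counts2.data["D000"]})
        samples = make_samples(
            [int(counts1.data["D000"].sum()), int(counts2.data["D000"].sum())],
            spike_reads=[int(spike1["D000"]), int(spike2["D000"])],
            samples=["x1", "x2"],
        )
        expr = rpkm(counts, ann, samples)
        out = normalize_expression(expr, spikein_scale_factors(samples, "x1"))
        totals = taxon_expression_totals(out, ann)
        rel_diff = (totals["x2"] - totals["x1"]).abs() / totals["x1"]
        assert (rel_diff < 0.1).all()


class TestTaxonShares:
    def test_all_reads_one_genome(self):
        ann = make_annotations([("g1", "A", 500), ("g2", "B", 500)])
        counts = pd.DataFrame({"s1": [9, 0]}, index=["g1", "g2"])
        shares = relative_expression_by_taxon(counts, ann)
        assert shares.data.loc["A", "s1"] == 1.0

    def test_hand_sum(self):
        ann = make_annotations([("g1", "A", 500), ("g2", "A", 500), ("g3", "B", 500)])
        counts = pd.DataFrame({"s1": [10, 20, 70]}, index=["g1", "g2", "g3"])
        shares = relative_expression_by_taxon(counts, ann)
        assert shares.data.loc["A", "s1"] == pytest.approx(0.3)
        assert shares.data.loc["B", "s1"] == pytest.approx(0.7)

    def test_gene_order_invariance(self):
        ann = make_annotations([("g1", "A", 500), ("g2", "B", 500), ("g3", "A", 500)])
        counts = pd.DataFrame({"s1": [5, 10, 15]}, index=["g1", "g2", "g3"])
        a = relative_expression_by_taxon(counts, ann)
        b = relative_expression_by_taxon(counts.iloc[::-1], ann)
        pd.testing.assert_frame_equal(a.data.sort_index(), b.data.sort_index())

    def test_empty_sample_flagged(self):
        ann = make_annotations([("g1", "A", 500)])
        counts = pd.DataFrame({"ok": [3], "dead": [0]}, index=["g1"])
        shares = relative_expression_by_taxon(counts, ann)
        assert "dead" in shares.empty_samples
        assert shares.data.loc["A", "dead"] == 0.0

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(3)
        ann = make_annotations([(f"g{i}", f"G{i % 4}", 500) for i in range(12)])
        counts = pd.DataFrame(
            rng.integers(1, 40, (12, 3)), index=ann.index, columns=["a", "b", "c"]
        )
        shares = relative_expression_by_taxon(counts, ann)
        assert np.allclose(shares.data.sum(axis=0), 1.0, atol=1e-12)


class TestReferenceScaling:
    def test_reference_column_sums_to_one(self):
        totals = pd.DataFrame({"ref": [3.0, 1.0], "other": [6.0, 2.0]}, index=["A", "B"])
        out = scale_to_reference_sample(totals, "ref")
        assert out["ref"].sum() == pytest.approx(1.0)
        assert out["other"].sum() == pytest.approx(2.0)

    def test_half_total_gives_half_column_sum(self):
        totals = pd.DataFrame({"ref": [4.0], "half": [2.0]}, index=["A"])
        out = scale_to_reference_sample(totals, "ref")
        assert out["half"].sum() == pytest.approx(0.5)

    def test_zero_reference_total_rejected(self):
        totals = pd.DataFrame({"ref": [0.0], "other": [2.0]}, index=["A"])
        with pytest.raises(ValueError, match="zero"):
            scale_to_reference_sample(totals, "ref")

    def test_missing_reference_rejected(self):
        totals = pd.DataFrame({"a": [1.0]}, index=["A"])
        with pytest.raises(ValueError, match="nope"):
            scale_to_reference_sample(totals, "nope")
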