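"""Metatranscriptome quantification: RPKM, spike-in scale factors, per-taxon
expression shares and reference-sample-relative totals.

RPKM (reads per kilobase of coding sequence per million mapped reads) removes
gene-length and library-size bias within a sample but says nothing about the
absolute transcript pool across samples.  Because a constant mass of foreign
spike-in RNA was added to every sample before extraction, the spike's share of
sequenced reads is inversely related to the sample's total mRNA mass: samples
with a small spike fraction have large transcript pools.  Dividing the
reference sample's spike fraction by each sample's spike fraction yields a
cross-sample scale factor that puts RPKM values on a common, mass-comparable
scale (factor(reference) = 1 by construction).
"""

from __future__ import annotations

from typing import Optional, Union

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .containers import (
    AbundanceProfile,
    ExpressionMatrix,
    FeatureCountMatrix,
    validate_gene_annotations,
)

__all__ = [
    "RpkmCalculator",
    "SpikeInNormalizer",
    "rpkm",
    "spikein_scale_factors",
    "normalize_expression",
    "relative_expression_by_taxon",
    "taxon_expression_totals",
    "scale_to_reference_sample",
]


def _gene_counts(counts: Union[FeatureCountMatrix, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(counts, FeatureCountMatrix):
        return counts.data
    return FeatureCountMatrix(counts, feature_kind="gene").data


class RpkmCalculator(TransformerMixin, BaseEstimator):
    """Per-gene RPKM from mRNA-mapped counts, gene lengths and library sizes.

    value(g, s) = count(g,s) / (length_bp_g / 1000) / (total_mapped(s) / 1e6)

    The per-sample denominator is ``total_mrna_mapped_reads`` from the sample
    metadata — mRNA reads mapped to the reference genomes, excluding spike-in
    and unmapped reads.
    """

    def __init__(self, annotations: Optional[pd.DataFrame] = None, samples: Optional[pd.DataFrame] = None):
        self.annotations = annotations
        self.samples = samples

    def fit(self, X=None, y=None):
        if self.annotations is None or self.samples is None:
            raise ValueError("RpkmCalculator requires gene annotations and a sample table")
        validate_gene_annotations(self.annotations)
        self.length_kb_ = self.annotations["length_bp"].astype(float) / 1000.0
        self.library_size_ = self.samples["total_mrna_mapped_reads"].astype(float)
        return self

    def transform(self, counts: Union[FeatureCountMatrix, pd.DataFrame]) -> ExpressionMatrix:
        if not hasattr(self, "length_kb_"):
            raise NotFittedError("RpkmCalculator is not fitted; call fit first")
        data = _gene_counts(counts)
        unknown = sorted(set(data.index) - set(self.length_kb_.index))
        if unknown:
            raise ValueError(f"genes without a length annotation: {unknown}")
        missing = [s for s in data.columns if s not in self.library_size_.index]
        if missing:
            raise ValueError(f"samples missing from the metadata table: {missing}")
        lib = self.library_size_.reindex(data.columns)
        colsum = data.sum(axis=0)
        too_small = [s for s in data.columns if lib[s] < colsum[s]]
        if too_small:
            raise ValueError(
                f"total_mrna_mapped_reads smaller than the column sum for sample(s): {too_small}"
            )
        zero_bad = [s for s in data.columns if lib[s] == 0 and colsum[s] > 0]
        if zero_bad:
            raise ValueError(f"zero total mapped reads with nonzero counts for sample(s): {zero_bad}")
        per_kb = data.div(self.length_kb_.reindex(data.index), axis=0)
        values = per_kb.div((lib / 1e6).replace(0, 1), axis=1)
        return ExpressionMatrix(values.astype(float), normalized=False)


class SpikeInNormalizer(TransformerMixin, BaseEstimator):
    """Cross-sample expression normalization anchored on spike-in reads.

    ``fit`` computes per-sample scale factors from the sample table:

    - ``variant="fraction"`` (default): factor(s) = spike_fraction(reference) /
      spike_fraction(s) with spike_fraction = spike reads / total mapped mRNA
      reads — robust to library-size differences;
    - ``variant="raw_count"``: factor(s) = spike_reads(reference) /
      spike_reads(s).

    ``transform`` multiplies each sample's RPKM column by its factor and
    records the factors and reference on the output; re-normalizing an
    already-normalized matrix is refused.
    """

    def __init__(
        self,
        samples: Optional[pd.DataFrame] = None,
        reference_sample: Optional[str] = None,
        variant: str = "fraction",
    ):
        self.samples = samples
        self.reference_sample = reference_sample
        self.variant = variant

    def fit(self, X=None, y=None):
        if self.samples is None:
            raise ValueError("SpikeInNormalizer requires a sample metadata table")
        if self.variant not in ("fraction", "raw_count"):
            raise ValueError(f"variant must be 'fraction' or 'raw_count', got {self.variant!r}")
        if self.reference_sample is None:
            raise ValueError("SpikeInNormalizer requires a reference sample")
        if self.reference_sample not in self.samples.index:
            raise ValueError(f"reference sample {self.reference_sample!r} not in the sample table")
        spike = self.samples["spike_in_reads"].astype(float)
        zero = spike.index[spike == 0].tolist()
        if zero:
            raise ValueError(f"zero spike-in reads for sample(s) {zero}: normalization undefined")
        if self.variant == "fraction":
            total = self.samples["total_mrna_mapped_reads"].astype(float)
            zero_lib = total.index[total == 0].tolist()
            if zero_lib:
                raise ValueError(f"zero mapped mRNA reads for sample(s) {zero_lib}: spike fraction undefined")
            frac = spike / total  # spike reads per mapped mRNA read
            self.scale_factors_ = frac[self.reference_sample] / frac
        else:
            self.scale_factors_ = spike[self.reference_sample] / spike
        self.scale_factors_ = self.scale_factors_.rename("scale_factor")
        return self

    def transform(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        if not hasattr(self, "scale_factors_"):
            raise NotFittedError("SpikeInNormalizer is not fitted; call fit first")
        if expr.normalized:
            raise ValueError("expression matrix is already spike-in normalized")
        missing = [s for s in expr.data.columns if s not in self.scale_factors_.index]
        if missing:
            raise ValueError(f"no scale factor for sample(s): {missing}")
        factors = self.scale_factors_.reindex(expr.data.columns)
        return ExpressionMatrix(
            expr.data.mul(factors, axis=1),
            normalized=True,
            scale_factors=factors,
            reference_sample=self.reference_sample,
        )


def rpkm(
    counts: Union[FeatureCountMatrix, pd.DataFrame],
    annotations: pd.DataFrame,
    samples: pd.DataFrame,
) -> ExpressionMatrix:
    """Per-gene RPKM; see :class:`RpkmCalculator`."""
    return RpkmCalculator(annotations=annotations, samples=samples).fit().transform(counts)


def spikein_scale_factors(
    samples: pd.DataFrame, reference_sample: str, variant: str = "fraction"
) -> pd.Series:
    """Per-sample spike-in scale factors; see :class:`SpikeInNormalizer`."""
    norm = SpikeInNormalizer(samples=samples, reference_sample=reference_sample, variant=variant)
    return norm.fit().scale_factors_


def normalize_expression(expr: ExpressionMatrix, factors: pd.Series, reference_sample: Optional[str] = None) -> ExpressionMatrix:
    """Apply precomputed per-sample scale factors to an RPKM matrix."""
    if expr.normalized:
        raise ValueError("expression matrix is already spike-in normalized")
    missing = [s for s in expr.data.columns if s not in factors.index]
    if missing:
        raise ValueError(f"no scale factor for sample(s): {missing}")
    if (factors <= 0).any():
        raise ValueError("scale factors must be positive")
    aligned = factors.reindex(expr.data.columns)
    return ExpressionMatrix(
        expr.data.mul(aligned, axis=1),
        normalized=True,
        scale_factors=aligned,
        reference_sample=reference_sample,
    )


def relative_expression_by_taxon(
    counts: Union[FeatureCountMatrix, pd.DataFrame], annotations: pd.DataFrame
) -> AbundanceProfile:
    """Per-genome shares of mRNA-mapped reads per sample.

    share(G, s) = Σ_{genes of G} count(g,s) / column sum; shares sum to 1 per
    sample, and empty samples are carried through as flagged all-zero columns.
    """
    data = _gene_counts(counts)
    unknown = sorted(set(data.index) - set(annotations.index))
    if unknown:
        raise ValueError(f"genes without a genome annotation: {unknown}")
    genome = annotations["genome_id"].reindex(data.index)
    by_taxon = data.groupby(genome).sum()
    by_taxon.index.name = "genome_id"
    colsum = by_taxon.sum(axis=0)
    empty = tuple(colsum.index[colsum == 0])
    shares = by_taxon.div(colsum.replace(0, 1), axis=1).astype(float)
    return AbundanceProfile(
        shares, kind="relative", domain_scope="all", basis="transcripts", empty_samples=empty
    )


def taxon_expression_totals(expr: ExpressionMatrix, annotations: pd.DataFrame) -> pd.DataFrame:
    """Summed (normalized) RPKM per genome per sample."""
    unknown = sorted(set(expr.data.index) - set(annotations.index))
    if unknown:
        raise ValueError(f"genes without a genome annotation: {unknown}")
    genome = annotations["genome_id"].reindex(expr.data.index)
    totals = expr.data.groupby(genome).sum()
    totals.index.name = "genome_id"
    return totals


def scale_to_reference_sample(totals: pd.DataFrame, reference_sample: str) -> pd.DataFrame:
    """Express per-taxon totals relative to the reference sample's grand total.

    output(G, s) = totals(G, s) / Σ_G totals(G, reference); the reference
    sample's column sums to 1 by construction.
    """
    if reference_sample not in totals.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in the totals table")
    grand = float(totals[reference_sample].sum())
    if grand <= 0:
        raise ValueError(f"reference sample {reference_sample!r} has zero grand total")
    return totals / grand
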