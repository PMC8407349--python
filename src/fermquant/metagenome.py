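"""Metagenome quantification: MAG quality filter, genome-size normalization,
copy-number-corrected absolute genome densities.

Shotgun read counts observe the community in nucleotide space: a genome's read
share is proportional to density × genome size.  Dividing counts by genome size
recovers genome-proportional relative abundances (``basis="genomes"``).
Anchoring those to the domain-specific qPCR total (marker copies/ml) requires
first re-expressing the profile in marker-copy space — each genome's share is
weighted by its marker copy number — and then dividing each genome's copies/ml
by its per-genome copy number, which recovers genomes/ml:

    density_g = rel_g × qpcr_domain / Σ_i rel_i × marker_copies_i

For amplicon-derived profiles (already marker-copy proportional) the conversion
reduces to the direct per-genome division rel_g × qpcr / marker_copies_g.
"""

from __future__ import annotations

from typing import Optional, Union

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .containers import (
    AbundanceProfile,
    FeatureCountMatrix,
    validate_genome_registry,
    validate_sample_info,
)

__all__ = [
    "MagQualityFilter",
    "GenomeSizeNormalizer",
    "CopyNumberCorrector",
    "filter_high_quality_mags",
    "size_normalized_relative_abundance",
    "absolute_genome_abundance",
    "mapping_rate",
]


class MagQualityFilter(TransformerMixin, BaseEstimator):
    """Keep metagenome-assembled genomes meeting completeness/contamination cuts.

    Thresholds are inclusive: completeness >= ``min_completeness`` percent and
    contamination <= ``max_contamination`` percent.  Record order is preserved.
    """

    def __init__(self, min_completeness: float = 90.0, max_contamination: float = 5.0):
        self.min_completeness = min_completeness
        self.max_contamination = max_contamination

    def fit(self, X=None, y=None):
        if not 0 <= self.min_completeness <= 100:
            raise ValueError("min_completeness must be in [0, 100]")
        if self.max_contamination < 0:
            raise ValueError("max_contamination must be >= 0")
        self.fitted_ = True
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "fitted_"):
            raise NotFittedError("MagQualityFilter is not fitted; call fit first")
        for col in ("completeness", "contamination"):
            if col not in records.columns:
                raise ValueError(f"MAG quality table missing column {col!r}")
        if (records["completeness"] > 100).any():
            bad = records.index[records["completeness"] > 100].tolist()
            raise ValueError(f"completeness above 100% for {bad}")
        keep = (records["completeness"] >= self.min_completeness) & (
            records["contamination"] <= self.max_contamination
        )
        return records.loc[keep]


class GenomeSizeNormalizer(TransformerMixin, BaseEstimator):
    """Genome-size-normalized relative abundance of genome-mapped read counts.

    value(g, s) = (count(g,s)/size_g) / Σ_{g' in scope} count(g',s)/size_{g'}

    Parameters
    ----------
    registry : pandas.DataFrame
        Genome registry (index genome_id) with ``genome_size_bp`` and
        ``domain`` columns.
    scope : {"all", "bacteria", "fungi"}
        Restrict and renormalize to one domain, or keep the full community.
    """

    def __init__(self, registry: Optional[pd.DataFrame] = None, scope: str = "all"):
        self.registry = registry
        self.scope = scope

    def fit(self, X=None, y=None):
        if self.registry is None:
            raise ValueError("GenomeSizeNormalizer requires a genome registry")
        validate_genome_registry(self.registry)
        if self.scope not in ("all", "bacteria", "fungi"):
            raise ValueError(f"scope must be all/bacteria/fungi, got {self.scope!r}")
        self.sizes_ = self.registry["genome_size_bp"].astype(float)
        return self

    def transform(self, counts: Union[FeatureCountMatrix, pd.DataFrame]) -> AbundanceProfile:
        if not hasattr(self, "sizes_"):
            raise NotFittedError("GenomeSizeNormalizer is not fitted; call fit first")
        data = counts.data if isinstance(counts, FeatureCountMatrix) else FeatureCountMatrix(counts).data
        unknown = sorted(set(data.index) - set(self.registry.index))
        if unknown:
            raise ValueError(f"count features without a genome registry entry: {unknown}")
        if self.scope != "all":
            members = [g for g in data.index if self.registry.loc[g, "domain"] == self.scope]
            data = data.loc[members]
        per_genome = data.div(self.sizes_.reindex(data.index), axis=0)
        colsum = per_genome.sum(axis=0)
        empty = tuple(colsum.index[colsum == 0])
        rel = per_genome.div(colsum.replace(0, 1), axis=1)
        return AbundanceProfile(
            rel, kind="relative", domain_scope=self.scope, basis="genomes", empty_samples=empty
        )


class CopyNumberCorrector(TransformerMixin, BaseEstimator):
    """Convert a domain relative profile plus its qPCR anchor to genomes/ml.

    ``fit`` stores the per-sample qPCR anchors and per-genome marker copy
    numbers.  ``transform`` accepts a relative profile; if it spans the whole
    community it is first restricted to the domain and renormalized.  The
    copy-number division is applied on the scale the profile's ``basis``
    declares (see module docstring), so both amplicon-derived and
    size-normalized shotgun profiles recover the same genome densities.
    """

    def __init__(
        self,
        registry: Optional[pd.DataFrame] = None,
        samples: Optional[pd.DataFrame] = None,
        domain: str = "bacteria",
        meju_removal_day: int = 60,
    ):
        self.registry = registry
        self.samples = samples
        self.domain = domain
        self.meju_removal_day = meju_removal_day

    def fit(self, X=None, y=None):
        if self.registry is None or self.samples is None:
            raise ValueError("CopyNumberCorrector requires a genome registry and sample table")
        validate_genome_registry(self.registry)
        validate_sample_info(self.samples, meju_removal_day=self.meju_removal_day)
        if self.domain not in ("bacteria", "fungi"):
            raise ValueError(f"domain must be bacteria or fungi, got {self.domain!r}")
        self.qpcr_ = self.samples[f"qpcr_{self.domain}"].astype(float)
        self.marker_copies_ = self.registry["marker_copies"].astype(float)
        return self

    def transform(self, rel: AbundanceProfile) -> AbundanceProfile:
        if not hasattr(self, "qpcr_"):
            raise NotFittedError("CopyNumberCorrector is not fitted; call fit first")
        if rel.kind != "relative":
            raise ValueError(f"expected a relative profile, got kind={rel.kind!r}")
        data = rel.data
        if rel.domain_scope == "all":
            members = [g for g in data.index if self.registry.loc[g, "domain"] == self.domain]
            data = data.loc[members]
            colsum = data.sum(axis=0)
            empty = tuple(set(rel.empty_samples) | set(colsum.index[colsum == 0]))
            data = data.div(colsum.replace(0, 1), axis=1)
        elif rel.domain_scope == self.domain:
            empty = tuple(rel.empty_samples)
        else:
            raise ValueError(
                f"profile scope {rel.domain_scope!r} does not match corrector domain {self.domain!r}"
            )
        missing_q = [s for s in data.columns if s not in self.qpcr_.index or pd.isna(self.qpcr_.get(s))]
        if missing_q:
            raise ValueError(f"missing qPCR value for sample(s): {missing_q}")
        missing_mc = sorted(set(data.index) - set(self.marker_copies_.index))
        if missing_mc:
            raise ValueError(f"missing marker copy number for genome(s): {missing_mc}")
        mc = self.marker_copies_.reindex(data.index)
        qpcr = self.qpcr_.reindex(data.columns)
        if rel.basis == "genomes":
            # re-express in marker-copy space, anchor, divide per-genome copies:
            # rel_g qpcr / Σ rel_i mc_i
            mean_copies = data.mul(mc, axis=0).sum(axis=0)
            density = data.mul(qpcr, axis=1).div(mean_copies.replace(0, 1), axis=1)
        else:  # marker-copy proportional already
            density = data.mul(qpcr, axis=1).div(mc, axis=0)
        return AbundanceProfile(
            density,
            kind="genomes_per_ml",
            domain_scope=self.domain,
            basis="genomes",
            empty_samples=empty,
        )


def filter_high_quality_mags(
    records: pd.DataFrame, min_completeness: float = 90.0, max_contamination: float = 5.0
) -> pd.DataFrame:
    """Inclusive completeness/contamination filter; see :class:`MagQualityFilter`."""
    return MagQualityFilter(min_completeness, max_contamination).fit().transform(records)


def size_normalized_relative_abundance(
    counts: Union[FeatureCountMatrix, pd.DataFrame], registry: pd.DataFrame, scope: str = "all"
) -> AbundanceProfile:
    """Genome-size-normalized relative abundances; see :class:`GenomeSizeNormalizer`."""
    return GenomeSizeNormalizer(registry=registry, scope=scope).fit().transform(counts)


def absolute_genome_abundance(
    rel: AbundanceProfile,
    samples: pd.DataFrame,
    registry: pd.DataFrame,
    domain: str,
    meju_removal_day: int = 60,
) -> AbundanceProfile:
    """qPCR-anchored, copy-number-corrected genome densities (genomes/ml)."""
    corrector = CopyNumberCorrector(
        registry=registry, samples=samples, domain=domain, meju_removal_day=meju_removal_day
    )
    return corrector.fit().transform(rel)


def mapping_rate(mapped_reads: int, total_reads: int) -> float:
    """Fraction of reads mapped to the reference genomes."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if mapped_reads < 0 or mapped_reads > total_reads:
        raise ValueError(f"mapped_reads {mapped_reads} outside [0, {total_reads}]")
    return mapped_reads / total_reads
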