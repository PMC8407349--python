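"""Amplicon quantification: relative abundance, coverage/diversity, qPCR anchoring.

Marker-gene (16S rRNA / ITS) amplicon counts observe the community in
marker-copy space: a taxon's read share is proportional to density × per-genome
marker copies.  Relative profiles computed here therefore carry
``basis="marker_copies"``, and multiplying a sample's profile by its domain
qPCR total (copies/ml) yields absolute marker-copy abundances whose column
sums reproduce the qPCR value exactly.

The transform-shaped steps are exposed as scikit-learn estimators
(:class:`RelativeAbundance`, :class:`QpcrAbsoluteScaler`); the module-level
functions are thin wrappers over them.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .containers import AbundanceProfile, FeatureCountMatrix, validate_sample_info

__all__ = [
    "RelativeAbundance",
    "QpcrAbsoluteScaler",
    "relative_abundance",
    "goods_coverage",
    "diversity_indices",
    "absolute_marker_abundance",
]


def _as_count_frame(X: Union[FeatureCountMatrix, pd.DataFrame]) -> tuple:
    if isinstance(X, FeatureCountMatrix):
        return X.data, X.feature_kind
    fcm = FeatureCountMatrix(X, feature_kind="amplicon_taxon")  # validates counts
    return fcm.data, "amplicon_taxon"


class RelativeAbundance(TransformerMixin, BaseEstimator):
    """Convert a feature count table to per-sample proportions.

    All-zero sample columns are carried through as all-zero and flagged in the
    output profile's ``empty_samples`` rather than dropped: a time course may
    legitimately contain failed libraries.

    Parameters
    ----------
    domain_scope : {"all", "bacteria", "fungi"}
        Recorded scope of the profile (the counts are assumed already
        restricted to this scope).
    basis : {"marker_copies", "genomes"}
        Physical quantity the proportions track; amplicon counts are
        marker-copy proportional, size-normalized shotgun counts are
        genome proportional.
    """

    def __init__(self, domain_scope: str = "all", basis: str = "marker_copies"):
        self.domain_scope = domain_scope
        self.basis = basis

    def fit(self, X, y=None):
        data, _ = _as_count_frame(X)
        self.n_features_in_ = data.shape[0]
        return self

    def transform(self, X) -> AbundanceProfile:
        if not hasattr(self, "n_features_in_"):
            raise NotFittedError("RelativeAbundance is not fitted; call fit first")
        data, _ = _as_count_frame(X)
        if data.shape[0] == 0:
            raise ValueError("count matrix has no features")
        colsum = data.sum(axis=0)
        empty = tuple(colsum.index[colsum == 0])
        safe = colsum.replace(0, 1)
        rel = data.div(safe, axis=1).astype(float)
        return AbundanceProfile(
            rel, kind="relative", domain_scope=self.domain_scope, basis=self.basis, empty_samples=empty
        )


class QpcrAbsoluteScaler(TransformerMixin, BaseEstimator):
    """Scale a relative profile to absolute marker-copy abundances (copies/ml).

    ``fit`` stores the per-sample qPCR anchor for the requested domain from the
    sample metadata table; ``transform`` multiplies each sample's relative
    column by its anchor, so column totals equal the qPCR value.

    Parameters
    ----------
    samples : pandas.DataFrame
        Per-sample metadata (index = sample_id) with ``qpcr_bacteria`` and
        ``qpcr_fungi`` columns in copies/ml.
    domain : {"bacteria", "fungi"}
    """

    def __init__(self, samples: Optional[pd.DataFrame] = None, domain: str = "bacteria"):
        self.samples = samples
        self.domain = domain

    def fit(self, X=None, y=None):
        if self.samples is None:
            raise ValueError("QpcrAbsoluteScaler requires a sample metadata table")
        if self.domain not in ("bacteria", "fungi"):
            raise ValueError(f"domain must be bacteria or fungi, got {self.domain!r}")
        self.qpcr_ = self.samples[f"qpcr_{self.domain}"].astype(float)
        return self

    def transform(self, rel: AbundanceProfile) -> AbundanceProfile:
        if not hasattr(self, "qpcr_"):
            raise NotFittedError("QpcrAbsoluteScaler is not fitted; call fit first")
        if rel.kind != "relative":
            raise ValueError(f"expected a relative profile, got kind={rel.kind!r}")
        missing = [s for s in rel.data.columns if s not in self.qpcr_.index or pd.isna(self.qpcr_.get(s))]
        if missing:
            raise ValueError(f"missing qPCR value for sample(s): {missing}")
        absolute = rel.data.mul(self.qpcr_.reindex(rel.data.columns), axis=1)
        return AbundanceProfile(
            absolute,
            kind="marker_copies_per_ml",
            domain_scope=rel.domain_scope,
            basis="marker_copies",
            empty_samples=rel.empty_samples,
        )


def relative_abundance(
    counts: Union[FeatureCountMatrix, pd.DataFrame],
    domain_scope: str = "all",
    basis: str = "marker_copies",
) -> AbundanceProfile:
    """Per-sample proportions of a count table; see :class:`RelativeAbundance`."""
    return RelativeAbundance(domain_scope=domain_scope, basis=basis).fit(counts).transform(counts)


def _sample_counts(counts: Union[FeatureCountMatrix, pd.DataFrame], sample: str) -> np.ndarray:
    data, _ = _as_count_frame(counts)
    if sample not in data.columns:
        raise KeyError(f"unknown sample {sample!r}")
    vec = data[sample].to_numpy()
    if vec.sum() < 1:
        raise ValueError(f"sample {sample!r} is empty (no reads)")
    return vec


def goods_coverage(counts: Union[FeatureCountMatrix, pd.DataFrame], sample: str) -> float:
    """Good's coverage 1 - n1/N: the chance the next read is a seen feature."""
    vec = _sample_counts(counts, sample)
    n1 = int((vec == 1).sum())
    return 1.0 - n1 / vec.sum()


def diversity_indices(counts: Union[FeatureCountMatrix, pd.DataFrame], sample: str) -> dict:
    """Observed richness, Shannon entropy (natural log) and Chao1 for a sample.

    Chao1 uses the bias-corrected form S_obs + n1(n1-1)/(2(n2+1)) with n1/n2 the
    singleton/doubleton counts.
    """
    vec = _sample_counts(counts, sample)
    nonzero = vec[vec > 0]
    richness = int(len(nonzero))
    p = nonzero / nonzero.sum()
    shannon = float(-(p * np.log(p)).sum())
    n1 = int((vec == 1).sum())
    n2 = int((vec == 2).sum())
    chao1 = richness + n1 * (n1 - 1) / (2.0 * (n2 + 1))
    return {"observed_richness": richness, "shannon": shannon, "chao1": float(chao1)}


def absolute_marker_abundance(
    rel: AbundanceProfile, samples: pd.DataFrame, domain: str, meju_removal_day: int = 60
) -> AbundanceProfile:
    """Relative profile × domain qPCR total → absolute copies/ml."""
    validate_sample_info(samples, meju_removal_day=meju_removal_day)
    return QpcrAbsoluteScaler(samples=samples, domain=domain).fit().transform(rel)
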