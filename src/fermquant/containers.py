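"""In-memory containers for count tables, abundance profiles and expression matrices.

All tabular data ride on :class:`pandas.DataFrame` with features as rows and
samples as columns.  The thin dataclass wrappers exist to carry the state that
plain frames cannot: what kind of feature the rows are, what scale a profile is
on (proportions of marker-gene copies vs. proportions of genomes), and whether
an expression matrix has already been spike-in normalized — state that the
quantification chain must check to refuse dimensionally inconsistent or
double-applied operations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

FEATURE_KINDS = ("amplicon_taxon", "genome", "gene")
DOMAINS = ("bacteria", "fungi")
PROFILE_KINDS = ("relative", "marker_copies_per_ml", "genomes_per_ml")
PROFILE_BASES = ("marker_copies", "genomes", "transcripts")
DOMAIN_SCOPES = ("bacteria", "fungi", "all")
PHASES = ("meju_in", "meju_out")

#: columns required in a per-sample metadata table (index = sample_id)
SAMPLE_INFO_COLUMNS = (
    "day",
    "phase",
    "qpcr_bacteria",
    "qpcr_fungi",
    "spike_in_reads",
    "total_mrna_mapped_reads",
)

#: columns required in a genome registry table (index = genome_id)
GENOME_REGISTRY_COLUMNS = (
    "taxon_label",
    "domain",
    "source",
    "genome_size_bp",
    "marker_copies",
    "marker_copies_estimated",
)

#: columns required in a gene annotation table (index = gene_id)
GENE_ANNOTATION_COLUMNS = ("genome_id", "length_bp", "ko_id", "kegg_level2", "kegg_level3")


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what} identifiers: {dups}")


@dataclass
class FeatureCountMatrix:
    """Nonnegative integer counts of features (taxa, genomes or genes) per sample."""

    data: pd.DataFrame
    feature_kind: str = "genome"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}")
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if values.size:
            if np.any(values < 0):
                raise ValueError("counts must be nonnegative")
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integral")
        self.data = self.data.astype(np.int64)

    @property
    def feature_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class AbundanceProfile:
    """Per-feature, per-sample abundances with their scale recorded.

    ``kind`` distinguishes proportions from absolute densities.  For relative
    profiles, ``basis`` records which physical quantity the proportions track:
    marker-gene copies (amplicon counts are copy-number biased) or genomes
    (size-normalized shotgun counts).  Absolute conversion must know this to
    apply the per-genome copy-number division on the correct scale.
    """

    data: pd.DataFrame
    kind: str = "relative"
    domain_scope: str = "all"
    basis: str = "genomes"
    empty_samples: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"kind must be one of {PROFILE_KINDS}, got {self.kind!r}")
        if self.domain_scope not in DOMAIN_SCOPES:
            raise ValueError(f"domain_scope must be one of {DOMAIN_SCOPES}, got {self.domain_scope!r}")
        if self.basis not in PROFILE_BASES:
            raise ValueError(f"basis must be one of {PROFILE_BASES}, got {self.basis!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and np.any(values < 0):
            raise ValueError("abundances must be nonnegative")
        self.empty_samples = tuple(self.empty_samples)
        if self.kind == "relative" and values.size:
            colsum = values.sum(axis=0)
            for j, sample in enumerate(self.data.columns):
                if sample in self.empty_samples:
                    continue
                if abs(colsum[j] - 1.0) > 1e-9:
                    raise ValueError(
                        f"relative profile column {sample!r} sums to {colsum[j]!r}, expected 1"
                    )


@dataclass
class ExpressionMatrix:
    """Per-gene RPKM values, with the spike-in normalization state recorded."""

    data: pd.DataFrame
    normalized: bool = False
    scale_factors: Optional[pd.Series] = None
    reference_sample: Optional[str] = None

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.size and np.any(values < 0):
            raise ValueError("expression values must be nonnegative")
        if self.normalized:
            if self.scale_factors is None:
                raise ValueError("normalized matrix must record its scale factors")
            if np.any(self.scale_factors.to_numpy(dtype=float) <= 0):
                raise ValueError("scale factors must be positive")
        elif self.scale_factors is not None:
            raise ValueError("scale factors present on an unnormalized matrix")


@dataclass
class FunctionalProfile:
    """Summed (normalized) RPKM per KEGG category/KO, with per-genome attribution.

    ``attribution`` is a long-format frame (category_or_ko, sample_id,
    genome_id, fraction, total_rpkm); fractions sum to 1 within each
    (category, sample) whose total is positive.  ``undefined`` lists the
    (category, sample) pairs with zero total, where attribution is undefined
    rather than NaN.  ``unannotated`` carries the per-sample expression mass of
    genes lacking the annotation level, so totals remain conserved.
    """

    level: str
    values: pd.DataFrame
    attribution: Optional[pd.DataFrame] = None
    undefined: tuple = ()
    unannotated: Optional[pd.Series] = None


@dataclass
class PathwayPresence:
    """KO × genome presence calls with per-cell provenance."""

    presence: pd.DataFrame  # bool, ko_id × genome_id
    provenance: pd.DataFrame  # str in {annotated, curated_override}


def validate_sample_info(samples: pd.DataFrame, meju_removal_day: int = 60) -> pd.DataFrame:
    """Validate a per-sample metadata table (index = sample_id).

    Checks the required columns, nonnegativity, and the phase/day consistency:
    ``phase == "meju_in"`` iff ``day <= meju_removal_day``.
    """
    missing = [c for c in SAMPLE_INFO_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    _check_unique(samples.index, "sample")
    for col in ("day", "qpcr_bacteria", "qpcr_fungi", "spike_in_reads", "total_mrna_mapped_reads"):
        if (samples[col] < 0).any():
            bad = samples.index[samples[col] < 0].tolist()
            raise ValueError(f"negative {col} for samples {bad}")
    for sample, row in samples.iterrows():
        expected = "meju_in" if row["day"] <= meju_removal_day else "meju_out"
        if row["phase"] not in PHASES:
            raise ValueError(f"sample {sample!r}: unknown phase {row['phase']!r}")
        if row["phase"] != expected:
            raise ValueError(
                f"sample {sample!r}: phase {row['phase']!r} inconsistent with day "
                f"{row['day']} and meju removal day {meju_removal_day}"
            )
    return samples


def validate_genome_registry(registry: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENOME_REGISTRY_COLUMNS if c not in registry.columns]
    if missing:
        raise ValueError(f"genome registry missing columns: {missing}")
    _check_unique(registry.index, "genome")
    if (registry["genome_size_bp"] <= 0).any():
        raise ValueError("genome_size_bp must be strictly positive")
    if (registry["marker_copies"] < 1).any():
        raise ValueError("marker_copies must be >= 1")
    bad = set(registry["domain"]) - set(DOMAINS)
    if bad:
        raise ValueError(f"unknown domains in registry: {sorted(bad)}")
    return registry


def validate_gene_annotations(annotations: pd.DataFrame, registry: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    missing = [c for c in GENE_ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"gene annotation table missing columns: {missing}")
    _check_unique(annotations.index, "gene")
    if (annotations["length_bp"] <= 0).any():
        bad = annotations.index[annotations["length_bp"] <= 0].tolist()
        raise ValueError(f"nonpositive gene length for genes {bad}")
    if registry is not None:
        unknown = sorted(set(annotations["genome_id"]) - set(registry.index))
        if unknown:
            raise ValueError(f"annotation references genomes absent from the registry: {unknown}")
    return annotations
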