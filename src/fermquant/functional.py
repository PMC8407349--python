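"""Functional aggregation of normalized expression into KEGG categories and
per-taxon attribution of each KEGG ortholog's expression.

Level-2 aggregation assigns each gene to at most one primary category, so
category sums plus the unannotated mass conserve total expression per sample.
Level-3 pathway labels may be semicolon-separated lists (a gene commonly
belongs to several KEGG pathways); a gene's full RPKM is then counted in each
of its pathways, matching the visual semantics of pathway-map renderers, at
the cost of the conservation identity at that level.

Attribution answers the pie-chart question: of all (normalized) expression of
one KEGG ortholog in one sample, what fraction came from each genome?
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .containers import ExpressionMatrix, FunctionalProfile, PathwayPresence, validate_gene_annotations

__all__ = [
    "KeggAggregator",
    "kegg_category_expression",
    "taxon_pathway_attribution",
    "pathway_presence",
]

_LEVELS = {"level2": "kegg_level2", "level3": "kegg_level3", "ko": "ko_id"}


def _require_normalized(expr: ExpressionMatrix) -> None:
    if not expr.normalized:
        raise ValueError("expression must be spike-in normalized before functional aggregation")


class KeggAggregator(TransformerMixin, BaseEstimator):
    """Sum (normalized) RPKM over genes sharing a KEGG annotation level.

    Parameters
    ----------
    annotations : pandas.DataFrame
        Gene annotation table (index gene_id) with ``ko_id``, ``kegg_level2``
        and ``kegg_level3`` columns; empty strings mean unannotated.
    level : {"level2", "level3", "ko"}
    """

    def __init__(self, annotations: Optional[pd.DataFrame] = None, level: str = "level2"):
        self.annotations = annotations
        self.level = level

    def fit(self, X=None, y=None):
        if self.annotations is None:
            raise ValueError("KeggAggregator requires a gene annotation table")
        if self.level not in _LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {sorted(_LEVELS)}")
        validate_gene_annotations(self.annotations)
        self.label_column_ = _LEVELS[self.level]
        return self

    def transform(self, expr: ExpressionMatrix) -> FunctionalProfile:
        if not hasattr(self, "label_column_"):
            raise NotFittedError("KeggAggregator is not fitted; call fit first")
        _require_normalized(expr)
        labels = self.annotations[self.label_column_].reindex(expr.data.index).fillna("")
        annotated = labels != ""
        unannotated_mass = expr.data.loc[~annotated].sum(axis=0)
        if self.level == "level3":
            # genes may belong to several pathways; count full RPKM in each
            rows = []
            for gene, lab in labels[annotated].items():
                for pathway in str(lab).split(";"):
                    pathway = pathway.strip()
                    if pathway:
                        rows.append((pathway, gene))
            if rows:
                membership = pd.DataFrame(rows, columns=["category", "gene_id"])
                values = (
                    expr.data.loc[membership["gene_id"]]
                    .set_axis(membership["category"], axis=0)
                    .groupby(level=0)
                    .sum()
                )
            else:
                values = pd.DataFrame(columns=expr.data.columns)
        else:
            values = expr.data.loc[annotated].groupby(labels[annotated]).sum()
        values.index.name = self.level
        return FunctionalProfile(
            level=self.level, values=values.astype(float), unannotated=unannotated_mass.astype(float)
        )


def kegg_category_expression(
    expr: ExpressionMatrix, annotations: pd.DataFrame, level: str = "level2"
) -> FunctionalProfile:
    """Summed RPKM per KEGG category; see :class:`KeggAggregator`."""
    return KeggAggregator(annotations=annotations, level=level).fit().transform(expr)


def taxon_pathway_attribution(
    expr: ExpressionMatrix, annotations: pd.DataFrame, ko_set: Iterable[str]
) -> FunctionalProfile:
    """Per-genome fractions of each KEGG ortholog's expression per sample.

    fraction(G; ko, s) = Σ_{genes of G with ko} expr(g,s) / Σ_{genes with ko} expr(g,s)

    (ko, sample) cells with zero total are listed in ``undefined`` instead of
    propagating NaN fractions.  Returns a long-format attribution table with
    columns (ko_id, sample_id, genome_id, fraction, total_rpkm).
    """
    _require_normalized(expr)
    ko_list = [k for k in ko_set]
    if not ko_list:
        raise ValueError("ko_set is empty")
    validate_gene_annotations(annotations)
    ann = annotations.reindex(expr.data.index)
    totals = {}
    records = []
    undefined = []
    for ko in ko_list:
        genes = ann.index[ann["ko_id"] == ko]
        sub = expr.data.loc[genes]
        per_genome = sub.groupby(ann.loc[genes, "genome_id"]).sum()
        total = sub.sum(axis=0)
        totals[ko] = total
        for s in expr.data.columns:
            if total[s] > 0:
                for genome, value in per_genome[s].items():
                    records.append((ko, s, genome, value / total[s], value))
            else:
                undefined.append((ko, s))
    values = pd.DataFrame(totals).T.reindex(ko_list)
    values.index.name = "ko_id"
    values.columns = expr.data.columns
    attribution = pd.DataFrame(
        records, columns=["ko_id", "sample_id", "genome_id", "fraction", "total_rpkm"]
    )
    return FunctionalProfile(
        level="ko",
        values=values.astype(float),
        attribution=attribution,
        undefined=tuple(undefined),
    )


def pathway_presence(
    annotations: pd.DataFrame,
    registry: pd.DataFrame,
    overrides: Optional[pd.DataFrame] = None,
) -> PathwayPresence:
    """KO × genome presence matrix from annotations, adjusted by curation.

    A KO is present in a genome iff any gene of that genome carries it;
    ``overrides`` (columns genome_id, ko_id, present) force individual cells,
    standing in for manual curation, and are recorded with provenance
    ``curated_override``.
    """
    validate_gene_annotations(annotations, registry)
    annotated = annotations[annotations["ko_id"] != ""]
    kos = sorted(annotated["ko_id"].unique())
    genomes = list(registry.index)
    presence = pd.DataFrame(False, index=pd.Index(kos, name="ko_id"), columns=genomes)
    for (genome, ko), _ in annotated.groupby(["genome_id", "ko_id"]):
        presence.loc[ko, genome] = True
    provenance = pd.DataFrame("annotated", index=presence.index, columns=presence.columns)
    if overrides is not None and len(overrides):
        for col in ("genome_id", "ko_id", "present"):
            if col not in overrides.columns:
                raise ValueError(f"override table missing column {col!r}")
        unknown = sorted(set(overrides["genome_id"]) - set(genomes))
        if unknown:
            raise ValueError(f"override references unknown genome(s): {unknown}")
        new_kos = sorted(set(overrides["ko_id"]) - set(presence.index))
        if new_kos:
            presence = pd.concat(
                [presence, pd.DataFrame(False, index=pd.Index(new_kos, name="ko_id"), columns=genomes)]
            ).sort_index()
            provenance = pd.concat(
                [provenance, pd.DataFrame("annotated", index=pd.Index(new_kos, name="ko_id"), columns=genomes)]
            ).sort_index()
        for _, row in overrides.iterrows():
            presence.loc[row["ko_id"], row["genome_id"]] = bool(row["present"])
            provenance.loc[row["ko_id"], row["genome_id"]] = "curated_override"
    return PathwayPresence(presence=presence, provenance=provenance)
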