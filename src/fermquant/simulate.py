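"""Synthetic fermentation-community generator with known ground truth.

Emulates the observation layers of a quantitative meta-omics study of a brine
fermentation (ganjang): per-taxon genome densities follow logistic growth while
meju bricks are in the brine and exponential decay after their removal;
marker-gene amplicon counts are biased by per-genome marker copy number,
shotgun metagenome counts by genome size, and mRNA counts by gene length and
per-gene activity; a constant mass of spike-in RNA competes with the sample's
mRNA pool for sequencing reads; qPCR totals carry lognormal noise.  The
quantification chain is expected to undo exactly these biases, so every bias
is injected here with its true value recorded.

All randomness derives from one global seed; each observation layer draws from
an independently spawned child stream so layers can be resampled without
perturbing one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import DOMAINS, FeatureCountMatrix, validate_genome_registry
from .registry import ganjang_genome_registry

__all__ = [
    "TaxonSpec",
    "SimulationParams",
    "SyntheticTruth",
    "simulate_timecourse",
    "sample_amplicon_counts",
    "sample_metagenome_counts",
    "sample_metatranscriptome_counts",
    "simulate_qpcr",
    "assemble_sample_info",
    "default_simulation_params",
    "logistic_decay_density",
]

# Deterministic child-stream indices, one per observation layer.
_LAYERS = {
    "truth": 0,
    "amplicon_bacteria": 1,
    "amplicon_fungi": 2,
    "metagenome": 3,
    "metatranscriptome": 4,
    "qpcr": 5,
}

#: per-gene expression weights are lognormal(mu, sigma) in log-space — a
#: heavy-tailed spread of basal transcription rates, frozen across samples.
GENE_WEIGHT_LOGMU = 0.0
GENE_WEIGHT_LOGSIGMA = 1.5

# Small synthetic KEGG-like hierarchy: (ko_id, level2 category, level3 pathway).
# Functions chosen to cover the metabolism active in a soy-sauce fermentation
# (sugar fermentation, aerobic respiration, amino acid and lipid turnover).
_KO_POOL = [
    ("K00845", "Carbohydrate metabolism", "Glycolysis / Gluconeogenesis"),
    ("K01810", "Carbohydrate metabolism", "Glycolysis / Gluconeogenesis"),
    ("K00873", "Carbohydrate metabolism", "Glycolysis / Gluconeogenesis"),
    ("K01689", "Carbohydrate metabolism", "Glycolysis / Gluconeogenesis"),
    ("K00850", "Carbohydrate metabolism", "Fructose and mannose metabolism"),
    ("K01818", "Carbohydrate metabolism", "Fructose and mannose metabolism"),
    ("K00849", "Carbohydrate metabolism", "Galactose metabolism"),
    ("K01784", "Carbohydrate metabolism", "Galactose metabolism"),
    ("K00615", "Carbohydrate metabolism", "Pentose phosphate pathway"),
    ("K01621", "Carbohydrate metabolism", "Pentose phosphate pathway"),
    ("K00016", "Carbohydrate metabolism", "Pyruvate metabolism"),
    ("K00156", "Carbohydrate metabolism", "Pyruvate metabolism"),
    ("K01905", "Carbohydrate metabolism", "Pyruvate metabolism"),
    ("K01647", "Carbohydrate metabolism", "Citrate cycle (TCA cycle)"),
    ("K01902", "Carbohydrate metabolism", "Citrate cycle (TCA cycle)"),
    ("K00239", "Energy metabolism", "Oxidative phosphorylation"),
    ("K00330", "Energy metabolism", "Oxidative phosphorylation"),
    ("K02275", "Energy metabolism", "Oxidative phosphorylation"),
    ("K00425", "Energy metabolism", "Oxidative phosphorylation"),
    ("K00600", "Amino acid metabolism", "Glycine, serine and threonine metabolism"),
    ("K00826", "Amino acid metabolism", "Valine, leucine and isoleucine degradation"),
    ("K00382", "Amino acid metabolism", "Valine, leucine and isoleucine degradation"),
    ("K01582", "Amino acid metabolism", "Lysine degradation"),
    ("K00274", "Amino acid metabolism", "Phenylalanine metabolism"),
    ("K01580", "Amino acid metabolism", "Alanine, aspartate and glutamate metabolism"),
    ("K00059", "Lipid metabolism", "Fatty acid biosynthesis"),
    ("K00632", "Lipid metabolism", "Fatty acid degradation"),
    ("K00864", "Lipid metabolism", "Glycerolipid metabolism"),
    ("K00005", "Lipid metabolism", "Glycerolipid metabolism"),
    ("K00948", "Nucleotide metabolism", "Purine metabolism"),
    ("K00760", "Nucleotide metabolism", "Purine metabolism"),
    ("K02518", "Translation", "Ribosome"),
    ("K02863", "Translation", "Ribosome"),
    ("K02835", "Translation", "Ribosome"),
    ("K02777", "Membrane transport", "Phosphotransferase system (PTS)"),
    ("K02793", "Membrane transport", "Phosphotransferase system (PTS)"),
    ("K02025", "Membrane transport", "ABC transporters"),
    ("K02032", "Membrane transport", "ABC transporters"),
    ("K07636", "Signal transduction", "Two-component system"),
    ("K07659", "Signal transduction", "Two-component system"),
]

#: fraction of simulated genes left without KEGG annotation
UNANNOTATED_FRACTION = 0.15


@dataclass
class TaxonSpec:
    """One simulated community member and its growth/decay trajectory."""

    genome_id: str
    domain: str
    genome_size_bp: int
    marker_copies: int
    initial_density: float  # genomes/ml at day 0
    growth_rate: float  # 1/day, logistic growth while meju is present
    carrying_capacity: float  # genomes/ml
    decay_rate: float  # 1/day, exponential decay after meju removal
    gene_count: int = 50
    activity_profile: dict = field(
        default_factory=lambda: {"meju_in": 1.0, "meju_out": 0.1}
    )
    taxon_label: str = ""
    source: str = "MAG"

    def validate(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"taxon {self.genome_id!r}: unknown domain {self.domain!r}")
        if self.genome_size_bp <= 0:
            raise ValueError(f"taxon {self.genome_id!r}: genome_size_bp must be > 0")
        if self.marker_copies < 1:
            raise ValueError(f"taxon {self.genome_id!r}: marker_copies must be >= 1")
        if self.initial_density <= 0:
            raise ValueError(f"taxon {self.genome_id!r}: initial_density must be > 0")
        if self.growth_rate < 0 or self.decay_rate < 0:
            raise ValueError(f"taxon {self.genome_id!r}: rate constants must be >= 0")
        if self.growth_rate > 0 and self.carrying_capacity <= 0:
            raise ValueError(
                f"taxon {self.genome_id!r}: growth requested but carrying_capacity <= 0"
            )
        if self.gene_count < 1:
            raise ValueError(f"taxon {self.genome_id!r}: gene_count must be >= 1")
        if any(v < 0 for v in self.activity_profile.values()):
            raise ValueError(f"taxon {self.genome_id!r}: activity multipliers must be >= 0")


@dataclass
class SimulationParams:
    """Full parameterization of one synthetic fermentation run."""

    taxa: list
    sample_days: Sequence[int] = (0, 20, 40, 60, 90, 180)
    meju_removal_day: int = 60
    depths: dict = field(
        default_factory=lambda: {
            "amplicon": 50_000,
            "metagenome": 200_000,
            "metatranscriptome": 500_000,
        }
    )
    spike_mass: float = 2.0  # constant spike-in RNA mass per sample (μg)
    spike_mass_fraction_scale: float = 2e-7  # converts transcript mass units to spike-mass units
    qpcr_cv: float = 0.2  # lognormal coefficient of variation of qPCR totals
    seed: int = 0

    def validate(self) -> None:
        if not self.taxa:
            raise ValueError("at least one taxon required")
        for taxon in self.taxa:
            taxon.validate()
        ids = [t.genome_id for t in self.taxa]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate genome_id in taxa")
        days = list(self.sample_days)
        if any(d < 0 for d in days):
            raise ValueError("sample_days must be >= 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sample_days must be strictly increasing")
        if self.spike_mass_fraction_scale <= 0:
            raise ValueError("spike_mass_fraction_scale must be > 0")
        if self.qpcr_cv < 0:
            raise ValueError("qpcr_cv must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: densities, transcript weights, genes."""

    density: pd.DataFrame  # genomes/ml, genome_id × sample_id
    transcript_weight: pd.DataFrame  # relative transcript mass, gene_id × sample_id
    genes: pd.DataFrame  # index gene_id; genome_id, length_bp, ko_id, kegg_level2/3, expression_weight
    registry: pd.DataFrame  # genome registry derived from the taxa
    sample_table: pd.DataFrame  # index sample_id; day, phase
    params: SimulationParams
    seed: int


def _layer_rng(seed: int, layer: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_LAYERS[layer],)))


def logistic_decay_density(taxon: TaxonSpec, day: float, meju_removal_day: int) -> float:
    """Density trajectory: logistic up to meju removal, exponential decay after.

    N(t) = K N0 e^{rt} / (K + N0 (e^{rt} - 1)) for t <= t_rm,
    N(t) = N(t_rm) e^{-d (t - t_rm)} afterward.
    """
    n0, r, k = taxon.initial_density, taxon.growth_rate, taxon.carrying_capacity
    t = min(day, meju_removal_day)
    if r == 0:
        n = n0
    else:
        ert = math.exp(r * t)
        n = k * n0 * ert / (k + n0 * (ert - 1.0))
    if day > meju_removal_day:
        n *= math.exp(-taxon.decay_rate * (day - meju_removal_day))
    return n


def _sample_ids(days: Sequence[int]) -> list:
    return [f"D{int(d):03d}" for d in days]


def simulate_timecourse(params: SimulationParams) -> SyntheticTruth:
    """Run the deterministic trajectory model and draw the frozen gene layer.

    Per-gene transcript weight at sample ``s`` for gene ``g`` of taxon ``i`` is
    ``density(s, i) * activity(i, phase(s)) * w_g`` where ``w_g`` is a frozen
    heavy-tailed (lognormal) per-gene expression weight; gene lengths and KEGG
    annotations are drawn once per simulation from the child stream of the
    global seed, so the truth is bit-identical across runs at a fixed seed.
    """
    params.validate()
    rng = _layer_rng(params.seed, "truth")
    days = list(params.sample_days)
    samples = _sample_ids(days)
    phases = ["meju_in" if d <= params.meju_removal_day else "meju_out" for d in days]
    sample_table = pd.DataFrame({"day": days, "phase": phases}, index=pd.Index(samples, name="sample_id"))

    density = pd.DataFrame(
        {
            s: [logistic_decay_density(t, d, params.meju_removal_day) for t in params.taxa]
            for s, d in zip(samples, days)
        },
        index=pd.Index([t.genome_id for t in params.taxa], name="genome_id"),
    )
    for s in samples:
        if not (density[s] > 0).any():
            raise ValueError(f"sample {s!r}: no taxon has positive density")

    registry = pd.DataFrame(
        {
            "taxon_label": [t.taxon_label or t.genome_id for t in params.taxa],
            "domain": [t.domain for t in params.taxa],
            "source": [t.source for t in params.taxa],
            "genome_size_bp": [t.genome_size_bp for t in params.taxa],
            "marker_copies": [t.marker_copies for t in params.taxa],
            "marker_copies_estimated": [False] * len(params.taxa),
        },
        index=density.index,
    )
    validate_genome_registry(registry)

    gene_rows = []
    ko_pool = np.array(range(len(_KO_POOL)))
    for taxon in params.taxa:
        n = taxon.gene_count
        lengths = np.clip(
            np.round(rng.lognormal(math.log(900.0), 0.35, size=n)).astype(int), 150, 6000
        )
        weights = rng.lognormal(GENE_WEIGHT_LOGMU, GENE_WEIGHT_LOGSIGMA, size=n)
        annotated = rng.random(n) >= UNANNOTATED_FRACTION
        kos = rng.choice(ko_pool, size=n, replace=True)
        for j in range(n):
            ko, lvl2, lvl3 = _KO_POOL[kos[j]] if annotated[j] else ("", "", "")
            gene_rows.append(
                (
                    f"{taxon.genome_id}_g{j + 1:04d}",
                    taxon.genome_id,
                    int(lengths[j]),
                    ko,
                    lvl2,
                    lvl3,
                    float(weights[j]),
                )
            )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "genome_id", "length_bp", "ko_id", "kegg_level2", "kegg_level3", "expression_weight"],
    ).set_index("gene_id")

    activity = {
        (t.genome_id, phase): t.activity_profile.get(phase, 0.0)
        for t in params.taxa
        for phase in ("meju_in", "meju_out")
    }
    tw = np.empty((len(genes), len(samples)))
    gene_genomes = genes["genome_id"].to_numpy()
    gene_weights = genes["expression_weight"].to_numpy()
    for j, (s, phase) in enumerate(zip(samples, phases)):
        dens = density[s]
        tw[:, j] = (
            dens.loc[gene_genomes].to_numpy()
            * np.array([activity[(g, phase)] for g in gene_genomes])
            * gene_weights
        )
    transcript_weight = pd.DataFrame(tw, index=genes.index, columns=samples)

    return SyntheticTruth(
        density=density,
        transcript_weight=transcript_weight,
        genes=genes,
        registry=registry,
        sample_table=sample_table,
        params=params,
        seed=params.seed,
    )


def _multinomial_columns(
    rng: np.random.Generator,
    weights: pd.DataFrame,
    depth_per_sample: dict,
    what: str,
) -> pd.DataFrame:
    counts = {}
    for s in weights.columns:
        w = weights[s].to_numpy(dtype=float)
        depth = int(depth_per_sample[s])
        if depth == 0:
            counts[s] = np.zeros(len(w), dtype=np.int64)
            continue
        total = w.sum()
        if total <= 0:
            raise ValueError(f"sample {s!r}: all-zero {what} weight vector, cannot draw reads")
        counts[s] = rng.multinomial(depth, w / total)
    return pd.DataFrame(counts, index=weights.index)


def sample_amplicon_counts(truth: SyntheticTruth, domain: str, depth: int) -> FeatureCountMatrix:
    """Draw marker-gene amplicon counts for one domain.

    Read probabilities are proportional to density × marker copy number — the
    copy-number bias that the absolute-abundance chain later divides out.
    """
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _layer_rng(truth.seed, f"amplicon_{domain}")
    reg = truth.registry
    members = reg.index[reg["domain"] == domain]
    if len(members) == 0:
        raise ValueError(f"no taxa of domain {domain!r} in the community")
    weights = truth.density.loc[members].mul(reg.loc[members, "marker_copies"], axis=0)
    data = _multinomial_columns(rng, weights, {s: depth for s in weights.columns}, f"{domain} amplicon")
    return FeatureCountMatrix(data, feature_kind="amplicon_taxon")


def sample_metagenome_counts(truth: SyntheticTruth, depth: int) -> FeatureCountMatrix:
    """Draw shotgun read counts over all genomes, biased by genome size."""
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _layer_rng(truth.seed, "metagenome")
    weights = truth.density.mul(truth.registry["genome_size_bp"], axis=0)
    data = _multinomial_columns(rng, weights, {s: depth for s in weights.columns}, "metagenome")
    return FeatureCountMatrix(data, feature_kind="genome")


def sample_metatranscriptome_counts(
    truth: SyntheticTruth, depth: int, spike_mass: Optional[float] = None
):
    """Draw mRNA read counts plus per-sample spike-in reads.

    A constant spike mass competes with the sample's total transcript mass
    ``T_s = Σ_g transcript_weight(s,g) × gene_length_kb(g)`` for sequencing
    reads: the spike read fraction is ``m / (m + c·T_s)`` with the recorded
    scale ``c``; remaining reads are multinomial over genes with probability
    proportional to transcript weight × gene length.  Returns
    ``(FeatureCountMatrix over genes, spike_reads Series)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    m = truth.params.spike_mass if spike_mass is None else spike_mass
    if m <= 0:
        raise ValueError("spike_mass must be > 0")
    c = truth.params.spike_mass_fraction_scale
    rng = _layer_rng(truth.seed, "metatranscriptome")
    len_kb = truth.genes["length_bp"].to_numpy() / 1000.0
    counts = {}
    spike = {}
    for s in truth.transcript_weight.columns:
        mass = truth.transcript_weight[s].to_numpy() * len_kb
        total_mass = mass.sum()
        f = m / (m + c * total_mass)
        n_spike = int(rng.binomial(depth, f))
        n_genes = depth - n_spike
        if n_genes > 0 and total_mass <= 0:
            # degenerate but possible only when f < 1 numerically fails; guard
            n_spike, n_genes = depth, 0
        counts[s] = (
            rng.multinomial(n_genes, mass / total_mass) if n_genes > 0 else np.zeros(len(mass), dtype=np.int64)
        )
        spike[s] = n_spike
    gene_counts = FeatureCountMatrix(
        pd.DataFrame(counts, index=truth.transcript_weight.index), feature_kind="gene"
    )
    spike_reads = pd.Series(spike, name="spike_in_reads")
    return gene_counts, spike_reads


def simulate_qpcr(truth: SyntheticTruth) -> pd.DataFrame:
    """Per-sample qPCR totals (marker copies/ml) per domain, with lognormal noise.

    The noiseless value is Σ_{i ∈ domain} density(s,i) × marker_copies_i; the
    multiplicative error is lognormal with mean 1 and CV = ``qpcr_cv``.
    """
    cv = truth.params.qpcr_cv
    rng = _layer_rng(truth.seed, "qpcr")
    reg = truth.registry
    out = {}
    for domain in DOMAINS:
        members = reg.index[reg["domain"] == domain]
        if len(members) == 0:
            out[f"qpcr_{domain}"] = pd.Series(0.0, index=truth.density.columns)
            continue
        copies = truth.density.loc[members].mul(reg.loc[members, "marker_copies"], axis=0).sum(axis=0)
        if cv > 0:
            sigma2 = math.log(1.0 + cv * cv)
            eps = rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2), size=len(copies))
        else:
            eps = np.ones(len(copies))
        out[f"qpcr_{domain}"] = copies * eps
    frame = pd.DataFrame(out)
    frame.index.name = "sample_id"
    return frame


def assemble_sample_info(
    truth: SyntheticTruth,
    qpcr: pd.DataFrame,
    gene_counts: FeatureCountMatrix,
    spike_reads: pd.Series,
) -> pd.DataFrame:
    """Assemble the per-sample metadata table from simulated observation layers."""
    info = truth.sample_table.copy()
    info["qpcr_bacteria"] = qpcr["qpcr_bacteria"]
    info["qpcr_fungi"] = qpcr["qpcr_fungi"]
    info["spike_in_reads"] = spike_reads.astype(int)
    info["total_mrna_mapped_reads"] = gene_counts.column_sums()
    return info


# Per-taxon trajectory defaults for the 17-genome ganjang community:
# (initial_density genomes/ml, growth_rate /day, carrying_capacity genomes/ml,
#  decay_rate /day, post-removal activity multiplier).  Chosen so that domain
# qPCR totals start near 1.0e6 (bacteria) / 1.0e4 (fungi) copies/ml and peak
# near 4.8e7 / 4.6e5 copies/ml at meju removal (day 60), with lactic acid
# bacteria and aerobic halophiles as the major bacteria, Debaryomyces as the
# dominant yeast, Wickerhamomyces transiently abundant early, and Bacillus /
# Aspergillus as minor meju-derived members.
_DEFAULT_TRAJECTORIES = {
    "KG1": (8e3, 0.04, 6e4, 0.02, 0.1),
    "KG2": (5e3, 0.04, 4e4, 0.02, 0.1),
    "KG3": (4e3, 0.04, 3e4, 0.02, 0.1),
    "KG4": (3e3, 0.05, 1.5e5, 0.02, 0.4),
    "KG5": (5e3, 0.06, 1.2e5, 0.08, 0.1),
    "KG6": (1.5e4, 0.09, 1.0e6, 0.05, 0.4),
    "KG7": (3e3, 0.04, 2.5e4, 0.02, 0.1),
    "KG8": (5e3, 0.07, 2.5e5, 0.08, 0.4),
    "KG9": (1.5e4, 0.10, 1.2e6, 0.12, 0.4),
    "KG10": (3e3, 0.05, 1.0e5, 0.04, 0.4),
    "KG11": (3e4, 0.12, 4.0e6, 0.06, 0.1),
    "KG12": (2e4, 0.12, 2.5e6, 0.06, 0.1),
    "KG13": (2e4, 0.10, 1.5e6, 0.10, 0.4),
    "KG14": (5e3, 0.06, 3.0e5, 0.03, 0.4),
    "KG15": (1e3, 0.03, 1.0e4, 0.01, 0.1),
    "KG16": (2e3, 0.20, 2.0e4, 0.15, 0.1),
    "C11": (8e2, 0.10, 8.0e4, 0.08, 0.1),
}


def default_simulation_params(
    seed: int = 0,
    gene_count: int = 50,
    depths: Optional[dict] = None,
    qpcr_cv: float = 0.2,
) -> SimulationParams:
    """The 17-genome ganjang community with its study-condition trajectories."""
    registry = ganjang_genome_registry()
    taxa = []
    for genome_id, row in registry.iterrows():
        n0, r, k, d, act_out = _DEFAULT_TRAJECTORIES[genome_id]
        taxa.append(
            TaxonSpec(
                genome_id=genome_id,
                domain=row["domain"],
                genome_size_bp=int(row["genome_size_bp"]),
                marker_copies=int(row["marker_copies"]),
                initial_density=n0,
                growth_rate=r,
                carrying_capacity=k,
                decay_rate=d,
                gene_count=gene_count,
                activity_profile={"meju_in": 1.0, "meju_out": act_out},
                taxon_label=row["taxon_label"],
                source=row["source"],
            )
        )
    params = SimulationParams(taxa=taxa, qpcr_cv=qpcr_cv, seed=seed)
    if depths is not None:
        params.depths = dict(depths)
    return params
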