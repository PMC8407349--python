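"""End-to-end pipeline: simulate or load inputs, quantify all omics layers,
aggregate functional profiles, and write a manifest with checksums.

Stages
------
1. inputs      — either generated by the synthetic-community simulator or read
                 from TSV tables (count matrices, genome registry, gene
                 annotations, per-sample metadata, optional MAG quality table
                 and curation overrides); exactly one of the two modes.
2. amplicon    — per-domain relative profiles, diversity statistics, and
                 qPCR-anchored absolute marker-copy abundances.
3. metagenome  — MAG quality filtering, genome-size-normalized relative
                 abundances (community-wide and per domain), and copy-number-
                 corrected absolute genome densities.
4. transcriptome — per-gene RPKM, spike-in scale factors, normalized
                 expression, per-taxon expression shares and reference-sample-
                 relative totals.
5. functional  — KEGG level-2/level-3 sums, per-KO taxon attribution, and the
                 KO × genome presence matrix.

Identical configuration and seed give byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as fio
from .amplicon import absolute_marker_abundance, diversity_indices, goods_coverage, relative_abundance
from .containers import FeatureCountMatrix
from .functional import kegg_category_expression, pathway_presence, taxon_pathway_attribution
from .metagenome import absolute_genome_abundance, filter_high_quality_mags, size_normalized_relative_abundance
from .simulate import (
    SimulationParams,
    assemble_sample_info,
    default_simulation_params,
    sample_amplicon_counts,
    sample_metagenome_counts,
    sample_metatranscriptome_counts,
    simulate_qpcr,
    simulate_timecourse,
)
from .transcriptome import (
    relative_expression_by_taxon,
    rpkm,
    scale_to_reference_sample,
    spikein_scale_factors,
    normalize_expression,
    taxon_expression_totals,
)

__version__ = "0.1.0"

logger = logging.getLogger("fermquant")

#: input table names in file mode (name -> required)
_INPUT_TABLES = {
    "amplicon_bacteria_counts": True,
    "amplicon_fungi_counts": True,
    "metagenome_counts": True,
    "mrna_counts": True,
    "genome_registry": True,
    "gene_annotations": True,
    "sample_info": True,
    "mag_quality": False,
    "pathway_overrides": False,
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run; see the module docstring for stages."""

    outdir: str = "fermquant_out"
    inputs: Optional[dict] = None  # name -> path, file mode
    simulation: Optional[dict] = None  # simulator settings, fixture mode
    meju_removal_day: int = 60
    reference_sample: Optional[str] = None  # default: the meju-removal-day sample
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    spike_norm: str = "fraction"  # or "raw_count"
    seed: int = 0
    full_precision: bool = False

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("exactly one of 'inputs' (file mode) or 'simulation' (fixture mode) must be given")
        if self.inputs is not None:
            missing = [k for k, required in _INPUT_TABLES.items() if required and k not in self.inputs]
            if missing:
                raise ValueError(f"input mode missing required tables: {missing}")
        if self.spike_norm not in ("fraction", "raw_count"):
            raise ValueError(f"spike_norm must be 'fraction' or 'raw_count', got {self.spike_norm!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = fio.read_yaml(path)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)


# Fixed MAG quality records for the simulated community: the ten MAG-derived
# genomes pass the inclusive >=90% completeness / <=5% contamination filter
# (including both boundary values); five additional unresolved bins fail it and
# are represented in the reference set by isolate genomes instead.
_FIXTURE_MAG_QUALITY = [
    ("KG1", 98.2, 0.5), ("KG2", 96.5, 1.2), ("KG3", 95.1, 2.1), ("KG4", 99.0, 0.8),
    ("KG5", 92.3, 3.4), ("KG6", 94.8, 1.9), ("KG7", 91.6, 4.2), ("KG8", 97.4, 0.3),
    ("KG9", 90.0, 2.8), ("KG10", 93.7, 5.0),
    ("bin_11", 72.4, 3.1), ("bin_12", 88.0, 1.0), ("bin_13", 95.0, 7.5),
    ("bin_14", 61.2, 12.8), ("bin_15", 89.9, 2.0),
]


def fixture_mag_quality() -> pd.DataFrame:
    frame = pd.DataFrame(_FIXTURE_MAG_QUALITY, columns=["genome_id", "completeness", "contamination"])
    return frame.set_index("genome_id")


def simulate_inputs(params: SimulationParams) -> dict:
    """Run the simulator and assemble the full set of pipeline input tables."""
    truth = simulate_timecourse(params)
    depths = params.depths
    amp_b = sample_amplicon_counts(truth, "bacteria", int(depths["amplicon"]))
    amp_f = sample_amplicon_counts(truth, "fungi", int(depths["amplicon"]))
    mg = sample_metagenome_counts(truth, int(depths["metagenome"]))
    mrna, spike = sample_metatranscriptome_counts(truth, int(depths["metatranscriptome"]))
    qpcr = simulate_qpcr(truth)
    samples = assemble_sample_info(truth, qpcr, mrna, spike)
    return {
        "truth": truth,
        "amplicon_bacteria_counts": amp_b,
        "amplicon_fungi_counts": amp_f,
        "metagenome_counts": mg,
        "mrna_counts": mrna,
        "genome_registry": truth.registry,
        "gene_annotations": truth.genes.drop(columns=["expression_weight"]),
        "sample_info": samples,
        "mag_quality": None,
        "pathway_overrides": None,
    }


def _simulation_params_from_config(config: PipelineConfig) -> SimulationParams:
    settings = dict(config.simulation or {})
    use_defaults = settings.pop("community", "ganjang17")
    if use_defaults != "ganjang17":
        raise ValueError(f"unknown simulated community {use_defaults!r}")
    params = default_simulation_params(
        seed=settings.pop("seed", config.seed),
        gene_count=settings.pop("gene_count", 50),
        depths=settings.pop("depths", None),
        qpcr_cv=settings.pop("qpcr_cv", 0.2),
    )
    if "sample_days" in settings:
        params.sample_days = tuple(settings.pop("sample_days"))
    if "spike_mass" in settings:
        params.spike_mass = float(settings.pop("spike_mass"))
    if settings:
        raise ValueError(f"unknown simulation settings: {sorted(settings)}")
    params.meju_removal_day = config.meju_removal_day
    return params


def _load_inputs(config: PipelineConfig) -> dict:
    paths = config.inputs
    registry = fio.read_genome_registry(paths["genome_registry"])
    tables = {
        "truth": None,
        "genome_registry": registry,
        "amplicon_bacteria_counts": fio.read_count_table(paths["amplicon_bacteria_counts"], "amplicon_taxon"),
        "amplicon_fungi_counts": fio.read_count_table(paths["amplicon_fungi_counts"], "amplicon_taxon"),
        "metagenome_counts": fio.read_count_table(paths["metagenome_counts"], "genome"),
        "mrna_counts": fio.read_count_table(paths["mrna_counts"], "gene"),
        "gene_annotations": fio.read_gene_annotations(paths["gene_annotations"], registry),
        "sample_info": fio.read_sample_info(paths["sample_info"], config.meju_removal_day),
        "mag_quality": fio.read_mag_quality(paths["mag_quality"]) if paths.get("mag_quality") else None,
        "pathway_overrides": pd.read_csv(paths["pathway_overrides"], sep="\t")
        if paths.get("pathway_overrides")
        else None,
    }
    unknown = sorted(set(tables["metagenome_counts"].data.index) - set(registry.index))
    if unknown:
        raise ValueError(f"metagenome counts reference genomes absent from the registry: {unknown}")
    return tables


def _resolve_reference_sample(config: PipelineConfig, samples: pd.DataFrame) -> str:
    if config.reference_sample is not None:
        if config.reference_sample not in samples.index:
            raise ValueError(f"reference sample {config.reference_sample!r} not among samples "
                             f"{list(samples.index)}")
        return config.reference_sample
    at_removal = samples.index[samples["day"] == config.meju_removal_day]
    if len(at_removal) == 0:
        raise ValueError(
            f"no sample at meju removal day {config.meju_removal_day}; set reference_sample explicitly"
        )
    return at_removal[0]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate/load → quantify → aggregate and write the output bundle.

    Returns a dict of the in-memory results keyed by output name; all tables
    are also written under ``config.outdir`` together with a run manifest
    listing parameters, per-stage shapes and a sha256 checksum per file.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    manifest: dict = {
        "version": __version__,
        "seed": int(config.seed),
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("inputs", "simulation")
        },
        "mode": "simulation" if config.simulation is not None else "inputs",
        "stages": {},
        "outputs": {},
    }
    results: dict = {}
    written: dict = {}

    def emit(name: str, frame: pd.DataFrame, subdir: str = "") -> None:
        path = outdir / subdir / f"{name}.tsv" if subdir else outdir / f"{name}.tsv"
        fio.write_table(frame, path, full_precision=config.full_precision)
        written[name] = path

    # ---- stage 1: inputs -------------------------------------------------
    if config.simulation is not None:
        params = _simulation_params_from_config(config)
        tables = simulate_inputs(params)
        if tables["mag_quality"] is None:
            tables["mag_quality"] = fixture_mag_quality()
        truth = tables["truth"]
        density_long = (
            truth.density.stack().rename("genomes_per_ml").rename_axis(["genome_id", "sample_id"]).reset_index()
        )[["sample_id", "genome_id", "genomes_per_ml"]]
        fio.write_table(density_long.set_index("sample_id"), outdir / "inputs" / "truth_density.tsv",
                        full_precision=config.full_precision)
        written["truth_density"] = outdir / "inputs" / "truth_density.tsv"
        fio.write_yaml(_params_to_dict(params), outdir / "inputs" / "simulation_params.yaml")
        manifest["simulation"] = _params_to_dict(params)
    else:
        tables = _load_inputs(config)
        manifest["inputs"] = {k: str(v) for k, v in config.inputs.items()}

    registry = tables["genome_registry"]
    samples = tables["sample_info"]
    annotations = tables["gene_annotations"]
    for name in ("amplicon_bacteria_counts", "amplicon_fungi_counts", "metagenome_counts",
                 "mrna_counts"):
        emit(name, tables[name].data, subdir="inputs")
    emit("genome_registry", registry, subdir="inputs")
    emit("gene_annotations", annotations, subdir="inputs")
    emit("sample_info", samples, subdir="inputs")
    if tables["mag_quality"] is not None:
        emit("mag_quality", tables["mag_quality"], subdir="inputs")
    manifest["stages"]["inputs"] = {
        "n_samples": int(samples.shape[0]),
        "n_genomes": int(registry.shape[0]),
        "n_genes": int(annotations.shape[0]),
    }
    logger.info("stage inputs done (%.2fs)", time.perf_counter() - t0)

    # ---- stage 2: amplicon ----------------------------------------------
    t = time.perf_counter()
    diversity_rows = []
    for domain, key in (("bacteria", "amplicon_bacteria_counts"), ("fungi", "amplicon_fungi_counts")):
        counts = tables[key]
        rel = relative_abundance(counts, domain_scope=domain, basis="marker_copies")
        results[f"amplicon_relative_{domain}"] = rel
        emit(f"amplicon_relative_{domain}", rel.data)
        absolute = absolute_marker_abundance(rel, samples, domain, config.meju_removal_day)
        results[f"amplicon_absolute_{domain}"] = absolute
        emit(f"amplicon_absolute_{domain}", absolute.data)
        for s in counts.data.columns:
            if counts.data[s].sum() == 0:
                continue
            stats = diversity_indices(counts, s)
            stats.update({"sample_id": s, "domain": domain, "goods_coverage": goods_coverage(counts, s)})
            diversity_rows.append(stats)
    diversity = pd.DataFrame(diversity_rows).set_index(["domain", "sample_id"])
    results["diversity"] = diversity
    emit("diversity", diversity)
    manifest["stages"]["amplicon"] = {"n_diversity_rows": int(diversity.shape[0])}
    logger.info("stage amplicon done (%.2fs)", time.perf_counter() - t)

    # ---- stage 3: metagenome --------------------------------------------
    t = time.perf_counter()
    mg_counts = tables["metagenome_counts"]
    working_registry = registry
    if tables["mag_quality"] is not None:
        kept = filter_high_quality_mags(
            tables["mag_quality"], config.min_completeness, config.max_contamination
        )
        results["mag_quality_kept"] = kept
        emit("mag_quality_kept", kept)
        judged = set(tables["mag_quality"].index) & set(registry.index)
        failed = judged - set(kept.index)
        if failed:
            working_registry = registry.drop(index=sorted(failed))
            mg_counts = FeatureCountMatrix(
                mg_counts.data.drop(index=[g for g in failed if g in mg_counts.data.index]),
                feature_kind="genome",
            )
        manifest["stages"].setdefault("metagenome", {})["mags_kept"] = int(kept.shape[0])
    rel_all = size_normalized_relative_abundance(mg_counts, working_registry, scope="all")
    results["metagenome_relative_all"] = rel_all
    emit("metagenome_relative_all", rel_all.data)
    for domain in ("bacteria", "fungi"):
        rel_domain = size_normalized_relative_abundance(mg_counts, working_registry, scope=domain)
        results[f"metagenome_relative_{domain}"] = rel_domain
        emit(f"metagenome_relative_{domain}", rel_domain.data)
        absolute = absolute_genome_abundance(
            rel_domain, samples, working_registry, domain, config.meju_removal_day
        )
        results[f"metagenome_absolute_{domain}"] = absolute
        emit(f"metagenome_absolute_{domain}", absolute.data)
    manifest["stages"].setdefault("metagenome", {})["n_genomes_used"] = int(working_registry.shape[0])
    logger.info("stage metagenome done (%.2fs)", time.perf_counter() - t)

    # ---- stage 4: transcriptome -----------------------------------------
    t = time.perf_counter()
    reference = _resolve_reference_sample(config, samples)
    manifest["reference_sample"] = reference
    expr = rpkm(tables["mrna_counts"], annotations, samples)
    results["rpkm"] = expr
    emit("rpkm", expr.data)
    factors = spikein_scale_factors(samples, reference, variant=config.spike_norm)
    normalized = normalize_expression(expr, factors, reference_sample=reference)
    results["rpkm_normalized"] = normalized
    emit("rpkm_normalized", normalized.data)
    fio.write_yaml(
        {
            "reference_sample": reference,
            "spike_norm": config.spike_norm,
            "scale_factors": {s: float(v) for s, v in factors.items()},
        },
        outdir / "rpkm_normalized.meta.yaml",
    )
    written["rpkm_normalized_meta"] = outdir / "rpkm_normalized.meta.yaml"
    shares = relative_expression_by_taxon(tables["mrna_counts"], annotations)
    results["expression_shares_by_taxon"] = shares
    emit("expression_shares_by_taxon", shares.data)
    totals = taxon_expression_totals(normalized, annotations)
    results["expression_totals_by_taxon"] = totals
    emit("expression_totals_by_taxon", totals)
    scaled = scale_to_reference_sample(totals, reference)
    results["expression_totals_relative_to_reference"] = scaled
    emit("expression_totals_relative_to_reference", scaled)
    manifest["stages"]["transcriptome"] = {
        "n_genes": int(expr.data.shape[0]),
        "scale_factor_range": [float(factors.min()), float(factors.max())],
    }
    logger.info("stage transcriptome done (%.2fs)", time.perf_counter() - t)

    # ---- stage 5: functional --------------------------------------------
    t = time.perf_counter()
    level2 = kegg_category_expression(normalized, annotations, level="level2")
    results["kegg_level2"] = level2
    emit("kegg_level2", level2.values)
    emit("kegg_unannotated_mass", level2.unannotated.to_frame("unannotated_rpkm"))
    level3 = kegg_category_expression(normalized, annotations, level="level3")
    results["kegg_level3"] = level3
    emit("kegg_level3", level3.values)
    ko_set = sorted(k for k in annotations["ko_id"].unique() if k)
    attribution = taxon_pathway_attribution(normalized, annotations, ko_set)
    results["ko_attribution"] = attribution
    emit("ko_attribution", attribution.attribution.set_index("ko_id"))
    presence = pathway_presence(annotations, working_registry, tables["pathway_overrides"])
    results["pathway_presence"] = presence
    emit("pathway_presence", presence.presence.astype(int))
    emit("pathway_presence_provenance", presence.provenance)
    manifest["stages"]["functional"] = {
        "n_level2": int(level2.values.shape[0]),
        "n_level3": int(level3.values.shape[0]),
        "n_kos": len(ko_set),
    }
    logger.info("stage functional done (%.2fs)", time.perf_counter() - t)

    # ---- manifest --------------------------------------------------------
    for name, path in sorted(written.items()):
        manifest["outputs"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": _sha256(path),
        }
    fio.write_yaml(manifest, outdir / "manifest.yaml")
    results["manifest"] = manifest
    logger.info("pipeline done (%.2fs total)", time.perf_counter() - t0)
    return results


def _params_to_dict(params: SimulationParams) -> dict:
    out = asdict(params)
    out["sample_days"] = [int(d) for d in params.sample_days]
    out["taxa"] = [
        {k: (v if not isinstance(v, dict) else dict(v)) for k, v in asdict(t).items()}
        for t in params.taxa
    ]
    return out


def make_fixture(seed: int = 0, outdir: str = "fixture", gene_count: int = 50) -> dict:
    """Write a small simulated dataset (17 genomes × 6 samples) suitable for CI.

    Uses the default community registry and the study sampling days with small
    sequencing depths; returns the table paths keyed by input name.
    """
    out = Path(outdir)
    params = default_simulation_params(
        seed=seed,
        gene_count=gene_count,
        depths={"amplicon": 10_000, "metagenome": 50_000, "metatranscriptome": 100_000},
    )
    tables = simulate_inputs(params)
    truth = tables["truth"]
    paths = {}
    density_long = (
        truth.density.stack().rename("genomes_per_ml").rename_axis(["genome_id", "sample_id"]).reset_index()
    )[["sample_id", "genome_id", "genomes_per_ml"]]
    fio.write_table(density_long.set_index("sample_id"), out / "truth_density.tsv")
    paths["truth_density"] = out / "truth_density.tsv"
    for name in ("amplicon_bacteria_counts", "amplicon_fungi_counts", "metagenome_counts", "mrna_counts"):
        fio.write_table(tables[name].data, out / f"{name}.tsv")
        paths[name] = out / f"{name}.tsv"
    fio.write_table(tables["genome_registry"], out / "genome_registry.tsv")
    paths["genome_registry"] = out / "genome_registry.tsv"
    fio.write_table(tables["gene_annotations"], out / "gene_annotations.tsv")
    paths["gene_annotations"] = out / "gene_annotations.tsv"
    fio.write_table(tables["sample_info"], out / "sample_info.tsv")
    paths["sample_info"] = out / "sample_info.tsv"
    fio.write_table(fixture_mag_quality(), out / "mag_quality.tsv")
    paths["mag_quality"] = out / "mag_quality.tsv"
    fio.write_yaml(_params_to_dict(params), out / "simulation_params.yaml")
    paths["simulation_params"] = out / "simulation_params.yaml"
    return paths
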