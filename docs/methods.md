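# Methods

## The quantification problem

Sequencing observations of a microbial community are compositional, and each
omics layer distorts the composition differently. For a genome `g` with cell
density `d_g` (genomes/ml):

- amplicon reads arrive with probability ∝ `d_g · m_g`, where `m_g` is the
  per-genome copy number of the marker gene (16S rRNA for bacteria, ITS for
  fungi);
- shotgun metagenome reads arrive with probability ∝ `d_g · L_g`, where `L_g`
  is genome size in bp;
- mRNA reads for gene `i` arrive with probability ∝ `w_i · ℓ_i`, where `w_i`
  is the transcript abundance and `ℓ_i` the coding-sequence length, and the
  library size itself carries no information about the absolute transcript
  pool.

Two external anchors restore absolute scale: domain-specific qPCR totals
`Q_dom = Σ_{g∈dom} d_g · m_g` (marker copies/ml), and a constant mass `m` of
foreign spike-in RNA added to every sample before extraction.

## Absolute abundance chains

**Amplicon chain.** Relative amplicon abundances `r_g` are marker-copy
proportional, so `r_g · Q_dom` is the genome's absolute marker-copy abundance
(copies/ml, column sums reproduce the qPCR total exactly), and
`r_g · Q_dom / m_g` is its density. This recovery is exact in expectation
because the amplicon bias and the qPCR unit are the same quantity.

**Metagenome chain.** Size-normalized relative abundances
`r_g ∝ (c_g / L_g)` are genome proportional, not copy proportional. Abundance
profiles therefore carry a `basis` flag (`marker_copies` vs `genomes`), and
the copy-number correction converts genome-basis profiles into copy space
before anchoring:

```
d̂_g = r_g · Q_dom / Σ_i r_i · m_i
```

i.e. the denominator is the abundance-weighted mean copy number of the
domain. Applying the per-genome division `r_g · Q_dom / m_g` directly to a
genome-basis profile would misestimate every taxon whose copy number differs
from the community mean (two equal-density taxa with 10 vs 1 copies would
come out 10-fold apart); the copy-space formulation recovers equal densities
exactly, and the end-to-end recovery tests enforce this. Both formulas
coincide when all copy numbers are equal. Because the weighted-mean
denominator is itself a ratio of the profile, the correction is invariant to
positive rescaling of the domain profile — restricting a community-wide
profile to one domain and renormalizing commutes with the correction.

qPCR assays are domain-specific, so bacterial profiles are anchored only to
the bacterial qPCR total and fungal profiles to the fungal one; community-wide
profiles are restricted and renormalized per domain before conversion.

**MAG quality filter.** Genomes assembled from metagenomes enter the
reference set only with completeness ≥ 90% and contamination ≤ 5%
(inclusive thresholds, configurable). Inclusive boundaries are chosen so the
contract is exactly testable at the boundary values.

## Expression normalization

RPKM for gene `i` in sample `s` is
`c_is / (ℓ_i/1000) / (N_s/10⁶)`, with `N_s` the per-sample count of mRNA
reads mapped to the reference genomes — excluding spike-in and unmapped
reads. The denominator choice matters: spike reads are an artificial
admixture and would otherwise couple the within-sample unit to the
between-sample anchor.

Across samples, the spike fraction `φ_s = spike reads / N_s` estimates
`m / (κ T_s)` where `T_s` is the sample's total transcript mass and `κ` a
fixed proportionality; hence

```
factor(s) = φ_ref / φ_s  ∝  T_s / T_ref ,   factor(ref) = 1,
```

and `RPKM × factor` is comparable across samples in transcript-mass units.
The factor is a ratio of fractions, so multiplying one sample's gene counts,
spike reads and library size by any constant leaves its normalized expression
unchanged (verified to 1e-9 relative). A `raw_count` variant
(`factor(s) = spike_reads(ref)/spike_reads(s)`) is provided behind a switch
for pipelines whose spike and library sizes are already matched; the fraction
variant is the default because it is robust to library-size differences. The
reference sample defaults to the sample taken at the meju-removal day
(day 60), and per-taxon normalized totals can additionally be expressed
relative to the reference sample's grand total.

## Functional aggregation

Level-2 KEGG aggregation assigns each gene to a single primary category, so
category sums plus the separately reported unannotated mass conserve total
expression per sample (checked to 1e-9 relative). Level-3 pathway labels may
be semicolon-separated lists; a gene's full RPKM is counted in each listed
pathway, matching the semantics of pathway-map renderers, and the
conservation identity is deliberately not claimed at that level. Attribution
fractions divide each genome's summed expression of a KEGG ortholog by the
ortholog's total per sample; (KO, sample) cells with zero total are reported
as undefined rather than NaN. Attribution is scale-invariant per sample by
construction. Pathway presence is `any gene of the genome carries the KO`,
with per-cell curation overrides recorded as `curated_override` provenance.

## The synthetic community generator

The generator emulates the study conditions of a ganjang fermentation time
course sampled at days 0, 20, 40, 60, 90 and 180, with meju bricks removed at
day 60.

**Trajectories.** Each taxon follows logistic growth
`N(t) = K N₀ e^{rt} / (K + N₀(e^{rt} − 1))` up to the removal day and
exponential decay `N(t_rm) e^{−δ(t−t_rm)}` afterward. This is the simplest
two-phase model producing the observed rise-then-collapse of both domains;
the study system reports only the qualitative shape plus endpoint qPCR
values, so the per-taxon parameters were calibrated once against those
anchors: summed initial marker copies ≈ 1.0×10⁶ (bacteria) and 1.0×10⁴
(fungi) copies/ml, summed day-60 copies ≈ 4.8×10⁷ and 4.6×10⁵ copies/ml,
with the community structure of the system (dominant *Tetragenococcus*,
abundant aerobic halophiles, *Debaryomyces* as the main yeast, transient
early *Wickerhamomyces*, minor meju-derived *Bacillus*/*Aspergillus*). The
17-genome registry carries the genome sizes (2.4–38.0 Mb) and marker copy
numbers (1–10) of the reference genomes, with a flag marking copy numbers
estimated from related complete genomes rather than resolved from the
assembly.

**Expression.** Gene `i` of taxon `g` has a frozen per-gene weight
`w_i ~ lognormal(0, 1.5)` (heavy-tailed basal rates, drawn once per
simulation) and a phase-dependent activity multiplier (default 1.0 while meju
is present, 0.1–0.4 after removal, higher for aerobes). Transcript weight at
sample `s` is `d_g(s) · activity · w_i`, which lets tests separate
abundance-driven from activity-driven expression changes. Gene lengths are
lognormal around 900 bp (clipped to 150–6000); ~15% of genes are left without
KEGG annotation; annotated genes draw from a 40-ortholog synthetic KEGG
hierarchy spanning the metabolism relevant to a soy-sauce fermentation.

**Observation layers.** Counts are multinomial at fixed depth with the biases
above. Spike-in sequencing is modeled at the read-fraction level: the spike
read fraction is `m / (m + κ T_s)` with spike mass `m = 2` (μg, the constant
aliquot) and scale `κ = 2×10⁻⁷` chosen so the spike claims a few percent of
reads at peak biomass and dominates in near-empty late samples. Spike reads
are binomial at that fraction, remaining reads multinomial over genes with
probability ∝ transcript weight × length. qPCR totals get multiplicative
lognormal noise with mean 1 and CV 0.2 by default (a realistic triplicate
spread); recovery experiments that isolate sampling error set CV = 0. One
global seed drives everything; each layer draws from a deterministically
spawned child stream, so layers can be resampled independently and a fixed
seed gives bit-identical outputs.

**What the generator does not emulate** — and what passing tests therefore do
not show about real data: read-level artifacts (sequencing error, chimeras,
mappability, multi-mapping), extraction and amplification efficiency
differences between taxa, rRNA depletion losses, qPCR primer bias,
compositional interactions between taxa, and within-phase activity dynamics.
The recovery results demonstrate that the chain inverts the modeled biases
correctly, not that real libraries contain no others.

## Numerical choices and degenerate inputs

- Shannon entropy uses the natural log; Chao1 is the bias-corrected form
  `S_obs + n₁(n₁−1)/(2(n₂+1))`. Both match scikit-bio's conventions and are
  cross-checked against brute-force tallies.
- All-zero sample columns are carried through flagged (`empty_samples`), not
  dropped: a time course may contain failed libraries.
- Relative profiles must sum to 1 within 1e-9 per live column; attribution
  fractions within 1e-9; oracle equivalence is asserted at 1e-12 relative.
- Output tables are UTF-8 TSV written at 6 significant digits (full precision
  on request), which makes determinism byte-level testable.
- Re-normalizing an already spike-normalized matrix, anchoring a
  non-relative profile, zero spike reads, zero reference grand totals, and
  identifier mismatches across tables are all hard errors naming the
  offending sample/genome/gene.

## Simulation sizes used in validation

Recovery experiments use 200,000 shotgun reads and 50,000 amplicon reads per
sample over 20 seeds (median relative error of recovered densities is well
under 5% for every taxon-sample above 1% of community density); spike-in
experiments use 100,000–300,000 mRNA reads; oracle equivalence runs 200
random small fixtures. These sizes make the whole validation suite run in
seconds while keeping per-taxon counts large enough that sampling error, not
the method, dominates the residuals.

## Known limitations

- The copy-number correction assumes the registry's marker copy numbers are
  correct; for several genomes they are estimates from related genomes (the
  `marker_copies_estimated` flag propagates this provenance but no
  uncertainty is modeled).
- qPCR noise is modeled as a single noisy mean per sample; replicate
  structure is not simulated.
- The simulator's two-phase activity profile cannot produce within-phase
  expression peaks (e.g. a taxon active only at day 20 vs 40).
- Multi-mapped reads and pathway-level double counting at KEGG level 3 mean
  level-3 sums are not conserved quantities and should be read as pathway
  signals, not masses.
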