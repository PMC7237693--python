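# Methods

This note documents the models, statistics and numerical choices behind
`mutland`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where several reasonable options existed.

## Coordinates and containers

All internal coordinates are 0-based half-open (BED convention); VCF
positions are converted on read and write. Variant catalogs are
columnar (numpy-backed) with per-record genotype summaries
(`n_called`, `n_missing`, `n_het`, `n_hom_alt` over a fixed sample
count) in population mode, or an event multiplicity (≥ 1) in somatic
mode. Interval arithmetic (mask combination, window fractions, feature
aggregation) is event-sweep based and is verified against per-base
boolean loops on ≤ 10 kb fixtures in the test suite.

## Accessible genome and windows

A base passes the combined mask iff it is mappable AND callable in
strictly more than 75% of every species group's samples AND outside CNV
intervals. The callability threshold is evaluated per species group
("poor in ≥ 25% of either group" fails the base); the boundary case is
exact — 3 callable of 4 samples is 25% poor and fails. The 35 bp k-mer
mappability computation itself is upstream of this package; mappability
arrives as a mask.

Windows start at multiples of the step and only windows fully contained
in the chromosome are emitted, so the passing-fraction denominator
(`window_size`) is constant; trailing partial windows are dropped.
Retention is inclusive: f_w ≥ 0.5 by default. Feature tracks aggregate
per window either as overlap (covered passing bases / passing bases) or
as a value-weighted mean over passing bases; windows with zero passing
bases yield NaN rather than 0.

## Densities

Quality filters (population mode): missingness ≥ 20% (inclusive),
distance ≤ 5 bp (inclusive) from any InDel record (both SNVs and
InDels are removed; an InDel is not its own neighbour), heterozygous
fraction strictly > 80% of called genotypes, and fixed-derived sites
(all called genotypes homozygous alternate) — the latter because a
fixed site is not segregating; it is tallied separately so the count is
visible. Somatic catalogs only receive the InDel-proximity filter;
requesting genotype filters on them is an error.

d_w = n_w / f_w with the count restricted to pass-mask SNVs; each
overlapping window counts a variant independently; somatic events are
weighted by multiplicity. Standardization uses the sample SD (n − 1);
Pearson correlations downstream are invariant to that choice. Ranks
are ascending with average ties, which keeps rank sums exact for the
Mann–Whitney test.

CpG>T means C>T where the reference C is followed by G, or G>A where
the reference G is preceded by C (strand-folded); non-CpG SNVs are
those whose mutated base participates in no reference CpG; other
substitutions at CpG sites belong to neither class and are returned
separately, so the three groups plus context-less edge records
partition the SNVs exactly.

## Statistical machinery

* **Mann–Whitney U** (diagonal split): exact null when the smaller
  group has ≤ 25 observations and the pooled response is tie-free,
  otherwise the normal approximation with tie and continuity
  corrections — mirroring R's `wilcox.test` switchover. Tied ranks
  (rank_A = rank_B) leave the split dichotomy undefined; such windows
  are excluded and counted in the result metadata.
* **Kolmogorov–Smirnov** (trinucleotide-difference): exact two-sided p
  when n·m ≤ 10⁴ and tie-free, asymptotic otherwise; tied ranks always
  take the asymptotic route. Both tests are checked against
  full-enumeration oracles (all label assignments) in the suite.
* **Chi-squared tables** use no continuity correction by default: the
  enrichment tables hold genome-scale counts where the correction is
  negligible, and a flag restores Yates parity with R's 2×2 default.
  The one exception is the signature-difference contingency table,
  which classifies only 96 classes and is sparse; there the Yates
  correction is the default, matching what R's `chisq.test` would do
  and keeping the test conservative on null signatures.
* **Sequential enrichment**: stage-1 chi-squared per class against the
  rest; classes are then re-tested from most to least significant with
  previously tested classes removed from both totals (class counts are
  not independent). Ordering is by ascending stage-1 p with descending
  statistic as tie-break (relevant when p underflows) and label as the
  final tie-break. Fold-enrichment E_T always uses the raw genome-wide
  fractions; classes empty in both datasets get E_T = NaN, p = 1,
  flagged.
* **Partial correlation** is computed from OLS residuals (intercept
  included), the definition underlying R's `pcor`; collinear controls
  and zero residual variance are rejected.
* **Quantiles** (95/5 fold-enrichment) use linear interpolation
  (R type 7).
* **Signature-difference test**: per signature, each class's Δσ is
  regressed across tumor types on the signature's mutation load
  (ordinary least squares, as with a Gaussian-identity `glm`);
  classes are cross-classified by slope significance (p < 0.05)
  against the pooled-run global significance (p < 0.05), and the 2×2
  table is chi-squared tested with Bonferroni correction across tested
  signatures. Only non-artifact signatures detected (≥ 2 samples) in
  ≥ 2 tumor types enter, and ≥ 3 tumor types are required for the
  regressions. Whether "globally significant" should come from the
  pooled tumor run or per-type runs is not uniquely determined; the
  pooled run is the default and the argument is explicit.

## High-confidence trinucleotide filter

A variant enters the spectra only if: (1) it lies where the
trinucleotide context is identical across all reference genomes — this
arrives as a *consistency mask* input, cross-genome mapping being out
of scope; (2) no other species carries a variant at the same position
(species exclusivity); (3) its full 3-base context lies inside the
pass region (exclusion within 1 bp of a mask border — the border
distance is not externally prescribed, and context containment is the
natural choice); (4) it is not part of a multinucleotide variant
(no same-species SNV within 1 bp); (5) it does not overlap a
same-species InDel; (6) it does not overlap another species' InDel at
frequency ≥ 50% (inclusive). Windows are re-retained only where ≥ 50%
passes the combined original + consistency mask. Because CpG>T
transitions recur across species far more often than non-CpG changes,
rule (2) removes proportionally more of them — the suite checks this
direction on fixtures with injected recurrence.

## The synthetic-data generator

The generator's purpose is statistical: give downstream stages inputs
with the cross-dataset correlation structure, spectrum composition,
CpG landscape and nuisance processes the analysis assumes, at sizes a
desk machine handles.

* **Latent field.** One zero-mean Gaussian vector per *tile* across
  datasets with correlation Σ (validated symmetric, unit-diagonal,
  PSD — the offending eigenvalue is reported otherwise), scaled by
  `latent_sd` (default 0.25) and exponentiated. The log-normal form
  guarantees positive rates and preserves rank correlations; no
  generative model of regional mutation-rate variation is claimed —
  this is an explicit stand-in. Tiles are `step`-length segments:
  overlapping windows share sequence, so they must share intensity; a
  window's rate is the sum of its tiles and window-level cross-dataset
  correlations equal the tile-level ones. Rates are scaled so each
  dataset's expected per-window count is `mean_mutations_per_window`.
  Σ is specified on the latent log scale; with `latent_sd` 0.25 the
  exp-scale Pearson of a 0.65 entry is ≈ 0.643, and Poisson counting
  attenuates further by var/(var + mean) — recovery tolerances absorb
  both.
* **Reference and CpG landscape.** Background bases are iid with CpG
  dinucleotides suppressed; CpGs are planted per tile at
  `cpg_rate` × step × (island profile), so per-window CpG density is
  proportional to the profile (default: a skewed log-normal profile,
  emulating the strongly skewed genome-wide CpG-content distribution).
  CpG>T classes can only be placed at reference CpG sites, which
  concentrates them where the profile is high.
* **Classes and placement.** Per tile, the SNV count is Poisson with
  the field's rate; counts are attributed hierarchically to signatures
  (the dataset's mixture) and classes (the signature's 96-vector), and
  placed uniformly at compatible folded contexts. Population draws are
  without replacement within a tile; when a tile's pool for a context
  is exhausted the excess is placed at other contexts in the *same*
  tile, so the spatial intensity field is preserved exactly (an
  earlier nearest-tile policy measurably attenuated cross-dataset
  correlations). Only when a tile has *no* position of a required
  context do draws move to the nearest tile that has one, with a
  logged warning — nothing is silently dropped.
* **Nuisance processes.** Extra records with ≥ 20% missing genotypes,
  100% heterozygous calls, and fixed-derived genotypes are injected at
  configured rates (defaults 2%/2%/0.5% of the clean rate), plus
  InDels at 2%; somatic catalogs aggregate repeated positions into
  multiplicities and add ~1% recurrent events. Genotype summaries for
  clean variants follow a 1/k allele-frequency spectrum with
  heterozygote counts from the random-pairing expectation (parity
  fixed); the ~1–2% of records this pushes over the heterozygote
  filter is uniform thinning and does not bias landscape correlations.
* **Signatures.** COSMIC probability vectors are external data, so the
  package ships a *synthetic* signature matrix: an SBS1-like column
  with 88% of its mass on the four N[C>T]G classes, flat-ish
  SBS5/SBS40-like columns with ~2% CpG>T mass (so the default
  0.1 × SBS1 + 0.9 × SBS5 mixture puts ≈ 10% of mutations at CpG>T),
  plus featureless null and flagged artifact columns. Any
  COSMIC-format 96 × S TSV can be supplied instead.
* **Signature-difference design.** The detection study for the
  signature-difference test is constructed at the statistic level: one
  signature's load drives the per-tumor-type Δσ of 30 designated
  (globally significant) classes linearly; null signatures' loads are
  made exactly orthogonal to the driver's (residualized and shifted —
  Pearson is shift-invariant), because with a handful of tumor types
  chance load correlation would otherwise leak the injected effects
  into a null signature's regressions and misstate its false-positive
  behaviour.
* **Determinism.** One global seed; every stage derives a child
  generator from the seed and the stage name, so identical configs
  reproduce byte-identical outputs and regenerating one stage does not
  perturb others.

What the generator does **not** emulate: linkage disequilibrium,
coalescent demography, selection, realistic chromosome counts or
lengths, sequencing-error models, or cross-genome alignment (the
consistency mask is random). Passing tests therefore demonstrate that
the *analysis machinery* is correct and calibrated under the assumed
statistical structure — not that real catalogs satisfy that structure.

## Study sizes

The bundled studies run at deliberately modest sizes chosen once as
desk-scale stand-ins for the classical 1 Mbp geometry: the recovery
study uses 5000 windows of 30 kb (15 kb steps) at 3000 SNVs per window
— enough that Poisson attenuation of a 0.65 correlation stays around
one percent, mirroring the thousands-per-window counts of real panels
— and the calibration study uses 1000 replicates of 500 windows. The
type-I band (3–7% at α = 0.05), the ±0.05 recovery tolerance and the
r > 0.99 spectrum-mixture bound all refer to these conditions.

## Known limitations

* Recovered cross-dataset correlations sit systematically ~0.02–0.03
  below the configured Σ (log-normal distortion, Poisson thinning,
  nuisance records); the tolerance absorbs this, but Σ should be read
  as a latent-scale parameter, not an exact prediction of measured r.
* The per-class rank machinery inherits heavy ties when a class is
  rare (many zero-count windows); KS then uses the asymptotic p, which
  is approximate under ties.
* The high-confidence filter treats "multinucleotide variant" as
  adjacency within 1 bp in the same catalog; true MNV annotation from
  read-backed phasing is out of scope.
* `aggregate_feature`'s mean mode loops over feature intervals and is
  intended for track-sized inputs (thousands of intervals), not
  base-pair-resolution signal.
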