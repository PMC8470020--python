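# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic tests do and do not demonstrate.

## Multiheme cytochrome detection

A c-type heme attachment site is the motif C-x-x-C-H. The scanner reports
every start index `p` with `seq[p]='C'`, `seq[p+3]='C'`, `seq[p+4]='H'`;
overlapping matches are all counted and ambiguity codes (`X` etc.) never
stand in for Cys or His. Longer spacer variants (CxxxCH, CX15CH) occur in
nature but are rare; they are deliberately excluded from the default motif
so that the reported counts mean exactly one thing. A protein is called an
MHC at `min_motifs = 2` (configurable): dihemes are the smallest proteins a
multiheme inventory conventionally counts, and the reference inventory
includes proteins with as few as 2 and as many as 67 motifs.

Surface localisation is approximated by a C-terminal transmembrane helix:
a length-19 window whose start lies within the last 40 residues and whose
mean Kyte–Doolittle hydropathy is ≥ 1.6. Window length 19 is the classic
choice for TM helices, 1.6 is the standard "putative TM" band of the
original scale, and the 40-residue leash keeps the call specific to
C-terminal anchoring. The threshold comparison carries a 1e-9 tolerance so
a window sitting exactly at the cutoff (e.g. poly-alanine at threshold 1.8)
is included regardless of float accumulation. These parameters are
configuration, not claims about any particular published predictor; real
inventories produced with other predictors may differ at the margin.

## Carbon-fixation completeness and autotrophy

Pathway completeness is set arithmetic: `100·|essential ∩ annotated| /
|essential|`, with presence binary per orthology identifier (a percent-
present heat map, not a copy-number measure) and one identifier per subunit
of multi-subunit complexes. The packaged essential-gene sets for the seven
pathways are curated working lists in the KEGG orthology namespace and are
explicitly editable configuration — different curations shift absolute
percentages, which is why the tests exercise planted synthetic annotations
against the shipped defaults rather than any real genome.

"Full genomic potential" means 100% completeness plus all diagnostic key
genes (RuBisCO large subunit and phosphoribulokinase for CBB; CO
dehydrogenase and acetyl-CoA synthase for WL; ATP-citrate lyase for rTCA;
and so on). The threshold is configurable because any fixed cutoff is a
judgment call. roTCA gets a stricter guard: its key enzyme, citrate
synthase, is part of the ordinary TCA cycle of countless heterotrophs, so a
roTCA call requires the complete TCA gene complement no matter the
threshold. This encodes the observation that bins carrying citrate synthase
alone must not be scored as reverse-oxidative-TCA autotrophs.

Related cycles genuinely share orthologs (rTCA and roTCA both contain TCA
enzymes; the two 4-hydroxybutyrate cycles share the 4-hydroxybutyryl-CoA
dehydratase), so planting one pathway legitimately raises a neighbour's
completeness. Exact planted-fraction recovery therefore holds per planted
pathway, and the recovery tests are structured that way.

## Reverse methanogenesis and metabolism labels

The ANME audit checks three things against the annotation table: all seven
central steps of the methanogenic pathway present (fmd, ftr, mch, mtd, mer,
mtr, mcr — any subunit counts a step), all four canonical methanogen
hydrogenases absent (Ech, Vho, Mvh, Frh), and the methylotrophy
methyltransferases absent. That combination is the genomic signature of an
archaeon that can only run the pathway in reverse, i.e. oxidize methane.
Nitrate- and sulfate-reduction absences and the Fpo/Hdr/Rnf electron-
transfer complexes are reported as context flags but do not enter the
verdict.

The putative-metabolism labels come from a fixed rule order (documented in
`magpot.markers.assign_metabolism`). Published tables of this kind are
curated by hand, and a literal marker-to-label mapping reproduces none of
them; the implemented order encodes the curation conventions needed to make
the rules deterministic:

* Only the aa3-type oxidase (coxA) fires a lifestyle label. The cbb3-type
  oxidase (ccoN) has high oxygen affinity and is common in microaerophiles
  and anaerobes, so on its own it is treated as evidence, not a lifestyle.
* The aerobic/facultative label is suppressed for organisms already
  labelled by a more specific energy metabolism (methane oxidizers,
  autotrophs); the facultative split keys on fermentation or sulfate-
  respiration evidence (Fe-hyd, dsrAB), not on nitrate genes, since many
  denitrifiers are conventionally listed as aerobes.
* Uptake hydrogenases are accessory — not "H₂ utilization" — in organisms
  labelled fermentative (their FeFe hydrogenases evolve H₂) and in
  sulfur-oxidizing autotrophs (sulfur is the electron donor).
* Acetogenesis requires the complete Wood–Ljungdahl pathway *and* the
  cooS–cooF pair; cooS alone is a widespread anaerobic CO dehydrogenase.
* narG with nosZ upgrades "nitrate reduction" to "denitrification"; nosZ
  alone fires nothing.

Under this order the packaged 33-bin marker table reproduces its reference
label column exactly (33/33), which is the design criterion the order was
built against; it is a reconstruction of an unstated curation procedure,
not a community standard, and is exposed as editable configuration. The
reference column itself ships normalized to the fixed label vocabulary
(e.g. "sulfide and sulfite oxidation" → "sulfur compound oxidation";
the organotrophic note of one GH1-carrying bin → "carbohydrate
utilization").

## Diversity statistics

Chao1 uses the bias-corrected form `S_obs + f1(f1−1)/(2(f2+1))` (computed
via scikit-bio). The optional corrected-singleton variant replaces the raw
singleton count by a Good–Turing estimate before applying the same form:
under a Poisson abundance model `f_k ∝ λ^k e^{−λ}/k!`, the ratio
`f2/f3 = 3/λ` gives `λ̂ = 3f3/f2` and hence `f̂1 = 2f2/λ̂ = 2f2²/(3f3)`.
This corrects for sequencing errors that inflate f1. When f3 = 0 the
estimate is undefined and the classic form is used with a warning; f3 and
f4 are always reported as diagnostics. Shannon H is reported in nats by
default (a 744-taxon community with H = 5.03 is only meaningful on the
natural-log scale, where the maximum is ln 744 ≈ 6.61); base 2 is a flag.
Coverage is defined as `100·S_obs/Chao1` — the fraction of the estimated
true richness that was observed — displayed rounded to an integer with full
precision retained. Good's coverage and rarefaction are out of scope.

## Quantification

qPCR: ordinary least squares of Cq on log10(copies) (scipy linregress);
efficiency `(10^(−1/slope)−1)·100` follows from the definition of
per-cycle amplification. Efficiencies are reported even when implausible —
field assays on inhibitor-rich mud can run far below 100% — with a warning
below 70%. Replicates aggregate as mean ± sample SD (n−1).

Tracer rates: the fraction of ¹⁴C label recovered in oxidation products
times the ambient methane pool, divided by incubation time, per replicate;
killed-control mean subtracted; negative net rates clamped to zero with a
warning. Whether the total-activity denominator includes only recovered
CH₄ or also product pools varies between labs; the implemented convention
(product/total of the same record) is stated here rather than inferred.
Isotope-fractionation corrections are out of scope.

## Ledger roll-ups

Completeness bands use explicit interval closure; the published prose band
"90–98%" is implemented as [90, 100), which is the interval its count (21)
actually corresponds to on the ledger. "Complete" 16S means strictly
greater than 1400 bp; absent entries (no 16S recovered in the bin) never
count. Phylum sums resolve bins through an explicit bin→phylum mapping
(shipped for the reference ledger, since the taxon column mixes ranks);
unmapped bins are reported under "unresolved", never dropped. Abundances
are stored to 2 decimals as printed and summed at full precision; sums are
displayed at 1 decimal. The genome fraction of a single protein is
`100·3·aa/bp`.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed) — repeat calls are
byte-identical.

* **Proteins.** Backgrounds are drawn from Swiss-Prot-like residue
  frequencies; accidental CxxCH motifs are removed by local rewrite
  (mutating the His) rather than by excluding C/H from the alphabet, so
  composition stays realistic. Planted proteins interleave exact motifs
  with spacers from a C/H-free, hydrophilic-biased alphabet, so the planted
  motif count is exact by construction and only deliberately planted tails
  (21 residues from {L,I,V,F,A} near the C-terminus) can satisfy the TM
  window. Real proteomes have domain structure, signal peptides and
  compositional heterogeneity that this does not model: perfect
  precision/recall on synthetic MAGs validates the scanner's logic, not
  any claim about real annotation pipelines.
* **Annotations.** Pathway subsets are chosen by seeded shuffle-then-prefix
  (uniform over subsets of the required size), with `round(fraction·|set|)`
  genes (half-up). Markers are planted via their catalog aliases;
  multi-subunit complexes plant their full complement.
* **ASV tables.** Species weights are log-normal (σ = 1.5 default; σ = 0
  uniform) or log-series; reads are a single multinomial draw, so depth is
  conserved exactly. Group planting rescales each group's weight mass to a
  target share, so a planted 39% dominant group is recovered within
  sampling error. No chimeras, no denoising artefacts, no compositional
  zeros beyond sampling.
* **qPCR.** Standards at 10³–10⁸ copies (six decades), intercept 38 Cq,
  Gaussian Cq noise (default sd 0.1), triplicates — the scale of a typical
  SYBR assay. Default efficiency 90%.
* **Tracer.** Defaults mirror the study design: true rate 0.47 nmol cm⁻³
  day⁻¹, 5-day incubation, triplicates, 5% multiplicative noise, an
  abiotic blank of 0.02 nmol cm⁻³ day⁻¹ present in live samples and killed
  controls alike (so control subtraction is unbiased), and a 1400 nmol cm⁻³
  ambient methane pool (≈1.4 mM dissolved CH₄, a realistic value for
  methane-saturated mud). The recovery criterion is on the mean estimate
  across seeded replicate experiments, because a single n = 3 experiment
  bounds the truth by its own sample SD only ~92% of the time.

## Problem sizes

The default test suite and the acceptance script run the motif oracle on
1,000 random 200-mers, 100-seed recovery loops for qPCR, tracer and
pathway-fraction checks, and the full 33-bin community; the whole suite
completes in a few seconds on one CPU. These sizes were chosen as the
smallest that make the recovery rates stable to the third decimal.

## Known limitations

* Marker and pathway gene lists are curated stand-ins; absolute
  completeness percentages depend on the curation.
* The metabolism rule order is a reconstruction of a hand-curated table;
  other communities may need different suppression conventions.
* The TM predictor is a single-window hydropathy rule, not a topology
  model (no signal-peptide discrimination).
* The corrected-singleton Chao1 variant assumes the Poisson ratio argument
  above; it is an option, and the default path never depends on it.
* Real MHC inventories, Table-style completeness values and wet-lab rates
  from the original community depend on deposited reads and lab
  measurements; the package reproduces their arithmetic and their planted
  synthetic analogues, not the measurements themselves.
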