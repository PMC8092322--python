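# Methods

This note documents the models and procedures implemented in `trnaswitch`,
the parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Domain model

A tRNA gene is a 60–100 nt RNA sequence (DNA input is normalized to the RNA
alphabet on ingest), optionally with a dot-bracket secondary structure and a
genomic interval (0-based half-open, stranded).  The genetic code is the
standard nuclear table: 61 sense codons, 3 stops; alternative tables can be
passed anywhere a `GeneticCode` is accepted, but none other is shipped.

**Anticodon localization.**  With a structure, the anticodon is the middle
three bases of the *second hairpin loop* in 5′→3′ order — the anticodon loop
of the cloverleaf — which equals positions 34–36 of the canonical numbering
for a canonical-length tRNA.  A loop-based rule is used instead of a fixed
offset because tRNA gene lengths vary (the Thr-CGU gene modeled here is only
72 nt), so fixed indices would misfire; this rule is this package's choice
for non-canonical-length genes.  Without a structure, the anticodon is
parsed from the gtRNAdb-style header (isotype and anticodon in the second
and third dash-separated tokens) and verified to occur in the sequence;
disagreement is an error, never silently resolved.  The decoded amino acid
is the genetic-code entry of the anticodon's reverse complement; anticodons
that would read a stop codon are representable and flagged, since a planted
or observed mutation may create one.

## Switch detection

The closest-nonequal-neighbor statistic asks, for each gene, which pool
member of *different sequence* is nearest under exact global (unit-cost
Needleman–Wunsch) edit distance, and whether that neighbor decodes a
different amino acid.  Exact edit distance replaces heuristic read-aligner
matching: it is deterministic, parameter-free and complete.  Identical
duplicate copies are excluded ("nonequal" is at the sequence level); ties
are broken by lexicographically smallest gene id, a convention this package
fixes because any choice must be fixed for determinism.  An optional banded
mode (default band 12 when requested) accelerates large pools; distances
beyond the band are reported as band + 1, which preserves the argmin
whenever the true nearest distance is within the band.  Both per-gene
events and a deduplicated pair count are reported, since a switched gene
and its donor parent can both flag.

Per-family trees use Jukes–Cantor distances d = −(3/4)·ln(1 − 4p/3) on
aligned sequences, with p ≥ 0.75 capped at 5.0 substitutions/site
(configurable) as the model's saturation point, and Saitou–Nei neighbor
joining (via scikit-bio).  Negative branch-length estimates on non-additive
inputs are clamped to zero; the deficit is *not* transferred to the sister
branch.  Bootstrap support resamples alignment columns with replacement and
reports, for each internal bipartition of the full-data tree, the fraction
of replicate trees containing it; fully deterministic under the seed.

## Variant scanning

Anticodon transcript positions are mapped to genomic coordinates through
the gene interval: ascending on the plus strand, descending on the minus
strand, with allele comparison through the reverse complement.  Only
single-nucleotide substitutions are scored; indels are logged and skipped,
and intron-containing genes are rejected.  Multi-allelic records are
decomposed per alternate allele.  A sample is a carrier when its genotype
contains at least `min_allele_count` copies of the allele (default 1, so
heterozygous carriers count — whether heterozygotes should count is not
decidable from the method description this emulates, so the knob is
exposed).  Synonymous anticodon changes (same decoded amino acid via the
wobble family) are retained and flagged, never dropped.

## Folding stability

`dg_fold` evaluates a *fixed* structure — this is deliberately not a folding
engine, because the question is how one mutation changes the stability of
the same cloverleaf.  ΔG(T) = Σ(ΔH − T·ΔS) over helix stacks and loop
penalties (hairpin, bulge, internal, and an affine multibranch term
a + b·branches + c·unpaired, with a = 3.4, b = 0.4, c = 0.1 kcal/mol at
37 °C).  The packaged table (`data/nn_energy_params.tsv`) stores ΔH and
ΔG37 per term; ΔS is derived as (ΔH − ΔG37)/310.15 at load, so tabulated
37 °C values are reproduced exactly and ΔG is affine in T with slope
−ΣΔS.  Watson–Crick stacks carry published-magnitude parameters;
G·U-containing stacks carry representative values (−1.40 kcal/mol with one
G·U, −0.50 with two); loops are modeled as purely entropic (ΔH = 0), with
Jacobson–Stockmayer 1.75·R·T·ln(n/n_max) extrapolation beyond the table.
The model therefore commits to *sign and ordering* contracts — a broken
stem pair destabilizes at every temperature, a restored pair re-stabilizes
— not to literal published energies; dangling ends and coaxial stacking
are omitted.  Non-canonical pairs other than G·U are not scored: the pair
is dissolved into the surrounding loop, which is how a stem U·C mismatch
is represented.  Temperatures are accepted in °C (default grid 30/35/42)
and converted to kelvin internally.

A variant whose ΔΔG versus the reference exceeds **2.65 kcal/mol** at any
requested temperature is flagged as a likely substrate of the rapid tRNA
decay pathway; the comparison is strictly greater-than.  The packaged
three-allele fixture (reference G28:C40 pair / 28 G>U mismatch / 28 G>U +
40 C>A restored pair) is a *constructed synthetic* 72-nt cloverleaf with
that pairing geometry, not the natural gene sequence.  When an external
RNA-energy evaluator is present, a test cross-checks the rank ordering of
ΔG across the fixtures (Spearman ≥ 0.9); it is skipped otherwise.

## Codon demand

"Relative codon usage frequency" is the focal codon's share within its
amino acid's synonymous family per gene; a gene lacking the amino acid has
an undefined (not zero) share and drops out of both means.  The demand
statistic at each time point is the unweighted mean share over the top-N
genes by log2 fold change (N = 25 by default; boundary ties broken by gene
id; each time point ranked independently) divided by the mean over all
genes.  The background *includes* the top genes by default — with ~25 top
genes among thousands the dilution is negligible, and an `exclude_top`
mode is provided.  On a 1000-gene fixture with enrichment 2.0 the
include-top ratio is 1.95 by construction (2/(1 + 25/1000)); the
exclude-top ratio is exactly 2.0.  Group comparisons use the tie-corrected
Kruskal–Wallis H with the χ² approximation (df = k − 1), with significance
stars at 0.05/0.01/0.001/0.0001.  qPCR fold changes use 2^−ΔΔCt with
reference genes aggregated by arithmetic mean of Ct (equivalent to a
geometric mean of abundances at efficiency 2).

## Proteome statistics

The pipeline operates on a peptides × samples log2-intensity matrix with
variant-class labels (`base`, `T>K`, `T>M`) and a sample→strain group map.

- **Filter**: keep rows with ≥ 3 observed values in at least one group
  (`min_valid` configurable); groups smaller than the threshold draw a
  warning since the rule can never pass within them.
- **Imputation**: per sample, missing values are drawn from
  N(μ − 1.8σ, (0.3σ)²) of that sample's observed values.  The 1.8/0.3
  constants are the common practice of label-free proteomics software;
  they are exposed as parameters.
- **Substitution fractions**: substituted-peptide observations over
  substituted + base observations *at substitutable sites* (base peptides
  containing Thr), in count mode by default; an intensity-weighted mode is
  provided.  The fraction for a strain divided by the control strain's
  fraction has null expectation 1.  Substitution fractions are computed on
  the unfiltered table: the valid-value rule exists for differential
  testing and would discard exactly the rare variant peptides of interest.
- **Thr shift**: median(subset) − median(all) plus a two-sample KS statistic
  between the subset and its complement, with a permutation p-value over
  random subset membership (vectorized; seeded).  Because the subset is
  part of the reference distribution, the measured shift understates the
  true depression by roughly the subset fraction — negligible when Thr
  peptides are a few percent of the table.
- **Moderated t / FDR**: t = (x̄₁ − x̄₂)/(SE_pooled + s₀) with s₀ = 1 by
  default; s₀ = 0 recovers the ordinary two-sample t.  The null pools |t|
  over group-label permutations (all distinct assignments when ≤ 2000,
  otherwise a seeded sample).  For each row, the FDR estimate at its own
  cutoff is median-over-permutations of null exceedances divided by
  observed exceedances; the q-value is the minimum estimate over all
  cutoffs that still include the row (suffix minimum over descending |t|),
  capped at 1 — hence monotone in the |t| ranking.  No π₀ shrinkage is
  applied (conservative).  Protein-level rollup is out of scope; the
  statistics operate on the quantification table as given.

## Tetrad model

Meiosis is modeled without crossover interference or gene conversion: each
heterozygous locus independently assigns its two mutant-allele spores to a
uniformly chosen 2-subset of the four spores, which reproduces the 1:1:4
PD:NPD:TT ratio for unlinked locus pairs; `same_locus` linkage copies the
partner's subset (cis).  A spore dies exactly when it carries the essential
deletion and no functional suppressor allele — death is deterministic given
genotype, matching all-or-none dissection grids.  Expectations are computed
exactly over the enumeration (as `Fraction`s); the simulator is checked
against them within binomial bounds.  This yields 1/2 viability for an
unsuppressed heterozygous deletion, 3/4 for an unlinked heterozygous
suppressor, 1 for a homozygous suppressor, and marker fractions of 1/2
among all spores, 0 among viable spores unsuppressed, 1/2 suppressed.

## Synthetic data: what it does and does not emulate

Generators are deterministic under their seed and export a `GroundTruth`
that scores the consumer stage exactly.

- **tRNA pools** share one 72-nt cloverleaf template; each family carries a
  private signature (default 6 fixed substitutions at unpaired,
  non-anticodon positions) so cross-family distances exceed within-family
  distances by construction (margin ≥ 3).  Within-family variation is
  Poisson(rate·L) at free positions, or — in `distinct_copies` mode — a
  deterministic ladder in which copy k differs from the consensus at
  exactly k−1 positions, making nearest-neighbor recovery of planted
  switches provably exact when switches are planted on interior copy
  indices.  Planted switches substitute anticodon bases only and keep the
  family header, the hallmark of a real switch.  Not emulated: real
  isodecoder diversity, modified bases, introns.
- **Genomes/VCFs** place pool genes non-overlapping on random chromosomes
  and both strands, write uncompressed VCF v4.2 with per-strain genotypes,
  plant anticodon variants at exact coordinates plus decoys elsewhere.
  Copy numbers mirror the modeled system (e.g. a 14-copy Lys-CUU family, a
  5-copy elongator-Met family, singleton Thr-CGU).  Not emulated: read
  errors, reference blocks of gVCFs, structural variation.
- **Expression time courses** use the five heat-shock time points (4, 11,
  16, 26, 40 min) and a top-25 induced set whose focal-codon share within
  the Thr family is the background share (0.15 for ACG) times the planted
  enrichment, realized by exact integer codon counts (60 Thr codons in a
  300-codon CDS) so zero-noise recovery is exact.  Induced genes carry an
  elevated log2FC (default +4) with Gaussian noise.
- **Peptide tables** have log-normal intensities (log2 means ~N(25, 2),
  replicate sd 0.3), *intensity-dependent* missingness (logistic in log2
  intensity, calibrated to the requested overall rate) so detection-limit
  imputation is genuinely exercised, substituted-variant rows planted at
  exact per-strain observation rates, and a planted differential set
  (default effect 1.2 log2 units = 4 replicate sd).  Scale mirrors the
  modeled study where useful (2,047 quantifiable rows with 132 planted
  differentials as a scaled fixture; triplicate samples per strain).  Not
  emulated: spectra, peptide-to-protein inference, batch effects.

Passing tests on these fixtures demonstrates correctness of the
*computations* under known truth — recovery of planted signals at the
stated tolerances — not performance on real data, where alignment
ambiguity, modification chemistry and unmodeled noise enter.

## Problem sizes and tolerances in the test suite

Oracle-equivalence checks run 50 seeded pools (120 genes) against a full
all-pairs scan, and 20 random additive matrices (5–9 taxa) for NJ with a
1e-9 path-length tolerance.  Variant-scan round trips run 50 seeded
genomes (plus explicit all-plus/all-minus strand-invariance fixtures).
Statistical calibration uses 10,000 Kruskal–Wallis null datasets
(rejection rate 0.05 ± 0.01), 400 permutation-p uniformity simulations
(KS at α = 0.01), and 20 seeded FDR datasets of 500 rows (mean sensitivity
≥ 0.9, mean observed FDR ≤ 0.1 at nominal 0.05).  These sizes were chosen
to give stable verdicts at desk scale; all thresholds are stated in the
tests themselves.

## Known limitations

The energy model is intentionally coarse (no dangles, no coaxial stacks,
representative G·U parameters); only orderings among alleles of the same
structure are meaningful.  The switch scan assumes pools of comparable
paralogs; it does not align tRNAs against genomes.  The FDR estimator's
permutation space is small for triplicate designs (20 assignments), which
limits per-row p resolution — the SAM-style pooled null compensates but
exact per-row calibration is approximate.  Variant scanning handles SNVs
only.  The tetrad model has no partial penetrance or germination noise.
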