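# Methods

## Problem setting

Large germplasm collections (the motivating case is rose gene banks, where
most cultivars are tetraploid) are fingerprinted with small panels of
biallelic SNP markers assayed by allele-specific PCR (KASP/PACE-type
chemistry). Each assay produces two endpoint-fluorescence channels, one per
allele; a tetraploid sample carries 0–4 copies of the B allele, so the
B-allele signal fraction clusters into five groups along the ratio axis.
The pipeline covers dosage calling from those signals, marker quality
statistics, robustness of the calls to the grouping of samples, molecular
identity analysis over dosage profiles, and amplicon-haplotype
discrimination — with a synthetic-data generator that reproduces the
plate-based structure of such a study so every stage is testable.

## Signal model and dosage caller

The two channels (a, b) are collapsed to the ratio r = b/(a + b) ∈ [0, 1].
The proportion is used rather than an angle transform: it is monotone
equivalent for clustering and keeps the contract simple; the transform is
isolated in `transform_signal` so a variant can be swapped in. Wells with
zero total signal are unprocessable and become missing calls, never
exceptions.

Within one *analysis unit* — the group of samples modelled together, either
a pooled 384-well run or one 95-sample source plate — the ratios are fitted
with a (ploidy + 1)-component Gaussian mixture. Dosage calling from
endpoint fluorescence is inherently *relative*: nothing in a single well
says "dosage 2"; only the sample's position among the unit's clusters
does. Two design consequences follow.

1. **Locations affine in dosage.** The EM constrains component locations
   to μ_d = α + β·d with β > 0, estimated by responsibility-weighted least
   squares in the M-step. An unconstrained mixture shifts *all* class
   labels in a unit that happens to lack one dosage class (common in
   95-sample units for markers with skewed dosage frequencies), because
   likelihood alone cannot identify labels. With the affine constraint the
   occupied clusters pin down α and β and an empty class keeps its correct
   position with a floored weight. This mirrors how established polyploid
   callers link cluster means to allele dosage.
2. **Canonical initialisation.** EM starts at α = 0.1, β = 0.8/ploidy —
   clusters evenly spaced and pulled slightly inward from the axis ends, as
   competitive allele-specific PCR produces. Initialisation is fully
   deterministic; identical inputs give bit-identical calls. Assays whose
   cluster geometry deviates grossly from this basin (e.g. all five
   clusters compressed into a third of the axis) are outside the caller's
   design envelope and should be inspected.

After the constrained fit, a free-location EM refinement is run from the
constrained solution and accepted only if it raises the likelihood without
moving any location by more than half the class spacing — flexibility for
unequally spaced clusters without re-labelling. Per-class scales are
floored at 1e-4 and weights at 1e-6 (renormalised) to prevent degenerate
collapse. If the fitted spacing collapses below max(2e-3, twice the median
component scale) the unit is effectively monomorphic — one unresolvable
cluster — and the caller anchors that cluster to the dosage class whose
canonical ratio d/ploidy is nearest, assigning it all the weight. A unit
with fewer usable samples than mixture components raises a fit error and
leaves its cells missing.

Calls use Bayes' rule on the fitted mixture: a sample is assigned the
posterior-argmax class iff the posterior reaches `posterior_threshold`
(default 0.95, matching the upstream tool's p.threshold setting used in
this kind of study); otherwise missing. The `dip_filter` flag is accepted
for config parity and is a no-op. Source plates whose missing fraction
strictly exceeds 20% are flagged for a repeat assay.

## Marker quality and selection

Evenness of the dosage-class proportions p_i is I = H_S / ln(S) with
H_S = −Σ p_i ln p_i and S the number of dosage classes (five for
tetraploids; 0·ln 0 := 0). Using the class count rather than the ploidy in
the denominator is deliberate: it is the only convention under which the
published per-marker worked examples reproduce, and it makes I = 1 exactly
at uniform occupancy. The chip-selection filter applies three criteria to
a samples × classes posterior table: every class holds ≥ 10% of samples
(by argmax, i.e. cluster occupancy before threshold calling), ≥ 90% of
samples have max posterior ≥ 0.99, and the mean max posterior is ≥ 0.99.
Panel coverage requires at least two markers on each of the seven
chromosomes.

## Layout robustness

Each marker is called twice: per pooled analysis plate ("original") and
per 95-sample source plate ("single"). Disagreement is computed over cells
called in both layouts (the only denominator under which the fraction is
well defined), broken down by |Δdosage| 1–4. Markers with disagreement
strictly above 10% are excluded. Combining layouts takes the union of
calls; when both layouts call a cell differently the higher-posterior call
wins and the cell is recorded as a conflict (when posteriors are absent
the single-layout call wins, deterministically). A conflicted cell counts
as called, which is what makes the combined call rate ≥ each input's rate
for every marker. The "robust subset" — accessions called completely and
identically in both layouts over the panel — is unaffected by the
conflict-winner choice, since any conflicted accession is excluded anyway.

## Identity analysis

Pairwise profile distance is the Chebyshev (maximum) metric over mutually
scored markers; pairs sharing no scored marker are flagged NaN rather than
given a fabricated extreme value. An assumed-duplicate pair is
*inconclusive* when more than four of the 18 panel markers are unscored in
either member; otherwise it is *identical* (0 differences over mutually
scored markers), *diff_1_3* (1–3) or *diff_gt3* (> 3). Missing markers are
counted pair-wise (unscored in either member) and differences over the
intersection only. Identity clusters are groups of ≥ 2 accessions with
exactly identical complete profiles, computed on the robust subset. The
combinatorics helpers give the smallest m with 5^m ≥ n (six markers for a
collection of 4,187) and exact 5^m capacities.

## Amplicon haplotypes

Genotypes with total reads < 100 are removed, then haplotypes below 10% of
a genotype's reads are zeroed (both strict; thresholds are configurable —
50 reads reproduces the lower-coverage sensitivity variant). The two rules
are re-applied to a fixpoint so that filtering is idempotent: zeroing can
push a genotype's retained total under the read threshold, and a filtered
table must be stable under re-filtering. The first iteration is exactly
the two-rule pass, so threshold boundary behaviour is unchanged.

A genotype's four chromosome copies are apportioned among its retained
haplotypes by largest-remainder rounding of ploidy × read fraction, every
retained haplotype receiving ≥ 1 copy and the dosages summing exactly to
the ploidy; ties break toward the higher-count haplotype, then
lexicographic id. A mixture fit per genotype is not possible (one
genotype's read fractions carry no cohort information), hence the
deterministic rounding rule. Genotypes retaining more haplotypes than the
ploidy are flagged and excluded from discriminability counting.
Polymorphic sites are alignment columns with > 1 distinct symbol, the gap
counting as a symbol (a 2-bp indel counts as two columns). Marker
combination counts distinct joint haplotype-dosage multiset pairs over
genotypes retained in both markers. Concordance against a reference dosage
matrix reports per-marker identical/differing/unscored counts and an
overall agreement over cells scored by both methods.

## Synthetic data

The generator emulates the study structure: per-marker dosage-class
frequencies from a symmetric Dirichlet (default concentration 5, giving
the 0.74–1.0 evenness spread seen across real fingerprinting panels),
dosages drawn per accession, source plates of 95 samples + 1 negative
control pooled four-per-384-well analysis plate, cluster locations
(0.1, 0.3, 0.5, 0.7, 0.9) with Gaussian noise (σ = 0.02 "easy" preset;
σ = 0.07 "hard" preset exercising threshold-driven missingness), per-well
dropout (default 2%, emitting zero signals → missing calls), injected
duplicates (copied dosage vectors under new ids) and mislabels (swapped
vectors behind fixed labels), and multinomial amplicon reads with
probabilities dosage/ploidy. All randomness flows from one master seed
through named SHA-256-derived substreams, so each operation is
independently reproducible.

What the generator does *not* emulate: instrument-specific fluorescence
drift between runs, triploid off-grid clusters (noted as an extension
hook), cluster-location asymmetry, read chimeras or sequencing error in
amplicons. Passing tests therefore demonstrate the statistical contract of
the pipeline under the stated cluster geometry, not robustness to assay
chemistry pathologies.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 300–500
accessions × 18 markers (two layouts, ~9,000–18,000 mixture calls) and
95-genotype amplicon tables — sizes chosen so a complete run finishes in a
few seconds while every structural feature of the study design (multiple
analysis plates, multiple source plates per plate, skewed markers, empty
classes) is exercised. EM convergence is |Δ log L| < 1e-8 (relative),
capped at 500 iterations. Posterior rows sum to 1 within 1e-9; evenness
input proportions must sum to 1 within 1e-6.

## Known limitations

- The caller's label identification relies on the canonical ratio-axis
  geometry; assays with strongly compressed or shifted cluster positions
  can be mis-anchored (the dual-layout disagreement filter is the safety
  net, as it is for the wet-lab assay itself).
- Monomorphic units are anchored by cluster position alone; a monomorphic
  marker whose single cluster sits midway between canonical positions is
  assigned the nearest class.
- Ploidies other than 4 are supported by the caller (n_classes =
  ploidy + 1) but the pipeline defaults, like the study design it mirrors,
  treat all samples as tetraploid; mixed-ploidy panels are not modelled.
- ROX normalisation of exported signals is assumed to have happened
  upstream; the reader treats the two channels as directly comparable.
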