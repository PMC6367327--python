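# Methods

## The analysis model

`snvaudit` treats variant-pathogenicity prediction as a measurement
problem with four levels of structure.

**Variant and site level.** One record is one observed single-nucleotide
change (multi-allelic positions are separate records sharing a site key;
coordinates are 1-based, fully closed, VCF convention). A site's class is
determined by pooling the clinical-significance terms of every allele
observed there: *pathogenic* if pathogenic evidence is present and benign
evidence absent, *benign* symmetrically, *both* with evidence of each
kind, *other* with neither. The term map is configurable; by default
`Pathogenic`, `Likely pathogenic` and `Pathogenic/Likely pathogenic`
count as pathogenic evidence, the benign triple symmetrically, and every
other term (`Uncertain significance`, `risk factor`, `Association`,
`Protective`, …) as no evidence. Whether "Likely" labels count as
evidence is genuinely open; making them count is this package's default
and is exposed as configuration. HGMD-style class codes provide an
independent arm: `DM` flags a disease-causing mutation; the broader
disease classes (`DM?`, `DP`, `DFP`, `FP`) matter only for the
back-mutation report.

**Prediction tools.** The fixed panel holds 12 predictors whose scores
are consumed as dbNSFP-style rank scores in [0, 1] (a raw score
transformed to its quantile rank over a reference collection). A score
strictly above the tool's cutoff is a pathogenic call; all cutoffs
default to 0.5 on the rank-score scale — the rule that is explicit for
CADD and DANN — and can be overridden per tool. Missing scores propagate
as no-calls rather than being imputed.

**Metric conventions.** Tool subsets are combined under the all-agree
rule: a subset classifies a variant only when every member gives the same
binary call; disagreement or any missing member score is a no-call, and
no-calls stay in the denominators (sensitivity = TP / all pathogenic,
specificity = TN / all benign, accuracy over all labeled variants;
undefined metrics are reported as missing, never as 0). Sites classified
*both* or *other* are excluded from evaluation truth. Under these
conventions, enlarging a subset can only shrink the called set, so along
any chain of nested subsets sensitivity is non-increasing and the
false-alarm rate FP / all-benign is non-increasing. Note the asymmetry:
with no-calls penalizing both arms, *reported* specificity
(TN / all benign) also shrinks as subsets grow; it is specificity in the
1 − FPR sense — the rate of false alarms — that the all-agree rule
monotonically improves. Both quantities are derivable from the reported
confusion tables; the monotonicity property tests assert the sensitivity
and false-alarm-rate forms.

**Conservation stratification.** Errors are stratified at a vertebrate
phastCons cutoff of 0.5 (high iff score ≥ cutoff; the boundary convention
is immaterial in practice because phastCons values are continuous, and
the tests confirm cohort-level insensitivity to nudging the cutoff). The
enrichment test is Pearson's χ² without continuity correction on the 2×2
table (error group vs background) × (high vs low), where the background
is *all* annotated positions of the same truth class, error group
included — mirroring a dashed-line reference against the overall
proportion. Because group ⊂ background, the test is conservative; a group
coinciding with its background yields χ² = 0, p = 1 exactly. Significance
stars follow * p < 0.05, ** p < 10⁻⁵, *** p < 10⁻¹⁰. phyloP panels are
summarized descriptively (sign counts, location, scale) with no attached
hypothesis test. Positions lacking conservation scores drop out of both
group and background.

**Back mutations.** A variant is a back mutation when an ancestral call
is present, its allele equals the alternative allele and differs from the
reference; low-confidence calls (lowercase in 1000G-style input, mapped
to an explicit confidence on ingestion) are excluded unless requested.
The bundled catalog of pathogenic back mutations qualifies a variant when
any ClinVar pathogenic-evidence term is present on the record (benign
co-annotations do not disqualify — several catalog entries carry both) or
its HGMD class is any disease class. Restricting HGMD to `DM` only is a
parameter.

**Four-allele statistics.** At a non-degenerate site each tool implicitly
scores the four possible nucleotides. The reference allele's score is not
produced by any tool; the default convention scores it 0 (no change ⇒ no
predicted deleteriousness). Because every downstream CV magnitude depends
on this choice, the conventions `mean-of-alts` (reference gets the mean
of the three alternatives) and `exclude-and-rescale` (statistics over the
three alternatives, divisor 2) are first-class, and the pipeline emits
the group-comparison report under each configured convention. With k
scores, μ = Σ S/k and σ uses divisor k − 1; k = 4 under the default and
mean-of-alts conventions, matching the divisor-3/mean-4 formulas. CV is
undefined (reported missing) at μ = 0. Non-degeneracy is an input flag;
the pipeline does not compute codon degeneracy (no transcript model in
scope).

**Gene level.** The pathogenic proportion behind the disease-sensitive
class (> 30 %, strict) uses the number of annotated variant sites in the
gene (sites in any of pathogenic/benign/both, or DM) as denominator;
using polymorphic-site counts instead is configurable. Disease-tolerant
requires zero pathogenic and zero DM sites and strictly more than 50
polymorphic sites. Tissue specificity is the information content
log₂ n + Σ pᵢ log₂ pᵢ with p log p ≔ 0 at p = 0; base 2 is used for both
terms so the score spans [0, log₂ n] (the printed source formula leaves
the inner base ambiguous; any other base would break that range). Ranked
PPI degree uses ascending mean ranks for ties divided by the number of
ranked genes. Exon-length/occurrence correlation is Pearson on log–log
values.

**PolyComb overlap.** BED intervals are 0-based half-open; a 1-based
position p is covered iff start ≤ p − 1 < end, and the conversion lives
in one place. The per-site statistic is the fraction of *all* supplied
epigenomes whose segmentation puts the site in the state (epigenomes with
no data at that chromosome count as not-in-state, matching a
percentage-of-cell-types reading); restricting the denominator to
covered epigenomes is an option. ReprPC, ReprPCWk and their union event
are all reported, since it is unknowable from the analysis alone whether
the two states should be pooled.

## Statistical engines

- Pearson χ² (2×2) is computed from the contingency formula with the
  χ²₁ upper tail; a zero row or column margin returns (0, 1). Verified
  against `scipy.stats.chi2_contingency(correction=False)`.
- The Wilcoxon rank-sum test enumerates the exact permutation null
  (tie-aware, via midranks) whenever C(n₁+n₂, n₁) ≤ 20 000 — full
  enumeration at the classical "n ≤ 50" boundary is combinatorially
  impossible (C(50,25) ≈ 1.3 × 10¹⁴), so the exact path is bounded by
  enumeration cost instead. Above the bound: normal approximation with
  tie correction and no continuity correction, so identical samples give
  p = 1 exactly. Simulated type-I error at cohort-typical sizes is
  0.04–0.05 at α = 0.05.
- Two-sample KS uses the exact null distribution below combined n = 35
  and the asymptotic distribution above
  (`scipy.stats.ks_2samp`).
- All small-sample paths are tested to 1 × 10⁻⁹ against independently
  coded brute-force enumerations.

The chromatin-state interval index is a sorted start/end array pair per
(epigenome, chromosome) queried by binary search — valid because a
segmentation's intervals are non-overlapping (enforced when the index is
built) — and is verified against a linear interval scan.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
real genomes: plausible formatting (22 chromosomes, 1 Mb gene blocks,
sites 200 bp apart), no linkage, no realistic allele-frequency spectrum,
no transcript structure. Passing recovery tests therefore demonstrates
that the pipeline detects the targeted effect structure at realistic
sizes and rejects at the nominal rate in its absence — not that any
particular real dataset would show those effects.

Defaults (one cohort ≈ 2 000 variants): 500 genes, Poisson(4) variants
per gene; site-class fractions 0.22 / 0.33 / 0.03 / 0.42 for
pathogenic / benign / both / other; P(DM | pathogenic) = 0.6 with a 2 %
DM rate elsewhere. Exon lengths are log-normal around 1.5 kb;
polymorphic-site rates are 15 + Gamma(2, 7.5) per Kb capped at 80 (mean
30/Kb). Expression spans 53 tissues; PPI degrees are log-normal.

Scores follow a multiplicative model: each (site, tool) draws a location
m from a Beta around the class mean (benign 0.42, other 0.38, both 0.55;
per-tool deterministic offsets of ±0.08 spread the panel so pairwise
agreement is non-trivial), and the three alternative-allele scores are
m·(1 + d·ε) with ε ~ U(−1, 1) and d the class's relative dispersion.
Since CV = σ/μ is scale-free, the quartet CV depends only on d, never on
m — the location knob (pathogenic mean = benign + 0.36) moves only the
maximum, and the dispersion knob (pathogenic d = 0.28 − 0.20 = 0.08)
only the CV, making the two planted effects exactly separable. Locations
are capped at 1/(1 + d) so no clipping re-couples them.

Planted effects, each with a zero setting for null cohorts:

- **over-reliance** — for three designated tools, scores mix 60 % toward
  the site's vertebrate phastCons value, producing false positives at
  conserved benign sites and false negatives at unconserved pathogenic
  sites;
- **gene-level coupling** — a standard-normal gene propensity z allocates
  pathogenic sites with weights ∝ exp(1.2 z) and couples expression
  abundance, dominant-tissue share and degree to z with loading 0.75;
  these strengths were chosen so the planted shifts are decisively
  detectable (p ≲ 10⁻⁴) at 500 genes;
- **PolyComb upshift** — pathogenic/DM sites with phastCons < 0.5 (the
  sites conservation-leaning tools will miss) get +0.25 on their ReprPC
  and ReprPCWk membership probabilities (base 0.12 each); every
  (site, epigenome) pair draws exactly one state from a six-state
  vocabulary, so fractions over the full vocabulary sum to 1.

All randomness flows from one seed through `SeedSequence.spawn`, one
child stream per stage (genes, sites, scores, conservation, ancestral,
expression, chromatin); the same seed yields byte-identical bundles, and
every file round-trips through the package's own readers.

## Recovery testing

A planted effect counts as *detected* only when the test rejects at
α = 0.05 **and** the observed difference points in the planted direction
(error proportion above background; pathogenic maximum up and CV down;
gene-group distributions shifted up; FN fractions above TP) — a
wrong-sign rejection is a false alarm, not a recovery. All comparison
reports carry group medians so direction is always visible next to the
p-value. The acceptance study runs 20 planted and 20 null cohorts at the
default size (≈ 2 000 variants, 500 genes, 127 epigenomes); each headline
effect must be detected in ≥ 18/20 planted replicates and in ≤ 2/20 under
the null generator (and for tools without the planted effect). Problem
sizes for the routine unit-test cohort are smaller (60 genes, 10
epigenomes) — enough for direction and round-trip checks while keeping
the default test run fast.

## Known limitations

- Real-data mode expects pre-annotated inputs (rank scores, conservation,
  ancestral calls, non-degeneracy flags, expression, degrees, chromHMM
  BED); the package performs no liftover, transcript mapping, raw-score
  recomputation, or network construction.
- The per-tool default cutoff of 0.5 on rank scores is a uniform stand-in
  for tool-specific published thresholds; real analyses should override
  per tool.
- The χ² enrichment design (group vs overlapping background) is
  deliberately conservative; its p-values understate evidence slightly
  when the error group is a large share of the background.
- Functional enrichment of gene sets, orthologue-tree inference,
  meta-predictor training, and protein-domain analyses are out of scope.
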