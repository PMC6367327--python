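# snvaudit

Multi-level audit of non-synonymous SNV pathogenicity predictions.

Computational predictors of variant pathogenicity (SIFT, PolyPhen-2, CADD,
DANN, MutationTaster, the FATHMM family, PROVEAN, MutationAssessor, the
MetaSVM/MetaLR meta-predictors) disagree with each other far more than their
published benchmarks suggest, and their errors are not random: they cluster
at particular conservation regimes, in particular genes, and at particular
chromatin states. `snvaudit` is a library for clinical-genetics and
variant-interpretation researchers that quantifies those failure modes on a
common footing:

- **Site classification.** Genomic sites are classified from the clinical
  annotations of their observed alleles into four exclusive groups —
  *pathogenic*, *benign*, *both* (conflicting alleles), *other* — with
  HGMD-style DM ("disease-causing mutation") flags as an independent arm.
- **Tool evaluation.** Per-tool confusion metrics on dbNSFP-style rank
  scores in [0,1] (score > 0.5 ⇒ pathogenic), pairwise agreement, and an
  exhaustive scan of all 2¹² − 1 = 4095 tool combinations under the
  *all-agree* rule: a subset classifies a variant only when every member
  tool gives the same call, and no-calls count against sensitivity.
- **Conservation stratification.** For each tool, the excess of false
  positives at highly conserved positions (vertebrate phastCons ≥ 0.5) and
  of false negatives at weakly conserved positions, tested with Pearson's
  χ² against the background of all annotated positions of the same class;
  plus a catalog of pathogenic *back mutations* — variants whose
  alternative allele restores the inferred ancestral state.
- **Four-allele site statistics.** At non-degenerate sites, the maximum of
  the scores assigned to the four nucleotides, and their coefficient of
  variation CV = σ/μ with μ = Σᵢ Sᵢ/4 and σ = √(Σᵢ(Sᵢ−μ)²/3): a low CV
  marks a site intolerant to *any* change. Group differences are tested
  with two-sided Wilcoxon rank-sum tests.
- **Gene level.** Polymorphic-site rates per Kb of exon,
  disease-sensitive (>30 % of annotated sites pathogenic) and
  disease-tolerant (no pathogenic annotation despite >50 polymorphic
  sites) gene classes, and Kolmogorov–Smirnov comparisons of gene groups
  on expression maximum, tissue specificity (information content
  log₂n + Σᵢ pᵢ log₂ pᵢ over n = 53 tissues) and ranked
  protein–protein-interaction degree.
- **PolyComb overlap.** Per site, the fraction of reference epigenomes
  (chromHMM segmentations, 127 by default) placing it in repressed
  PolyComb state (ReprPC / ReprPCWk / their union), compared between site
  classes and between false-negative and true-positive predictions.

A seeded synthetic-cohort generator (`snvaudit.synthetic`) emits the full
input bundle — variant table, gene metadata, expression matrix, PPI
degrees, chromatin-state BED — with configurable planted effects and truth
tables, so every analysis stage has a recoverable ground truth.

## Worked example

```python
from snvaudit.site_stats import assemble_quartet, quartet_max, quartet_cv

q = assemble_quartet({"C": 0.4, "G": 0.6, "T": 0.8}, ref="A", tool="SIFT")
print(quartet_max(q), round(quartet_cv(q), 6))
```

```
0.8 0.759033
```

The site's worst substitution has rank score 0.8; with the reference
allele scored 0 (no change, no predicted damage), the four scores
(0, 0.4, 0.6, 0.8) give CV = σ/μ = 0.759033 — a dispersed quartet, i.e. a
site whose predicted impact depends noticeably on *which* change occurs.

```python
from snvaudit.conservation import load_back_mutation_catalog, back_mutation_report

table, summary = back_mutation_report(load_back_mutation_catalog().variants)
print(summary)
```

```
{'n_variants': 35, 'n_genes': 33}
```

The bundled catalog holds 35 non-synonymous variants in 33 genes whose
alternative allele reverts to the high-confidence ancestral nucleotide yet
which carry pathogenic annotation from ClinVar and/or an HGMD disease
class — cases where the *derived* allele is the healthy state.

The `examples/` directory has one narrative script per capability
(`python examples/02_combination_scan.py` runs the 4095-subset scan on a
synthetic cohort and prints the per-size summary). A thin CLI mirrors the
library: `snvaudit generate`, `snvaudit run-all --config run.yaml`, plus
per-stage subcommands (`classify`, `evaluate`, `conservation`, `sites`,
`genes`, `polycomb`).

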