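"""Conservation stratification of prediction errors, and pathogenic back mutations.

Asks two questions: (1) are a tool's false positives concentrated at
highly conserved positions (phastCons >= 0.5) beyond the background of all
benign variants? (2) which variants restore the ancestral allele yet carry
pathogenic annotation?
"""

import tempfile

from snvaudit import TOOLS, annotate_sites, parse_variant_table
from snvaudit.conservation import (
    back_mutation_report, error_conservation_profile, load_back_mutation_catalog,
)
from snvaudit.pipeline import build_calls, variant_labels
from snvaudit.synthetic import CohortConfig, generate_cohort

with tempfile.TemporaryDirectory() as tmp:
    paths = generate_cohort(CohortConfig(seed=3, n_genes=150, n_epigenomes=4), tmp)
    variants = parse_variant_table(paths["variants"]).variants

annotations = annotate_sites(variants)
calls = build_calls(variants)
labels, _ = variant_labels(variants, annotations)
cons = [pv.conservation.phastcons.get("vertebrate") for pv in variants]
keep = [i for i, lab in enumerate(labels) if lab is not None]
labels_k = [labels[i] for i in keep]
cons_k = [cons[i] for i in keep]

print("false-positive enrichment at highly conserved positions:")
print(f"{'tool':<16s} {'FP high/total':>14s} {'bg high/total':>14s} {'chi2':>8s}  p        stars")
for tool in ("SIFT", "PROVEAN", "CADD", "DANN"):
    calls_k = [calls[tool][i] for i in keep]
    t = error_conservation_profile(calls_k, labels_k, cons_k, "FP-at-high")
    print(
        f"{tool:<16s} {t.group_count:>6d}/{t.group_total:<7d}"
        f" {t.background_count:>6d}/{t.background_total:<7d}"
        f" {t.chi2:>8.1f}  {t.p:.2e} {t.stars}"
    )
# In this cohort SIFT and PROVEAN lean on conservation, so nearly all of
# their false positives sit at conserved positions (stars); CADD/DANN do
# not, and their FP conservation matches the background (no stars).

catalog = load_back_mutation_catalog()
table, summary = back_mutation_report(catalog.variants)
print(
    f"\nback-mutation catalog: {summary['n_variants']} pathogenic derived-to-"
    f"ancestral variants in {summary['n_genes']} genes; first rows:"
)
print(table[["gene", "hgvs", "clinvar", "hgmd_class"]].head(5).to_string(index=False))
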