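"""Gene-level disease susceptibility: rates, classes, and ECDF comparisons.

Aggregates variants per gene, computes polymorphic-site rates per Kb and
susceptibility classes, and compares genes carrying pathogenic sites
against the whole gene universe on expression maximum, tissue specificity
(information content) and ranked protein-protein interaction degree with
two-sample Kolmogorov-Smirnov tests.
"""

import tempfile

import pandas as pd

from snvaudit import parse_variant_table
from snvaudit.gene_level import build_gene_summaries, gene_group_comparisons, snv_rate, classify_susceptibility
from snvaudit.synthetic import CohortConfig, generate_cohort

with tempfile.TemporaryDirectory() as tmp:
    paths = generate_cohort(CohortConfig(seed=5, n_epigenomes=4), tmp)
    variants = parse_variant_table(paths["variants"]).variants
    gene_table = pd.read_csv(paths["genes"], sep="\t")
    expression = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    deg_df = pd.read_csv(paths["degrees"], sep="\t")

degrees = dict(zip(deg_df["gene"], deg_df["degree"]))
summaries = build_gene_summaries(variants, gene_table, expression, degrees)

rates = [snv_rate(s) for s in summaries.values() if s.n_polymorphic > 0]
print(f"{len(summaries)} genes; SNV occurrence rate "
      f"{min(rates):.0f}-{max(rates):.0f}/Kb, mean {sum(rates)/len(rates):.0f}/Kb")

classes = pd.Series([classify_susceptibility(s) for s in summaries.values()])
print("susceptibility classes:", classes.value_counts().to_dict())

cmp = gene_group_comparisons(summaries, arm="clinvar")
sub = cmp[(cmp["group_a"] == "n>0") & (cmp["group_b"] == "all")]
print("\ngenes with >0 pathogenic sites vs all genes (KS):")
print(sub[["metric", "n_a", "n_b", "median_a", "median_b", "D", "p"]].round(4).to_string(index=False))

# Pathogenic-site-bearing genes sit higher on all three distributions:
# they are more abundantly and more tissue-specifically expressed, and
# their products are better-connected network hubs.
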