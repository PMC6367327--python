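"""Classify genomic sites from clinical annotations and binarize tool scores.

Builds a five-variant table by hand, assigns each site its four-group
class (pathogenic / benign / both / other), and turns rank scores into
pathogenic/benign calls at the 0.5 cutoff.
"""

from snvaudit import annotate_sites, call_tool, parse_variant_table
import tempfile, pathlib

table = """chrom	pos	ref	alt	gene	clinvar	hgmd_class	ancestral	SIFT	CADD
1	100	A	G	BRCA1	Pathogenic	DM	A	0.91	0.88
1	100	A	T	BRCA1	Benign	.	A	0.12	0.55
2	200	C	T	TP53	Likely pathogenic	.	.	0.77	.
3	300	G	A	CFTR	Benign;Likely benign	.	a	0.08	0.21
4	400	T	C	MYH7	.	DM	T	0.66	0.70
"""

with tempfile.TemporaryDirectory() as tmp:
    path = pathlib.Path(tmp) / "variants.tsv"
    path.write_text(table)
    result = parse_variant_table(path)

print(f"parsed {len(result.variants)} variants, {len(result.errors)} malformed rows")

annotations = annotate_sites(result.variants)
print("\nsite classification (multi-allelic evidence is pooled per site):")
for (chrom, pos), ann in sorted(annotations.items()):
    print(f"  {chrom}:{pos}  group={ann.group:<10s} DM={ann.is_dm}")

print("\nbinary calls (rank score > 0.5 means pathogenic; '.' propagates):")
for pv in result.variants:
    calls = {t: call_tool(pv.scores.get(t), t) for t in ("SIFT", "CADD")}
    print(f"  {pv.record.gene:<6s} {pv.record.ref}>{pv.record.alt}  {calls}")

# The 1:100 site is classified "both": one allele has pathogenic evidence,
# the other benign evidence. The 4:400 site is "other" for ClinVar but
# carries an HGMD disease-causing (DM) flag, so it enters the DM analysis arm.
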