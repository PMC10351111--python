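"""Work with the bundled published summary statistics.

Applies the causal-classification rule to the published per-CpG coefficient
changes, reproduces the reported causal counts, and crosses the reported
DMR intervals against the top-30 CpG positions.
"""

from twinmeth import classify_printed_rows, datasets, region_site_coverage, summarize_causal_counts

rows = classify_printed_rows(datasets.causal_inference_rows())
counts = summarize_causal_counts(rows["label"])
print("causal labels over the 30 top CpGs:", counts)
print(f"  per-direction calls: {int(rows['call_meth_to_fpg'].sum())} meth->FPG, "
      f"{int(rows['call_fpg_to_meth'].sum())} FPG->meth")

top = datasets.top_cpg_associations()
print(f"top CpGs map to {top['gene'].nunique()} distinct genes")

dmrs = datasets.dmr_intervals()
hit = region_site_coverage(dmrs, top, require_gene_concordance=True)
print("regions covering top CpGs (annotation-concordant):")
for _, r in hit.iterrows():
    print(f"  DMR{r['dmr_id']} {r['chrom']}:{r['start']}-{r['end']} ({r['gene']}): "
          f"{r['covered_cpgs']} CpG(s)")
pos = region_site_coverage(dmrs, top)
print(f"(purely positional overlap touches {len(pos)} regions)")
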