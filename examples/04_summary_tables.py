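"""Reproduce the published survey arithmetic from the bundled tables.

The package ships transcriptions of the published horse splenic clonotype
survey (212 clonotypes over the 13 TRBJ genes) and the germline census
(136 TRBV genes in 29 subgroups).  The statistics layer recomputes every
derived number: totals, weighted CDR3 means, rearrangement-class
accounting and usage percentages.
"""

from equitrb.stats import (
    j_usage_from_table,
    load_reference_census,
    load_reference_j_usage,
    load_reference_v_usage,
    rearrangement_accounting,
    resolved_totals,
    summarize_germline,
    usage_percentages,
)

j_table = load_reference_j_usage()
summary = j_usage_from_table(j_table)
totals = summary.totals.set_index("scope")
print("clonotypes by TRBJ cluster:")
for scope in ("cluster1", "cluster2", "overall"):
    row = totals.loc[scope]
    print(f"  {scope:<9} n={int(row.clonotypes):<4} mean CDR3 "
          f"{row.mean_cdr3:.2f} AA (range {int(row.cdr3_min)}-{int(row.cdr3_max)})")
print(f"  TRBJ2 cluster preference: "
      f"{usage_percentages(totals.loc['cluster2'].clonotypes, totals.loc['overall'].clonotypes, 0):.0f}%")

acc = rearrangement_accounting(j_table)
print(f"\nrearrangement accounting over {acc['d_identified']} D-identified"
      " clonotypes:")
print(f"  intra-cluster {acc['intra_count']} ({acc['intra_pct']}%), "
      f"inter-cluster {acc['inter_count']}, trans {acc['trans_count']}, "
      f"not determined {acc['nd_count']}")

census = summarize_germline(load_reference_census())
f_pct = usage_percentages(census.totals["n_f"], census.totals["n_genes"], 0)
print(f"\ngermline census: {census.totals['n_genes']} TRBV genes, "
      f"{census.totals['n_f']} functional (~{f_pct:.0f}%), "
      f"{census.totals['n_p']} pseudogenes, {census.totals['n_orf']} ORF")

v_table = load_reference_v_usage()
assigned = int(v_table["clonotypes"].sum())
resolved, _ = resolved_totals(v_table, load_reference_census())
v = v_table.set_index("subgroup")
print(f"\nV-assigned clonotypes: {assigned} ({resolved} resolved to a member"
      " gene); top subgroups:")
for sg in ("TRBV20", "TRBV5", "TRBV21", "TRBV28"):
    pct = usage_percentages(v.loc[sg, "clonotypes"], assigned, 1)
    print(f"  {sg:<7} {int(v.loc[sg, 'clonotypes']):>3} clonotypes ({pct}%)")
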