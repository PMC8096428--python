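"""Ask whether mRNA mediates the age (or sex) effects on protein.

For each gene the age term's -log10 p on protein is compared between
Protein ~ Age + Sex + Generation and the same model with mRNA added.  A
positive delta (base minus adjusted) means the mRNA absorbed part of the
effect — transcriptional mediation.  In this simulated cohort age effects
on protein are direct while sex effects flow through mRNA, so the two scans
behave very differently.
"""

import duotrend as dt

mrna, protein, metadata, truth = dt.simulate_cohort(dt.CohortSimConfig(
    seed=3, n_genes_per_class={
        "concordant_up": 40, "mrna_down_protein_up": 25, "mrna_up_protein_down": 15,
        "concordant_down": 45, "mediated": 25, "null": 50,
    }))

size_factors = dt.median_ratio_size_factors(mrna)
mrna_rn = dt.rank_normal_matrix(dt.variance_stabilize(mrna, size_factors).values)
protein_rn = dt.rank_normal_matrix(protein)

for focal in ("age_coded", "sex"):
    scan = dt.mediation_scan(protein_rn.values, mrna_rn.values, metadata, focal)
    s = dt.mediation_summary(scan)
    print(f"focal={focal:>9}: median delta {s['median_delta']:+.2f}, "
          f"major-axis slope {s['major_axis_slope']:.2f}, "
          f"{s['fraction_delta_gt']:.0%} of genes drop by >{s['delta0']}")

truly_mediated = truth.index[truth["mediated"]]
scan_age = dt.mediation_scan(protein_rn.values, mrna_rn.values, metadata, "age_coded")
med = scan_age[scan_age["gene_id"].isin(truly_mediated)]
print(f"truly mediated genes only: median age delta {med['delta'].median():+.2f}")
print("delta near 0 + slope near 1 -> protein aging is independent of mRNA;")
print("large positive delta -> the effect is transcriptionally mediated.")
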