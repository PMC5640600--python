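"""Run the per-SNP association scans and look at the two regional patterns.

The eQTL scan regresses expression on dosage (OLS, t test); the disease
scan fits a per-SNP logistic regression (Wald test). Both report the
effect of allele 1, the ingredients of the DEC statistic.
"""

from decstat import SimulationConfig, disease_scan, eqtl_scan, generate_dataset

cfg = SimulationConfig(
    n_individuals=2000, n_snps=200,
    causal_index_expr=100, h2_expr=0.2,
    causal_index_dis=100, log_or_dis=0.4,
    seed=1,
)
data = generate_dataset(cfg)

scan_e = eqtl_scan(data)
scan_d = disease_scan(data)

top_e = min(scan_e, key=lambda r: r.p)
top_d = min(scan_d, key=lambda r: r.p)

print(f"{'scan':<10}{'top SNP':<12}{'beta':>8}{'p':>12}{'log10(1/p)':>12}")
print(f"{'eQTL':<10}{top_e.snp_id:<12}{top_e.beta:>8.3f}{top_e.p:>12.2e}"
      f"{top_e.log1p:>12.2f}")
print(f"{'disease':<10}{top_d.snp_id:<12}{top_d.beta:>8.3f}{top_d.p:>12.2e}"
      f"{top_d.log1p:>12.2f}")
print()
print(f"informative SNPs (log10(1/p) >= 1.2 in either scan): "
      f"{sum(1 for a, b in zip(scan_d, scan_e) if a.log1p >= 1.2 or b.log1p >= 1.2)}")
print()
print("Both scans peak at the shared causal SNP (snp0101 = index 100); the")
print("positive betas mean allele 1 raises expression and disease risk alike.")
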