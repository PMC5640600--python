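"""Assess DEC significance with the LD-preserving in-silico eQTL null.

For every SNP in the region an artificial expression trait driven by that
SNP (explaining the same variance as the true eQTL) is rescanned on the
real genotypes and scored with DEC against the fixed disease pattern; the
empirical p-value is the fraction of simulated DEC >= the observed DEC.
"""

from decstat import (
    NullConfig, SimulationConfig, compute_dec, dec_significance,
    disease_scan, eqtl_scan, generate_dataset, harmonize,
)

cfg = SimulationConfig(
    n_individuals=2000, n_snps=200,
    causal_index_expr=100, h2_expr=0.2,
    causal_index_dis=100, log_or_dis=0.4,
    seed=1,
)
data = generate_dataset(cfg)

scan_e = eqtl_scan(data)
scan_d = disease_scan(data)
observed = compute_dec(harmonize(scan_d, scan_e))
null = dec_significance(data, scan_d, scan_e, observed,
                        null_config=NullConfig(seed=1))

print(f"observed DEC:           {null.observed_dec:+.3e}")
print(f"variance explained r2:  {null.r2_used:.3f} (sample R^2 at top eQTL SNP)")
print(f"simulated eQTLs:        {null.n_sims} (one per SNP in the region)")
print(f"simulated DEC >= obs:   {null.n_exceed}")
print(f"empirical p-value:      {null.p_empirical:.3f}")
print()
print("A small p says real colocalization beats LD-matched artificial eQTLs:")
print("the shared-variant signal is not explained by the region's LD alone.")
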