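"""Infer the number of founders by coalescent simulation and rejection ABC.

The observed distribution of founder-haplotype counts across genomic blocks
is compared with the lineage-count distributions produced by a coalescent
under linear population growth from Nf founders to the contemporary size N0.
Rejection ABC keeps the simulations closest to the observation, giving a
posterior for Nf.  Run here on the observed 2,648-block table of the
15-accession cohort, at a scaled-down simulation count.
"""

from allofound import FounderDistribution, abc_posterior, founder_lower_bound

# blocks whose accessions split into 1, 2, 3 and 4 founder clusters
observed = FounderDistribution({1: 1273, 2: 1267, 3: 106, 4: 2})
print(f"observed blocks: {observed.counts} (total {observed.total})")
print(f"hard lower bound on founders: {founder_lower_bound(observed)}")

result = abc_posterior(
    observed, n0_fixed=5_000.0, nf_prior=(1.0, 1_000.0),
    n_sims=50_000, n_keep=500, n_loci=2_648,
    t_query=16_000.0, T=16_000.0, n_samples=15, seed=1,
)
q05, q25, q50, q75, q95 = result.posterior_quantile([0.05, 0.25, 0.5, 0.75, 0.95])
print(f"ABC posterior for Nf (founders), {result.n_keep}/{result.n_sims} accepted:")
print(f"  median {q50:.0f}, IQR [{q25:.0f}, {q75:.0f}], 90% interval [{q05:.0f}, {q95:.0f}]")
print("-> half the observed blocks retain two or more founder lineages, so at")
print("   N0 = 5,000 the fit pushes Nf toward the top of the prior: the summary")
print("   only says the bottleneck was weak, not how many founders there were.")
print("   The haplotype-count lower bound remains the firmest statement.")
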