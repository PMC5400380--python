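"""Find the longest shared (identical-by-descent-like) haplotype.

Scans a polyploid accession against parental-panel accessions for the
longest genomic interval whose mismatch proportion stays below an error
threshold.  Against the true founder the shared segment spans most of the
genome (only post-founding mutations interrupt it); against an unrelated
panel member it is much shorter.
"""

from allofound import (
    FoundingScenario,
    closest_accessions,
    longest_shared_haplotype_tables,
    simulate_scenario,
)

scenario = FoundingScenario(k_founders=1, L=1_000_000, n_parentA=6, n_parentB=6,
                            missing_rate=0.0, founder_correlation=1.0, seed=52)
sim = simulate_scenario(scenario)
founder = sim.panelA.accessions[sim.truth.founder_accessions["A"][0]]

ranking = closest_accessions(sim.subgenomeA, sim.panelA)
print("panel accessions ranked by minimal divergence to the cohort:")
print(ranking.head(3).to_string(index=False))
print(f"(true founder: {founder})")

for name in (founder, ranking["accession"].iloc[-1]):
    share = longest_shared_haplotype_tables(
        sim.subgenomeA, sim.panelA, "suecica_00", name, max_error=2e-4,
    )
    print(f"suecica_00 vs {name}: longest shared interval "
          f"[{share.start:,}, {share.end:,}) = {share.length:,} bp "
          f"({share.n_mismatches} mismatches)")
print("-> a multi-hundred-kb segment at <0.02% mismatch marks descent from")
print("   the same founder haplotype rather than mere species-level relatedness.")
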