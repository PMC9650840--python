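"""Decide whether a species is truly clonal, two independent ways.

Simulates one strictly clonal and one heavily recombining population,
then applies (i) the simulation test — is the observed homoplasy ratio
h/m within 3 resampling SDs of a diversity-matched clonal simulation? —
and (ii) the LD test — does linkage disequilibrium (r^2) decay with
genomic distance?
"""

import coreflow as cf
from coreflow.ld import run_ld_clonality_test

for label, rate in (("clonal population", 0.0), ("recombining population", 0.02)):
    tree = cf.simulate_tree(15, "yule", depth=0.01, seed=3)
    params = cf.default_params(tree, length=60_000, target_pi=0.02)
    aln, _ = cf.simulate_population(
        params, recombination_rate=rate, tract_mean=15_000, seed=3
    )
    verdict, real, sweep = cf.run_clonality_simulation_test(aln, seed=3)
    ld = run_ld_clonality_test(aln)
    print(f"{label} (gene conversion rate {rate}):")
    print(
        f"  h/m = {verdict.real_ratio:.4f}  clonal-null h/m = {verdict.null_ratio:.4f}"
        f"  (3-SD band +-{3 * verdict.sd:.4f}, rescale factor {sweep.factor:.2f})"
    )
    print(f"  simulation test: clonal = {verdict.clonal}")
    print(f"  LD test: Spearman rho = {ld.rho:.2f}, p = {ld.p_value:.2g}, clonal = {ld.clonal}")
    print()

print(
    "The clonal population's h/m is fully explained by convergent mutation\n"
    "(within the 3-SD band) and its r^2 shows no distance decay; the\n"
    "recombining population exceeds the clonal null and its LD decays."
)
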